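"""Summary statistics and report generation.

Counts structural-role classes and their union over unique missense
variants, compares ΔΔG_fold distributions between clinical classes per
domain (Wilcoxon rank-sum), correlates the two physiologic conditions and
conservation with stability (Spearman), and writes deterministic TSV/JSON
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stability import StabilityRecord, Thresholds
from .structural_annotation import RoleFlags
from .structure_io import DomainMap
from .variant_catalog import Variant

__all__ = [
    "AnnotatedVariant",
    "ClassCounts",
    "DomainDistribution",
    "spearman_rho",
    "rank_sum_test",
    "class_counts",
    "residue_coverage",
    "ddg_distribution_compare",
    "conservation_vs_stability",
    "generate_report",
]


@dataclass
class AnnotatedVariant:
    """One unique missense variant with all per-variant results attached."""
    variant: Variant
    flags: RoleFlags = field(default_factory=RoleFlags)
    stability: StabilityRecord | None = None
    conservation_z: float = float("nan")

    @property
    def delta_category(self) -> str | None:
        if self.stability is None or self.stability.is_partial:
            return None
        return self.stability.delta_category()


@dataclass
class ClassCounts:
    n_total: int
    n_conserved: int
    n_disulfide: int
    n_ca: int
    n_union: int
    n_by_clinical: dict[str, int]
    n_delta: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_union > self.n_conserved + self.n_disulfide + self.n_ca:
            raise ValueError("union exceeds the sum of class sizes")
        if self.n_union > self.n_total:
            raise ValueError("union exceeds the variant total")
        if sum(self.n_by_clinical.values()) != self.n_total:
            raise ValueError("clinical counts must partition the total")

    def percentages(self) -> dict[str, int]:
        """Counts as integer percentages of the total (half-up rounding)."""
        import math
        if self.n_total == 0:
            return {}
        def pct(n: int) -> int:
            return int(math.floor(n / self.n_total * 100 + 0.5))
        out = {"conserved": pct(self.n_conserved),
               "disulfide": pct(self.n_disulfide),
               "ca": pct(self.n_ca), "union": pct(self.n_union)}
        n_complete = sum(self.n_delta.values())
        if n_complete:
            for k, v in self.n_delta.items():
                out[f"delta_{k}"] = int(
                    np.floor(v / n_complete * 100 + 0.5))
        return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the first sample.  The exact
    null distribution is used when both groups have ≤ 10 observations and
    there are no ties; otherwise the normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return w, float(res.pvalue)


def class_counts(records: list[AnnotatedVariant],
                 domain_map: DomainMap | None = None,
                 domain_class: str | None = None) -> ClassCounts:
    """Role-class counts over unique missense variants.

    ``domain_class`` restricts to variants whose position falls in a domain
    of that class (e.g. ``"classA"``); condition-difference categories are
    counted over complete stability records only.
    """
    if domain_class is not None:
        if domain_map is None:
            raise ValueError("domain_map required for a domain_class filter")
        spans = [(e.start, e.end) for e in
                 domain_map.entries_of_class(domain_class)]
        records = [r for r in records
                   if any(s <= r.variant.change.position <= e
                          for s, e in spans)]
    n_cons = sum(r.flags.at_conserved for r in records)
    n_ss = sum(r.flags.alters_disulfide for r in records)
    n_ca = sum(r.flags.alters_ca_site for r in records)
    n_union = sum(r.flags.in_any_class for r in records)
    by_clin = {c: 0 for c in ("pathogenic", "benign", "vus")}
    for r in records:
        by_clin[r.variant.clinical_class] += 1
    delta = {c: 0 for c in ("gray", "orange", "red")}
    for r in records:
        cat = r.delta_category
        if cat is not None:
            delta[cat] += 1
    return ClassCounts(n_total=len(records), n_conserved=n_cons,
                       n_disulfide=n_ss, n_ca=n_ca, n_union=n_union,
                       n_by_clinical=by_clin, n_delta=delta)


def residue_coverage(records: list[AnnotatedVariant], domain_map: DomainMap,
                     domain_class: str = "classA") -> float:
    """Fraction of residues in the filtered domains hit by ≥ 1 variant."""
    spans = [(e.start, e.end) for e in domain_map.entries_of_class(domain_class)]
    total = sum(e - s + 1 for s, e in spans)
    if total == 0:
        raise ValueError(f"no domains of class {domain_class!r}")
    hit = {
        r.variant.change.position for r in records
        if any(s <= r.variant.change.position <= e for s, e in spans)
    }
    return len(hit) / total


@dataclass
class DomainDistribution:
    domain_name: str
    ddg_by_class: dict[str, list[float]]
    tests: dict[str, dict]          # class pair -> {statistic, p}
    frac_exceeding: dict[str, float]  # class -> fraction with ddg > significant


def ddg_distribution_compare(records: list[AnnotatedVariant],
                             condition: str = "extracellular",
                             thresholds: Thresholds = Thresholds(),
                             group_by_domain: bool = True
                             ) -> list[DomainDistribution]:
    """Compare ΔΔG distributions between clinical classes within domains.

    For each domain (or overall), a two-sided rank-sum test is run for each
    pair of non-empty clinical classes, and the fraction of each class with
    ΔΔG above the significance threshold is reported.
    """
    groups: dict[str, list[AnnotatedVariant]] = {}
    for r in records:
        if r.stability is None:
            continue
        key = (r.variant.domain_name or "none") if group_by_domain else "all"
        groups.setdefault(key, []).append(r)

    attr = f"ddg_{condition}"
    out = []
    for domain in sorted(groups):
        by_class: dict[str, list[float]] = {
            c: [] for c in ("pathogenic", "vus", "benign")}
        for r in groups[domain]:
            v = getattr(r.stability, attr)
            if v is not None:
                by_class[r.variant.clinical_class].append(v)
        tests: dict[str, dict] = {}
        pairs = [("pathogenic", "vus"), ("pathogenic", "benign"),
                 ("vus", "benign")]
        for a, b in pairs:
            if not by_class[a] or not by_class[b]:
                tests[f"{a}_vs_{b}"] = {"skipped": "empty class"}
                continue
            w, p = rank_sum_test(by_class[a], by_class[b])
            tests[f"{a}_vs_{b}"] = {"statistic": w, "p": p}
        frac = {c: (float(np.mean([v > thresholds.significant for v in vals]))
                    if vals else float("nan"))
                for c, vals in by_class.items()}
        out.append(DomainDistribution(domain_name=domain,
                                      ddg_by_class=by_class, tests=tests,
                                      frac_exceeding=frac))
    # Benjamini-Hochberg across all computed p-values (reported alongside
    # the raw values, never substituted for them)
    flat = [(d, name) for d in out for name, t in d.tests.items() if "p" in t]
    if flat:
        ps = np.array([d.tests[name]["p"] for d, name in flat])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        for (d, name), q in zip(flat, adj):
            d.tests[name]["p_bh"] = float(q)
    return out


def conservation_vs_stability(records: list[AnnotatedVariant],
                              domain_map: DomainMap | None = None) -> dict:
    """Spearman association of per-variant conservation with stability.

    Reports rho and p for (conservation z, |condition delta|) and
    (conservation z, extracellular ΔΔG), overall and per domain class when
    a map is supplied.
    """
    def _subset(recs: list[AnnotatedVariant]) -> dict:
        cons, deltas, ddgs = [], [], []
        for r in recs:
            if np.isnan(r.conservation_z) or r.stability is None \
                    or r.stability.is_partial:
                continue
            cons.append(r.conservation_z)
            deltas.append(abs(r.stability.condition_delta))
            ddgs.append(r.stability.ddg_extracellular)
        out = {"n": len(cons)}
        for name, y in (("vs_condition_delta", deltas), ("vs_ddg", ddgs)):
            try:
                res = sps.spearmanr(cons, y)
                out[name] = {"rho": float(res.statistic),
                             "p": float(res.pvalue)}
            except ValueError:
                out[name] = {"rho": float("nan"), "p": float("nan")}
        return out

    result = {"overall": _subset(records)}
    if domain_map is not None:
        for cls in sorted({e.domain_class for e in domain_map.entries}):
            spans = [(e.start, e.end)
                     for e in domain_map.entries_of_class(cls)]
            sub = [r for r in records
                   if any(s <= r.variant.change.position <= e
                          for s, e in spans)]
            result[cls] = _subset(sub)
    return result


def generate_report(records: list[AnnotatedVariant],
                    out_dir: str | Path,
                    domain_map: DomainMap | None = None,
                    quality_reports: list | None = None,
                    thresholds: Thresholds = Thresholds(),
                    config: dict | None = None) -> dict[str, Path]:
    """Write summary.json, variants_annotated.tsv and quality.json.

    Output is deterministic: fixed row and key ordering, no timestamps.
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    counts = class_counts(records)
    summary: dict = {
        "config": dict(sorted((config or {}).items())),
        "thresholds_kcal_per_mol": {"significant": thresholds.significant,
                                    "strong": thresholds.strong,
                                    "severe": thresholds.severe},
        "sign_convention": "positive ddG_fold = destabilizing",
        "n_total": counts.n_total,
        "n_conserved": counts.n_conserved,
        "n_disulfide": counts.n_disulfide,
        "n_ca": counts.n_ca,
        "n_union": counts.n_union,
        "n_by_clinical": counts.n_by_clinical,
        "n_delta": counts.n_delta,
        "percentages": counts.percentages(),
    }
    if domain_map is not None:
        class_a = class_counts(records, domain_map, "classA")
        summary["classA"] = {
            "n_total": class_a.n_total, "n_conserved": class_a.n_conserved,
            "n_disulfide": class_a.n_disulfide, "n_ca": class_a.n_ca,
            "n_union": class_a.n_union, "n_delta": class_a.n_delta,
            "residue_coverage": residue_coverage(records, domain_map,
                                                 "classA"),
        }
    pairs = [(r.stability.ddg_extracellular, r.stability.ddg_endosomal)
             for r in records
             if r.stability is not None and not r.stability.is_partial]
    if len(pairs) >= 3:
        xs, ys = zip(*pairs)
        try:
            summary["rho_conditions"] = spearman_rho(xs, ys)
        except ValueError:
            summary["rho_conditions"] = None
    summary["conservation_association"] = conservation_vs_stability(
        records, domain_map)

    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    rows = []
    for r in sorted(records, key=lambda r: r.variant.change.key):
        st = r.stability
        rows.append({
            "variant": str(r.variant.change),
            "position": r.variant.change.position,
            "clinical_class": r.variant.clinical_class,
            "domain": r.variant.domain_name or "",
            "at_conserved": r.flags.at_conserved,
            "alters_disulfide": r.flags.alters_disulfide,
            "alters_ca_site": r.flags.alters_ca_site,
            "at_core": r.flags.at_core,
            "near_glyco": r.flags.near_glyco,
            "at_glyco": r.flags.at_glyco,
            "conservation_z": round(r.conservation_z, 4)
                if not np.isnan(r.conservation_z) else "",
            "ddg_extracellular": "" if st is None or
                st.ddg_extracellular is None else st.ddg_extracellular,
            "ddg_endosomal": "" if st is None or st.ddg_endosomal is None
                else st.ddg_endosomal,
            "delta_category": r.delta_category or "",
        })
    paths["variants"] = out / "variants_annotated.tsv"
    with open(paths["variants"], "w") as fh:
        fh.write("# sign convention: positive ddG_fold = destabilizing\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    if quality_reports is not None:
        paths["quality"] = out / "quality.json"
        with open(paths["quality"], "w") as fh:
            json.dump([q.to_dict() for q in quality_reports], fh, indent=1,
                      sort_keys=True)
            fh.write("\n")
    return paths
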