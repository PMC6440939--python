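"""Condition-specific folding-stability effects of missense variants.

ΔΔG_fold values per physiologic condition (extracellular vs endosomal) are
normally *ingested* from precomputed tables (e.g. FoldX output exported to
TSV); the sign convention throughout is positive = destabilizing.  The
classification thresholds are 0.6 kcal/mol for a significant change and
1.8 kcal/mol for a strong one; the endosomal-vs-extracellular difference is
binned gray (< 1.8), orange ([1.8, 3.0]), red (> 3.0) kcal/mol.

For synthetic end-to-end tests the module also provides
:func:`estimate_ddg`, a deliberately simple interpretable scoring function
(steric clash + hydrogen-bond loss + burial hydropathy + disulfide and
Ca²⁺ penalties).  It is not a FoldX reimplementation and is never a
substitute for ingested energies when analysing real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .structural_annotation import (
    CaSite, DisulfideBond, SIDECHAIN_OXYGEN_AA, relative_accessibility,
)
from .structure_io import Structure
from .variant_catalog import VariantChange

__all__ = [
    "Thresholds",
    "StabilityRecord",
    "load_ddg_table",
    "classify_stability",
    "condition_difference",
    "estimate_ddg",
    "load_estimator_weights",
]

STABILITY_CLASSES = ("stabilizing", "neutral", "destabilizing",
                     "strongly_destabilizing")
DELTA_CATEGORIES = ("gray", "orange", "red")


@dataclass(frozen=True)
class Thresholds:
    """Stability thresholds in kcal/mol."""
    significant: float = 0.6
    strong: float = 1.8
    severe: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.significant < self.strong < self.severe):
            raise ValueError(
                f"need 0 < significant < strong < severe, got {self}")


@dataclass
class StabilityRecord:
    change: VariantChange
    ddg_extracellular: float | None = None
    ddg_endosomal: float | None = None

    @property
    def is_partial(self) -> bool:
        return self.ddg_extracellular is None or self.ddg_endosomal is None

    @property
    def condition_delta(self) -> float | None:
        """Signed extracellular − endosomal difference (kcal/mol)."""
        if self.is_partial:
            return None
        return self.ddg_extracellular - self.ddg_endosomal

    def stability_class(self, condition: str,
                        thresholds: Thresholds = Thresholds()) -> str | None:
        ddg = {"extracellular": self.ddg_extracellular,
               "endosomal": self.ddg_endosomal}[condition]
        return None if ddg is None else classify_stability(ddg, thresholds)

    def delta_category(self,
                       thresholds: Thresholds = Thresholds()) -> str | None:
        if self.is_partial:
            return None
        return condition_difference(self, thresholds)


def classify_stability(ddg: float, thresholds: Thresholds = Thresholds()) -> str:
    """Bin one ΔΔG_fold value (kcal/mol, positive = destabilizing).

    > strong → strongly_destabilizing; (significant, strong] → destabilizing;
    [−significant, significant] → neutral; < −significant → stabilizing.
    """
    if math.isnan(ddg) or math.isinf(ddg):
        raise ValueError(f"ddg must be finite, got {ddg}")
    t = thresholds
    if ddg > t.strong:
        return "strongly_destabilizing"
    if ddg > t.significant:
        return "destabilizing"
    if ddg >= -t.significant:
        return "neutral"
    return "stabilizing"


def condition_difference(record: StabilityRecord,
                         thresholds: Thresholds = Thresholds()) -> str:
    """Category of the absolute condition difference: gray/orange/red.

    The orange band is closed on both ends ([strong, severe]); red is
    strictly above severe.
    """
    if record.is_partial:
        raise ValueError(f"partial record for {record.change}: both condition "
                         "values are required")
    d = abs(record.condition_delta)
    if d < thresholds.strong:
        return "gray"
    if d <= thresholds.severe:
        return "orange"
    return "red"


def load_ddg_table(path: str | Path,
                   condition_labels: tuple[str, str] = ("extracellular",
                                                        "endosomal")
                   ) -> list[StabilityRecord]:
    """Read per-variant per-condition ΔΔG values from TSV/CSV.

    Expected columns: ``variant`` (HGVS-style missense) plus
    ``ddg_<condition>`` for each requested condition.  A missing condition
    column leaves that field absent (record flagged partial).  Duplicate
    rows must agree; conflicting duplicates raise.  Non-numeric ΔΔG cells
    reject the row.
    """
    from .variant_catalog import parse_hgvs_p, HgvsRejected

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if "variant" not in df.columns:
        raise ValueError(f"{path}: missing 'variant' column")
    cols = {c: f"ddg_{c}" for c in condition_labels if f"ddg_{c}" in df.columns}
    if not cols:
        raise ValueError(f"{path}: no ddg_<condition> columns found")

    records: dict[tuple, StabilityRecord] = {}
    for row in df.itertuples(index=False):
        try:
            change = parse_hgvs_p(str(row.variant))
        except HgvsRejected:
            continue
        values: dict[str, float | None] = {}
        bad = False
        for cond, col in cols.items():
            cell = getattr(row, col)
            if pd.isna(cell):
                values[cond] = None
                continue
            try:
                values[cond] = float(cell)
            except (TypeError, ValueError):
                bad = True
        if bad:
            continue
        rec = StabilityRecord(
            change=change,
            ddg_extracellular=values.get("extracellular"),
            ddg_endosomal=values.get("endosomal"),
        )
        prev = records.get(change.key)
        if prev is not None:
            if (prev.ddg_extracellular, prev.ddg_endosomal) != (
                    rec.ddg_extracellular, rec.ddg_endosomal):
                raise ValueError(
                    f"{path}: conflicting duplicate rows for {change}")
            continue
        records[change.key] = rec
    return [records[k] for k in sorted(records)]


# ---------------------------------------------------------------------------
# simplified internal estimator (synthetic pipelines only)

#: Kyte–Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Count of side-chain hydrogen-bond donors+acceptors per residue type.
HBOND_CAPACITY = {
    "A": 0, "R": 5, "N": 4, "D": 4, "C": 1, "Q": 4, "E": 4, "G": 0,
    "H": 2, "I": 0, "L": 0, "K": 3, "M": 0, "F": 0, "P": 0, "S": 3,
    "T": 3, "W": 1, "Y": 3, "V": 0,
}

#: Approximate side-chain pseudo-atom radius (Å) per residue type, used for
#: the idealized-swap clash term.
SIDECHAIN_RADIUS = {
    "A": 1.9, "R": 3.4, "N": 2.7, "D": 2.6, "C": 2.3, "Q": 2.9, "E": 2.8,
    "G": 0.0, "H": 3.0, "I": 2.8, "L": 2.8, "K": 3.2, "M": 3.0, "F": 3.2,
    "P": 2.4, "S": 2.1, "T": 2.4, "W": 3.6, "Y": 3.4, "V": 2.5,
}

_DEFAULT_WEIGHTS_FILE = "ddg_weights.tsv"


def load_estimator_weights(path: str | Path | None = None) -> dict[str, float]:
    """Term weights for :func:`estimate_ddg` (shipped TSV: term, weight)."""
    if path is None:
        ref = resources.files("ldlr_varstruct") / "data" / _DEFAULT_WEIGHTS_FILE
        df = pd.read_csv(str(ref), sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["term"], df["weight"].astype(float)))


def estimate_ddg(structure: Structure, change: VariantChange,
                 disulfides: list[DisulfideBond] | None = None,
                 ca_sites: list[CaSite] | None = None,
                 rsa: dict[int, float] | None = None,
                 weights: dict[str, float] | None = None,
                 return_terms: bool = False):
    """Simple interpretable ΔΔG_fold estimate for an idealized side-chain swap.

    Terms (each reported when ``return_terms``):

    * ``clash`` — van der Waals overlap of the alt side-chain pseudo-atom
      (placed along the Cα→Cβ direction) with surrounding atoms, minus the
      same quantity for the reference side chain.
    * ``hbond_loss`` — lost side-chain hydrogen-bonding capacity.
    * ``hydropathy`` — Kyte–Doolittle change weighted by burial (1 − RSA).
    * ``disulfide_loss`` — fixed penalty when a bonded Cys loses its thiol.
    * ``ca_loss`` — fixed penalty when a side-chain Ca²⁺ coordinator loses
      its side-chain oxygen.

    Depends only on interatomic distances, so it is invariant to rigid-body
    transforms of the structure.
    """
    from .structural_annotation import detect_ca_sites, detect_disulfides

    res = structure.residue_at(change.position)
    if res is None:
        raise ValueError(f"position {change.position} absent from structure")
    if res.one_letter != change.ref_aa:
        raise ValueError(
            f"reference mismatch at {change.position}: structure has "
            f"{res.one_letter}, variant states {change.ref_aa}")
    if change.alt_aa == change.ref_aa:  # unreachable via VariantChange
        return (0.0, {}) if return_terms else 0.0

    if weights is None:
        weights = load_estimator_weights()
    if disulfides is None:
        disulfides = detect_disulfides(structure)
    if ca_sites is None:
        ca_sites = detect_ca_sites(structure)
    if rsa is None:
        rsa = relative_accessibility(structure)

    ca_atom = res.atom("CA")
    cb_atom = res.atom("CB")
    if ca_atom is None:
        raise ValueError(f"residue {change.position} lacks a CA atom")

    def clash_volume(aa: str) -> float:
        r_sc = SIDECHAIN_RADIUS[aa]
        if r_sc == 0.0:
            return 0.0
        if cb_atom is not None:
            direction = cb_atom.coord - ca_atom.coord
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        else:
            direction = np.array([0.0, 0.0, 1.0])
        center = ca_atom.coord + direction * (1.53 + 0.4 * r_sc)
        overlap = 0.0
        for other in structure.residues:
            if other is res:
                continue
            for atom in other.atoms:
                d = float(np.linalg.norm(atom.coord - center))
                gap = (r_sc + 1.7) - d
                if gap > 0:
                    overlap += gap ** 2
        return overlap

    terms: dict[str, float] = {}
    terms["clash"] = max(0.0, clash_volume(change.alt_aa)
                         - clash_volume(change.ref_aa))
    terms["hbond_loss"] = max(0, HBOND_CAPACITY[change.ref_aa]
                              - HBOND_CAPACITY[change.alt_aa])
    burial = 1.0 - rsa.get(change.position, 1.0)
    terms["hydropathy"] = (KYTE_DOOLITTLE[change.ref_aa]
                           - KYTE_DOOLITTLE[change.alt_aa]) * burial
    bonded = {p for b in disulfides for p in b.positions()}
    terms["disulfide_loss"] = float(
        change.ref_aa == "C" and change.alt_aa != "C"
        and change.position in bonded)
    side_coord = {
        r.seq_position for site in ca_sites
        for r, name, _ in site.coordinating_atoms
        if name not in ("N", "CA", "C", "O", "OXT")
    }
    terms["ca_loss"] = float(
        change.position in side_coord
        and change.alt_aa not in SIDECHAIN_OXYGEN_AA)

    total = sum(weights[name] * value for name, value in terms.items())
    return (total, terms) if return_terms else total
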