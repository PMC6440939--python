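"""Parsing, deduplication, and clinical harmonization of missense variants.

Source records come from heterogeneous databases (ClinVar, HGMD, LOVD, and
population catalogs such as ExAC).  The harmonization rule is deliberately
asymmetric: any single pathogenic-side criterion makes the variant
pathogenic; benign requires a benign-side criterion *and* the absence of any
pathogenic one; everything else is a VUS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .structure_io import AA1_TO_3, AA3_TO_1, DomainMap, convert_numbering

logger = logging.getLogger(__name__)

__all__ = [
    "VariantChange",
    "SourceRecord",
    "Variant",
    "HgvsRejected",
    "parse_hgvs_p",
    "harmonize_classification",
    "deduplicate",
    "assign_domain",
    "load_variant_table",
    "detect_numbering_frame",
]

SOURCES = {"clinvar", "hgmd", "lovd", "population"}
CLASSES = ("pathogenic", "benign", "vus")

_HGVS_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z])"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|[A-Z])"
    r"\)?$"
)


class HgvsRejected(ValueError):
    """A protein HGVS string that is not a simple missense change.

    ``reason`` is a stable machine-readable code: one of ``nonsense``,
    ``frameshift``, ``synonymous``, ``not_missense``, ``unparsable``.
    """

    def __init__(self, text: str, reason: str):
        super().__init__(f"{text!r} rejected: {reason}")
        self.text = text
        self.reason = reason


@dataclass(frozen=True)
class VariantChange:
    ref_aa: str
    position: int  # precursor numbering
    alt_aa: str
    raw_hgvs: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1_TO_3 or self.alt_aa not in AA1_TO_3:
            raise ValueError(f"non-standard amino acid in {self.ref_aa}>{self.alt_aa}")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.ref_aa, self.position, self.alt_aa)

    def __str__(self) -> str:
        return f"p.{AA1_TO_3[self.ref_aa].capitalize()}{self.position}" \
               f"{AA1_TO_3[self.alt_aa].capitalize()}"

    def __eq__(self, other) -> bool:  # raw_hgvs is provenance, not identity
        return isinstance(other, VariantChange) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass
class SourceRecord:
    source: str
    raw_class: str
    change: VariantChange

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class Variant:
    change: VariantChange
    sources: list[SourceRecord] = field(default_factory=list)
    clinical_class: str = "vus"
    domain_name: str | None = None


def _aa_token(token: str) -> str | None:
    if len(token) == 1:
        return token if token in AA1_TO_3 else None
    return AA3_TO_1.get(token.upper())


def parse_hgvs_p(text: str) -> VariantChange:
    """Parse a protein-level HGVS missense description.

    Accepts 3-letter ("p.Cys27Arg"), 1-letter ("p.C27R"), bare
    ("Cys27Arg"), and parenthesized ("p.(Cys27Arg)") spellings.  Anything
    that is not a simple missense substitution raises :class:`HgvsRejected`
    with a reason code — the analysis is missense-only.
    """
    raw = text
    text = text.strip()
    lowered = text.lower()
    if "fs" in lowered:
        raise HgvsRejected(raw, "frameshift")
    if "ter" in lowered or text.rstrip(")").endswith("*"):
        raise HgvsRejected(raw, "nonsense")
    if text.rstrip(")").endswith("=") or lowered.endswith("="):
        raise HgvsRejected(raw, "synonymous")
    if any(tok in lowered for tok in ("del", "dup", "ins", "ext")):
        raise HgvsRejected(raw, "not_missense")
    m = _HGVS_RE.match(text)
    if m is None:
        raise HgvsRejected(raw, "unparsable")
    ref = _aa_token(m.group("ref"))
    alt = _aa_token(m.group("alt"))
    if ref is None or alt is None:
        raise HgvsRejected(raw, "unparsable")
    if ref == alt:
        raise HgvsRejected(raw, "synonymous")
    return VariantChange(ref, int(m.group("pos")), alt, raw_hgvs=raw)


_ACGS_RE = re.compile(r"(?:acgs\s*)?(?:class\s*)?([1-5])\b")


def _lovd_acgs_class(raw: str) -> int | None:
    m = _ACGS_RE.search(raw.strip().lower())
    return int(m.group(1)) if m else None


def _is_pathogenic_criterion(rec: SourceRecord) -> bool:
    raw = rec.raw_class.strip().lower()
    if rec.source == "clinvar":
        if "conflicting" in raw:
            return False
        return "pathogenic" in raw  # matches "pathogenic" and "likely pathogenic"
    if rec.source == "hgmd":
        return rec.raw_class.strip() == "DM"
    if rec.source == "lovd":
        return _lovd_acgs_class(raw) in (4, 5)
    return False


def _is_benign_criterion(rec: SourceRecord) -> bool:
    raw = rec.raw_class.strip().lower()
    if rec.source == "clinvar":
        if "conflicting" in raw:
            return False
        return "benign" in raw
    if rec.source == "lovd":
        return _lovd_acgs_class(raw) in (1, 2)
    return False


def harmonize_classification(records: list[SourceRecord]) -> str:
    """Collapse multi-source labels into pathogenic / benign / vus.

    Pathogenic criteria (ClinVar (likely) pathogenic, HGMD DM, LOVD ACGS
    class 4/5) dominate; benign (ClinVar (likely) benign, ACGS 1/2) applies
    only in their absence.  Unknown labels and population-frequency records
    contribute nothing.
    """
    if not records:
        raise ValueError("harmonize_classification requires at least one record")
    if any(_is_pathogenic_criterion(r) for r in records):
        return "pathogenic"
    if any(_is_benign_criterion(r) for r in records):
        return "benign"
    return "vus"


def deduplicate(records: list[SourceRecord]) -> list[Variant]:
    """One :class:`Variant` per distinct (ref, position, alt) key.

    Sources are merged and the harmonization rule applied to the merged set.
    If two sources claim different reference residues at one (position, alt)
    there is a coordinate error somewhere upstream; those keys are excluded
    and logged rather than silently counted.
    """
    by_key: dict[tuple[str, int, str], list[SourceRecord]] = {}
    for rec in records:
        by_key.setdefault(rec.change.key, []).append(rec)

    # conflicting ref at the same (position, alt)
    refs_at: dict[tuple[int, str], set[str]] = {}
    for (ref, pos, alt) in by_key:
        refs_at.setdefault((pos, alt), set()).add(ref)
    conflicted = {pa for pa, refs in refs_at.items() if len(refs) > 1}
    for pos, alt in sorted(conflicted):
        logger.warning(
            "conflicting reference residues at position %d (alt %s): %s — excluded",
            pos, alt, sorted(refs_at[(pos, alt)]),
        )

    variants = []
    for key in sorted(by_key):
        ref, pos, alt = key
        if (pos, alt) in conflicted:
            continue
        recs = by_key[key]
        variants.append(Variant(
            change=recs[0].change,
            sources=recs,
            clinical_class=harmonize_classification(recs),
        ))
    return variants


def assign_domain(variant: Variant, domain_map: DomainMap) -> str | None:
    """First domain whose span contains the variant position (also stored)."""
    variant.domain_name = domain_map.lookup(variant.change.position)
    return variant.domain_name


def detect_numbering_frame(changes: list[VariantChange], sequence: str,
                           offset: int) -> str:
    """Decide whether a variant table uses precursor or mature numbering.

    Counts how many stated reference residues match the canonical sequence
    (1-based precursor string) in each frame and returns the better one
    (``"precursor"`` or ``"mature"``); ties go to precursor.
    """
    def matches(shift: int) -> int:
        n = 0
        for ch in changes:
            pos = ch.position + shift
            if 1 <= pos <= len(sequence) and sequence[pos - 1] == ch.ref_aa:
                n += 1
        return n

    precursor, mature = matches(0), matches(offset)
    frame = "mature" if mature > precursor else "precursor"
    logger.info("numbering frame detected: %s (%d vs %d reference matches)",
                frame, precursor, mature)
    return frame


def load_variant_table(path: str | Path,
                       sequence: str | None = None,
                       offset: int | None = None) -> tuple[list[SourceRecord], dict]:
    """Read a delimited (or XLSX) variant table into source records.

    Required columns: ``source``, ``classification``, ``hgvs_p``.  Rows whose
    HGVS is not a simple missense change are rejected with reasons collected
    in the returned summary.  If ``sequence`` is given, the numbering frame
    is auto-detected; mature-frame positions are normalized to precursor and
    rows whose reference residue still mismatches the sequence are excluded.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, comment="#")
    required = {"source", "classification", "hgvs_p"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    records: list[SourceRecord] = []
    rejected: dict[str, int] = {}
    n_parseable_changes: set[str] = set()
    for row in df.itertuples(index=False):
        hgvs = str(row.hgvs_p)
        try:
            change = parse_hgvs_p(hgvs)
            n_parseable_changes.add(str(change))
        except HgvsRejected as exc:
            rejected[exc.reason] = rejected.get(exc.reason, 0) + 1
            if exc.reason != "unparsable":
                n_parseable_changes.add(hgvs.strip())
            continue
        records.append(SourceRecord(str(row.source).strip().lower(),
                                    str(row.classification), change))

    summary: dict = {"n_rows": int(len(df)), "n_missense_records": len(records),
                     "n_distinct_protein_changes": len(n_parseable_changes),
                     "rejected": rejected}
    if sequence is not None:
        off = offset if offset is not None else 21
        frame = detect_numbering_frame([r.change for r in records], sequence, off)
        summary["numbering_frame"] = frame
        if frame == "mature":
            records = [
                SourceRecord(r.source, r.raw_class, VariantChange(
                    r.change.ref_aa,
                    convert_numbering(r.change.position, "mature_to_precursor", off),
                    r.change.alt_aa, r.change.raw_hgvs))
                for r in records
            ]
        kept = []
        n_mismatch = 0
        for r in records:
            pos = r.change.position
            if pos <= len(sequence) and sequence[pos - 1] == r.change.ref_aa:
                kept.append(r)
            else:
                n_mismatch += 1
                logger.warning("reference mismatch for %s — excluded", r.change)
        summary["n_ref_mismatch_excluded"] = n_mismatch
        records = kept
    return records, summary
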