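"""End-to-end orchestration: fixture directory in, report directory out.

Ties the stages together in the order a full analysis runs: parse and
harmonize variants, assign domains, attach per-condition stability values,
annotate structural roles from the model geometry, and write the report.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .alignment_conservation import conservation_profile
from .stability import Thresholds, load_ddg_table
from .stats_report import AnnotatedVariant, generate_report
from .structural_annotation import (
    annotate_residues, detect_ca_sites, detect_disulfides,
    variant_role_flags,
)
from .structure_io import load_domain_map, read_structure
from .variant_catalog import assign_domain, deduplicate, load_variant_table

logger = logging.getLogger(__name__)

__all__ = ["annotate_and_report", "read_msa_fasta"]


def read_msa_fasta(path: str | Path) -> list[str]:
    """Aligned FASTA → list of gapped row strings."""
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                    current = []
            elif line:
                current.append(line)
    if current:
        rows.append("".join(current))
    return rows


def annotate_and_report(fixture_dir: str | Path, out_dir: str | Path,
                        thresholds: Thresholds = Thresholds(),
                        config: dict | None = None) -> dict:
    """Run the full variant pipeline over a fixture directory.

    Expects the file layout produced by
    :func:`ldlr_varstruct.synthetic_data.write_fixture_directory`
    (``variants.tsv``, ``ddg.tsv``, ``domains.tsv``, ``sequence.txt``;
    optionally ``mini.pdb``, ``msa.fasta``, ``glyco.txt``).  Returns the
    summary dictionary written to ``summary.json``.
    """
    fixture = Path(fixture_dir)
    domain_map = load_domain_map(fixture / "domains.tsv")
    sequence = None
    if (fixture / "sequence.txt").exists():
        sequence = (fixture / "sequence.txt").read_text().strip()

    records, ingest_summary = load_variant_table(
        fixture / "variants.tsv", sequence=sequence,
        offset=domain_map.numbering_offset)
    variants = deduplicate(records)
    for v in variants:
        assign_domain(v, domain_map)

    stability = {}
    if (fixture / "ddg.tsv").exists():
        for rec in load_ddg_table(fixture / "ddg.tsv"):
            stability[rec.change.key] = rec

    annotations = None
    if (fixture / "mini.pdb").exists():
        structure = read_structure(fixture / "mini.pdb")
        disulfides = detect_disulfides(structure)
        ca_sites = detect_ca_sites(structure)
        profile = None
        if (fixture / "msa.fasta").exists():
            msa = read_msa_fasta(fixture / "msa.fasta")
            if msa:
                profile = conservation_profile(msa)
        glyco = []
        if (fixture / "glyco.txt").exists():
            glyco = [int(line) for line in
                     (fixture / "glyco.txt").read_text().split()]
            glyco = [g for g in glyco
                     if any(r.seq_position == g for r in structure.residues)]
        annotations = annotate_residues(structure, disulfides, ca_sites,
                                        profile, glyco_sites=glyco)

    annotated = []
    for v in variants:
        av = AnnotatedVariant(variant=v,
                              stability=stability.get(v.change.key))
        if annotations is not None and v.change.position in annotations:
            av.flags = variant_role_flags(v, annotations)
            av.conservation_z = annotations[v.change.position].conservation_z
        annotated.append(av)

    cfg = dict(config or {})
    cfg.update({f"ingest_{k}": v for k, v in ingest_summary.items()
                if not isinstance(v, dict)})
    generate_report(annotated, out_dir, domain_map=domain_map,
                    thresholds=thresholds, config=cfg)
    import json
    with open(Path(out_dir) / "summary.json") as fh:
        return json.load(fh)
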