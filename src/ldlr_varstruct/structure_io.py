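"""Coordinate I/O, structure containers, domain maps, and residue numbering.

All residue positions inside the package use *precursor* numbering, i.e. the
UniProt frame that includes the 21-residue signal peptide.  Legacy clinical
literature on LDLR frequently uses mature-protein numbering; conversion
between the two frames is a fixed offset (:func:`convert_numbering`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DomainEntry",
    "DomainMap",
    "FormatError",
    "read_structure",
    "write_structure",
    "load_domain_map",
    "convert_numbering",
    "SIGNAL_PEPTIDE_LENGTH",
]

#: Length of the LDLR signal peptide; mature position 1 = precursor position 22.
SIGNAL_PEPTIDE_LENGTH = 21

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Modified residues mapped back to their parent amino acid on ingest.
NONSTANDARD_PARENT = {
    "MSE": "MET", "CSO": "CYS", "CME": "CYS", "OCS": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "HYP": "PRO",
}

DOMAIN_CLASSES = {"classA", "EGF", "classB", "O-linked", "TM", "cytoplasmic"}


class FormatError(ValueError):
    """Raised when a coordinate or table file violates the expected format."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_position: int
    res_name: str
    atoms: list[Atom]
    insertion_code: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_name}{self.seq_position}: no atoms")
        if not self.is_hetero and self.res_name not in STANDARD_AA3:
            raise ValueError(
                f"residue {self.res_name}{self.seq_position}: non-standard residue "
                "must be flagged is_hetero"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_position, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.res_name, "X")


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    ions: list[Residue] = field(default_factory=list)
    condition_label: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, position, insertion) residue keys")
        ion_ids = {id(r) for r in self.ions}
        if ion_ids & {id(r) for r in self.residues}:
            raise ValueError("ions must be disjoint from protein residues")

    def residue_at(self, position: int, chain_id: str | None = None) -> Residue | None:
        for r in self.residues:
            if r.seq_position == position and (chain_id is None or r.chain_id == chain_id):
                return r
        return None

    def atoms_array(self, hetero: bool = False) -> np.ndarray:
        """Stacked (n, 3) heavy-atom coordinates of all protein residues."""
        pools = self.residues + (self.ions if hetero else [])
        coords = [a.coord for r in pools for a in r.atoms]
        return np.asarray(coords, dtype=float).reshape(-1, 3)


@dataclass
class DomainEntry:
    domain_name: str
    domain_class: str
    start: int  # 1-based inclusive, precursor frame
    end: int

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if self.start > self.end:
            raise ValueError(f"{self.domain_name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class DomainMap:
    entries: list[DomainEntry]
    numbering_offset: int = SIGNAL_PEPTIDE_LENGTH

    def __post_init__(self) -> None:
        by_class: dict[str, list[DomainEntry]] = {}
        for e in self.entries:
            by_class.setdefault(e.domain_class, []).append(e)
        for cls, entries in by_class.items():
            spans = sorted((e.start, e.end, e.domain_name) for e in entries)
            for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {cls} entries {n1} and {n2}")
        # Class-A repeats are ~40 aa; a wildly different span usually signals a
        # mis-entered coordinate, so warn but accept.
        for e in self.entries:
            if e.domain_class == "classA" and not 25 <= (e.end - e.start + 1) <= 60:
                warnings.warn(
                    f"class-A entry {e.domain_name} spans {e.end - e.start + 1} "
                    "residues; expected about 40",
                    stacklevel=2,
                )

    def lookup(self, position: int) -> str | None:
        """Name of the first domain whose span contains ``position``."""
        for e in self.entries:
            if position in e:
                return e.domain_name
        return None

    def entries_of_class(self, domain_class: str) -> list[DomainEntry]:
        return [e for e in self.entries if e.domain_class == domain_class]


def read_structure(path: str | Path, condition_label: str = "") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ATOM records become protein residues; HETATM calcium ions are collected
    into ``ions``; other hetero groups (waters, ligands) are dropped with a
    warning.  Alternate locations are resolved to the highest-occupancy
    conformer.  Only the first model of a multi-model file is used.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models; using the first", stacklevel=2)
    st.remove_alternative_conformations()  # keeps highest occupancy
    model = st[0]

    residues: list[Residue] = []
    ions: list[Residue] = []
    for chain in model:
        for res in chain:
            name = res.name
            het = res.het_flag == "H"
            if name in NONSTANDARD_PARENT:
                name, het = NONSTANDARD_PARENT[name], False
            atoms = [
                Atom(a.name, a.element.name or a.name[:1],
                     np.array([a.pos.x, a.pos.y, a.pos.z]), a.occ, a.b_iso)
                for a in res
            ]
            if not atoms:
                continue
            record = Residue(
                chain_id=chain.name,
                seq_position=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=name,
                atoms=atoms,
                is_hetero=het or name not in STANDARD_AA3,
            )
            if not record.is_hetero:
                residues.append(record)
            elif name in ("CA", "CAL") or any(a.element == "Ca" for a in atoms):
                ions.append(record)
            elif name != "HOH":
                warnings.warn(f"{path}: dropping hetero group {name}", stacklevel=2)
    if not residues:
        raise FormatError(f"{path}: no protein ATOM records")
    return Structure(id=path.stem, residues=residues, ions=ions,
                     condition_label=condition_label)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a PDB file (ATOM/HETATM/TER/END)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def _append(res: Residue, het: bool) -> None:
        chain = chains.setdefault(res.chain_id, gemmi.Chain(res.chain_id))
        g = gemmi.Residue()
        g.name = res.res_name
        g.seqid = gemmi.SeqId(res.seq_position, res.insertion_code or " ")
        g.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            g.add_atom(ga)
        chain.add_residue(g)

    for res in structure.residues:
        _append(res, het=False)
    for ion in structure.ions:
        _append(ion, het=True)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def load_domain_map(path: str | Path) -> DomainMap:
    """Load a domain-architecture map from TSV.

    Required columns: ``domain_name``, ``class``, ``start``, ``end``
    (1-based inclusive precursor coordinates).  An optional ``#``-prefixed
    metadata line ``numbering_offset=<int>`` overrides the default signal
    peptide length of 21.
    """
    path = Path(path)
    offset = SIGNAL_PEPTIDE_LENGTH
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "numbering_offset=" in line:
                offset = int(line.split("numbering_offset=")[1].strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"domain_name", "class", "start", "end"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    entries = [
        DomainEntry(str(name), str(cls), int(start), int(end))
        for name, cls, start, end in zip(df["domain_name"], df["class"],
                                         df["start"], df["end"])
    ]
    return DomainMap(entries=entries, numbering_offset=offset)


def convert_numbering(position: int, direction: str,
                      offset: int = SIGNAL_PEPTIDE_LENGTH) -> int:
    """Convert a residue position between mature and precursor frames.

    ``mature_to_precursor`` adds the signal-peptide offset;
    ``precursor_to_mature`` subtracts it.  The two directions compose to the
    identity.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if direction == "mature_to_precursor":
        return position + offset
    if direction == "precursor_to_mature":
        result = position - offset
        if result < 1:
            raise ValueError(
                f"precursor position {position} lies within the signal peptide "
                f"(offset {offset})"
            )
        return result
    raise ValueError(f"unknown direction {direction!r}")
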