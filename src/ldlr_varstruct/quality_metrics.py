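"""Model-quality panel: Ramachandran statistics, hydrogen-bond participation,
atomic clash z-score, and a coarse statistical-potential ("dope-like")
z-score against shuffled decoys.

The z-standardizations use this package's own shipped reference constants
(see ``data/quality_reference.json``); they indicate relative quality on a
common scale but are not calibrated against any external validation server.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .geometry import angle, dihedral
from .structure_io import Residue, Structure

__all__ = [
    "QualityReport",
    "ramachandran_stats",
    "hydrogen_bonds",
    "hbond_fraction",
    "clash_zscore",
    "count_clashes",
    "potential_zscore",
]

#: Van der Waals radii (Å) by element for clash detection.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "CA": 1.97, "P": 1.80}
CLASH_TOLERANCE = 0.4  # Å subtracted from the radius sum

HBOND_DIST_MAX = 3.5   # donor-heavy to acceptor, Å
HBOND_ANGLE_MIN = 120.0  # antecedent-donor-acceptor, degrees

#: Residue classes for the contact potential.
HYDROPHOBIC = set("AVILMFWC")
POLAR = set("GSTYNQH")
CHARGED = set("DEKR")

_SIDECHAIN_DONORS = {
    "SER": [("OG", "CB")], "THR": [("OG1", "CB")], "TYR": [("OH", "CZ")],
    "LYS": [("NZ", "CE")], "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("ND2", "CG")], "GLN": [("NE2", "CD")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")], "TRP": [("NE1", "CD1")],
    "CYS": [("SG", "CB")],
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
}


from functools import lru_cache


@lru_cache(maxsize=1)
def _load_reference() -> dict:
    ref = resources.files("ldlr_varstruct") / "data" / "quality_reference.json"
    return json.loads(ref.read_text())


@lru_cache(maxsize=1)
def _load_rama_regions() -> dict:
    ref = resources.files("ldlr_varstruct") / "data" / "rama_regions.json"
    return json.loads(ref.read_text())


@dataclass
class QualityReport:
    structure_id: str
    rama_core_fraction: float
    rama_allowed_fraction: float
    rama_outlier_z: float
    hbond_fraction: float
    clash_z: float
    potential_z: float

    def __post_init__(self) -> None:
        if not (0 <= self.rama_core_fraction <= self.rama_allowed_fraction <= 1):
            raise ValueError("need 0 <= core <= allowed <= 1")
        if not 0 <= self.hbond_fraction <= 1:
            raise ValueError("hbond_fraction outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _residue_class(res: Residue, next_res: Residue | None) -> str:
    if res.res_name == "GLY":
        return "gly"
    if res.res_name == "PRO":
        return "pro"
    if next_res is not None and next_res.res_name == "PRO":
        return "prepro"
    return "general"


def _in_boxes(phi: float, psi: float, boxes: list[list[float]]) -> bool:
    return any(lo_f <= phi <= hi_f and lo_s <= psi <= hi_s
               for lo_f, hi_f, lo_s, hi_s in boxes)


def phi_psi(structure: Structure) -> list[tuple[Residue, float, float]]:
    """Backbone (φ, ψ) for every residue with both dihedrals defined."""
    out = []
    by_chain: dict[str, list[Residue]] = {}
    for res in structure.residues:
        by_chain.setdefault(res.chain_id, []).append(res)
    for chain in by_chain.values():
        for prev, cur, nxt in zip(chain, chain[1:], chain[2:]):
            needed = (prev.atom("C"), cur.atom("N"), cur.atom("CA"),
                      cur.atom("C"), nxt.atom("N"))
            if any(a is None for a in needed):
                warnings.warn(f"residue {cur.seq_position}: incomplete backbone; "
                              "excluded from Ramachandran statistics", stacklevel=2)
                continue
            c_prev, n, ca, c, n_next = (a.coord for a in needed)
            out.append((cur, dihedral(c_prev, n, ca, c),
                        dihedral(n, ca, c, n_next)))
    return out


def ramachandran_stats(structure: Structure) -> tuple[float, float, float]:
    """(core fraction, allowed fraction, outlier z-score).

    Residues are binned with separate region definitions for Gly, Pro,
    pre-Pro, and general residues; ``allowed`` is cumulative (core ⊆
    allowed).  The outlier z standardizes the outlier fraction against the
    shipped reference constants.
    """
    dihedrals = phi_psi(structure)
    if not dihedrals:
        raise ValueError("structure has no residue with both phi and psi "
                         "defined (need >= 3 consecutive residues)")
    regions = _load_rama_regions()
    order = {id(r): i for i, r in enumerate(structure.residues)}
    n_core = n_allowed = 0
    for res, phi, psi in dihedrals:
        idx = order[id(res)]
        nxt = structure.residues[idx + 1] if idx + 1 < len(structure.residues) else None
        cls = regions[_residue_class(res, nxt)]
        core = _in_boxes(phi, psi, cls["core"])
        allowed = core or _in_boxes(phi, psi, cls["allowed"])
        n_core += core
        n_allowed += allowed
    n = len(dihedrals)
    outlier_fraction = 1.0 - n_allowed / n
    ref = _load_reference()["rama_outlier_fraction"]
    z = (outlier_fraction - ref["mu"]) / ref["sigma"]
    return n_core / n, n_allowed / n, float(z)


def _donors(structure: Structure) -> list[tuple[Residue, np.ndarray, np.ndarray]]:
    """(residue, donor coordinate, antecedent coordinate) triples."""
    donors = []
    for res in structure.residues:
        if res.res_name != "PRO":  # proline nitrogen carries no hydrogen
            n, ca = res.atom("N"), res.atom("CA")
            if n is not None and ca is not None:
                donors.append((res, n.coord, ca.coord))
        for donor_name, ante_name in _SIDECHAIN_DONORS.get(res.res_name, []):
            d, a = res.atom(donor_name), res.atom(ante_name)
            if d is not None and a is not None:
                donors.append((res, d.coord, a.coord))
    return donors


def _acceptors(structure: Structure) -> list[tuple[Residue, str, np.ndarray]]:
    acceptors = []
    for res in structure.residues:
        for name in ("O", "OXT"):
            a = res.atom(name)
            if a is not None:
                acceptors.append((res, name, a.coord))
        for name in _SIDECHAIN_ACCEPTORS.get(res.res_name, []):
            a = res.atom(name)
            if a is not None:
                acceptors.append((res, name, a.coord))
    return acceptors


def hydrogen_bonds(structure: Structure) -> list[tuple[Residue, Residue, float, float]]:
    """Geometric hydrogen bonds (donor residue, acceptor residue, Å, degrees).

    Criterion: donor-heavy to acceptor distance ≤ 3.5 Å and
    antecedent–donor–acceptor angle ≥ 120°.  Pairs within one residue, and
    backbone–backbone pairs of sequence-adjacent residues (covalently
    constrained across the peptide bond), are excluded.  Backbone and
    side-chain bonds count alike.
    """
    donors = _donors(structure)
    acceptors = _acceptors(structure)
    if not donors or not acceptors:
        return []
    tree = cKDTree(np.array([c for _, _, c in acceptors]))
    bonds = []
    for res_d, d_coord, ante_coord in donors:
        for j in tree.query_ball_point(d_coord, HBOND_DIST_MAX):
            res_a, acc_name, a_coord = acceptors[j]
            if res_a is res_d:
                continue
            same_chain = res_a.chain_id == res_d.chain_id
            if same_chain and abs(res_a.seq_position - res_d.seq_position) <= 1 \
                    and acc_name in ("O", "OXT"):
                continue
            dist = float(np.linalg.norm(a_coord - d_coord))
            if dist < 1e-6:
                continue
            theta = angle(ante_coord, d_coord, a_coord)
            if theta >= HBOND_ANGLE_MIN:
                bonds.append((res_d, res_a, dist, theta))
    return bonds


def hbond_fraction(structure: Structure) -> float:
    """Fraction of residues participating in ≥1 intramolecular hydrogen bond."""
    participating: set[tuple[str, int, str]] = set()
    for res_d, res_a, _, _ in hydrogen_bonds(structure):
        participating.add(res_d.key)
        participating.add(res_a.key)
    return len(participating) / len(structure.residues)


def _atom_table(structure: Structure):
    coords, elements, res_idx, names = [], [], [], []
    for i, res in enumerate(structure.residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            elements.append(atom.element)
            res_idx.append(i)
            names.append(atom.name)
    return (np.asarray(coords).reshape(-1, 3), elements, np.asarray(res_idx),
            names)


#: Greek-letter branch depth of a side-chain atom from Cα.
_BRANCH_DEPTH = {"B": 1, "G": 2, "D": 3, "E": 4, "Z": 5, "H": 6}


def _bond_separation(name_a: str, res_a: int, name_b: str, res_b: int) -> int:
    """Approximate number of covalent bonds between two atoms of the same
    chain, from backbone chain position plus side-chain branch depth."""
    def chain_pos(name: str, seq: int) -> tuple[int, int]:
        base = 3 * seq
        if name == "N":
            return base, 0
        if name == "CA":
            return base + 1, 0
        if name == "C":
            return base + 2, 0
        if name in ("O", "OXT"):
            return base + 2, 1
        depth = _BRANCH_DEPTH.get(name[1:2], 2)
        return base + 1, depth  # side chain hangs off CA

    pa, da = chain_pos(name_a, res_a)
    pb, db = chain_pos(name_b, res_b)
    return abs(pb - pa) + da + db


def count_clashes(structure: Structure) -> int:
    """Steric clashes: heavy-atom pairs closer than (r_vdw sum − 0.4 Å).

    Pairs within one residue are treated as fixed covalent geometry and not
    counted; across residues, pairs within 3 covalent bonds of each other
    (peptide-link neighbourhood, estimated from backbone position and
    side-chain branch depth) and disulfide-bonded cysteine side chains are
    excluded.
    """
    coords, elements, res_idx, names = _atom_table(structure)
    residues = structure.residues
    tree = cKDTree(coords)
    max_r = 2 * max(VDW_RADII.values())
    pairs = tree.query_pairs(max_r, output_type="ndarray")

    # residue-index pairs joined by a disulfide
    ss_pairs: set[frozenset[int]] = set()
    sg = [(k, res_idx[k]) for k in range(len(names)) if names[k] == "SG"]
    for a in range(len(sg)):
        for b in range(a + 1, len(sg)):
            i, ri = sg[a]
            j, rj = sg[b]
            if np.linalg.norm(coords[i] - coords[j]) <= 2.5:
                ss_pairs.add(frozenset((ri, rj)))

    n_clashes = 0
    for i, j in pairs:
        ri, rj = res_idx[i], res_idx[j]
        if ri == rj:
            continue
        if elements[i] == "H" or elements[j] == "H":
            continue
        cutoff = VDW_RADII.get(elements[i], 1.7) + VDW_RADII.get(elements[j], 1.7) \
            - CLASH_TOLERANCE
        if np.linalg.norm(coords[i] - coords[j]) >= cutoff:
            continue
        if residues[ri].chain_id == residues[rj].chain_id:
            if _bond_separation(names[i], residues[ri].seq_position,
                                names[j], residues[rj].seq_position) <= 3:
                continue
        if frozenset((ri, rj)) in ss_pairs and \
                {names[i], names[j]} <= {"SG", "CB"}:
            continue
        n_clashes += 1
    return n_clashes


def clash_zscore(structure: Structure) -> float:
    """Clash rate per 1000 heavy atoms standardized against the reference."""
    coords, elements, _, _ = _atom_table(structure)
    n_heavy = sum(1 for e in elements if e != "H")
    rate = count_clashes(structure) / n_heavy * 1000.0
    ref = _load_reference()["clash_rate_per_1000_atoms"]
    return float((rate - ref["mu"]) / ref["sigma"])


@lru_cache(maxsize=1)
def _load_potential() -> tuple[dict[tuple[str, str, int], float], np.ndarray]:
    import pandas as pd
    ref = resources.files("ldlr_varstruct") / "data" / "contact_potential.tsv"
    df = pd.read_csv(str(ref), sep="\t", comment="#")
    edges = np.array(sorted(set(df.bin_lo) | set(df.bin_hi)), dtype=float)
    table: dict[tuple[str, str, int], float] = {}
    for row in df.itertuples(index=False):
        b = int(np.searchsorted(edges, row.bin_lo, side="right")) - 1
        table[(row.class_a, row.class_b, b)] = float(row.value)
        table[(row.class_b, row.class_a, b)] = float(row.value)
    return table, edges


def _aa_class(one_letter: str) -> str:
    if one_letter in HYDROPHOBIC:
        return "H"
    if one_letter in CHARGED:
        return "C"
    return "P"


def contact_potential_score(structure: Structure,
                            identities: list[str] | None = None) -> float:
    """Sum of the contact potential over Cβ–Cβ pairs (sequence sep > 4).

    ``identities`` optionally overrides the residue identities (used for
    decoys: shuffled identities on fixed coordinates).  Cα substitutes for
    the missing Cβ of glycine.
    """
    residues = structure.residues
    if identities is None:
        identities = [r.one_letter for r in residues]
    coords = []
    for res in residues:
        cb = res.atom("CB") or res.atom("CA")
        if cb is None:
            raise ValueError(f"residue {res.seq_position} lacks CB/CA")
        coords.append(cb.coord)
    coords = np.asarray(coords)
    table, edges = _load_potential()
    score = 0.0
    n_pairs = 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if residues[i].chain_id == residues[j].chain_id and \
                    abs(residues[i].seq_position - residues[j].seq_position) <= 4:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d >= edges[-1]:
                continue
            b = int(np.searchsorted(edges, d, side="right")) - 1
            score += table.get((_aa_class(identities[i]),
                                _aa_class(identities[j]), b), 0.0)
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no residue pairs beyond sequence separation 4")
    return score


def potential_zscore(structure: Structure, n_decoys: int = 100,
                     seed: int = 0) -> float:
    """Native contact-potential score standardized against shuffled decoys.

    Decoys shuffle the residue identities over the fixed coordinates; a
    more negative z means the native identity arrangement scores better
    (lower) than random, i.e. a plausibly packed model.
    """
    if n_decoys < 20:
        raise ValueError("need at least 20 decoys for a stable z-score")
    native = contact_potential_score(structure)
    rng = np.random.default_rng(seed)
    identities = [r.one_letter for r in structure.residues]
    decoy_scores = np.empty(n_decoys)
    for k in range(n_decoys):
        shuffled = list(identities)
        rng.shuffle(shuffled)
        decoy_scores[k] = contact_potential_score(structure, shuffled)
    sd = float(np.std(decoy_scores))
    if sd < 1e-9:  # degenerate decoy set (e.g. uniform identities)
        return 0.0
    return float((native - float(np.mean(decoy_scores))) / sd)


def quality_report(structure: Structure, n_decoys: int = 100,
                   seed: int = 0) -> QualityReport:
    """Full quality panel for one structure."""
    core, allowed, rama_z = ramachandran_stats(structure)
    return QualityReport(
        structure_id=structure.id,
        rama_core_fraction=core,
        rama_allowed_fraction=allowed,
        rama_outlier_z=rama_z,
        hbond_fraction=hbond_fraction(structure),
        clash_z=clash_zscore(structure),
        potential_z=potential_zscore(structure, n_decoys=n_decoys, seed=seed),
    )
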