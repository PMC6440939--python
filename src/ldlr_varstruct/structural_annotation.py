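"""Geometric annotation of structural roles: disulfides, Ca²⁺ coordination,
hydrophobic-core membership, conservation, and glycosylation proximity.

Class-A repeats owe their fold to three disulfide bonds and a single
Ca²⁺ ion chelated by a cluster of acidic residues; variants that remove a
bonded cysteine or a coordinating oxygen are mechanistically distinct from
generic destabilizers, so these roles are detected explicitly from the
model geometry rather than inferred from sequence motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as bst

from .alignment_conservation import ConservationProfile
from .structure_io import Residue, Structure
from .variant_catalog import Variant

__all__ = [
    "DisulfideBond",
    "CaSite",
    "ResidueAnnotation",
    "detect_disulfides",
    "detect_ca_sites",
    "relative_accessibility",
    "annotate_residues",
    "variant_role_flags",
    "DISULFIDE_CUTOFF",
    "CA_COORDINATION_CUTOFF",
    "CORE_RSA_THRESHOLD",
]

#: Sγ–Sγ distance ceiling for a covalent disulfide (Å).
DISULFIDE_CUTOFF = 2.5
#: Ca²⁺–oxygen coordination distance ceiling (Å); mean Ca–O is ~2.4 Å,
#: widened to tolerate modeling error.
CA_COORDINATION_CUTOFF = 3.2
#: Relative solvent accessibility at or below which a residue is "core".
CORE_RSA_THRESHOLD = 0.15

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Theoretical maximum accessible surface areas (Å², Tien et al. set).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Amino acids whose side chain carries at least one oxygen.
SIDECHAIN_OXYGEN_AA = set("DENQSTY")


@dataclass
class DisulfideBond:
    residue_a: Residue
    residue_b: Residue
    s_s_distance: float

    def positions(self) -> tuple[int, int]:
        return tuple(sorted((self.residue_a.seq_position, self.residue_b.seq_position)))


@dataclass
class CaSite:
    ion: Residue
    coordinating_residues: list[Residue]
    coordinating_atoms: list[tuple[Residue, str, float]]  # (residue, atom name, Å)


@dataclass
class ResidueAnnotation:
    position: int
    res_name: str = ""
    rsa: float = float("nan")
    is_core: bool = False
    in_disulfide: bool = False
    coordinates_ca: bool = False
    ca_via_sidechain: bool = False
    ca_via_backbone: bool = False
    conservation_z: float = float("nan")
    is_conserved: bool = False
    near_glyco: bool = False
    glyco_site: bool = False


def detect_disulfides(structure: Structure) -> list[DisulfideBond]:
    """Find disulfide bonds as Cys Sγ pairs within the covalent cutoff.

    Candidate pairs are matched greedily nearest-first so that each cysteine
    joins at most one bond; a third cysteine crowding a formed bond is left
    unpaired with a warning.
    """
    cys = []
    for res in structure.residues:
        if res.res_name != "CYS":
            continue
        sg = res.atom("SG")
        if sg is None:
            warnings.warn(
                f"Cys {res.seq_position} has no SG atom; skipped", stacklevel=2)
            continue
        cys.append((res, sg.coord))

    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1] - cys[j][1]))
            if d <= DISULFIDE_CUTOFF:
                candidates.append((d, i, j))
    candidates.sort(key=lambda t: t[0])

    used: set[int] = set()
    bonds: list[DisulfideBond] = []
    for d, i, j in candidates:
        if i in used or j in used:
            warnings.warn(
                f"Cys {cys[i][0].seq_position}/{cys[j][0].seq_position} within "
                "disulfide range but partner already bonded; left unpaired",
                stacklevel=2)
            continue
        used.update((i, j))
        bonds.append(DisulfideBond(cys[i][0], cys[j][0], d))
    return bonds


def detect_ca_sites(structure: Structure,
                    cutoff: float = CA_COORDINATION_CUTOFF) -> list[CaSite]:
    """Identify Ca²⁺ coordination shells.

    For every calcium ion, all protein oxygen atoms (side-chain carboxylate,
    carbonyl, hydroxyl, and backbone carbonyl O) within ``cutoff`` Å are
    collected; a site with fewer than 4 coordinating oxygens is reported
    with a warning since class-A geometry implies a higher coordination
    number.
    """
    sites: list[CaSite] = []
    for ion in structure.ions:
        if not any(a.element == "Ca" for a in ion.atoms):
            continue
        ion_pos = ion.atoms[0].coord
        atoms: list[tuple[Residue, str, float]] = []
        for res in structure.residues:
            for atom in res.atoms:
                if atom.element != "O":
                    continue
                d = float(np.linalg.norm(atom.coord - ion_pos))
                if d <= cutoff:
                    atoms.append((res, atom.name, d))
        atoms.sort(key=lambda t: (t[0].seq_position, t[1]))
        residues = []
        seen = set()
        for res, _, _ in atoms:
            if id(res) not in seen:
                seen.add(id(res))
                residues.append(res)
        if len(atoms) < 4:
            warnings.warn(
                f"Ca site at ion {ion.seq_position}: only {len(atoms)} "
                "coordinating oxygens within cutoff", stacklevel=2)
        sites.append(CaSite(ion=ion, coordinating_residues=residues,
                            coordinating_atoms=atoms))
    return sites


def _to_atom_array(structure: Structure) -> tuple[bst.AtomArray, list[int]]:
    """Flatten protein residues into a biotite AtomArray.

    Returns the array plus, per atom, the index of its residue in
    ``structure.residues``.
    """
    n = sum(len(r.atoms) for r in structure.residues)
    arr = bst.AtomArray(n)
    owner: list[int] = []
    k = 0
    for ridx, res in enumerate(structure.residues):
        for atom in res.atoms:
            arr.coord[k] = atom.coord
            arr.atom_name[k] = atom.name
            arr.element[k] = atom.element.upper()
            arr.res_id[k] = res.seq_position
            arr.res_name[k] = res.res_name
            arr.chain_id[k] = res.chain_id
            arr.hetero[k] = False
            owner.append(ridx)
            k += 1
    return arr, owner


def solvent_accessible_surface(structure: Structure,
                               point_number: int = 960) -> np.ndarray:
    """Per-residue solvent-accessible surface area (Å², Shrake–Rupley).

    Probe radius 1.4 Å with single-element van der Waals radii, so the
    decomposition over residues sums exactly to the whole-structure SASA.
    """
    arr, owner = _to_atom_array(structure)
    atom_sasa = bst.sasa(arr, probe_radius=1.4, point_number=point_number,
                         vdw_radii="Single")
    per_res = np.zeros(len(structure.residues))
    for k, ridx in enumerate(owner):
        if np.isfinite(atom_sasa[k]):
            per_res[ridx] += atom_sasa[k]
    return per_res


def relative_accessibility(structure: Structure,
                           point_number: int = 960) -> dict[int, float]:
    """Relative solvent accessibility per residue, clipped to [0, 1].

    Absolute SASA divided by the residue's theoretical maximum area.
    Keyed by sequence position.
    """
    sasa = solvent_accessible_surface(structure, point_number=point_number)
    rsa: dict[int, float] = {}
    for res, area in zip(structure.residues, sasa):
        max_area = MAX_ASA.get(res.one_letter, 200.0)
        rsa[res.seq_position] = float(np.clip(area / max_area, 0.0, 1.0))
    return rsa


def annotate_residues(structure: Structure,
                      disulfides: list[DisulfideBond],
                      ca_sites: list[CaSite],
                      profile: ConservationProfile | None = None,
                      glyco_sites: list[int] | None = None,
                      window: int = 5,
                      core_rsa: float = CORE_RSA_THRESHOLD,
                      rsa: dict[int, float] | None = None
                      ) -> dict[int, ResidueAnnotation]:
    """Merge all structural roles into one record per residue.

    ``near_glyco`` is true iff the sequence distance to the nearest
    glycosylation site is at most ``window`` residues (a site is trivially
    near itself).  ``profile`` scores are indexed by residue order along the
    structure.
    """
    glyco_sites = list(glyco_sites or [])
    positions = {r.seq_position for r in structure.residues}
    valid_glyco = []
    for g in glyco_sites:
        if g in positions:
            valid_glyco.append(g)
        else:
            warnings.warn(f"glycosylation site {g} outside sequence; ignored",
                          stacklevel=2)

    if rsa is None:
        rsa = relative_accessibility(structure)
    ss_positions = {p for b in disulfides for p in
                    (b.residue_a.seq_position, b.residue_b.seq_position)}
    ca_side: set[int] = set()
    ca_back: set[int] = set()
    for site in ca_sites:
        for res, atom_name, _ in site.coordinating_atoms:
            if atom_name in BACKBONE_ATOMS:
                ca_back.add(res.seq_position)
            else:
                ca_side.add(res.seq_position)

    annotations: dict[int, ResidueAnnotation] = {}
    for idx, res in enumerate(structure.residues):
        pos = res.seq_position
        ann = ResidueAnnotation(position=pos, res_name=res.res_name)
        ann.rsa = rsa.get(pos, float("nan"))
        ann.is_core = bool(ann.rsa <= core_rsa)
        ann.in_disulfide = pos in ss_positions
        ann.ca_via_sidechain = pos in ca_side
        ann.ca_via_backbone = pos in ca_back
        ann.coordinates_ca = ann.ca_via_sidechain or ann.ca_via_backbone
        if profile is not None and idx < len(profile):
            ann.conservation_z = float(profile.scores[idx])
            ann.is_conserved = bool(profile.conserved_flags[idx])
        if valid_glyco:
            dist = min(abs(pos - g) for g in valid_glyco)
            ann.near_glyco = dist <= window
            ann.glyco_site = dist == 0
        annotations[pos] = ann
    return annotations


@dataclass
class RoleFlags:
    alters_disulfide: bool = False
    alters_ca_site: bool = False
    at_conserved: bool = False
    at_core: bool = False
    near_glyco: bool = False
    at_glyco: bool = False

    @property
    def in_any_class(self) -> bool:
        return self.alters_disulfide or self.alters_ca_site or self.at_conserved


def variant_role_flags(variant: Variant,
                       annotations: dict[int, ResidueAnnotation]) -> RoleFlags:
    """Structural-role flags for one missense variant.

    ``alters_disulfide``: the reference residue is a disulfide-bonded Cys
    and the substitution removes the thiol.  ``alters_ca_site``: the residue
    coordinates Ca²⁺ through a side-chain oxygen (any substitution changes
    the shell), or only through backbone carbonyls but the substitution
    involves Pro or Gly (the cases that perturb backbone geometry).
    """
    ch = variant.change
    ann = annotations.get(ch.position)
    if ann is None:
        warnings.warn(f"variant {ch} at unannotated position; all flags false",
                      stacklevel=2)
        return RoleFlags()
    flags = RoleFlags(
        at_conserved=ann.is_conserved,
        at_core=ann.is_core,
        near_glyco=ann.near_glyco,
        at_glyco=ann.glyco_site,
    )
    if ann.in_disulfide and ch.ref_aa == "C" and ch.alt_aa != "C":
        flags.alters_disulfide = True
    if ann.ca_via_sidechain:
        flags.alters_ca_site = True
    elif ann.ca_via_backbone and ("P" in (ch.ref_aa, ch.alt_aa)
                                  or "G" in (ch.ref_aa, ch.alt_aa)):
        flags.alters_ca_site = True
    return flags
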