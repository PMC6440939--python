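"""Generators for every input the pipeline consumes, with machine-readable
planted truth: mini-domain structures with known disulfides and a Ca²⁺
site, ideal/decoy backbones for quality metrics, MSAs with planted
conserved columns, and variant/ΔΔG tables with planted clinical classes
and condition differences.

The mini-domain is a class-A-like toy: ~40 residues, three disulfide
bonds, one chelated Ca²⁺, and a hydrophobic interior.  Its Cα trace is a
compact self-avoiding lattice path (not a physical fold); side chains are
reduced to Cβ plus the functionally required terminal atoms (Sγ for Cys,
carboxylate oxygens for the Ca²⁺ coordinators), which is all the geometric
detectors need.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import place_atom
from .structure_io import (
    AA1_TO_3, Atom, DomainEntry, DomainMap, Residue, Structure,
)

__all__ = [
    "MiniDomainSpec",
    "build_minidomain",
    "build_helix",
    "build_backbone",
    "perturb_structure",
    "synth_msa",
    "synth_domain_map",
    "synth_sequence",
    "synth_variant_table",
    "write_fixture_directory",
]

LATTICE_SPACING = 3.8  # Å between consecutive Cα positions
SS_BOND_LENGTH = 2.05  # planted Sγ–Sγ distance, Å
CA_O_DISTANCE = 2.4    # planted ion–oxygen distance, Å
MAX_PAIR_CA_DIST = 7.0  # feasibility limit for a planted disulfide

FILLER_AA = "ASTEKQNRG"  # surface filler residue pool


@dataclass
class MiniDomainSpec:
    n_residues: int = 40
    disulfide_pairs: tuple[tuple[int, int], ...] = ((2, 7), (10, 15), (34, 39))
    ca_coordinators: tuple[int, ...] = (22, 27)
    hydrophobic_core_positions: tuple[int, ...] = (23, 26)
    surface_hydrophobic_positions: tuple[int, ...] = (5,)
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [p for pair in self.disulfide_pairs for p in pair]
        special = flat + list(self.ca_coordinators) + \
            list(self.hydrophobic_core_positions) + \
            list(self.surface_hydrophobic_positions)
        if len(set(flat)) != len(flat):
            raise ValueError("disulfide pairs must be disjoint")
        if any(not 1 <= p <= self.n_residues for p in special):
            raise ValueError("planted positions must lie in 1..n_residues")


def _snake_path(n: int) -> np.ndarray:
    """Boustrophedon path through a 4 x 4 x nz lattice; consecutive sites
    are always one lattice step apart."""
    nx = ny = 4
    sites = []
    z = 0
    while len(sites) < n:
        ys = range(ny) if z % 2 == 0 else range(ny - 1, -1, -1)
        for y in ys:
            row = len(sites) // nx
            xs = range(nx) if row % 2 == 0 else range(nx - 1, -1, -1)
            for x in xs:
                sites.append((x, y, z))
                if len(sites) == n:
                    return np.array(sites, dtype=float) * LATTICE_SPACING
        z += 1
    return np.array(sites, dtype=float) * LATTICE_SPACING


def build_minidomain(spec: MiniDomainSpec | None = None
                     ) -> tuple[Structure, dict]:
    """Build a class-A-like mini-domain with planted geometry.

    Returns the structure and a truth dictionary recording the planted
    disulfide pairs, Ca²⁺ coordinators (plus any backbone oxygens the
    generator's own distance scan finds within the coordination cutoff),
    and the interior/surface position sets.
    """
    spec = spec or MiniDomainSpec()
    rng = np.random.default_rng(spec.seed)
    ca = _snake_path(spec.n_residues)
    centroid = ca.mean(axis=0)

    for a, b in spec.disulfide_pairs:
        d = float(np.linalg.norm(ca[a - 1] - ca[b - 1]))
        if d > MAX_PAIR_CA_DIST:
            raise ValueError(
                f"disulfide pair ({a},{b}) infeasible: Cα distance {d:.1f} Å "
                f"exceeds {MAX_PAIR_CA_DIST} Å on the lattice path")

    cys_positions = {p for pair in spec.disulfide_pairs for p in pair}
    asp_positions = set(spec.ca_coordinators)
    leu_positions = set(spec.hydrophobic_core_positions) | \
        set(spec.surface_hydrophobic_positions)

    names = {}
    for pos in range(1, spec.n_residues + 1):
        if pos in cys_positions:
            names[pos] = "CYS"
        elif pos in asp_positions:
            names[pos] = "ASP"
        elif pos in leu_positions:
            names[pos] = "LEU"
        else:
            names[pos] = AA1_TO_3[FILLER_AA[rng.integers(len(FILLER_AA))]]

    interior = set(spec.hydrophobic_core_positions) | asp_positions

    # local frames along the path
    cb_coords = {}
    atoms_by_pos: dict[int, list[Atom]] = {}
    for i in range(spec.n_residues):
        pos = i + 1
        if i < spec.n_residues - 1:
            t = ca[i + 1] - ca[i]
        else:
            t = ca[i] - ca[i - 1]
        t = t / np.linalg.norm(t)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, t)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = ref - np.dot(ref, t) * t
        u /= np.linalg.norm(u)
        w = np.cross(t, u)

        n_coord = ca[i] - 1.2 * t + 0.4 * u
        c_coord = ca[i] + 1.2 * t + 0.4 * u
        o_coord = c_coord + 1.23 * w
        inward = centroid - ca[i]
        norm = np.linalg.norm(inward)
        inward = inward / norm if norm > 1e-9 else u
        cb_dir = inward if pos in interior else -inward
        cb = ca[i] + 1.53 * cb_dir
        cb_coords[pos] = cb

        atoms = [
            Atom("N", "N", n_coord),
            Atom("CA", "C", ca[i]),
            Atom("C", "C", c_coord),
            Atom("O", "O", o_coord),
        ]
        if names[pos] != "GLY":
            atoms.append(Atom("CB", "C", cb))
        atoms_by_pos[pos] = atoms

    # plant disulfides: Sγ pair symmetric about the Cβ midpoint
    for a, b in spec.disulfide_pairs:
        cb_a, cb_b = cb_coords[a], cb_coords[b]
        axis = cb_b - cb_a
        axis /= np.linalg.norm(axis)
        mid = (cb_a + cb_b) / 2.0
        atoms_by_pos[a].append(Atom("SG", "S", mid - axis * SS_BOND_LENGTH / 2))
        atoms_by_pos[b].append(Atom("SG", "S", mid + axis * SS_BOND_LENGTH / 2))

    # plant the Ca site: ion placed clear of the protein, carboxylate
    # oxygens of each coordinator at the target ion-O distance
    coord_ca = np.array([ca[p - 1] for p in spec.ca_coordinators])
    mid = coord_ca.mean(axis=0)
    all_atoms = np.array([a.coord for atoms in atoms_by_pos.values()
                          for a in atoms])
    ion_pos = None
    for h in np.arange(2.0, 6.05, 0.1):
        for d in (np.array([0, 0, 1.0]), np.array([0, 0, -1.0]),
                  np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            candidate = mid + h * d
            if np.min(np.linalg.norm(all_atoms - candidate, axis=1)) >= 2.6:
                ion_pos = candidate
                break
        if ion_pos is not None:
            break
    if ion_pos is None:
        raise ValueError("could not place the Ca ion clear of the protein")

    for p in spec.ca_coordinators:
        v = cb_coords[p] - ion_pos
        v /= np.linalg.norm(v)
        perp = np.cross(v, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(v, np.array([1.0, 0.0, 0.0]))
        perp /= np.linalg.norm(perp)
        for sign, name in ((1.0, "OD1"), (-1.0, "OD2")):
            direction = v + 0.25 * sign * perp
            direction /= np.linalg.norm(direction)
            atoms_by_pos[p].append(
                Atom(name, "O", ion_pos + CA_O_DISTANCE * direction))

    residues = [
        Residue(chain_id="A", seq_position=pos, res_name=names[pos],
                atoms=atoms_by_pos[pos])
        for pos in range(1, spec.n_residues + 1)
    ]
    ion = Residue(chain_id="A", seq_position=spec.n_residues + 1,
                  res_name="CA", atoms=[Atom("CA", "Ca", ion_pos)],
                  is_hetero=True)
    structure = Structure(id="minidomain", residues=residues, ions=[ion])

    # generator-side scan: backbone oxygens that end up inside the shell
    backbone_coordinators = sorted(
        pos for pos in range(1, spec.n_residues + 1)
        for a in atoms_by_pos[pos]
        if a.name == "O"
        and np.linalg.norm(a.coord - ion_pos) <= 3.2
    )
    truth = {
        "disulfide_pairs": [sorted(p) for p in spec.disulfide_pairs],
        "ca_sidechain_coordinators": sorted(spec.ca_coordinators),
        "ca_backbone_coordinators": backbone_coordinators,
        "hydrophobic_core_positions": sorted(spec.hydrophobic_core_positions),
        "surface_hydrophobic_positions":
            sorted(spec.surface_hydrophobic_positions),
        "sequence": "".join(
            {v: k for k, v in AA1_TO_3.items()}[names[p]]
            for p in range(1, spec.n_residues + 1)),
        "seed": spec.seed,
    }
    return structure, truth


IDEAL = {  # bond lengths (Å) and angles (deg) for backbone construction
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7, "ca_c_o": 120.8,
}


def build_backbone(phi_psi: list[tuple[float, float]],
                   sequence: str | None = None,
                   structure_id: str = "backbone") -> Structure:
    """Build an all-backbone chain (N, CA, C, O, CB) from φ/ψ dihedrals.

    Ideal bond lengths and angles, ω fixed at 180°.  φ of the first residue
    is unused (no preceding carbonyl).
    """
    n = len(phi_psi)
    if n < 2:
        raise ValueError("need at least 2 residues")
    sequence = sequence or "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length must match phi/psi list")

    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([IDEAL["n_ca"], 0.0, 0.0])
    theta = np.radians(IDEAL["n_ca_c"])
    c0 = ca0 + IDEAL["ca_c"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         IDEAL["c_n"], IDEAL["ca_c_n"], psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          IDEAL["n_ca"], IDEAL["c_n_ca"], 180.0)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         IDEAL["ca_c"], IDEAL["n_ca_c"], phi_psi[i][0])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O anti to the next amide N; last residue uses its own psi
    for i in range(n):
        psi = phi_psi[i][1]
        coords[i]["O"] = place_atom(coords[i]["N"], coords[i]["CA"],
                                    coords[i]["C"], IDEAL["c_o"],
                                    IDEAL["ca_c_o"], psi + 180.0)
        if sequence[i] != "G":
            coords[i]["CB"] = place_atom(coords[i]["C"], coords[i]["N"],
                                         coords[i]["CA"], 1.53, 110.4, 122.5)

    residues = []
    for i in range(n):
        atoms = [Atom(name, name[0], coord)
                 for name, coord in coords[i].items()]
        residues.append(Residue(chain_id="A", seq_position=i + 1,
                                res_name=AA1_TO_3[sequence[i]], atoms=atoms))
    return Structure(id=structure_id, residues=residues)


def build_helix(n_residues: int = 20, sequence: str | None = None) -> Structure:
    """Ideal α-helix (φ = −57°, ψ = −47°)."""
    return build_backbone([(-57.0, -47.0)] * n_residues, sequence,
                          structure_id="ideal_helix")


def build_random_coil(n_residues: int, seed: int = 0) -> Structure:
    """Backbone with uniformly random dihedrals — a Ramachandran decoy."""
    rng = np.random.default_rng(seed)
    phi_psi = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
               for _ in range(n_residues)]
    return build_backbone(phi_psi, structure_id=f"random_coil_{seed}")


def perturb_structure(structure: Structure, magnitude: float,
                      seed: int = 0) -> Structure:
    """Add isotropic Gaussian noise (sd = magnitude, Å) to all coordinates."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)

    def _noisy(res: Residue) -> Residue:
        atoms = [Atom(a.name, a.element,
                      a.coord + rng.normal(0.0, magnitude, 3)
                      if magnitude > 0 else a.coord.copy(),
                      a.occupancy, a.b_factor)
                 for a in res.atoms]
        return Residue(res.chain_id, res.seq_position, res.res_name, atoms,
                       res.insertion_code, res.is_hetero)

    return Structure(id=f"{structure.id}_perturbed",
                     residues=[_noisy(r) for r in structure.residues],
                     ions=[_noisy(r) for r in structure.ions],
                     condition_label=structure.condition_label)


MSA_BACKGROUND = "AVLIDK"  # 6-letter background alphabet


def synth_msa(n_rows: int = 50, n_cols: int = 40,
              conserved_columns: tuple[int, ...] = (3, 7, 11, 15, 19, 23, 27,
                                                    31, 35, 39),
              seed: int = 0) -> tuple[list[str], dict]:
    """MSA with planted invariant columns (1-based) on a uniform background."""
    if any(not 1 <= c <= n_cols for c in conserved_columns):
        raise ValueError("conserved columns must lie in 1..n_cols")
    rng = np.random.default_rng(seed)
    conserved = set(conserved_columns)
    letters = {c: MSA_BACKGROUND[rng.integers(len(MSA_BACKGROUND))]
               for c in conserved}
    rows = []
    for _ in range(n_rows):
        row = [
            letters[c + 1] if (c + 1) in conserved
            else MSA_BACKGROUND[rng.integers(len(MSA_BACKGROUND))]
            for c in range(n_cols)
        ]
        rows.append("".join(row))
    truth = {"conserved_columns": sorted(conserved), "n_rows": n_rows,
             "n_cols": n_cols, "seed": seed}
    return rows, truth


def synth_domain_map() -> DomainMap:
    """A fixture domain architecture shaped like the LDLR: seven ~40-residue
    class-A repeats, three EGF-like repeats, a six-bladed propeller region,
    an O-linked sugar region, transmembrane helix and cytoplasmic tail.
    Precursor coordinates with the standard 21-residue signal peptide."""
    entries = [
        DomainEntry("LA1", "classA", 25, 64),
        DomainEntry("LA2", "classA", 66, 105),
        DomainEntry("LA3", "classA", 107, 146),
        DomainEntry("LA4", "classA", 148, 187),
        DomainEntry("LA5", "classA", 196, 235),
        DomainEntry("LA6", "classA", 237, 276),
        DomainEntry("LA7", "classA", 278, 317),
        DomainEntry("EGF1", "EGF", 318, 353),
        DomainEntry("EGF2", "EGF", 355, 393),
        DomainEntry("propeller", "classB", 394, 650),
        DomainEntry("EGF3", "EGF", 651, 693),
        DomainEntry("O-linked", "O-linked", 700, 755),
        DomainEntry("TM", "TM", 768, 790),
        DomainEntry("cytoplasmic", "cytoplasmic", 791, 839),
    ]
    return DomainMap(entries=entries)


def synth_sequence(length: int = 860, seed: int = 0) -> str:
    """Random canonical sequence used as the reference frame for variant
    tables (not the real receptor sequence)."""
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(len(aas), size=length))


_CLASS_TO_LABEL = {
    "pathogenic": ("clinvar", "Pathogenic"),
    "benign": ("clinvar", "Benign"),
    "vus": ("clinvar", "Uncertain significance"),
}


def synth_variant_table(domain_map: DomainMap | None = None,
                        n_variants: int = 400,
                        class_fractions: dict[str, float] | None = None,
                        delta_fractions: dict[str, float] | None = None,
                        role_fractions: dict[str, float] | None = None,
                        sequence: str | None = None,
                        seed: int = 0) -> tuple["pd.DataFrame", "pd.DataFrame", dict]:
    """Variant + ΔΔG tables with planted truth.

    Clinical classes are planted directly through unambiguous source labels
    (fractions default pathogenic 0.30 / benign 0.20 / VUS 0.50).  Per
    condition, the endosomal ΔΔG is drawn from a class-dependent
    distribution — pathogenic shifted to +2.5 kcal/mol (scale 1.5), benign
    N(0, 0.3) truncated to |ΔΔG| ≤ 0.6 so no benign variant is
    destabilizing, VUS an even mixture — and the extracellular value is the
    endosomal one plus a condition delta planted past the category
    boundaries to hit the target gray/orange/red fractions exactly
    (defaults 0.56 / 0.14 / 0.30).  Optional role fractions plant boolean
    structural-role flags used by the reporting layer.

    Returns (variant table, ddg table, truth dict).
    """
    import pandas as pd

    domain_map = domain_map or synth_domain_map()
    class_fractions = class_fractions or {"pathogenic": 0.30, "benign": 0.20,
                                          "vus": 0.50}
    delta_fractions = delta_fractions or {"gray": 0.56, "orange": 0.14,
                                          "red": 0.30}
    role_fractions = role_fractions or {"conserved": 0.45, "disulfide": 0.20,
                                        "ca_site": 0.15}
    for name, fr in (("class_fractions", class_fractions),
                     ("delta_fractions", delta_fractions)):
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")

    rng = np.random.default_rng(seed)
    class_a_positions = [
        p for e in domain_map.entries_of_class("classA")
        for p in range(e.start, e.end + 1)
    ]
    if n_variants > len(class_a_positions) * 19:
        raise ValueError("n_variants exceeds available (position, alt) space")
    sequence = sequence or synth_sequence(
        length=max(p for p in class_a_positions) + 50, seed=seed)

    aas = "ACDEFGHIKLMNPQRSTVWY"
    keys: set[tuple[int, str]] = set()
    while len(keys) < n_variants:
        pos = int(class_a_positions[rng.integers(len(class_a_positions))])
        ref = sequence[pos - 1]
        alt = aas[rng.integers(len(aas))]
        if alt != ref:
            keys.add((pos, alt))
    ordered = sorted(keys)
    rng.shuffle(ordered)

    def _partition(n: int, fractions: dict[str, float],
                   order: tuple[str, ...]) -> list[str]:
        counts = {k: int(round(fractions[k] * n)) for k in order}
        drift = n - sum(counts.values())
        counts[order[0]] += drift  # rounding drift absorbed by first bin
        labels = [k for k in order for _ in range(counts[k])]
        rng.shuffle(labels)
        return labels

    classes = _partition(n_variants, class_fractions,
                         ("vus", "pathogenic", "benign"))
    categories = _partition(n_variants, delta_fractions,
                            ("gray", "orange", "red"))

    delta_ranges = {"gray": (0.0, 1.7), "orange": (1.85, 2.95),
                    "red": (3.1, 6.0)}

    variant_rows, ddg_rows = [], []
    truth_variants = {}
    for (pos, alt), clin, cat in zip(ordered, classes, categories):
        ref = sequence[pos - 1]
        hgvs = f"p.{AA1_TO_3[ref].capitalize()}{pos}{AA1_TO_3[alt].capitalize()}"
        source, label = _CLASS_TO_LABEL[clin]
        variant_rows.append({"source": source, "classification": label,
                             "hgvs_p": hgvs})
        if clin == "pathogenic" or (clin == "vus" and rng.random() < 0.5):
            ddg_endo = float(rng.normal(2.5, 1.5))
        else:
            ddg_endo = float(np.clip(rng.normal(0.0, 0.3), -0.6, 0.6))
        delta = float(rng.uniform(*delta_ranges[cat]))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ddg_extra = ddg_endo + sign * delta
        ddg_rows.append({"variant": hgvs,
                         "ddg_extracellular": round(ddg_extra, 4),
                         "ddg_endosomal": round(ddg_endo, 4)})
        roles = {k: bool(rng.random() < fr)
                 for k, fr in role_fractions.items()}
        truth_variants[f"{ref}{pos}{alt}"] = {
            "clinical_class": clin,
            "delta_category": cat,
            "ddg_extracellular": round(ddg_extra, 4),
            "ddg_endosomal": round(ddg_endo, 4),
            "domain": domain_map.lookup(pos),
            "roles": roles,
        }

    truth = {
        "n_variants": n_variants,
        "class_counts": {k: classes.count(k) for k in class_fractions},
        "delta_counts": {k: categories.count(k) for k in delta_fractions},
        "variants": truth_variants,
        "seed": seed,
    }
    return (pd.DataFrame(variant_rows), pd.DataFrame(ddg_rows), truth)


def write_fixture_directory(out_dir: str | Path, seed: int = 0,
                            n_variants: int = 400) -> dict:
    """Write a complete fixture set: mini.pdb, domains.tsv, msa.fasta,
    variants.tsv, ddg.tsv, glyco.txt, truth.json.  Returns the merged truth.
    """
    from .structure_io import write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    structure, mini_truth = build_minidomain(MiniDomainSpec(seed=seed))
    write_structure(structure, out / "mini.pdb")

    domain_map = synth_domain_map()
    with open(out / "domains.tsv", "w") as fh:
        fh.write("domain_name\tclass\tstart\tend\n")
        for e in domain_map.entries:
            fh.write(f"{e.domain_name}\t{e.domain_class}\t{e.start}\t{e.end}\n")

    msa, msa_truth = synth_msa(seed=seed)
    with open(out / "msa.fasta", "w") as fh:
        for i, row in enumerate(msa):
            fh.write(f">seq{i}\n{row}\n")

    sequence = synth_sequence(seed=seed)
    variants, ddg, table_truth = synth_variant_table(
        domain_map, n_variants=n_variants, sequence=sequence, seed=seed)
    variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    ddg.to_csv(out / "ddg.tsv", sep="\t", index=False)
    with open(out / "sequence.txt", "w") as fh:
        fh.write(sequence + "\n")

    glyco = [700, 710, 721, 735, 748]  # synthetic O-linked-region sites
    with open(out / "glyco.txt", "w") as fh:
        fh.writelines(f"{g}\n" for g in glyco)

    truth = {"minidomain": mini_truth, "msa": msa_truth,
             "variant_table": table_truth, "glyco_sites": glyco, "seed": seed}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
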