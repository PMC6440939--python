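import numpy as np
import pytest

from conftest import rigid_transform
from ldlr_varstruct.alignment_conservation import conservation_profile
from ldlr_varstruct.structural_annotation import (
    annotate_residues, detect_ca_sites, detect_disulfides,
    relative_accessibility, solvent_accessible_surface, variant_role_flags,
)
from ldlr_varstruct.structure_io import Atom, Residue, Structure
from ldlr_varstruct.synthetic_data import build_minidomain, synth_msa
from ldlr_varstruct.variant_catalog import Variant, VariantChange


def _cys(pos, sg_xyz, cb_xyz=None):
    atoms = [Atom("N", "N", (pos * 5.0, 0, 0)),
             Atom("CA", "C", (pos * 5.0 + 1.4, 0, 0)),
             Atom("C", "C", (pos * 5.0 + 2.8, 0, 0)),
             Atom("O", "O", (pos * 5.0 + 2.8, 1.2, 0)),
             Atom("SG", "S", sg_xyz)]
    if cb_xyz is not None:
        atoms.insert(4, Atom("CB", "C", cb_xyz))
    return Residue("A", pos, "CYS", atoms)


class TestDisulfides:
    def test_planted_pairs_recovered_exactly(self, minidomain):
        structure, truth = minidomain
        bonds = detect_disulfides(structure)
        assert sorted(list(b.positions()) for b in bonds) == \
            truth["disulfide_pairs"]
        assert all(b.s_s_distance == pytest.approx(2.05, abs=1e-6)
                   for b in bonds)

    def test_distant_cysteines_not_bonded(self):
        st = Structure("x", [_cys(1, (0, 0, 0)), _cys(2, (6.0, 0, 0))])
        assert detect_disulfides(st) == []

    def test_three_crowded_cysteines_give_one_bond(self):
        st = Structure("x", [_cys(1, (0, 0, 0)), _cys(2, (2.0, 0, 0)),
                             _cys(3, (0.0, 2.2, 0))])
        with pytest.warns(UserWarning):
            bonds = detect_disulfides(st)
        assert len(bonds) == 1
        assert bonds[0].s_s_distance == pytest.approx(2.0)

    def test_cys_without_sg_skipped_with_warning(self):
        broken = Residue("A", 9, "CYS", [Atom("CA", "C", (0, 0, 0))])
        st = Structure("x", [broken, _cys(2, (40, 0, 0))])
        with pytest.warns(UserWarning, match="no SG"):
            assert detect_disulfides(st) == []

    def test_invariant_under_rigid_transform(self, minidomain):
        structure, _ = minidomain
        moved = rigid_transform(structure, seed=5)
        a = sorted(list(b.positions()) for b in detect_disulfides(structure))
        b = sorted(list(b.positions()) for b in detect_disulfides(moved))
        assert a == b


class TestCaSites:
    def _site_structure(self):
        """Ca at origin; 4 carboxylate O and 2 backbone O at 2.4 Å."""
        def asp(pos, angle0):
            base = np.array([np.cos(angle0), np.sin(angle0), 0])
            atoms = [Atom("N", "N", base * 8), Atom("CA", "C", base * 7),
                     Atom("C", "C", base * 8 + [0, 0, 1.5]),
                     Atom("O", "O", base * 2.4 if pos <= 2 else base * 8
                          + [0, 1.2, 1.5]),
                     Atom("CB", "C", base * 5),
                     Atom("OD1", "O", base * 2.4),
                     Atom("OD2", "O", np.array([np.cos(angle0 + 0.3),
                                                np.sin(angle0 + 0.3), 0])
                          * 2.4)]
            return Residue("A", pos, "ASP", atoms)
        residues = [asp(1, 0.0), asp(2, 2.1), asp(3, 4.2)]
        ion = Residue("A", 99, "CA", [Atom("CA", "Ca", (0, 0, 0))],
                      is_hetero=True)
        return Structure("casite", residues, ions=[ion])

    def test_coordinating_atom_census(self):
        st = self._site_structure()
        sites = detect_ca_sites(st)
        assert len(sites) == 1
        names = sorted(n for _, n, _ in sites[0].coordinating_atoms)
        # residues 1,2 contribute backbone O + OD1 + OD2; residue 3 OD1+OD2
        assert names.count("OD1") == 3 and names.count("OD2") == 3
        assert names.count("O") == 2
        assert all(d <= 3.2 for _, _, d in sites[0].coordinating_atoms)

    def test_minidomain_planted_coordinators(self, minidomain):
        structure, truth = minidomain
        sites = detect_ca_sites(structure)
        assert len(sites) == 1
        side = sorted({r.seq_position
                       for r, n, _ in sites[0].coordinating_atoms
                       if n.startswith("OD")})
        back = sorted({r.seq_position
                       for r, n, _ in sites[0].coordinating_atoms if n == "O"})
        assert side == truth["ca_sidechain_coordinators"]
        assert back == truth["ca_backbone_coordinators"]
        assert len(sites[0].coordinating_atoms) >= 4

    def test_isolated_ion_reported_empty_with_warning(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", (0, 0, 0)),
                                      Atom("O", "O", (1.2, 0, 0))])
        ion = Residue("A", 9, "CA", [Atom("CA", "Ca", (6.2, 0, 0))],
                      is_hetero=True)
        st = Structure("x", [res], ions=[ion])
        with pytest.warns(UserWarning):
            sites = detect_ca_sites(st)
        assert sites[0].coordinating_atoms == []

    def test_zero_cutoff_finds_nothing(self, minidomain):
        structure, _ = minidomain
        with pytest.warns(UserWarning):
            sites = detect_ca_sites(structure, cutoff=0.0)
        assert all(not s.coordinating_atoms for s in sites)

    def test_no_ions_is_empty_not_error(self, helix):
        assert detect_ca_sites(helix) == []


def _numeric_sasa(structure, n_points=10000):
    """Independent SASA oracle: plain sphere-point sampling."""
    radii = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    atoms = [(a.coord, radii.get(a.element, 1.7) + 1.4)
             for r in structure.residues for a in r.atoms]
    coords = np.array([c for c, _ in atoms])
    rs = np.array([r for _, r in atoms])
    # Fibonacci sphere
    k = np.arange(n_points)
    phi = np.pi * (3 - np.sqrt(5)) * k
    z = 1 - 2 * (k + 0.5) / n_points
    rho = np.sqrt(1 - z * z)
    sphere = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    per_atom = []
    for i in range(len(atoms)):
        pts = coords[i] + rs[i] * sphere
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
        d[:, i] = np.inf
        exposed = np.all(d >= rs[None, :], axis=1)
        per_atom.append(4 * np.pi * rs[i] ** 2 * exposed.mean())
    return per_atom


class TestAccessibility:
    def test_free_glycine_fully_exposed(self):
        res = Residue("A", 1, "GLY", [Atom("N", "N", (0, 0, 0)),
                                      Atom("CA", "C", (1.45, 0, 0)),
                                      Atom("C", "C", (2.0, 1.4, 0)),
                                      Atom("O", "O", (3.2, 1.5, 0))])
        rsa = relative_accessibility(Structure("g", [res]))
        assert rsa[1] == pytest.approx(1.0, abs=0.1)

    def test_caged_residue_is_buried(self):
        """A residue enclosed in a shell of atoms has near-zero SASA,
        checked against a direct 10k-point numeric oracle."""
        center = Residue("A", 1, "ALA", [Atom("CA", "C", (0, 0, 0)),
                                         Atom("N", "N", (1.4, 0, 0)),
                                         Atom("C", "C", (-1.4, 0, 0)),
                                         Atom("O", "O", (0, 1.3, 0)),
                                         Atom("CB", "C", (0, -1.4, 0))])
        # cage: dense shell at radius 5
        shell_atoms = []
        golden = np.pi * (3 - np.sqrt(5))
        for k in range(120):
            z = 1 - 2 * (k + 0.5) / 120
            rho = np.sqrt(1 - z * z)
            p = np.array([rho * np.cos(golden * k), rho * np.sin(golden * k),
                          z]) * 5.0
            shell_atoms.append(Atom("CA", "C", p))
        cage = Residue("A", 2, "GLY", shell_atoms, is_hetero=False)
        st = Structure("cage", [center, cage])
        rsa = relative_accessibility(st)
        assert rsa[1] < 0.05
        oracle = _numeric_sasa(st)
        assert sum(oracle[:5]) == pytest.approx(0.0, abs=5.0)  # Å²

    def test_per_residue_decomposition_is_additive(self, minidomain):
        structure, _ = minidomain
        import biotite.structure as bst
        from ldlr_varstruct.structural_annotation import _to_atom_array
        per_res = solvent_accessible_surface(structure)
        arr, _ = _to_atom_array(structure)
        total = np.nansum(bst.sasa(arr, probe_radius=1.4, point_number=960,
                                   vdw_radii="Single"))
        assert per_res.sum() == pytest.approx(total, rel=0.01)

    def test_core_positions_more_buried_than_surface(self, minidomain):
        structure, truth = minidomain
        rsa = relative_accessibility(structure)
        core = [rsa[p] for p in truth["hydrophobic_core_positions"]]
        surface = [rsa[p] for p in truth["surface_hydrophobic_positions"]]
        assert max(core) < min(surface)
        assert all(0 <= v <= 1 for v in rsa.values())


@pytest.fixture(scope="module")
def annotated(minidomain):
    structure, truth = minidomain
    msa, _ = synth_msa(n_cols=40, seed=0)
    profile = conservation_profile(msa)
    anns = annotate_residues(structure, detect_disulfides(structure),
                             detect_ca_sites(structure), profile,
                             glyco_sites=[30], window=5)
    return structure, truth, anns


class TestAnnotations:
    def test_glyco_window_boundary(self, annotated):
        _, _, anns = annotated
        assert anns[30].glyco_site and anns[30].near_glyco
        assert anns[35].near_glyco       # distance 5: inside window
        assert not anns[36].near_glyco   # distance 6: outside
        assert not anns[35].glyco_site

    def test_out_of_range_glyco_site_ignored(self, minidomain):
        structure, _ = minidomain
        with pytest.warns(UserWarning, match="outside sequence"):
            annotate_residues(structure, [], [], glyco_sites=[999])

    def test_roles_match_planted_truth(self, annotated):
        _, truth, anns = annotated
        ss_positions = {p for pair in truth["disulfide_pairs"] for p in pair}
        for pos, ann in anns.items():
            assert ann.in_disulfide == (pos in ss_positions)
            assert ann.ca_via_sidechain == \
                (pos in truth["ca_sidechain_coordinators"])
        for p in truth["hydrophobic_core_positions"]:
            assert anns[p].is_core

    def test_core_flag_consistent_with_rsa(self, annotated):
        _, _, anns = annotated
        for ann in anns.values():
            if ann.is_core:
                assert ann.rsa <= 0.15


class TestVariantRoleFlags:
    def test_disulfide_cys_substitution_flagged(self, minidomain):
        structure, truth = minidomain
        anns = annotate_residues(structure, detect_disulfides(structure),
                                 detect_ca_sites(structure))
        pos = truth["disulfide_pairs"][0][0]
        v = Variant(VariantChange("C", pos, "R"))
        assert variant_role_flags(v, anns).alters_disulfide

    def test_sidechain_coordinator_any_substitution_flagged(self, minidomain):
        structure, truth = minidomain
        anns = annotate_residues(structure, detect_disulfides(structure),
                                 detect_ca_sites(structure))
        pos = truth["ca_sidechain_coordinators"][0]
        v = Variant(VariantChange("D", pos, "A"))
        assert variant_role_flags(v, anns).alters_ca_site

    def test_backbone_coordinator_needs_pro_or_gly(self, minidomain):
        structure, truth = minidomain
        anns = annotate_residues(structure, detect_disulfides(structure),
                                 detect_ca_sites(structure))
        backbone_only = [p for p in truth["ca_backbone_coordinators"]
                         if p not in truth["ca_sidechain_coordinators"]]
        assert backbone_only, "fixture must have a backbone-only coordinator"
        pos = backbone_only[0]
        ref = next(r for r in structure.residues
                   if r.seq_position == pos).one_letter
        alt_plain = "W" if ref != "W" else "F"
        assert not variant_role_flags(
            Variant(VariantChange(ref, pos, alt_plain)), anns).alters_ca_site
        if ref not in ("P", "G"):
            assert variant_role_flags(
                Variant(VariantChange(ref, pos, "P")), anns).alters_ca_site

    def test_unannotated_position_warns_all_false(self, minidomain):
        structure, _ = minidomain
        anns = annotate_residues(structure, [], [])
        with pytest.warns(UserWarning):
            flags = variant_role_flags(Variant(VariantChange("A", 999, "T")),
                                       anns)
        assert not flags.in_any_class
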