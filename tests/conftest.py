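import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from ldlr_varstruct.synthetic_data import (
    MiniDomainSpec, build_helix, build_minidomain, synth_domain_map,
    write_fixture_directory,
)


@pytest.fixture(scope="session")
def minidomain():
    """Default mini-domain with planted geometry truth."""
    return build_minidomain(MiniDomainSpec(seed=0))


@pytest.fixture(scope="session")
def helix():
    return build_helix(20)


@pytest.fixture(scope="session")
def domain_map():
    return synth_domain_map()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic fixture directory (seed 1, 200 variants)."""
    d = tmp_path_factory.mktemp("fixture")
    truth = write_fixture_directory(d, seed=1, n_variants=200)
    return d, truth


def rigid_transform(structure, seed=0):
    """Random rotation + translation applied to every atom (test helper)."""
    from ldlr_varstruct.structure_io import Atom, Residue, Structure

    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(-20, 20, 3)

    def move(res):
        return Residue(res.chain_id, res.seq_position, res.res_name,
                       [Atom(a.name, a.element, q @ a.coord + shift,
                             a.occupancy, a.b_factor) for a in res.atoms],
                       res.insertion_code, res.is_hetero)

    return Structure(id=structure.id + "_moved",
                     residues=[move(r) for r in structure.residues],
                     ions=[move(r) for r in structure.ions],
                     condition_label=structure.condition_label)
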