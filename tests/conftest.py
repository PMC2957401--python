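import numpy as np
import pytest

import sitealign as sa


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clone_instance():
    """Noise-free 20-point instance with a known planted transform."""
    return sa.make_instance(n=20, decoys=0, sigma=0.0, seed=42)


@pytest.fixture
def decoy_instance():
    """20 true atoms + 10 decoys, compatible labels, noise-free."""
    return sa.make_instance(n=20, decoys=10, sigma=0.0, seed=42)


def random_unit_quaternion(rng):
    q = rng.standard_normal(4)
    return q / np.linalg.norm(q)


@pytest.fixture
def toy_patch():
    """Small hand-built patch with one atom per physico-chemical class."""
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0],
         [0.0, 0.0, 1.5], [1.5, 1.5, 0.0]]
    )
    return sa.SurfacePatch(
        coords=coords,
        chain_ids=np.array(["A"] * 5),
        res_ids=np.arange(1, 6),
        res_names=np.array(["LYS", "ASP", "PHE", "SER", "ALA"]),
        atom_names=np.array(["NZ", "OD1", "CG", "OG", "CB"]),
        elements=np.array(["N", "O", "C", "O", "C"]),
        labels=np.array(["DO", "ACC", "PI", "AD", "ALI"]),
        source="hand-built",
    )
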