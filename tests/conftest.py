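import numpy as np
import pytest

from tnp import fixtures, profiler, structure_io, surface_metrics


@pytest.fixture(scope="session")
def toy():
    """Default full-occupancy synthetic nanobody (CDR3 13 residues, reach 10 A)."""
    return fixtures.make_toy_nanobody(fixtures.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def toy_sasa(toy):
    return surface_metrics.compute_sasa(toy)


@pytest.fixture(scope="session")
def panel36():
    """36-structure synthetic calibration panel (mirrors a clinical-stage set)."""
    return fixtures.make_reference_set(36, seed=20260930)


@pytest.fixture(scope="session")
def refs36(panel36):
    return profiler.calibrate(panel36, provenance="synthetic panel seed=20260930")


def single_atom_structure(coords=((0.0, 0.0, 0.0),), aa="G", atom="CA"):
    """Structures of bare CA atoms at given coordinates, one per residue."""
    residues = [
        structure_io.Residue(structure_io.ImgtId(i + 1), aa, {atom: np.asarray(c, float)})
        for i, c in enumerate(coords)
    ]
    return structure_io.NanobodyStructure(residues)


def random_rotation(rng):
    """Uniform random rotation matrix from a seeded generator."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
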