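import numpy as np
import pytest

from isomerge.reflection_io import PartialDataset
from isomerge.symmetry import CrystalCell, SpaceGroupInfo
from isomerge.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def p1():
    return SpaceGroupInfo.from_number(1)


@pytest.fixture(scope="session")
def sg96():
    return SpaceGroupInfo.from_number(96)


@pytest.fixture(scope="session")
def cubic_cell():
    return CrystalCell(10, 10, 10)


@pytest.fixture(scope="session")
def tetra_cell():
    return CrystalCell(58.07, 58.07, 150.56)


def make_dataset(
    ds_id: str,
    hkl,
    intensity,
    sigma=None,
    cell=None,
    sg_number=1,
) -> PartialDataset:
    """Small hand-built dataset for unit tests."""
    hkl = np.asarray(hkl, dtype=np.int64)
    intensity = np.asarray(intensity, dtype=float)
    if sigma is None:
        sigma = np.ones(len(intensity))
    return PartialDataset(
        id=ds_id,
        cell=cell or CrystalCell(10, 10, 10),
        spacegroup=SpaceGroupInfo.from_number(sg_number),
        hkl=hkl,
        intensity=intensity,
        sigma=np.asarray(sigma, dtype=float),
    )


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 2 isomorphism classes of small wedges."""
    return SimulationConfig(
        cell=CrystalCell(30.0, 36.0, 44.0),
        sg_number=19,
        d_min=2.0,
        n_classes=2,
        datasets_per_class=(20, 10),
        within_cc=0.95,
        between_cc=0.30,
        wedge_fraction=0.25,
        noise_level=0.05,
        cell_jitter=0.002,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """Datasets + class labels + truth for the small 2-class experiment."""
    return simulate(small_config)
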