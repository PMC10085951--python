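import numpy as np
import pytest

from mbfale import (
    ALE,
    BrainGrid,
    Experiment,
    FociDataset,
    RandomDatasetSpec,
    SignalSpec,
    clustered_signal_dataset,
)


@pytest.fixture(scope="session")
def small_grid() -> BrainGrid:
    """Compact 4 mm ellipsoid grid for fast unit tests (~1.6k mask voxels)."""
    return BrainGrid.synthetic(
        spacing_mm=4.0, semi_axes_mm=(28.0, 32.0, 28.0), center_mm=(0.0, 0.0, 0.0),
        margin_mm=8.0,
    )


@pytest.fixture(scope="session")
def medium_grid() -> BrainGrid:
    """3 mm grid with >1e4 mask voxels for distributional oracle checks."""
    return BrainGrid.synthetic(
        spacing_mm=3.0, semi_axes_mm=(45.0, 45.0, 45.0), center_mm=(0.0, 0.0, 0.0),
        margin_mm=9.0,
    )


@pytest.fixture(scope="session")
def colocal_dataset(small_grid) -> FociDataset:
    """30 experiments all reporting the same focus: an extreme planted signal."""
    center = np.array([0.0, 0.0, 0.0])
    exps = [
        Experiment(id=f"exp_{i}", n_subjects=20, foci=center[None, :])
        for i in range(30)
    ]
    return FociDataset(experiments=exps, name="colocal30")


@pytest.fixture(scope="session")
def colocal_fit(small_grid, colocal_dataset) -> ALE:
    return ALE(grid=small_grid, bin_width=1e-4).fit(colocal_dataset)


@pytest.fixture(scope="session")
def planted_fit(small_grid) -> ALE:
    """A mixed signal+background pool fitted on the small grid."""
    spec = RandomDatasetSpec(
        n_experiments=25, foci_range=(5, 10), n_subjects_range=(10, 30), seed=3
    )
    sig = SignalSpec(centers=((0.0, 0.0, 0.0),), displacement_sd_mm=6.0,
                     signal_fraction=0.6)
    ds = clustered_signal_dataset(spec, sig, small_grid)
    return ALE(grid=small_grid, bin_width=1e-4).fit(ds)
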