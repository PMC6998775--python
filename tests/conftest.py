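"""Shared fixtures: tiny hand-built datasets and small simulated studies."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from xtalmerge.core import OBS_COLUMNS, CrystalDataset, PointGroup, UnitCell

# the no-overlap scale fallback is expected with sparse synthetic windows
warnings.filterwarnings("ignore", message="crystal .* shares no reflections")


@pytest.fixture(scope="session")
def pg1() -> PointGroup:
    return PointGroup.from_name("1")


@pytest.fixture(scope="session")
def pg222() -> PointGroup:
    return PointGroup.from_name("222")


@pytest.fixture(scope="session")
def cubic10() -> UnitCell:
    return UnitCell(10.0, 10.0, 10.0)


def make_dataset(
    crystal_id: str,
    cell: UnitCell,
    rows: list[tuple],
    n_frames: int | None = None,
) -> CrystalDataset:
    """Build a CrystalDataset from (frame, h, k, l, intensity, sigma) tuples."""
    df = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    if n_frames is None:
        n_frames = int(df["frame"].max())
    return CrystalDataset(crystal_id=crystal_id, cell=cell, n_frames=n_frames, observations=df)


def dataset_covering(
    crystal_id: str,
    cell: UnitCell,
    refl: pd.DataFrame,
    intensities: np.ndarray,
    n_copies: int = 2,
    sigma: float = 1.0,
) -> CrystalDataset:
    """A crystal observing every reflection of ``refl`` ``n_copies`` times.

    Copy j goes on frame j+1; intensities are exact (no noise), so merged
    statistics are analytic: rmerge 0, cc_half 1.
    """
    rows = []
    for j in range(n_copies):
        for (h, k, l), i in zip(refl[["h", "k", "l"]].to_numpy(), intensities):
            rows.append((j + 1, int(h), int(k), int(l), float(i), sigma))
    return make_dataset(crystal_id, cell, rows, n_frames=n_copies)
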