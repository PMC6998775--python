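"""Readers and writers for the plain tabular observation format.

The interchange format is two text tables (tab- or comma-separated, one
header line):

* observations — columns ``crystal_id, frame, h, k, l, intensity, sigma``
* cells — columns ``crystal_id, a, b, c, alpha, beta, gamma``

Simulated and imported studies are indistinguishable downstream.  An hdf5 /
detector-file adapter would attach at :func:`read_observations`, but only
the tabular route is implemented.

Amplitude export is the naive clamped square root F = sqrt(max(I, 0)) with
first-order error propagation — a deliberate simplification, not a
French-Wilson treatment; documented loudly in docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import OBS_COLUMNS, CrystalDataset, UnitCell
from .stats import MergedDataset, StatsBundle

__all__ = [
    "ReadReport",
    "read_observations",
    "write_observations",
    "export_amplitudes",
    "write_amplitudes",
    "write_merged",
    "write_stats",
]

log = logging.getLogger("xtalmerge")

CELL_COLUMNS = ("crystal_id", "a", "b", "c", "alpha", "beta", "gamma")
FLOAT_FMT = "%.6g"


@dataclass
class ReadReport:
    """Row-level validation outcome of one read."""

    n_loaded: int = 0
    rejected_rows: list[int] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_rows)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_observations(
    obs_path, cells_path, return_report: bool = False
) -> list[CrystalDataset] | tuple[list[CrystalDataset], ReadReport]:
    """Load crystals from an observation table plus its unit-cell sidecar.

    Rows violating invariants (sigma <= 0, all-zero hkl, frame < 1) are
    rejected individually; their 1-based data row numbers are logged and
    collected in the report.  A missing column raises a schema error naming
    it.  An empty data section yields an empty collection with a warning.
    """
    obs = _read_table(obs_path)
    cells = _read_table(cells_path)
    for col in ("crystal_id",) + OBS_COLUMNS:
        if col not in obs.columns:
            raise ValueError(f"observation table is missing required column {col!r}")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing required column {col!r}")
    report = ReadReport()
    if not len(obs):
        log.warning("observation table %s has no data rows", obs_path)
        return ([], report) if return_report else []

    bad = pd.Series(False, index=obs.index)
    reasons = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in obs.index[mask & ~bad]:
            reasons[idx] = reason
        bad.loc[mask] = True

    flag(obs["sigma"] <= 0, "sigma <= 0")
    flag((obs[["h", "k", "l"]] == 0).all(axis=1), "zero Miller index")
    flag(obs["frame"] < 1, "frame < 1")
    if bad.any():
        rows = [int(i) + 1 for i in obs.index[bad]]
        log.warning("rejected %d observation rows: %s", len(rows), rows[:20])
        report.rejected_rows = rows
        report.reasons = [reasons[i] for i in obs.index[bad]]
    obs = obs.loc[~bad]
    report.n_loaded = len(obs)

    cell_by_id = {
        str(r["crystal_id"]): UnitCell(r["a"], r["b"], r["c"], r["alpha"], r["beta"], r["gamma"])
        for _, r in cells.iterrows()
    }
    datasets = []
    for cid, grp in obs.groupby("crystal_id", sort=True):
        cid = str(cid)
        if cid not in cell_by_id:
            raise ValueError(f"no unit cell recorded for crystal {cid!r}")
        datasets.append(
            CrystalDataset(
                crystal_id=cid,
                cell=cell_by_id[cid],
                n_frames=int(grp["frame"].max()),
                observations=grp.loc[:, list(OBS_COLUMNS)].reset_index(drop=True),
            )
        )
    return (datasets, report) if return_report else datasets


def write_observations(datasets: Sequence[CrystalDataset], obs_path, cells_path) -> None:
    """Write crystals back to the two-table interchange format (tab-separated).

    Full floating-point precision (unlike the 6-significant-digit reports),
    so a write -> read round trip reproduces the observations exactly.
    """
    obs_frames = []
    cell_rows = []
    for ds in sorted(datasets, key=lambda d: d.crystal_id):
        obs_frames.append(ds.observations.assign(crystal_id=ds.crystal_id))
        cell_rows.append((ds.crystal_id,) + ds.cell.as_tuple())
    obs = (
        pd.concat(obs_frames, ignore_index=True)
        if obs_frames
        else pd.DataFrame(columns=["crystal_id", *OBS_COLUMNS])
    )
    obs = obs.loc[:, ["crystal_id", *OBS_COLUMNS]]
    obs.to_csv(obs_path, sep="\t", index=False)
    pd.DataFrame(cell_rows, columns=list(CELL_COLUMNS)).to_csv(
        cells_path, sep="\t", index=False
    )


def export_amplitudes(
    merged: MergedDataset, rfree_fraction: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Structure-factor amplitudes with a free-set flag column.

    F = sqrt(max(I, 0)); sigF = sigI / (2F) for F > 0, else sqrt(sigI).
    Exactly floor(rfree_fraction * n) reflections are flagged free (flag 1),
    chosen uniformly without replacement from the seeded generator.
    """
    if not 0.0 < rfree_fraction < 0.5:
        raise ValueError("rfree_fraction must lie in (0, 0.5)")
    if not len(merged.table):
        raise ValueError("cannot export an empty merged dataset")
    t = merged.table
    f = np.sqrt(np.maximum(t["i"].to_numpy(), 0.0))
    sigf = np.where(f > 0, t["sig"].to_numpy() / (2.0 * np.maximum(f, 1e-300)), np.sqrt(t["sig"]))
    out = pd.DataFrame(
        {"h": t["h"], "k": t["k"], "l": t["l"], "F": f, "sigF": sigf, "free_flag": 0}
    )
    n_free = int(rfree_fraction * len(out))
    rng = np.random.default_rng(seed)
    free_idx = rng.choice(len(out), size=n_free, replace=False)
    out.iloc[free_idx, out.columns.get_loc("free_flag")] = 1
    return out


def write_amplitudes(merged: MergedDataset, path, rfree_fraction: float = 0.05, seed: int = 0) -> None:
    export_amplitudes(merged, rfree_fraction, seed).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_merged(merged: MergedDataset, path) -> None:
    """Merged reflection table: h k l I sigI multiplicity (+sign if anomalous)."""
    merged.to_table().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_stats(stats: StatsBundle, path) -> None:
    Path(path).write_text(stats.summary() + "\n")
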