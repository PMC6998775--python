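"""Iterative crystal and frame rejection (workflow step 3).

Within each unit-cell class that passes the completeness gate (> 90% by
default), crystals incompatible with the class consensus are rejected in
steps: before each iteration the per-crystal mean smoothed Rmerge
<SmRmerge> is computed against the current merged reference, the worst
``xtal_step`` crystals are dropped, and the class is re-merged.  The loop
stops once the surviving count is <= ``xtal_step``.

After each iteration, frame rejection (optional) grid-searches a decay
parameter: frames whose SmRmerge exceeds

    rjframe = min(SmRmerge) * (1 + decay)

are discarded, one assembled dataset per decay value.  The default sequence
(5.0, 3.0, 2.0, 1.0) probes cutoffs of 6, 4, 3 and 2 times the per-crystal
minimum.  Among all emitted datasets, the one with maximum CC1/2 serves
high-resolution work, maximum DelAnom serves anomalous phasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import CrystalDataset, PointGroup, UnitCell
from .stats import (
    FrameProfile,
    MergedDataset,
    ScaleSet,
    StatsBundle,
    compute_stats,
    frame_profile,
    scale_datasets,
)

__all__ = [
    "RejectionConfig",
    "FrameRejectionResult",
    "AssemblyResult",
    "crystal_scores",
    "reject_crystals_once",
    "iterate_crystal_rejection",
    "frame_cutoff",
    "reject_frames",
    "assemble_class",
    "select_best",
]

DEFAULT_DECAY_SEQUENCE = (5.0, 3.0, 2.0, 1.0)


@dataclass(frozen=True)
class RejectionConfig:
    """Knobs of the rejection loops (defaults mirror the CLI defaults)."""

    xtal_step: int = 10
    decay_sequence: tuple[float, ...] = DEFAULT_DECAY_SEQUENCE
    completeness_threshold: float = 90.0
    reject_crystals: bool = False
    reject_frames: bool = False
    kernel_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.xtal_step < 1:
            raise ValueError("xtal_step must be >= 1")
        if any(d <= 0 for d in self.decay_sequence):
            raise ValueError("decay values must be positive")
        if self.reject_frames and not self.reject_crystals:
            raise ValueError("frame rejection runs inside the crystal-rejection loop; enable both")


@dataclass
class FrameRejectionResult:
    """Outcome of the decay-cutoff rule for one crystal."""

    crystal_id: str
    decay: float
    min_smr: float
    cutoff: float
    kept_frames: np.ndarray


@dataclass
class AssemblyResult:
    """One assembled dataset: a (class, iteration, decay) combination."""

    class_label: int
    iteration: int
    decay: Optional[float]
    crystal_ids: tuple[str, ...]
    kept_frames: Optional[dict[str, np.ndarray]]
    stats: StatsBundle
    merged: Optional[MergedDataset] = field(default=None, repr=False)

    @property
    def n_crystals(self) -> int:
        return len(self.crystal_ids)

    def provenance(self) -> dict:
        return {
            "class": self.class_label,
            "iteration": self.iteration,
            "decay": self.decay,
            "n_crystals": self.n_crystals,
            "crystal_ids": list(self.crystal_ids),
            "kept_frames": None
            if self.kept_frames is None
            else {cid: [int(f) for f in fr] for cid, fr in self.kept_frames.items()},
            "stats": self.stats.as_dict(),
        }


# ---------------------------------------------------------------------------
# Crystal rejection
# ---------------------------------------------------------------------------

def crystal_scores(profiles: Sequence[FrameProfile]) -> dict[str, float]:
    """Per-crystal <SmRmerge>: unweighted mean over defined frames.

    Crystals whose whole profile is undefined score +inf and are rejected
    first (no evidence of compatibility at all).
    """
    if not profiles:
        raise ValueError("no profiles to score")
    out = {}
    for p in profiles:
        vals = p.smoothed[np.isfinite(p.smoothed)]
        out[p.crystal_id] = float(vals.mean()) if len(vals) else math.inf
    return out


def reject_crystals_once(scores: dict[str, float], xtal_step: int) -> list[str]:
    """Ids of the ``xtal_step`` worst crystals (ties by ascending id).

    Returns an empty list when the population is already <= xtal_step — the
    loop-termination signal, not an error.
    """
    if len(scores) <= xtal_step:
        return []
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return sorted(cid for cid, _ in ranked[:xtal_step])


# ---------------------------------------------------------------------------
# Frame rejection
# ---------------------------------------------------------------------------

def frame_cutoff(profile: FrameProfile, decay: float) -> Optional[float]:
    """rjframe = min(SmRmerge) * (1 + decay); None for an all-undefined profile."""
    finite = profile.smoothed[np.isfinite(profile.smoothed)]
    if not len(finite):
        return None
    return float(finite.min()) * (1.0 + decay)


def reject_frames(profile: FrameProfile, decay: float) -> FrameRejectionResult:
    """Keep frames with SmRmerge <= the decay cutoff.

    Frames with undefined SmRmerge are kept (no evidence against them); the
    kept set is not forced contiguous.  The minimising frame always survives.
    """
    cutoff = frame_cutoff(profile, decay)
    frames = np.arange(1, profile.n_frames + 1)
    if cutoff is None:
        return FrameRejectionResult(profile.crystal_id, decay, math.nan, math.nan, frames)
    smr = profile.smoothed
    keep = ~np.isfinite(smr) | (smr <= cutoff)
    finite = smr[np.isfinite(smr)]
    return FrameRejectionResult(
        crystal_id=profile.crystal_id,
        decay=decay,
        min_smr=float(finite.min()),
        cutoff=cutoff,
        kept_frames=frames[keep],
    )


# ---------------------------------------------------------------------------
# The assembly loops
# ---------------------------------------------------------------------------

def _result(
    class_label: int,
    iteration: int,
    decay: Optional[float],
    datasets: dict[str, CrystalDataset],
    kept_frames: Optional[dict[str, np.ndarray]],
    pg: PointGroup,
    cell: UnitCell,
    reso: float,
    scales: ScaleSet,
    seed: int,
    anomalous: bool,
    keep_merged: bool,
) -> tuple[AssemblyResult, MergedDataset]:
    merged, bundle = compute_stats(
        list(datasets.values()), pg, cell, reso, scales, seed=seed, anomalous=anomalous
    )
    res = AssemblyResult(
        class_label=class_label,
        iteration=iteration,
        decay=decay,
        crystal_ids=tuple(sorted(datasets)),
        kept_frames=kept_frames,
        stats=bundle,
        merged=merged if keep_merged else None,
    )
    return res, merged


def iterate_crystal_rejection(
    class_datasets: Sequence[CrystalDataset],
    config: RejectionConfig,
    pg: PointGroup,
    reso: float,
    class_label: int = 1,
    seed: int = 0,
    anomalous: bool = False,
    keep_merged: bool = False,
) -> list[AssemblyResult]:
    """Crystal-rejection loop without frame rejection (see assemble_class)."""
    cfg = RejectionConfig(
        xtal_step=config.xtal_step,
        decay_sequence=config.decay_sequence,
        completeness_threshold=config.completeness_threshold,
        reject_crystals=True,
        reject_frames=False,
        kernel_sigma=config.kernel_sigma,
    )
    return assemble_class(
        class_datasets, cfg, pg, reso, class_label=class_label, seed=seed,
        anomalous=anomalous, keep_merged=keep_merged,
    )


def assemble_class(
    class_datasets: Sequence[CrystalDataset],
    config: RejectionConfig,
    pg: PointGroup,
    reso: float,
    class_label: int = 1,
    seed: int = 0,
    anomalous: bool = False,
    keep_merged: bool = False,
) -> list[AssemblyResult]:
    """Assemble one unit-cell class into its family of candidate datasets.

    Iteration 0 merges the full class.  When the class completeness exceeds
    the threshold and crystal rejection is on, crystals are then removed
    ``xtal_step`` at a time by worst <SmRmerge> (profiles recomputed against
    the surviving-set merged reference each iteration) until the count drops
    to <= xtal_step; the final small dataset is emitted, not discarded.
    With frame rejection on, each emitted crystal set additionally yields one
    frame-filtered dataset per decay value.

    Per-class scales are fit once on the full class and held fixed across
    iterations, so SmRmerge scores stay comparable between iterations.
    """
    if not class_datasets:
        raise ValueError("empty class")
    datasets = {d.crystal_id: d for d in class_datasets}
    cell = UnitCell.mean([d.cell for d in class_datasets])
    scales = (
        scale_datasets(class_datasets, pg, reso)
        if len(class_datasets) > 1
        else ScaleSet.identity([d.crystal_id for d in class_datasets])
    )

    def level_seed(iteration: int, decay_idx: int) -> int:
        return (seed * 1_000_003 + iteration * 101 + decay_idx) % (2**31)

    results: list[AssemblyResult] = []
    res0, merged = _result(
        class_label, 0, None, datasets, None, pg, cell, reso, scales,
        level_seed(0, 0), anomalous, keep_merged,
    )
    results.append(res0)

    gate = (
        res0.stats.completeness > config.completeness_threshold
        and config.reject_crystals
        and len(datasets) >= 2
    )
    if not gate:
        return results

    iteration = 0
    while True:
        if not config.reject_frames and len(datasets) <= config.xtal_step:
            break
        profiles = [
            frame_profile(ds, merged, kernel_sigma=config.kernel_sigma, scale=scales[cid])
            for cid, ds in sorted(datasets.items())
        ]
        if config.reject_frames:
            for di, decay in enumerate(config.decay_sequence, start=1):
                rejections = {p.crystal_id: reject_frames(p, decay) for p in profiles}
                sub = {
                    cid: datasets[cid].subset_frames(rejections[cid].kept_frames)
                    for cid in datasets
                }
                sub = {cid: ds for cid, ds in sub.items() if ds.n_obs > 0}
                kept = {cid: rejections[cid].kept_frames for cid in sub}
                res, _ = _result(
                    class_label, iteration, decay, sub, kept, pg, cell, reso,
                    scales, level_seed(iteration, di), anomalous, keep_merged,
                )
                results.append(res)
        if len(datasets) <= config.xtal_step:
            break
        removed = reject_crystals_once(crystal_scores(profiles), config.xtal_step)
        if not removed:
            break
        for cid in removed:
            datasets.pop(cid)
        iteration += 1
        res, merged = _result(
            class_label, iteration, None, datasets, None, pg, cell, reso,
            scales, level_seed(iteration, 0), anomalous, keep_merged,
        )
        results.append(res)
    return results


_CRITERIA = ("cc_half", "delanom")


def select_best(results: Sequence[AssemblyResult], criterion: str = "cc_half") -> AssemblyResult:
    """Dataset with the maximum value of the chosen quality criterion.

    Ties prefer fewer rejections: earlier iteration, then larger decay (no
    frame rejection ranks above any decay), then more crystals.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    defined = [r for r in results if getattr(r.stats, criterion) is not None]
    if not defined:
        raise ValueError(f"criterion {criterion!r} is undefined for every result")
    return max(
        defined,
        key=lambda r: (
            getattr(r.stats, criterion),
            -r.iteration,
            math.inf if r.decay is None else r.decay,
            r.n_crystals,
        ),
    )
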