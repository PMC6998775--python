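"""Synthetic microcrystal study generator.

Emulates the experimental situation the assembly workflow targets: many
microcrystals, each surviving only a small rotation wedge (10-100 frames at
0.1-0.3 degrees per frame), with

* true intensities drawn from an acentric Wilson (exponential) distribution
  whose mean falls off as exp(-B s^2 / 2) with s = 1/d,
* per-frame radiation damage as a growing isotropic B factor
  B(f) = B0 + beta * max(0, f - onset),
* unit cells jittered around one or more class means,
* optional planted anomalous (Bijvoet) differences, and
* optional "bad" crystals with inflated noise.

Wedge geometry is emulated combinatorially: the unique reflection list is
put in one shared shuffled order; each crystal owns a contiguous window of
it (its reachable slice of reciprocal space) and every frame exposes a
random contiguous sub-slice of that window.  Reflections are therefore
re-observed throughout a crystal's series (internal multiplicity, so
per-wedge CC1/2 is defined and per-frame damage spreads across a
reflection's observations) while different crystals cover different,
overlapping parts of reciprocal space.  The assembly logic consumes only
(hkl, frame, I, sigma), which this reproduces faithfully; no Ewald-sphere
geometry is modelled.

All randomness flows from ``SimulationConfig.seed``: the truth uses stream
``(seed, 0)`` and crystal i uses stream ``(seed, 1000 + i)``, so changing
one crystal's spec never perturbs the others' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import OBS_COLUMNS, CrystalDataset, PointGroup, UnitCell, unique_reflections

__all__ = [
    "ClassSpec",
    "SimulationConfig",
    "TruthRecord",
    "CrystalSpec",
    "simulate_truth",
    "simulate_crystal",
    "simulate_study",
]


@dataclass(frozen=True)
class ClassSpec:
    """One unit-cell population: mean cell, per-parameter jitter sd, share of M."""

    cell: UnitCell
    jitter: tuple[float, float, float, float, float, float] = (0.05, 0.05, 0.05, 0.0, 0.0, 0.0)
    fraction: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Defaults sit inside the anticipated envelope of microcrystal rotation
    collection: 10-100 frames per crystal at 0.1-0.3 deg per frame, a
    moderate Wilson B of 20 A^2, and damage accumulating at 0.2 A^2 per
    frame so a long wedge roughly doubles the effective B.  ``noise_gain``
    sets counting-statistics-like noise, sigma = sqrt(I/gain + sigma0^2).
    """

    n_crystals: int = 20
    class_specs: tuple[ClassSpec, ...] = (
        ClassSpec(cell=UnitCell(50.0, 60.0, 70.0)),
    )
    pointgroup: str = "222"
    frames_range: tuple[int, int] = (10, 100)
    frame_width_range: tuple[float, float] = (0.1, 0.3)
    dmin: float = 3.0
    wilson_b: float = 20.0
    intensity_scale: float = 1000.0
    decay_b0: float = 0.0
    decay_rate: float = 0.2
    decay_onset: int = 0
    noise_gain: float = 1.0
    sigma0: float = 0.5
    scale_spread: float = 0.1
    anomalous_fraction: float = 0.0
    friedel_split: bool = False  # measure I(+)/I(-) separately even with no planted signal
    bad_crystals: dict = field(default_factory=dict)  # crystal index -> noise multiplier
    frame_coverage: float = 0.03  # fraction of unique list exposed per frame
    window_factor: int = 8  # crystal window = window_factor * per-frame slice
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = sum(cs.fraction for cs in self.class_specs)
        if abs(fracs - 1.0) > 1e-6:
            raise ValueError("class fractions must sum to 1")
        for v in (self.dmin, self.intensity_scale, self.noise_gain, self.frame_coverage):
            if v <= 0:
                raise ValueError("scale parameters must be positive")
        if not 0.0 <= self.anomalous_fraction:
            raise ValueError("anomalous_fraction must be >= 0")

    @property
    def pg(self) -> PointGroup:
        return PointGroup.from_name(self.pointgroup)


@dataclass
class CrystalSpec:
    """Per-crystal ground-truth parameters drawn by simulate_study."""

    crystal_id: str
    index: int
    cell: UnitCell
    class_index: int
    n_frames: int
    frame_width: float
    scale: float
    b0: float
    beta: float
    onset: int
    noise_multiplier: float
    start: int


@dataclass
class TruthRecord:
    """Ground truth behind a simulated study (the parameter-recovery oracle)."""

    reflections: pd.DataFrame  # h, k, l, d, i_true, danom
    order: np.ndarray  # shared shuffled scan order of the reflection rows
    pointgroup: str
    config: SimulationConfig
    crystal_specs: list[CrystalSpec] = field(default_factory=list)

    @property
    def class_labels(self) -> dict[str, int]:
        return {cs.crystal_id: cs.class_index for cs in self.crystal_specs}

    @property
    def bad_crystal_ids(self) -> list[str]:
        return [cs.crystal_id for cs in self.crystal_specs if cs.noise_multiplier > 1.0]


def simulate_truth(config: SimulationConfig) -> TruthRecord:
    """Draw the true merged intensities (and Bijvoet differences).

    Acentric Wilson statistics: I_true ~ Exponential with mean
    ``intensity_scale * exp(-wilson_b * s^2 / 2)``, s = 1/d, over the unique
    reflections of the first class's mean cell to ``dmin``.  Anomalous mode
    adds an antisymmetric perturbation ``danom ~ N(0, (f_anom * mean)^2)``
    split as I(+/-) = I_true +/- danom/2.  Deterministic per seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    cell = config.class_specs[0].cell
    refl = unique_reflections(cell, config.pg, config.dmin)
    s2 = 1.0 / refl["d"].to_numpy() ** 2
    mean_i = config.intensity_scale * np.exp(-config.wilson_b * s2 / 2.0)
    refl = refl.assign(
        i_true=rng.exponential(mean_i),
        danom=rng.normal(0.0, config.anomalous_fraction * mean_i)
        if config.anomalous_fraction > 0
        else np.zeros(len(refl)),
    )
    order = rng.permutation(len(refl))
    return TruthRecord(reflections=refl, order=order, pointgroup=config.pointgroup, config=config)


def simulate_crystal(truth: TruthRecord, spec: CrystalSpec) -> CrystalDataset:
    """Generate one crystal's observation table from the shared truth.

    The crystal owns a contiguous window of the shared scan order starting
    at ``spec.start``; each frame exposes a random contiguous sub-slice of
    it (wrapping), so the same reflections recur across the series.  The
    observed intensity is

        I = I_true(+/-) * scale * exp(-(B0 + beta * max(0, f - onset)) s^2 / 2) + noise

    with noise sd ``sigma = noise_multiplier * sqrt(max(I,0)/gain + sigma0^2)``
    reported honestly in the sigma column.  Deterministic per (seed, index).
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 1000 + spec.index])
    refl = truth.reflections
    n_unique = len(refl)
    width = max(10, int(round(cfg.frame_coverage * n_unique)))
    window = min(n_unique, cfg.window_factor * width)
    rot = cfg.pg.matrices

    idx_true = truth.order
    frames_out = []
    for f in range(1, spec.n_frames + 1):
        off = int(rng.integers(0, max(1, window - width + 1)))
        pos = (spec.start + off + np.arange(width)) % n_unique
        rows = refl.iloc[idx_true[pos]]
        s2 = 1.0 / rows["d"].to_numpy() ** 2
        b_eff = spec.b0 + spec.beta * max(0, f - spec.onset)
        damage = np.exp(-b_eff * s2 / 2.0)
        measure_mates = cfg.anomalous_fraction > 0 or cfg.friedel_split
        sign = rng.choice([1, -1], size=len(rows)) if measure_mates else np.ones(len(rows), dtype=int)
        i_noiseless = (rows["i_true"].to_numpy() + sign * rows["danom"].to_numpy() / 2.0) * spec.scale * damage
        sigma = spec.noise_multiplier * np.sqrt(
            np.maximum(i_noiseless, 0.0) / cfg.noise_gain + cfg.sigma0**2
        )
        observed = i_noiseless + rng.normal(0.0, 1.0, len(rows)) * sigma
        # record a random symmetry equivalent (negated for the Friedel mate)
        r_idx = rng.integers(0, len(rot), len(rows))
        base = rows[["h", "k", "l"]].to_numpy(dtype=np.int64)
        hkl = np.einsum("nij,nj->ni", rot[r_idx], base) * sign[:, None]
        frames_out.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "h": hkl[:, 0],
                    "k": hkl[:, 1],
                    "l": hkl[:, 2],
                    "intensity": observed,
                    "sigma": sigma,
                }
            )
        )
    obs = pd.concat(frames_out, ignore_index=True)
    return CrystalDataset(
        crystal_id=spec.crystal_id, cell=spec.cell, n_frames=spec.n_frames, observations=obs
    )


def _class_counts(fractions: Sequence[float], m: int) -> list[int]:
    """Largest-remainder apportionment of M crystals across classes."""
    exact = np.array(fractions) * m
    counts = np.floor(exact).astype(int)
    rem = m - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return counts.tolist()


def simulate_study(config: SimulationConfig) -> tuple[list[CrystalDataset], TruthRecord]:
    """Simulate the full M-crystal study.

    Crystals are apportioned across the class populations by their fractions
    (largest remainder), cells jittered per class spec, and each crystal's
    frames, width, scale and window start drawn from its own random stream.
    """
    truth = simulate_truth(config)
    counts = _class_counts([cs.fraction for cs in config.class_specs], config.n_crystals)
    class_of = [ci for ci, n in enumerate(counts) for _ in range(n)]
    n_unique = len(truth.reflections)
    datasets = []
    for i in range(config.n_crystals):
        rng = np.random.default_rng([config.seed, 1_000_000 + i])
        cs = config.class_specs[class_of[i]]
        cell_params = np.array(cs.cell.as_tuple()) + rng.normal(0, 1, 6) * np.array(cs.jitter)
        lo, hi = config.frames_range
        spec = CrystalSpec(
            crystal_id=f"xtal_{i:03d}",
            index=i,
            cell=UnitCell(*cell_params),
            class_index=class_of[i],
            n_frames=int(rng.integers(lo, hi + 1)),
            frame_width=float(rng.uniform(*config.frame_width_range)),
            scale=float(np.exp(rng.normal(0.0, config.scale_spread))),
            b0=config.decay_b0,
            beta=config.decay_rate,
            onset=config.decay_onset,
            noise_multiplier=float(config.bad_crystals.get(i, 1.0)),
            start=int(rng.integers(0, n_unique)),
        )
        truth.crystal_specs.append(spec)
        datasets.append(simulate_crystal(truth, spec))
    return datasets, truth
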