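"""Internal merging-statistics engine.

Computes every quantity the assembly logic consumes: per-crystal linear
scales, inverse-variance merged intensities, Rmerge/Rmeas, the half-dataset
correlation CC1/2, the anomalous-difference correlation DelAnom, completeness
against the enumerated unique set, and the per-frame smoothed Rmerge trace
(SmRmerge) that drives crystal and frame rejection.

Undefined statistics (too few repeated observations, empty denominators) are
reported as ``None`` — never silently as zero.

All stochastic steps (the random half-splits behind CC1/2 and DelAnom) are
seeded and bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CrystalDataset,
    PointGroup,
    UnitCell,
    asu_map,
    d_spacings,
    unique_reflections,
)

__all__ = [
    "ScaleSet",
    "MergedDataset",
    "StatsBundle",
    "FrameProfile",
    "scale_datasets",
    "merge",
    "rmerge",
    "rmerge_rmeas",
    "cc_half",
    "delanom",
    "completeness",
    "frame_profile",
    "gaussian_smooth",
    "compute_stats",
]


# ---------------------------------------------------------------------------
# Prepared observation tables
# ---------------------------------------------------------------------------

def _prepare(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    dmin: float,
    scales: Optional["ScaleSet"] = None,
) -> pd.DataFrame:
    """Flatten datasets into one table of scaled, ASU-reduced observations.

    Columns: crystal_id, frame, ch/ck/cl (canonical index), key (encoded
    canonical index for fast grouping), sign (Friedel), d, i, sig.
    Observations beyond the resolution cutoff (d < dmin) are dropped.
    """
    frames = []
    for ds in sorted(datasets, key=lambda d: d.crystal_id):
        obs = ds.observations
        if not len(obs):
            continue
        hkl = obs[["h", "k", "l"]].to_numpy(dtype=np.int64)
        d = d_spacings(ds.cell, hkl)
        keep = d >= dmin - 1e-9
        if not keep.any():
            continue
        canon, signs = asu_map(hkl[keep], pg)
        k = 1.0 if scales is None else scales[ds.crystal_id]
        frames.append(
            pd.DataFrame(
                {
                    "crystal_id": ds.crystal_id,
                    "frame": obs["frame"].to_numpy()[keep],
                    "ch": canon[:, 0],
                    "ck": canon[:, 1],
                    "cl": canon[:, 2],
                    "sign": signs,
                    "d": d[keep],
                    "i": obs["intensity"].to_numpy()[keep] * k,
                    "sig": obs["sigma"].to_numpy()[keep] * k,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["crystal_id", "frame", "ch", "ck", "cl", "sign", "d", "i", "sig", "key"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["key"] = _encode_keys(out)
    return out


_KEY_BOUND = 512  # fixed packing radix so keys agree across independent calls
_KEY_BASE = 2 * _KEY_BOUND


def _encode_keys(df: pd.DataFrame) -> np.ndarray:
    """Pack a canonical index into one int64 grouping key.

    The radix is fixed (|h|,|k|,|l| < 512, far beyond any macromolecular
    dataset) so that keys computed in separate calls — per-crystal scale
    fits, frame profiles joined against a merged reference — stay
    compatible.
    """
    h = df["ch"].to_numpy(np.int64)
    k = df["ck"].to_numpy(np.int64)
    l = df["cl"].to_numpy(np.int64)
    if max(np.abs(h).max(), np.abs(k).max(), np.abs(l).max(), 0) >= _KEY_BOUND:
        raise ValueError(f"Miller indices beyond +/-{_KEY_BOUND} are not supported")
    return ((h + _KEY_BOUND) * _KEY_BASE + k + _KEY_BOUND) * _KEY_BASE + l + _KEY_BOUND


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaleSet:
    """Per-crystal multiplicative scale factors; the reference crystal is 1."""

    scales: dict[str, float]
    reference: str

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.scales.values()):
            raise ValueError("scale factors must be positive")
        if not math.isclose(self.scales[self.reference], 1.0):
            raise ValueError("reference crystal must carry scale 1")

    def __getitem__(self, crystal_id: str) -> float:
        return self.scales[crystal_id]

    @classmethod
    def identity(cls, crystal_ids: Sequence[str]) -> "ScaleSet":
        ids = sorted(crystal_ids)
        return cls(scales={i: 1.0 for i in ids}, reference=ids[0])


def _per_crystal_means(prep: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-reflection mean intensity for one crystal's rows."""
    g = prep.groupby("key", sort=False)
    out = g.agg(i=("i", "mean"), n=("i", "size"))
    sig2 = prep.groupby("key", sort=False)["sig"].apply(lambda s: float(np.sum(s**2)))
    out["sem2"] = sig2 / out["n"] ** 2
    return out


def scale_datasets(
    datasets: Sequence[CrystalDataset], pg: PointGroup, dmin: float
) -> ScaleSet:
    """Closed-form linear scaling of every crystal against a reference.

    The reference is the first crystal by sorted id (scale exactly 1).  Each
    other crystal's factor k minimises sum_hkl w (I_ref - k I_crys)^2 over
    canonical reflections observed in both, with weights from the propagated
    standard errors of the per-reflection means.  Crystals with no overlap
    with the reference get k = 1 and a warning.
    """
    if not datasets:
        raise ValueError("no datasets to scale")
    by_id = {d.crystal_id: d for d in datasets}
    ids = sorted(by_id)
    ref_id = ids[0]
    means = {}
    for cid in ids:
        prep = _prepare([by_id[cid]], pg, dmin)
        means[cid] = _per_crystal_means(prep) if len(prep) else pd.DataFrame(
            columns=["i", "n", "sem2"]
        )
    ref = means[ref_id]
    scales = {ref_id: 1.0}
    for cid in ids[1:]:
        joined = ref.join(means[cid], how="inner", lsuffix="_r", rsuffix="_c")
        if not len(joined):
            warnings.warn(
                f"crystal {cid!r} shares no reflections with the reference; scale set to 1"
            )
            scales[cid] = 1.0
            continue
        w = 1.0 / (joined["sem2_r"] + joined["sem2_c"] + 1e-12)
        num = float(np.sum(w * joined["i_r"] * joined["i_c"]))
        den = float(np.sum(w * joined["i_c"] ** 2))
        if den <= 0 or num <= 0:
            warnings.warn(f"ill-conditioned scale fit for crystal {cid!r}; scale set to 1")
            scales[cid] = 1.0
        else:
            scales[cid] = num / den
    return ScaleSet(scales=scales, reference=ref_id)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

@dataclass
class MergedDataset:
    """Merged reflections of one assembled dataset.

    ``table`` columns: h, k, l, (sign when anomalous), i, sig, mult, d.
    Intensities are inverse-variance weighted means of the scaled
    observations; merged sigma is 1/sqrt(sum 1/sigma^2).
    """

    table: pd.DataFrame
    pg: PointGroup
    dmin: float
    anomalous: bool
    crystal_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.table):
            if self.table["mult"].min() < 1:
                raise ValueError("multiplicity must be >= 1")
            if self.table["sig"].min() <= 0:
                raise ValueError("merged sigma must be positive")

    @property
    def n_reflections(self) -> int:
        return len(self.table)

    def reference_means(self) -> pd.DataFrame:
        """Per-canonical-index merged intensity, Friedel mates pooled."""
        if not self.anomalous:
            return self.table.set_index("key")[["i"]]
        g = self.table.groupby("key", sort=False)
        return g.apply(
            lambda t: float(np.average(t["i"], weights=t["mult"])), include_groups=False
        ).to_frame("i")

    def to_table(self) -> pd.DataFrame:
        """Plain export table (h, k, l, I, sigI, multiplicity [, sign])."""
        cols = ["h", "k", "l"] + (["sign"] if self.anomalous else []) + ["i", "sig", "mult", "d"]
        return self.table.loc[:, cols].copy()


def merge(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    dmin: float,
    scales: ScaleSet | None = None,
    anomalous: bool = False,
) -> MergedDataset:
    """Scale, ASU-reduce and combine observations by inverse-variance mean."""
    prep = _prepare(datasets, pg, dmin, scales)
    group_cols = ["key", "sign"] if anomalous else ["key"]
    if not len(prep):
        table = pd.DataFrame(columns=["key", "h", "k", "l", "sign", "i", "sig", "mult", "d"])
        return MergedDataset(table, pg, dmin, anomalous, tuple(sorted(d.crystal_id for d in datasets)))
    prep = prep.assign(w=1.0 / prep["sig"] ** 2)
    prep["iw"] = prep["i"] * prep["w"]
    g = prep.groupby(group_cols, sort=True)
    agg = g.agg(
        iw=("iw", "sum"),
        w=("w", "sum"),
        mult=("i", "size"),
        h=("ch", "first"),
        k=("ck", "first"),
        l=("cl", "first"),
        d=("d", "first"),
    ).reset_index()
    agg["i"] = agg["iw"] / agg["w"]
    agg["sig"] = 1.0 / np.sqrt(agg["w"])
    if not anomalous:
        agg["sign"] = 1
    cols = ["key", "h", "k", "l", "sign", "i", "sig", "mult", "d"]
    table = agg.loc[:, cols].sort_values(["h", "k", "l", "sign"]).reset_index(drop=True)
    return MergedDataset(
        table, pg, dmin, anomalous, tuple(sorted(d.crystal_id for d in datasets))
    )


# ---------------------------------------------------------------------------
# Merging R factors
# ---------------------------------------------------------------------------

def _rmerge_from_prep(prep: pd.DataFrame) -> tuple[Optional[float], Optional[float]]:
    g = prep.groupby("key", sort=False)["i"]
    n = g.transform("size")
    multi = prep.loc[n >= 2].copy()
    if not len(multi):
        return None, None
    gm = multi.groupby("key", sort=False)["i"]
    mean = gm.transform("mean")
    nn = gm.transform("size")
    dev = (multi["i"] - mean).abs()
    den = float(multi["i"].sum())
    if den == 0:
        return None, None
    r_merge = float(dev.sum()) / den
    r_meas = float((dev * np.sqrt(nn / (nn - 1))).sum()) / den
    return r_merge, r_meas


def rmerge_rmeas(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    dmin: float,
    scales: ScaleSet | None = None,
) -> tuple[Optional[float], Optional[float]]:
    """(Rmerge, Rmeas) over reflections with multiplicity >= 2.

    Rmerge = sum_hkl sum_i |I_i - <I>| / sum_hkl sum_i I_i with <I> the
    unweighted mean of the reflection's scaled observations; Rmeas multiplies
    each reflection's numerator by sqrt(n/(n-1)).  ``None`` when no reflection
    is multiply observed.
    """
    return _rmerge_from_prep(_prepare(datasets, pg, dmin, scales))


def rmerge(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    dmin: float,
    scales: ScaleSet | None = None,
) -> Optional[float]:
    return rmerge_rmeas(datasets, pg, dmin, scales)[0]


# ---------------------------------------------------------------------------
# Half-dataset correlations
# ---------------------------------------------------------------------------

def _half_split(prep: pd.DataFrame, rng: np.random.Generator, by_sign: bool) -> pd.DataFrame:
    """Assign each observation to half 0 or 1, randomly within its reflection.

    Observations of one reflection (and one Friedel sign, if ``by_sign``) are
    shuffled and dealt alternately, so any group of >= 2 observations
    populates both halves.
    """
    df = prep.copy()
    df["r"] = rng.random(len(df))
    cols = ["key", "sign"] if by_sign else ["key"]
    df = df.sort_values(cols + ["r"], kind="stable")
    df["half"] = df.groupby(cols, sort=False).cumcount() % 2
    return df


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _cc_half_from_prep(prep: pd.DataFrame, seed: int) -> Optional[float]:
    n = prep.groupby("key", sort=False)["i"].transform("size")
    multi = prep.loc[n >= 2]
    if multi["key"].nunique() < 3:
        return None
    rng = np.random.default_rng(seed)
    df = _half_split(multi, rng, by_sign=False)
    means = df.groupby(["key", "half"], sort=False)["i"].mean().unstack("half")
    means = means.dropna()
    if len(means) < 3:
        return None
    return _pearson(means[0].to_numpy(), means[1].to_numpy())


def cc_half(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    dmin: float,
    scales: ScaleSet | None = None,
    seed: int = 0,
) -> Optional[float]:
    """Half-dataset correlation CC1/2.

    Observations of each multiply-observed reflection are split at random
    (seeded, reproducible) into two halves; the Pearson correlation of the
    two vectors of per-half unweighted means is returned.  ``None`` when
    fewer than three reflections are usable.
    """
    return _cc_half_from_prep(_prepare(datasets, pg, dmin, scales), seed)


def _delanom_from_prep(prep: pd.DataFrame, seed: int) -> Optional[float]:
    if not len(prep):
        return None
    counts = prep.groupby(["key", "sign"], sort=False)["i"].transform("size")
    # both mates need >= 2 observations so each half defines both mates
    nsign = prep.groupby("key", sort=False)["sign"].transform("nunique")
    usable = prep.loc[(counts >= 2) & (nsign == 2)]
    if usable["key"].nunique() < 3:
        return None
    rng = np.random.default_rng(seed)
    df = _half_split(usable, rng, by_sign=True)
    means = (
        df.groupby(["key", "sign", "half"], sort=False)["i"].mean().unstack(["sign", "half"])
    )
    means = means.dropna()
    if len(means) < 3:
        return None
    danom0 = means[(1, 0)] - means[(-1, 0)]
    danom1 = means[(1, 1)] - means[(-1, 1)]
    return _pearson(danom0.to_numpy(), danom1.to_numpy())


def delanom(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    dmin: float,
    scales: ScaleSet | None = None,
    seed: int = 0,
) -> Optional[float]:
    """Anomalous-difference half-dataset correlation (CCanom interpretation).

    Per reflection, the I(+) and I(-) observations are each randomly halved;
    the per-half Bijvoet differences <I+> - <I-> are correlated across
    reflections where both halves define both mates.  ``None`` with fewer
    than three usable Bijvoet pairs.
    """
    return _delanom_from_prep(_prepare(datasets, pg, dmin, scales), seed)


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

def completeness(
    merged: MergedDataset, cell: UnitCell, pg: PointGroup, dmin: float
) -> float:
    """Percent of enumerated unique reflections present in ``merged``.

    ``cell`` should be the class-average cell; counting intersects the merged
    indices with the enumerated set, so the value never exceeds 100.
    """
    expected = unique_reflections(cell, pg, dmin)
    if not len(expected):
        raise ValueError("no reflections expected at this resolution")
    exp_keys = set(map(tuple, expected[["h", "k", "l"]].to_numpy()))
    if not len(merged.table):
        return 0.0
    got_keys = set(map(tuple, merged.table[["h", "k", "l"]].to_numpy()))
    return 100.0 * len(got_keys & exp_keys) / len(exp_keys)


# ---------------------------------------------------------------------------
# Per-frame profiles (SmRmerge)
# ---------------------------------------------------------------------------

@dataclass
class FrameProfile:
    """Per-frame raw and smoothed Rmerge trace for one crystal.

    Frames with no matchable observations carry NaN (an explicit undefined
    marker), never an implicit zero.
    """

    crystal_id: str
    raw: np.ndarray
    smoothed: np.ndarray
    kernel_sigma: float

    @property
    def n_frames(self) -> int:
        return len(self.raw)

    def defined_frames(self) -> np.ndarray:
        """1-based frame numbers with a defined smoothed value."""
        return np.flatnonzero(np.isfinite(self.smoothed)) + 1


def gaussian_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-kernel smoothing over frame number, NaN-aware.

    The kernel is truncated at +/-3 sigma and renormalised over the defined
    frames inside the window, so edges and gaps keep unit total weight.
    Undefined (NaN) frames stay undefined.  ``sigma -> 0`` returns the input.
    """
    raw = np.asarray(values, dtype=float)
    if sigma <= 1e-9:
        return raw.copy()
    half = int(math.ceil(3.0 * sigma))
    offsets = np.arange(-half, half + 1)
    weights = np.exp(-0.5 * (offsets / sigma) ** 2)
    defined = np.isfinite(raw)
    filled = np.where(defined, raw, 0.0)
    num = np.zeros_like(raw)
    den = np.zeros_like(raw)
    n = len(raw)
    for off, w in zip(offsets, weights):
        lo, hi = max(0, -off), min(n, n - off)
        if lo >= hi:  # kernel arm falls entirely outside the trace
            continue
        num[lo:hi] += w * filled[lo + off : hi + off]
        den[lo:hi] += w * defined[lo + off : hi + off]
    out = np.full(n, np.nan)
    ok = defined & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def frame_profile(
    crystal: CrystalDataset,
    merged_reference: MergedDataset,
    kernel_sigma: float = 2.0,
    scale: float = 1.0,
) -> FrameProfile:
    """SmRmerge trace of one crystal against a merged class reference.

    The raw value of frame f is
    sum_obs |k I_obs - <I>_ref| / sum_obs <I>_ref over the frame's
    observations whose canonical reflection exists in the reference (the
    reference mean appears in the denominator, so single-observation frames
    stay well defined).  The smoothed trace applies :func:`gaussian_smooth`.
    """
    raw = np.full(crystal.n_frames, np.nan)
    prep = _prepare([crystal], merged_reference.pg, merged_reference.dmin)
    if len(prep):
        ref = merged_reference.reference_means()
        joined = prep.join(ref, on="key", how="inner", rsuffix="_ref")
        if len(joined):
            joined = joined.assign(
                dev=(joined["i"] * scale - joined["i_ref"]).abs(), ref=joined["i_ref"]
            )
            g = joined.groupby("frame", sort=False).agg(num=("dev", "sum"), den=("ref", "sum"))
            ok = g["den"] > 0
            frames = g.index.to_numpy()[ok.to_numpy()]
            raw[frames - 1] = (g["num"] / g["den"]).to_numpy()[ok.to_numpy()]
    return FrameProfile(
        crystal_id=crystal.crystal_id,
        raw=raw,
        smoothed=gaussian_smooth(raw, kernel_sigma),
        kernel_sigma=kernel_sigma,
    )


# ---------------------------------------------------------------------------
# Bundled quality indicators
# ---------------------------------------------------------------------------

@dataclass
class StatsBundle:
    """Merged-data quality indicators of one assembled dataset."""

    rmerge: Optional[float]
    rmeas: Optional[float]
    cc_half: Optional[float]
    delanom: Optional[float]
    completeness: float
    mean_multiplicity: float
    mean_i_over_sig: float
    n_unique: int = 0
    n_obs: int = 0

    def as_dict(self) -> dict:
        return {
            "rmerge": self.rmerge,
            "rmeas": self.rmeas,
            "cc_half": self.cc_half,
            "delanom": self.delanom,
            "completeness": self.completeness,
            "mean_multiplicity": self.mean_multiplicity,
            "mean_i_over_sig": self.mean_i_over_sig,
            "n_unique": self.n_unique,
            "n_obs": self.n_obs,
        }

    def summary(self) -> str:
        def fmt(v):
            return "n/a" if v is None else f"{v:.6g}"

        lines = [f"{k}\t{fmt(v)}" for k, v in self.as_dict().items()]
        return "\n".join(lines)


def compute_stats(
    datasets: Sequence[CrystalDataset],
    pg: PointGroup,
    cell: UnitCell,
    dmin: float,
    scales: ScaleSet | None = None,
    seed: int = 0,
    anomalous: bool = False,
) -> tuple[MergedDataset, StatsBundle]:
    """Merge a set of crystals and evaluate the full indicator bundle.

    Returns the (non-anomalous when ``anomalous`` is off) merged dataset used
    as the reference for frame profiles, plus the StatsBundle.  DelAnom is
    evaluated only in anomalous mode.
    """
    prep = _prepare(datasets, pg, dmin, scales)
    merged = merge(datasets, pg, dmin, scales, anomalous=anomalous)
    r_merge, r_meas = _rmerge_from_prep(prep)
    cc = _cc_half_from_prep(prep, seed)
    dla = _delanom_from_prep(prep, seed + 1) if anomalous else None
    comp = completeness(merged, cell, pg, dmin)
    if len(merged.table):
        if merged.anomalous:
            mult = float(merged.table.groupby("key")["mult"].sum().mean())
            n_unique = int(merged.table["key"].nunique())
        else:
            mult = float(merged.table["mult"].mean())
            n_unique = len(merged.table)
        iosig = float((merged.table["i"] / merged.table["sig"]).mean())
    else:
        mult, n_unique, iosig = 0.0, 0, float("nan")
    bundle = StatsBundle(
        rmerge=r_merge,
        rmeas=r_meas,
        cc_half=cc,
        delanom=dla,
        completeness=comp,
        mean_multiplicity=mult,
        mean_i_over_sig=iosig,
        n_unique=n_unique,
        n_obs=int(len(prep)),
    )
    return merged, bundle
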