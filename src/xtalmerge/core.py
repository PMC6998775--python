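"""Reflection data model: unit cells, point-group symmetry and resolution machinery.

Everything downstream (scaling, merging, CC1/2, completeness) reduces Miller
indices to a canonical asymmetric-unit representative and filters observations
by d-spacing; both primitives live here.

The canonical representative of a reflection is the lexicographic maximum of
its symmetry orbit *including* Friedel inversion, so ``(h, k, l)`` and
``(-h, -k, -l)`` always share one canonical index.  A Friedel sign (+1/-1)
records which hemisphere the original index came from; anomalous merging keeps
the two signs apart, ordinary merging ignores them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "PointGroup",
    "Observation",
    "CrystalDataset",
    "ResolutionConfig",
    "OBS_COLUMNS",
    "d_spacing",
    "d_spacings",
    "map_to_asu",
    "asu_map",
    "enumerate_unique",
    "unique_reflections",
]

OBS_COLUMNS = ("frame", "h", "k", "l", "intensity", "sigma")


# ---------------------------------------------------------------------------
# Unit cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees.

    Monoclinic cells use the b-unique convention (beta != 90).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie strictly between 0 and 180 deg")
        if np.linalg.det(self.metric) <= 0:
            raise ValueError("degenerate cell: metric tensor is not positive definite")

    @property
    def metric(self) -> np.ndarray:
        """Real-space metric tensor G (Angstrom^2)."""
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric)))

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @staticmethod
    def mean(cells: Sequence["UnitCell"]) -> "UnitCell":
        """Component-wise average cell (used as a class-representative cell)."""
        if not cells:
            raise ValueError("mean of zero cells")
        arr = np.array([c.as_tuple() for c in cells])
        return UnitCell(*arr.mean(axis=0))


def d_spacings(cell: UnitCell, hkl: np.ndarray | Sequence) -> np.ndarray:
    """d-spacings in Angstrom for an (n, 3) array of Miller indices.

    Uses the full triclinic reciprocal metric; symmetric under hkl -> -hkl.
    """
    arr = np.atleast_2d(np.asarray(hkl, dtype=float))
    if arr.shape[-1] != 3:
        raise ValueError("expected (n, 3) Miller indices")
    if np.any(np.all(arr == 0, axis=1)):
        raise ValueError("the (0,0,0) index has no d-spacing")
    q = np.einsum("ni,ij,nj->n", arr, cell.reciprocal_metric, arr)
    return 1.0 / np.sqrt(q)


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """d-spacing of a single reflection."""
    return float(d_spacings(cell, [tuple(hkl)])[0])


# ---------------------------------------------------------------------------
# Point groups
# ---------------------------------------------------------------------------

def _closure(generators: Sequence) -> tuple:
    """Close a set of integer 3x3 matrices under multiplication."""
    ident = tuple(map(tuple, np.eye(3, dtype=int)))
    group = {ident}
    frontier = [np.asarray(g, dtype=int) for g in generators]
    mats = [np.eye(3, dtype=int)] + frontier
    changed = True
    while changed:
        changed = False
        for m1 in list(mats):
            for m2 in list(mats):
                prod = m1 @ m2
                key = tuple(map(tuple, prod))
                if key not in group:
                    group.add(key)
                    mats.append(prod)
                    changed = True
    return tuple(sorted(group))


# Generators act directly on (h, k, l) column vectors.  Trigonal/hexagonal
# groups are in the hexagonal-axes setting; "32" is the 321 orientation.
_R4C = ((0, 1, 0), (-1, 0, 0), (0, 0, 1))            # 4-fold about c
_R3C = ((0, 1, 0), (-1, -1, 0), (0, 0, 1))           # 3-fold about c (hex axes)
_R6C = ((1, 1, 0), (-1, 0, 0), (0, 0, 1))            # 6-fold about c (hex axes)
_2A = ((1, 0, 0), (0, -1, 0), (0, 0, -1))            # 2-fold about a
_2B = ((-1, 0, 0), (0, 1, 0), (0, 0, -1))            # 2-fold about b
_2HK = ((0, 1, 0), (1, 0, 0), (0, 0, -1))            # 2-fold in the hex basal plane
_P3 = ((0, 1, 0), (0, 0, 1), (1, 0, 0))              # cyclic axis permutation

_GENERATORS: dict[str, tuple] = {
    "1": (),
    "2": (_2B,),
    "222": (_2A, _2B),
    "4": (_R4C,),
    "422": (_R4C, _2A),
    "3": (_R3C,),
    "32": (_R3C, _2HK),
    "6": (_R6C,),
    "622": (_R6C, _2HK),
    "23": (_2A, _2B, _P3),
    "432": (_R4C, _2A, _P3),
}

# Common macromolecular space-group symbols reduced to their rotation point
# group (screw components and lattice centring stripped).  Sohncke groups only;
# lookups are case- and whitespace-insensitive.
_SPACE_GROUP_TO_PG: dict[str, str] = {
    "p1": "1",
    "p2": "2", "p21": "2", "c2": "2", "i2": "2",
    "p222": "222", "p2221": "222", "p21212": "222", "p212121": "222",
    "c2221": "222", "c222": "222", "f222": "222", "i222": "222", "i212121": "222",
    "p4": "4", "p41": "4", "p42": "4", "p43": "4", "i4": "4", "i41": "4",
    "p422": "422", "p4212": "422", "p4122": "422", "p41212": "422",
    "p4222": "422", "p42212": "422", "p4322": "422", "p43212": "422",
    "i422": "422", "i4122": "422",
    "p3": "3", "p31": "3", "p32": "3", "r3": "3", "h3": "3",
    "p312": "32", "p321": "32", "p3112": "32", "p3121": "32",
    "p3212": "32", "p3221": "32", "r32": "32", "h32": "32",
    "p6": "6", "p61": "6", "p65": "6", "p62": "6", "p64": "6", "p63": "6",
    "p622": "622", "p6122": "622", "p6522": "622", "p6222": "622",
    "p6422": "622", "p6322": "622",
    "p23": "23", "f23": "23", "i23": "23", "p213": "23", "i213": "23",
    "p432": "432", "p4232": "432", "f432": "432", "f4132": "432",
    "i432": "432", "p4332": "432", "p4132": "432", "i4132": "432",
}


@dataclass(frozen=True)
class PointGroup:
    """A rotation point group acting on Miller indices.

    ``rotations`` is a closed set of integer 3x3 matrices (as nested tuples)
    containing the identity; every matrix has determinant +/-1.
    """

    name: str
    rotations: tuple = field(repr=False)

    def __post_init__(self) -> None:
        mats = self.matrices
        if len(mats) == 0:
            raise ValueError("empty point group")
        ident = np.eye(3, dtype=int)
        keys = {tuple(map(tuple, m)) for m in mats}
        if tuple(map(tuple, ident)) not in keys:
            raise ValueError("point group must contain the identity")
        for m in mats:
            if abs(round(np.linalg.det(m))) != 1:
                raise ValueError("rotation matrices must have determinant +/-1")
            for m2 in mats:
                if tuple(map(tuple, m @ m2)) not in keys:
                    raise ValueError("rotation set is not closed under multiplication")

    @property
    def matrices(self) -> np.ndarray:
        """(n, 3, 3) integer array of the rotations."""
        return np.asarray(self.rotations, dtype=int)

    @property
    def order(self) -> int:
        return len(self.rotations)

    @classmethod
    def from_name(cls, name: str) -> "PointGroup":
        """Build from a point-group or space-group symbol, case-insensitively.

        Space-group strings like ``p2221`` are reduced to their point group
        (here 222) via a lookup of common macromolecular settings.
        """
        key = "".join(str(name).lower().split())
        if key in _GENERATORS:
            return cls(name=key, rotations=_closure(_GENERATORS[key]))
        if key in _SPACE_GROUP_TO_PG:
            pg = _SPACE_GROUP_TO_PG[key]
            return cls(name=pg, rotations=_closure(_GENERATORS[pg]))
        raise ValueError(
            f"unknown point-group/space-group symbol {name!r}; "
            f"supported point groups: {sorted(_GENERATORS)}"
        )

    @classmethod
    def from_matrices(cls, name: str, matrices: Iterable) -> "PointGroup":
        """Accept a user-supplied rotation set (validated for closure)."""
        rots = tuple(tuple(map(tuple, np.asarray(m, dtype=int))) for m in matrices)
        return cls(name=name, rotations=rots)


def asu_map(hkl: np.ndarray, pg: PointGroup) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised asymmetric-unit reduction.

    Parameters
    ----------
    hkl : (n, 3) integer array of Miller indices.
    pg : point group.

    Returns
    -------
    canonical : (n, 3) array — lexicographic maximum over the full orbit
        {R.hkl} union {-R.hkl} of each index.
    friedel_sign : (n,) array of +1/-1 — +1 when the rotation-only orbit of
        the input reaches the canonical index, -1 when only its Friedel mate
        does (centric reflections get +1).
    """
    arr = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    if arr.size == 0:
        return arr.reshape(0, 3), np.zeros(0, dtype=np.int64)
    rot = pg.matrices  # (r, 3, 3)
    plus = np.einsum("rij,nj->rni", rot, arr)  # (r, n, 3)
    bound = int(np.abs(plus).max()) + 1
    base = 2 * bound + 1

    def encode(v: np.ndarray) -> np.ndarray:
        return ((v[..., 0] + bound) * base + (v[..., 1] + bound)) * base + (
            v[..., 2] + bound
        )

    keys_plus = encode(plus).max(axis=0)
    keys_minus = encode(-plus).max(axis=0)
    best = np.maximum(keys_plus, keys_minus)
    signs = np.where(keys_plus >= keys_minus, 1, -1).astype(np.int64)
    l = best % base - bound
    rest = best // base
    k = rest % base - bound
    h = rest // base - bound
    return np.stack([h, k, l], axis=1), signs


def map_to_asu(
    hkl: Sequence[int], pg: PointGroup, anomalous: bool = False
) -> tuple[tuple[int, int, int], int]:
    """Reduce one Miller index to its canonical representative.

    The canonical index is identical in ordinary and anomalous mode; the
    Friedel sign is what anomalous merging uses to keep I(+) and I(-) apart.
    Idempotent: a canonical index maps to itself with sign +1.
    """
    if all(v == 0 for v in hkl):
        raise ValueError("the (0,0,0) index is not a reflection")
    canon, signs = asu_map(np.asarray([hkl]), pg)
    del anomalous  # same canonical representative either way; sign carries the mate
    return (int(canon[0, 0]), int(canon[0, 1]), int(canon[0, 2])), int(signs[0])


def _index_grid(cell: UnitCell, dmin: float) -> np.ndarray:
    """All nonzero integer indices that can satisfy d >= dmin.

    Per-axis bounds are exact: h = s . a, so |h| <= a / dmin (and likewise for
    k, l), whatever the cell angles.
    """
    hmax = int(cell.a / dmin)
    kmax = int(cell.b / dmin)
    lmax = int(cell.c / dmin)
    h, k, l = np.mgrid[-hmax : hmax + 1, -kmax : kmax + 1, -lmax : lmax + 1]
    grid = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    return grid[np.any(grid != 0, axis=1)]


def unique_reflections(cell: UnitCell, pg: PointGroup, dmin: float) -> pd.DataFrame:
    """Table of unique canonical reflections with d >= dmin.

    Columns ``h, k, l, d``, sorted by descending d then index.  The (0,0,0)
    index is excluded.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    grid = _index_grid(cell, dmin)
    d = d_spacings(cell, grid)
    keep = d >= dmin - 1e-9
    canon, _ = asu_map(grid[keep], pg)
    uniq, first = np.unique(canon, axis=0, return_index=True)
    dd = d[keep][first]
    df = pd.DataFrame({"h": uniq[:, 0], "k": uniq[:, 1], "l": uniq[:, 2], "d": dd})
    return df.sort_values(["d", "h", "k", "l"], ascending=[False, True, True, True]).reset_index(
        drop=True
    )


def enumerate_unique(cell: UnitCell, pg: PointGroup, dmin: float) -> int:
    """Number of symmetry-unique reflections to resolution dmin.

    This is the denominator of completeness.
    """
    return len(unique_reflections(cell, pg, dmin))


# ---------------------------------------------------------------------------
# Observations and per-crystal datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Observation:
    """One measured intensity of one reflection on one frame of one crystal."""

    crystal_id: str
    frame: int
    hkl: tuple[int, int, int]
    intensity: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.frame < 1:
            raise ValueError("frames are numbered from 1")
        if all(v == 0 for v in self.hkl):
            raise ValueError("the (0,0,0) index is not a reflection")


@dataclass
class CrystalDataset:
    """A crystal's unit cell plus its ordered frames and observations.

    ``observations`` is a DataFrame with columns
    ``frame, h, k, l, intensity, sigma``; frames are 1-based and lie in
    ``[1, n_frames]``.  This is the unit of wedge selection and of crystal
    rejection.
    """

    crystal_id: str
    cell: UnitCell
    n_frames: int
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        self.observations = obs = obs.loc[:, list(OBS_COLUMNS)].reset_index(drop=True)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if len(obs):
            if obs["sigma"].min() <= 0:
                raise ValueError("all sigmas must be positive")
            if obs["frame"].min() < 1 or obs["frame"].max() > self.n_frames:
                raise ValueError("frame numbers must lie in [1, n_frames]")
            if (obs[["h", "k", "l"]].to_numpy() == 0).all(axis=1).any():
                raise ValueError("the (0,0,0) index is not a reflection")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def subset_frames(self, frames: Iterable[int]) -> "CrystalDataset":
        """Restrict to a set of frames (frame numbering is preserved)."""
        keep = set(int(f) for f in frames)
        mask = self.observations["frame"].isin(keep)
        return CrystalDataset(
            crystal_id=self.crystal_id,
            cell=self.cell,
            n_frames=self.n_frames,
            observations=self.observations.loc[mask].reset_index(drop=True),
        )

    def up_to_frame(self, last_frame: int) -> "CrystalDataset":
        """Restrict to the leading wedge 1..last_frame."""
        mask = self.observations["frame"] <= int(last_frame)
        return CrystalDataset(
            crystal_id=self.crystal_id,
            cell=self.cell,
            n_frames=min(self.n_frames, int(last_frame)),
            observations=self.observations.loc[mask].reset_index(drop=True),
        )

    @classmethod
    def from_records(
        cls,
        crystal_id: str,
        cell: UnitCell,
        observations: Iterable[Observation],
        n_frames: int | None = None,
    ) -> "CrystalDataset":
        rows = [
            (o.frame, o.hkl[0], o.hkl[1], o.hkl[2], o.intensity, o.sigma)
            for o in observations
        ]
        df = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
        if n_frames is None:
            n_frames = int(df["frame"].max()) if len(df) else 1
        return cls(crystal_id=crystal_id, cell=cell, n_frames=n_frames, observations=df)


@dataclass(frozen=True)
class ResolutionConfig:
    """The two resolution cutoffs of the workflow.

    ``reso`` is the assembly/processing cutoff; ``reso_cchalf`` (numerically
    larger, i.e. lower resolution) is where per-wedge CC1/2 is evaluated.
    When not supplied, ``reso_cchalf`` defaults to ``reso + 1`` Angstrom.
    """

    reso: float
    reso_cchalf: float | None = None

    def __post_init__(self) -> None:
        if self.reso <= 0:
            raise ValueError("reso must be positive")
        if self.reso_cchalf is None:
            object.__setattr__(self, "reso_cchalf", self.reso + 1.0)
        if self.reso_cchalf < self.reso:
            raise ValueError(
                "reso_cchalf must be >= reso (statistics at lower resolution)"
            )
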