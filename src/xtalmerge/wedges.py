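"""Progressive-wedge scoring and best-wedge selection (workflow step 1).

Each crystal's rotation series is divided into ``q_total`` contiguous base
wedges; cumulative wedge q spans base wedges 1..q.  Every cumulative wedge is
scored by CC1/2 at the statistics resolution (``reso_cchalf``, lower than the
assembly resolution so damaged-but-useful frames still count), and the wedge
with maximum CC1/2 becomes the crystal's dataset.  Radiation damage makes
this a rising-then-falling curve: adding frames first raises multiplicity,
then admits decayed intensities that decorrelate the halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import CrystalDataset, PointGroup
from .stats import cc_half

__all__ = [
    "WedgeStats",
    "wedge_boundaries",
    "build_progressive_wedges",
    "score_wedges",
    "select_best_wedge",
    "select_dataset",
]


@dataclass
class WedgeStats:
    """One cumulative wedge: frames 1..last_frame of a crystal."""

    q: int
    last_frame: int
    cc_half: Optional[float] = None
    n_obs: int = 0


def wedge_boundaries(n_frames: int, q_total: int) -> list[int]:
    """Cumulative last-frame numbers of the q_total base wedges.

    Frames are divided as evenly as possible; remainder frames go to the
    earliest wedges (the least-damaged part of the series).
    """
    if not 1 <= q_total <= n_frames:
        raise ValueError("q_total must lie in [1, n_frames]")
    base, rem = divmod(n_frames, q_total)
    ends, last = [], 0
    for q in range(q_total):
        last += base + (1 if q < rem else 0)
        ends.append(last)
    return ends


def build_progressive_wedges(crystal: CrystalDataset, q_total: int) -> list[WedgeStats]:
    """Unscored cumulative wedges for one crystal (nested frame ranges)."""
    return [
        WedgeStats(q=q + 1, last_frame=end)
        for q, end in enumerate(wedge_boundaries(crystal.n_frames, q_total))
    ]


def score_wedges(
    crystal: CrystalDataset,
    wedges: Sequence[WedgeStats],
    pg: PointGroup,
    reso_cchalf: float,
    seed: int = 0,
) -> list[WedgeStats]:
    """CC1/2 of every cumulative wedge at the statistics resolution.

    Wedges with too few repeated observations keep ``cc_half = None`` —
    explicitly undefined, never 0 or -inf.  Within one crystal a common scale
    cancels in the correlation, so no scaling is applied here.
    """
    out = []
    for w in wedges:
        sub = crystal.up_to_frame(w.last_frame)
        cc = cc_half([sub], pg, reso_cchalf, scales=None, seed=seed + w.q)
        out.append(WedgeStats(q=w.q, last_frame=w.last_frame, cc_half=cc, n_obs=sub.n_obs))
    return out


def select_best_wedge(stats: Sequence[WedgeStats]) -> Optional[WedgeStats]:
    """Wedge with maximum CC1/2; ties go to the larger wedge.

    Returns ``None`` when no wedge has a defined CC1/2 (the crystal is then
    excluded from assembly rather than raising).
    """
    defined = [w for w in stats if w.cc_half is not None]
    if not defined:
        return None
    return max(defined, key=lambda w: (w.cc_half, w.last_frame))


def select_dataset(
    crystal: CrystalDataset,
    pg: PointGroup,
    reso_cchalf: float,
    q_total: int = 10,
    seed: int = 0,
) -> tuple[Optional[CrystalDataset], list[WedgeStats]]:
    """Score all wedges and trim the crystal to its best one.

    Returns ``(trimmed dataset or None, per-wedge statistics)``; ``None``
    marks a crystal excluded for having no defined CC1/2 in any wedge.
    """
    q_eff = min(q_total, crystal.n_frames)
    wedges = build_progressive_wedges(crystal, q_eff)
    scored = score_wedges(crystal, wedges, pg, reso_cchalf, seed=seed)
    best = select_best_wedge(scored)
    if best is None:
        return None, scored
    return crystal.up_to_frame(best.last_frame), scored
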