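"""Unit-cell classification (workflow step 2).

Microcrystals drift in cell dimensions with environment and handling; merging
non-isomorphous crystals degrades the assembled data.  The M selected
datasets are therefore split into N classes by agglomerative hierarchical
clustering of their six cell parameters, z-scored so Angstrom lengths and
degree angles weigh equally.  ``single`` linkage keeps as many crystals as
possible in one class (useful when maximising anomalous redundancy);
``ward`` maximises class separation (more, cleaner classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy

from .core import UnitCell

__all__ = ["ClassAssignment", "cell_features", "cluster_cells", "export_dendrogram"]

_LINKAGES = ("single", "ward")


def cell_features(cells: Sequence[UnitCell]) -> tuple[np.ndarray, np.ndarray]:
    """Standardised M x 6 feature matrix of (a, b, c, alpha, beta, gamma).

    Each column is centred and divided by its sample standard deviation
    (ddof=1); zero-variance parameters give a zero column rather than a
    division error.  Returns ``(features, per-column sds)``.
    """
    if len(cells) < 2:
        raise ValueError("need at least two cells to classify")
    raw = np.array([c.as_tuple() for c in cells], dtype=float)
    sds = raw.std(axis=0, ddof=1)
    centred = raw - raw.mean(axis=0)
    feats = np.zeros_like(centred)
    nz = sds > 0
    feats[:, nz] = centred[:, nz] / sds[nz]
    return feats, sds


@dataclass
class ClassAssignment:
    """Result of cutting the cell dendrogram into N classes.

    ``labels`` maps crystal_id -> class label in [1, N]; label 1 is always
    the largest class (the assembly's primary candidate).  ``linkage_record``
    is the scipy linkage matrix (merge pairs and heights).
    """

    labels: dict[str, int]
    linkage_record: np.ndarray
    linkage_method: str
    feature_sds: np.ndarray
    crystal_ids: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return [cid for cid, lab in self.labels.items() if lab == label]


def _cut_to_n(Z: np.ndarray, m: int, n_classes: int) -> np.ndarray:
    """Replay the first m - n merges of the linkage record.

    Unlike a height cut this always yields exactly N non-empty classes, even
    with duplicate feature rows.
    """
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    clusters = {i: [i] for i in range(m)}
    next_id = m
    for row in Z[: m - n_classes]:
        a, b = find(int(row[0])), find(int(row[1]))
        merged = clusters.pop(a) + clusters.pop(b)
        parent.append(next_id)
        parent[a] = parent[b] = next_id
        clusters[next_id] = merged
        next_id += 1
    labels = np.empty(m, dtype=int)
    # order classes by descending size, ties by smallest member index
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    for lab, members in enumerate(ordered, start=1):
        labels[members] = lab
    return labels


def cluster_cells(
    features: np.ndarray,
    n_classes: int,
    linkage: str = "ward",
    crystal_ids: Sequence[str] | None = None,
    feature_sds: np.ndarray | None = None,
) -> ClassAssignment:
    """Agglomerative clustering of standardised cell features into N classes.

    Euclidean distance; ``linkage`` is ``single`` or ``ward``.  The tree is
    cut by replaying merges, guaranteeing exactly N non-empty classes.
    """
    feats = np.asarray(features, dtype=float)
    m = len(feats)
    if not 1 <= n_classes <= m:
        raise ValueError("number of classes must lie in [1, M]")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if crystal_ids is None:
        crystal_ids = [f"xtal_{i:03d}" for i in range(m)]
    Z = hierarchy.linkage(feats, method=linkage)
    labels = _cut_to_n(Z, m, n_classes)
    return ClassAssignment(
        labels={cid: int(lab) for cid, lab in zip(crystal_ids, labels)},
        linkage_record=Z,
        linkage_method=linkage,
        feature_sds=np.asarray(feature_sds) if feature_sds is not None else np.array([]),
        crystal_ids=tuple(crystal_ids),
    )


def classify_datasets(
    cells: Sequence[UnitCell],
    crystal_ids: Sequence[str],
    n_classes: int,
    linkage: str = "ward",
) -> ClassAssignment:
    """Convenience wrapper: features + clustering in one call."""
    feats, sds = cell_features(cells)
    return cluster_cells(feats, n_classes, linkage, crystal_ids, feature_sds=sds)


def export_dendrogram(assignment: ClassAssignment, path) -> str:
    """Write the classification dendrogram as a vector-format figure (PDF).

    Leaf labels are crystal ids; the vertical axis carries merge distances.
    Returns the path written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6.0, 0.25 * len(assignment.crystal_ids)), 4.5))
    hierarchy.dendrogram(
        assignment.linkage_record, labels=list(assignment.crystal_ids), ax=ax
    )
    ax.set_ylabel("merge distance (z-scored cell space)")
    ax.set_title(f"unit-cell classification ({assignment.linkage_method} linkage)")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)
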