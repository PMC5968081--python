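"""Subfield connectivity matrices and bundle extraction by ROI filtering.

A streamline contributes one count to the (endpoint label, endpoint label)
cell when its two endpoints fall in different nonzero labels; self-connections
and unlabeled endpoints contribute nothing, so the matrix is symmetric with a
zero diagonal.  No length normalization is applied by default (the
hippocampus is a small, internally connected structure with short fibers);
the log-mean-length normalization used in whole-brain studies is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (HIPPOCAMPAL_LEGEND, LabelMap, Tractogram, ValidationError)


@dataclass
class ConnectivityMatrix:
    """K x K streamline-count matrix with an ordered region legend."""

    counts: np.ndarray
    legend: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(HIPPOCAMPAL_LEGEND))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.legend)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts must be {k}x{k} to match the legend")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be >= 0")
        if np.any(self.counts != self.counts.T):
            raise ValidationError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValidationError("self-connections are excluded (zero diagonal)")


@dataclass
class BundleSelector:
    """Endpoint/waypoint/exclusion label sets defining a named bundle."""

    start_labels: frozenset[int]
    end_labels: frozenset[int]
    waypoint_labels: tuple[frozenset[int], ...] = ()
    exclusion_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.start_labels = frozenset(self.start_labels)
        self.end_labels = frozenset(self.end_labels)
        self.waypoint_labels = tuple(frozenset(w) for w in self.waypoint_labels)
        self.exclusion_labels = frozenset(self.exclusion_labels)
        if not self.start_labels or not self.end_labels:
            raise ValidationError("start and end label sets must be nonempty")
        if (self.start_labels & self.exclusion_labels
                or self.end_labels & self.exclusion_labels):
            raise ValidationError("start/end sets must not overlap exclusions")


def _labels_at(points: np.ndarray, labels: LabelMap) -> np.ndarray:
    inv = np.linalg.inv(labels.grid.affine)
    vox = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = labels.grid.shape
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(len(points), dtype=np.int64)
    if inside.any():
        v = vox[inside]
        out[inside] = labels.labels[v[:, 0], v[:, 1], v[:, 2]]
    return out


def build_matrix(tractogram: Tractogram, labels: LabelMap) -> ConnectivityMatrix:
    """Endpoint-pair streamline counts over the label legend."""
    keys = sorted(labels.legend)
    pos = {lab: i for i, lab in enumerate(keys)}
    k = len(keys)
    counts = np.zeros((k, k), dtype=np.int64)
    for line in tractogram.streamlines:
        ends = _labels_at(line[[0, -1]], labels)
        a, b = int(ends[0]), int(ends[1])
        if a == 0 or b == 0 or a == b:
            continue
        counts[pos[a], pos[b]] += 1
        counts[pos[b], pos[a]] += 1
    legend = {lab: labels.legend[lab] for lab in keys}
    return ConnectivityMatrix(counts, legend,
                              provenance=dict(tractogram.provenance))


def normalize_by_log_length(matrix: ConnectivityMatrix,
                            tractogram: Tractogram,
                            labels: LabelMap) -> np.ndarray:
    """Counts divided by log mean fiber length per cell (optional variant)."""
    keys = sorted(matrix.legend)
    pos = {lab: i for i, lab in enumerate(keys)}
    k = len(keys)
    tot_len = np.zeros((k, k))
    n = np.zeros((k, k))
    for line in tractogram.streamlines:
        ends = _labels_at(line[[0, -1]], labels)
        a, b = int(ends[0]), int(ends[1])
        if a == 0 or b == 0 or a == b:
            continue
        ln = float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())
        for i, j in ((pos[a], pos[b]), (pos[b], pos[a])):
            tot_len[i, j] += ln
            n[i, j] += 1
    out = np.zeros((k, k), dtype=float)
    nz = n > 0
    mean_len = np.where(nz, tot_len / np.where(nz, n, 1), 1.0)
    denom = np.log(np.clip(mean_len, np.e, None))  # log >= 1
    out[nz] = matrix.counts[nz] / denom[nz]
    return out


def filter_bundle(tractogram: Tractogram, selector: BundleSelector,
                  labels: LabelMap) -> Tractogram:
    """Keep streamlines joining the start and end sets through all waypoints.

    One endpoint must lie in ``start_labels`` and the other in ``end_labels``
    (order-insensitive, and not the same voxel-set membership on both ends
    when the sets coincide); the polyline must traverse at least one voxel of
    every waypoint set and none of the exclusion set.
    """
    kept = []
    for line in tractogram.streamlines:
        traversed = _labels_at(line, labels)
        a, b = int(traversed[0]), int(traversed[-1])
        ends_ok = ((a in selector.start_labels and b in selector.end_labels)
                   or (b in selector.start_labels and a in selector.end_labels))
        if not ends_ok or (a == b and selector.start_labels
                           == selector.end_labels):
            continue
        tset = set(traversed.tolist())
        if any(not (w & tset) for w in selector.waypoint_labels):
            continue
        if selector.exclusion_labels & tset:
            continue
        kept.append(line)
    return Tractogram(kept, tractogram.step_size,
                      dict(tractogram.provenance, bundle_filtered=True))


def matrix_summaries(matrix: ConnectivityMatrix):
    """Per-region degree and within/between part (head/body/tail) aggregates."""
    import pandas as pd

    keys = sorted(matrix.legend)
    degree = matrix.counts.sum(axis=1)
    regions = pd.DataFrame({
        "label": keys,
        "part": [matrix.legend[k][0] for k in keys],
        "structure": [matrix.legend[k][1] for k in keys],
        "degree": degree,
    })
    parts = sorted({p for p, _ in matrix.legend.values()})
    part_idx = {p: [i for i, k in enumerate(keys)
                    if matrix.legend[k][0] == p] for p in parts}
    rows = []
    for i, p in enumerate(parts):
        for q in parts[i:]:
            block = matrix.counts[np.ix_(part_idx[p], part_idx[q])]
            total = int(np.triu(block).sum()) if p == q else int(block.sum())
            rows.append({"part_a": p, "part_b": q, "connections": total})
    return regions, pd.DataFrame(rows)
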