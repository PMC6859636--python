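"""Skeleton feature points: endpoints and bifurcations.

Classification looks only at the 3x3 neighborhood of a skeleton pixel.  The
eight neighbor cells are partitioned into 8-connected groups (two foreground
neighbors belong to the same group when they touch each other, edge or
corner).  The group count determines the role of the center pixel:

* exactly one group of one or two mutually adjacent neighbors — **endpoint**:
  the pixel terminates a single root branch;
* exactly two groups — interior pixel of an arc;
* three or more groups — **bifurcation**: three or more branches meet here.

This reading makes the endpoint rule (one connected neighbor, or a connected
pair) and the bifurcation rule (not fewer than two *disconnected* neighbor
groups beyond the first) consistent with each other: no pixel is both.  The
historical literal form of the bifurcation rule — "more than one neighbor and
the neighbors are connected" — contradicts the disconnected-branches intent
and would label two-neighbor endpoints as bifurcations; it is kept available
behind ``literal_bifurcation=True`` for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thinning import RING_OFFSETS

__all__ = [
    "FeaturePointSet",
    "is_endpoint",
    "is_bifurcation",
    "neighbor_groups",
    "extract_feature_points",
]


@dataclass(frozen=True)
class FeaturePointSet:
    """Endpoints and bifurcations of a skeleton, in raster order."""

    endpoints: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    bifurcations: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.endpoints) + len(self.bifurcations)


def _fg_offsets(window: np.ndarray) -> list[tuple[int, int]]:
    window = np.asarray(window)
    if window.shape != (3, 3):
        raise ValueError(f"expected 3x3 window, got {window.shape}")
    if not window[1, 1]:
        raise ValueError("center pixel must be foreground")
    return [(dr, dc) for dr, dc in RING_OFFSETS if window[1 + dr, 1 + dc]]


def neighbor_groups(window: np.ndarray) -> list[list[tuple[int, int]]]:
    """Partition the foreground neighbors of the center into 8-connected groups.

    Adjacency is true pixel adjacency between the neighbor cells themselves
    (Chebyshev distance 1); the center cell does not mediate connectivity.
    """
    cells = _fg_offsets(window)
    groups: list[list[tuple[int, int]]] = []
    for cell in cells:  # cells come in ring order; union into groups
        attached = [g for g in groups
                    if any(max(abs(cell[0] - o[0]), abs(cell[1] - o[1])) == 1
                           for o in g)]
        if not attached:
            groups.append([cell])
        else:
            merged = attached[0]
            for g in attached[1:]:
                merged.extend(g)
                groups.remove(g)
            merged.append(cell)
    return groups


def is_endpoint(window: np.ndarray) -> bool:
    """True when the center terminates a single branch.

    Requires exactly one neighbor, or exactly two neighbors that are adjacent
    to each other.  An isolated pixel (no neighbors) is not an endpoint.
    """
    groups = neighbor_groups(window)
    return len(groups) == 1 and len(groups[0]) <= 2


def is_bifurcation(window: np.ndarray, literal: bool = False) -> bool:
    """True when three or more disconnected branches meet at the center.

    With ``literal=True`` the uncorrected historical rule is applied instead
    (more than one neighbor forming a single connected group), which exists
    only for side-by-side comparison; see the module docstring.
    """
    groups = neighbor_groups(window)
    if literal:
        n = sum(len(g) for g in groups)
        return n > 1 and len(groups) == 1
    return len(groups) >= 3


def extract_feature_points(skel: np.ndarray,
                           literal_bifurcation: bool = False) -> FeaturePointSet:
    """Scan a skeleton and classify every foreground pixel.

    Borders are zero-padded.  Output coordinate lists are in raster order
    (row-major), so downstream processing queues are reproducible.
    """
    skel = np.asarray(skel)
    padded = np.pad((skel > 0).astype(np.uint8), 1)
    endpoints: list[tuple[int, int]] = []
    bifurcations: list[tuple[int, int]] = []
    for r, c in np.argwhere(skel > 0):
        window = padded[r:r + 3, c:c + 3]
        if is_endpoint(window):
            endpoints.append((int(r), int(c)))
        elif is_bifurcation(window, literal=literal_bifurcation):
            bifurcations.append((int(r), int(c)))
    return FeaturePointSet(tuple(endpoints), tuple(bifurcations))
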