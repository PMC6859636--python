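"""Progressive corrosion: endpoint-seeded serial-number labeling of skeleton arcs.

The skeleton is consumed from its endpoints inward.  Each endpoint receives a
fresh serial number; a FIFO queue of frontier pixels carries its serial along
the arc, erasing the working skeleton as it goes.  When a wave reaches a
junction pixel (a skeleton pixel with three or more foreground neighbors) the
wave stops, and each branch leaving the junction is restarted with a fresh
serial.  When two waves meet head-on along the same arc — the normal outcome
for an isolated line seeded at both of its ends — their serials are unified,
so every bifurcation-free arc ends up carrying a single serial number.

The final label map assigns each arc a compact positive id (1..K, in order of
first raster appearance), keeps junction pixels under the reserved marker
``JUNCTION_LABEL``, and leaves background at 0.  Equivalently: the positive
labels are exactly the 8-connected components of the skeleton with its
junction pixels removed, which is what makes the labeling checkable against
an independent graph decomposition.  Pure cycles and any other region not
reachable from an endpoint are swept up by seeding from their raster-first
pixel.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import FeaturePointSet

__all__ = [
    "JUNCTION_LABEL",
    "CorrosionState",
    "Segment",
    "init_state",
    "corrode",
    "segments_from_labels",
    "junction_mask",
]

JUNCTION_LABEL = -1

_NB8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class CorrosionState:
    """Queues and label image of a corrosion run.

    ``a`` holds frontier coordinates, ``b`` the serial number travelling with
    each coordinate (the two queues always have equal length), and ``c`` is
    the label image with serials stamped at their current frontier.
    """

    a: deque = field(default_factory=deque)
    b: deque = field(default_factory=deque)
    c: np.ndarray | None = None
    next_serial: int = 1


@dataclass(frozen=True)
class Segment:
    """One bifurcation-free skeleton arc as an ordered pixel path."""

    id: int
    path: tuple[tuple[int, int], ...]

    @property
    def ends(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.path[0], self.path[-1]

    @property
    def length_px(self) -> int:
        return len(self.path)


def junction_mask(skel: np.ndarray) -> np.ndarray:
    """Boolean mask of junction pixels: foreground with >= 3 foreground neighbors."""
    fg = (np.asarray(skel) > 0).astype(np.uint8)
    deg = ndimage.convolve(fg, np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
                           mode="constant")
    return (fg > 0) & (deg >= 3)


def init_state(skel: np.ndarray, fps: FeaturePointSet) -> CorrosionState:
    """Seed the corrosion queues from the endpoint set.

    Endpoints are enqueued in raster order with serial numbers 1..|M|, and the
    label image ``c`` is stamped with each serial at its endpoint coordinate.
    """
    skel = np.asarray(skel)
    state = CorrosionState(c=np.zeros(skel.shape, dtype=np.int32))
    for r, c in fps.endpoints:
        if not skel[r, c]:
            raise ValueError(f"endpoint {(r, c)} is not on the skeleton")
        state.a.append((r, c))
        state.b.append(state.next_serial)
        state.c[r, c] = state.next_serial
        state.next_serial += 1
    return state


def corrode(skel: np.ndarray, state: CorrosionState) -> np.ndarray:
    """Run progressive corrosion to completion and return the label map.

    The returned int32 array holds 0 on background, ``JUNCTION_LABEL`` on
    junction pixels, and a compact arc id (1..K) on every other skeleton
    pixel.  Identical inputs give identical outputs: the queue is FIFO and
    neighbors are visited in raster order.
    """
    skel = (np.asarray(skel) > 0)
    if state.c is None or state.c.shape != skel.shape:
        raise ValueError("state not initialized for this skeleton")
    rows, cols = skel.shape
    junction = junction_mask(skel)

    labels = state.c.astype(np.int64).copy()
    labels[junction] = JUNCTION_LABEL
    work = skel.copy()
    queue = deque(zip(state.a, state.b))
    # endpoints that coincide with junctions were overwritten above; drop them
    queue = deque((p, s) for p, s in queue if labels[p] == s)

    parent: dict[int, int] = {s: s for _, s in queue}
    next_serial = state.next_serial

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    def fresh() -> int:
        nonlocal next_serial
        s = next_serial
        next_serial += 1
        parent[s] = s
        return s

    expanded = np.zeros(skel.shape, dtype=bool)

    def drain() -> None:
        while queue:
            (r, c), s = queue.popleft()
            work[r, c] = False
            for dr, dc in _NB8:
                qr, qc = r + dr, c + dc
                if not (0 <= qr < rows and 0 <= qc < cols) or not skel[qr, qc]:
                    continue
                lq = labels[qr, qc]
                if lq == 0:
                    labels[qr, qc] = s
                    queue.append(((qr, qc), s))
                elif lq == JUNCTION_LABEL:
                    if not expanded[qr, qc]:
                        # each branch leaving the junction restarts with a
                        # fresh serial
                        expanded[qr, qc] = True
                        for er, ec in _nbrs(qr, qc, rows, cols):
                            if skel[er, ec] and labels[er, ec] == 0:
                                ns = fresh()
                                labels[er, ec] = ns
                                queue.append(((er, ec), ns))
                elif lq != s:
                    union(s, int(lq))  # two waves met on the same arc

    drain()
    # sweep regions with no endpoint seed (cycles, junction-locked arcs)
    remaining = np.argwhere(skel & (labels == 0))
    for r, c in remaining:
        if labels[r, c] == 0:
            ns = fresh()
            labels[r, c] = ns
            queue.append(((int(r), int(c)), ns))
            drain()

    # compact the union-find classes to 1..K in raster order of first pixel
    compact: dict[int, int] = {}
    out = np.zeros(skel.shape, dtype=np.int32)
    out[junction] = JUNCTION_LABEL
    for r, c in np.argwhere(labels > 0):
        root = find(int(labels[r, c]))
        if root not in compact:
            compact[root] = len(compact) + 1
        out[r, c] = compact[root]
    return out


def _nbrs(r: int, c: int, rows: int, cols: int):
    for dr, dc in _NB8:
        qr, qc = r + dr, c + dc
        if 0 <= qr < rows and 0 <= qc < cols:
            yield qr, qc


def segments_from_labels(label_map: np.ndarray) -> list[Segment]:
    """Materialize each positive arc label as an ordered pixel path.

    Every arc is a simple path or a simple cycle (a pixel with three or more
    within-arc neighbors would have been a junction); a cycle is opened at
    its raster-first pixel.  A label violating this indicates an upstream
    bug and raises ``RuntimeError``.
    """
    label_map = np.asarray(label_map)
    segments: list[Segment] = []
    if label_map.size == 0 or label_map.max(initial=0) <= 0:
        return segments
    for k in range(1, int(label_map.max()) + 1):
        coords = [tuple(map(int, rc)) for rc in np.argwhere(label_map == k)]
        if not coords:
            continue
        cell_set = set(coords)
        adj = {p: [q for q in _adj8(p) if q in cell_set] for p in coords}
        if any(len(v) > 2 for v in adj.values()):
            raise RuntimeError(f"label {k} is not a simple path")
        ends = [p for p in coords if len(adj[p]) <= 1]
        start = min(ends) if ends else coords[0]  # cycle: open at raster-first
        path = [start]
        seen = {start}
        while True:
            nxt = [q for q in adj[path[-1]] if q not in seen]
            if not nxt:
                break
            nxt.sort()
            path.append(nxt[0])
            seen.add(nxt[0])
        if len(path) != len(coords):
            raise RuntimeError(f"label {k} is not a simple path")
        segments.append(Segment(id=k, path=tuple(path)))
    return segments


def _adj8(p: tuple[int, int]):
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _NB8]
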