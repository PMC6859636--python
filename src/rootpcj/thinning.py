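"""Zhang-Suen two-subiteration thinning.

The binary root mask is reduced to a unit-width skeleton by repeated boundary
peeling.  Each round runs two sub-passes; in both, a foreground pixel P1 is
deleted when, on the image as it stood at the start of the sub-pass,

* ``2 <= N(P1) <= 6`` — N counts foreground pixels among its 8 neighbors,
* ``S(P1) == 1`` — S counts 0->1 transitions along the cyclic neighbor ring
  P2, P3, ..., P9, P2,
* two three-neighbor products vanish: ``P2*P4*P6 == 0`` and ``P4*P6*P8 == 0``
  in sub-pass A, ``P2*P4*P8 == 0`` and ``P2*P6*P8 == 0`` in sub-pass B.

Neighbor positions follow the conventional compass layout: P2 is north of the
center, then clockwise P3 = NE, P4 = E, P5 = SE, P6 = S, P7 = SW, P8 = W,
P9 = NW.  Pixels outside the frame count as background (zero padding).  Both
sub-passes mark all deletions first and apply them at once, so the result does
not depend on scan order.  Iteration stops when a full A+B round deletes
nothing; the output is a fixed point of the procedure.
"""

from __future__ import annotations

import numpy as np

from .preprocess import as_mask

__all__ = ["neighbor_count", "transition_count", "thin", "RING_OFFSETS"]

#: (row, col) offsets of P2..P9 relative to the center P1.
RING_OFFSETS = (
    (-1, 0),   # P2 N
    (-1, 1),   # P3 NE
    (0, 1),    # P4 E
    (1, 1),    # P5 SE
    (1, 0),    # P6 S
    (1, -1),   # P7 SW
    (0, -1),   # P8 W
    (-1, -1),  # P9 NW
)


def _ring(window: np.ndarray) -> list[int]:
    """Extract P2..P9 from a 3x3 window centred on P1."""
    window = np.asarray(window)
    if window.shape != (3, 3):
        raise ValueError(f"expected a 3x3 window, got shape {window.shape}")
    return [int(window[1 + dr, 1 + dc]) for dr, dc in RING_OFFSETS]


def neighbor_count(window: np.ndarray) -> int:
    """N(P1): number of foreground pixels among the 8 neighbors of the center."""
    return sum(_ring(window))


def transition_count(window: np.ndarray) -> int:
    """S(P1): number of 0->1 transitions along the cyclic ring P2..P9, P2."""
    ring = _ring(window)
    ring.append(ring[0])
    return sum(1 for a, b in zip(ring, ring[1:]) if a == 0 and b == 1)


def _shifted_neighbors(img: np.ndarray):
    """Return P2..P9 as full-image arrays (zero-padded shifts of ``img``)."""
    p = np.pad(img, 1)
    return (
        p[:-2, 1:-1],   # P2 N
        p[:-2, 2:],     # P3 NE
        p[1:-1, 2:],    # P4 E
        p[2:, 2:],      # P5 SE
        p[2:, 1:-1],    # P6 S
        p[2:, :-2],     # P7 SW
        p[1:-1, :-2],   # P8 W
        p[:-2, :-2],    # P9 NW
    )


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a unit-width skeleton.

    Returns a uint8 {0, 1} array of the same shape whose foreground is a
    subset of the input foreground.  Re-thinning the output leaves it
    unchanged.
    """
    img = as_mask(mask).copy()
    while True:
        changed = False
        for sub_b in (False, True):
            p2, p3, p4, p5, p6, p7, p8, p9 = _shifted_neighbors(img)
            ring = (p2, p3, p4, p5, p6, p7, p8, p9, p2)
            n = sum(int_arr.astype(np.int16) for int_arr in ring[:-1])
            s = np.zeros(img.shape, dtype=np.int16)
            for a, b in zip(ring, ring[1:]):
                s += (a == 0) & (b == 1)
            if not sub_b:
                prod_ok = ((p2 * p4 * p6) == 0) & ((p4 * p6 * p8) == 0)
            else:
                prod_ok = ((p2 * p4 * p8) == 0) & ((p2 * p6 * p8) == 0)
            delete = (img == 1) & (n >= 2) & (n <= 6) & (s == 1) & prod_ok
            if delete.any():
                img[delete] = 0
                changed = True
        if not changed:
            return img
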