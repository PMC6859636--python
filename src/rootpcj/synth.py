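"""Synthetic root-system images with exact ground truth.

The generator emulates what a camera sees through the transparent wall of an
annular growth container: a collar (seed) point near the top of the frame
from which several smooth root curves of finite width descend and fan out,
partially hidden by soil.  Each root center line is a quadratic polynomial in
the row coordinate,

    col(r) = c0 + tan(theta) * (r - r0) + q * (r - r0)^2,

with departure angle ``theta`` (degrees from straight down, positive toward
increasing column) and curvature coefficient ``q`` kept small enough that a
root turns only gently over its length — the regime in which the low-degree
polynomial matching model downstream is well specified.  Occlusion is modeled
by punching circular soil patches through single roots, and imaging noise by
Bernoulli speckle on the background.

Everything is driven by ``numpy.random.default_rng`` with a recorded seed, so
a truth object regenerates its images exactly, on any platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.draw import disk as _disk

from .preprocess import as_mask

__all__ = [
    "RootTruth",
    "GapTruth",
    "SyntheticTruth",
    "generate_root_system",
    "occlude",
    "add_noise",
    "score_recovery",
    "RecoveryMetrics",
]


@dataclass
class RootTruth:
    """Ground truth of one root: curve parameters and rasterized center line."""

    root_id: int
    departure_angle_deg: float
    curvature: float
    width_px: int
    arc_length_px: int
    path: list[list[int]]  # ordered center-line pixels, collar to tip


@dataclass
class GapTruth:
    """One occlusion gap: the root it cuts and its arc-index extent."""

    root_id: int
    arc_start: int
    span_px: int

    @property
    def arc_end(self) -> int:
        return self.arc_start + self.span_px


@dataclass
class SyntheticTruth:
    """Full ground truth of a generated scene."""

    shape: tuple[int, int]
    collar: tuple[int, int]
    roots: list[RootTruth]
    gaps: list[GapTruth] = field(default_factory=list)
    rng_seed: int = 0
    mm_per_px: float = 0.1
    total_arc_px: int = 0   # pixels in the union of all center lines
    rel_px: int = 0         # horizontal span of the clean mask
    mean_width_px: float = 0.0

    @property
    def n_roots(self) -> int:
        return len(self.roots)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["shape"] = list(self.shape)
        payload["collar"] = list(self.collar)
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        payload["shape"] = tuple(payload["shape"])
        payload["collar"] = tuple(payload["collar"])
        payload["roots"] = [RootTruth(**r) for r in payload["roots"]]
        payload["gaps"] = [GapTruth(**g) for g in payload["gaps"]]
        return cls(**payload)


def _raster_curve(collar, theta_deg, q, depth_limit, target_len, shape):
    """Rasterize col(r) into an 8-connected pixel path of ~target_len pixels."""
    r0, c0 = collar
    t0 = math.tan(math.radians(theta_deg))
    path = [(r0, c0)]
    prev = (r0, c0)
    for dr in range(1, depth_limit):
        r = r0 + dr
        c = int(round(c0 + t0 * dr + q * dr * dr))
        if not (1 <= r < shape[0] - 1 and 1 <= c < shape[1] - 1):
            break
        # connect consecutive samples so the center line stays 8-connected
        while max(abs(r - prev[0]), abs(c - prev[1])) > 1:
            step_r = prev[0] + np.sign(r - prev[0])
            step_c = prev[1] + np.sign(c - prev[1])
            prev = (int(step_r), int(step_c))
            path.append(prev)
        if (r, c) != prev:
            prev = (r, c)
            path.append(prev)
        if len(path) >= target_len:
            break
    return path


def generate_root_system(n_roots: int = 5,
                         shape: tuple[int, int] = (320, 320),
                         curvature: tuple[float, float] = (-4e-4, 4e-4),
                         width: tuple[int, int] = (2, 4),
                         angle_spread_deg: float = 50.0,
                         length: tuple[int, int] = (130, 200),
                         rng_seed: int = 0,
                         mm_per_px: float = 0.1,
                         ) -> tuple[np.ndarray, SyntheticTruth]:
    """Generate a clean root-system mask plus its ground truth.

    Departure angles are spread evenly over ``±angle_spread_deg`` around
    straight-down with a small jitter, so neighboring roots separate within a
    couple of dozen pixels of the collar.  Root lengths (center-line pixels)
    are drawn from ``length``; widths (pixels) from ``width``.
    """
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    rows, cols = shape
    if rows < 60 or cols < 60:
        raise ValueError(f"image {shape} too small for a root system")
    rng = np.random.default_rng(rng_seed)
    collar = (8, cols // 2)

    if n_roots == 1:
        thetas = np.array([float(rng.uniform(-15, 15))])
    else:
        thetas = np.linspace(-angle_spread_deg, angle_spread_deg, n_roots)
        thetas = thetas + rng.uniform(-2, 2, size=n_roots)

    mask = np.zeros(shape, dtype=np.uint8)
    center_union = np.zeros(shape, dtype=bool)
    roots: list[RootTruth] = []
    for i, theta in enumerate(thetas):
        q = float(rng.uniform(*curvature))
        w = int(rng.integers(width[0], width[1] + 1))
        target = int(rng.integers(length[0], length[1] + 1))
        depth_limit = rows - collar[0] - 2
        path = _raster_curve(collar, float(theta), q, depth_limit, target, shape)
        if len(path) < 30:
            raise ValueError(
                f"root {i} truncated to {len(path)} px: angle {theta:.1f} deg "
                f"with curvature {q:.2e} leaves the {shape} frame; enlarge the "
                "image or narrow the angle spread")
        radius = (w - 1) / 2
        for r, c in path:
            if radius <= 0:
                mask[r, c] = 1
            else:
                rr, cc = _disk((r, c), radius + 0.5, shape=shape)
                mask[rr, cc] = 1
            center_union[r, c] = True
        roots.append(RootTruth(root_id=i, departure_angle_deg=float(theta),
                               curvature=q, width_px=w,
                               arc_length_px=len(path),
                               path=[[int(r), int(c)] for r, c in path]))

    occupied = np.flatnonzero(mask.sum(axis=0) > 0)
    truth = SyntheticTruth(
        shape=shape, collar=collar, roots=roots, rng_seed=int(rng_seed),
        mm_per_px=mm_per_px, total_arc_px=int(center_union.sum()),
        rel_px=int(occupied.max() - occupied.min()) if len(occupied) else 0,
        mean_width_px=float(np.mean([r.width_px for r in roots])),
    )
    return mask, truth


def occlude(mask: np.ndarray, truth: SyntheticTruth, n_gaps: int,
            span: tuple[int, int] = (5, 15), rng_seed: int = 0,
            arc_band: tuple[float, float] = (0.3, 0.8),
            ) -> tuple[np.ndarray, SyntheticTruth]:
    """Punch ``n_gaps`` circular soil patches through the roots.

    Each gap is centred on a root center line at an arc position within
    ``arc_band`` (fractions of that root's length), far enough from every
    other root that exactly one root is severed, far enough from other gaps
    on the same root that the intervening fragment stays usable, and never
    near the collar.  Raises if the requested number of gaps cannot be
    placed after a bounded search.
    """
    from scipy.spatial import cKDTree

    mask = as_mask(mask).copy()
    rng = np.random.default_rng(rng_seed)
    gaps = list(truth.gaps)
    trees = {r.root_id: cKDTree(np.asarray(r.path, dtype=float))
             for r in truth.roots}
    max_w = max(r.width_px for r in truth.roots)

    placed = 0
    for _ in range(400 * max(1, n_gaps)):
        if placed >= n_gaps:
            break
        root = truth.roots[int(rng.integers(len(truth.roots)))]
        s = int(rng.integers(span[0], span[1] + 1))
        n = root.arc_length_px
        lo, hi = int(arc_band[0] * n), int(arc_band[1] * n)
        if hi - lo < 2:
            continue
        idx = int(rng.integers(lo, hi))
        center = root.path[idx]
        # keep clear of gaps already on this root
        if any(g.root_id == root.root_id and
               abs((g.arc_start + g.span_px / 2) - idx) < g.span_px / 2 + s / 2 + 25
               for g in gaps):
            continue
        # sever exactly one root: no other center line inside the patch
        clearance = s / 2 + max_w + 2
        if any(rid != root.root_id and
               trees[rid].query(np.asarray(center, dtype=float))[0] < clearance
               for rid in trees):
            continue
        rr, cc = _disk(tuple(center), s / 2 + 0.5, shape=truth.shape)
        mask[rr, cc] = 0
        gaps.append(GapTruth(root_id=root.root_id,
                             arc_start=max(0, idx - s // 2), span_px=s))
        placed += 1
    if placed < n_gaps:
        raise ValueError(f"could only place {placed} of {n_gaps} gaps; "
                         "loosen span or arc_band, or use fewer gaps")

    new_truth = SyntheticTruth(**{**asdict(truth),
                                  "roots": truth.roots, "gaps": gaps,
                                  "shape": truth.shape, "collar": truth.collar})
    return mask, new_truth


def add_noise(image: np.ndarray, density: float = 0.001,
              blob_radius: tuple[int, int] = (0, 0),
              rng_seed: int = 0) -> np.ndarray:
    """Sprinkle soil/reflection speckle over an image.

    On a binary mask, background pixels turn foreground independently with
    probability ``density`` (optionally grown into small blobs); on a
    grayscale image, bright specks are added on top of mild gaussian
    texture.  Deterministic per seed.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    image = np.asarray(image)
    binary = image.ndim == 2 and image.max(initial=0) <= 1
    out = image.astype(float).copy() if not binary else as_mask(image).copy()
    if density == 0:
        return out
    if binary:
        bg = out == 0
        seeds = bg & (rng.random(out.shape) < density)
        if blob_radius[1] > 0:
            for r, c in np.argwhere(seeds):
                rad = int(rng.integers(blob_radius[0], blob_radius[1] + 1))
                rr, cc = _disk((int(r), int(c)), rad + 0.5, shape=out.shape)
                out[rr, cc] = 1
        else:
            out[seeds] = 1
        return out
    out += rng.normal(0, 4.0, size=out.shape)
    specks = rng.random(out.shape) < density
    out[specks] = 255.0
    return np.clip(out, 0, 255)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Repair quality against ground truth."""

    n_gaps: int
    n_joins: int
    rejoined: int
    wrong_joins: int
    rejoin_rate: float
    wrong_join_rate: float
    trait_errors_pct: dict[str, float]


def _locate(point, trees, tol):
    """Map a pixel to (root_id, arc index) via the nearest center line."""
    best = (None, None, math.inf)
    p = np.asarray(point, dtype=float)
    for rid, tree in trees.items():
        d, idx = tree.query(p)
        if d < best[2]:
            best = (rid, int(idx), float(d))
    if best[2] <= tol:
        return best[0], best[1]
    return None, None


def score_recovery(repaired: np.ndarray, joins, truth: SyntheticTruth,
                   measured_traits: dict[str, float] | None = None
                   ) -> RecoveryMetrics:
    """Score a repair run against the gap registry.

    A join is *correct* when both of its anchor tips map (by nearest center
    line, within half a root width plus a small skeletonization tolerance)
    to the same root and at least one registered gap of that root lies
    between the two arc positions; every such gap counts as rejoined.  Any
    other join is a wrong join.  With no gaps the rejoin rate is 1.0 by
    convention.  ``measured_traits`` (keys RTN/RTL_mm/REL_mm) adds percent
    errors against the truth values.
    """
    from scipy.spatial import cKDTree

    repaired = as_mask(repaired)
    if repaired.shape != tuple(truth.shape):
        raise ValueError(f"repaired shape {repaired.shape} != truth {truth.shape}")
    trees = {r.root_id: cKDTree(np.asarray(r.path, dtype=float))
             for r in truth.roots}
    widths = {r.root_id: r.width_px for r in truth.roots}

    rejoined_gaps: set[int] = set()
    wrong = 0
    for j in joins:
        tol = max(widths.values()) / 2 + 4
        ra, ia = _locate(j.end_pair[0], trees, tol)
        rb, ib = _locate(j.end_pair[1], trees, tol)
        if ra is None or rb is None or ra != rb:
            wrong += 1
            continue
        lo, hi = min(ia, ib), max(ia, ib)
        hit = [gi for gi, g in enumerate(truth.gaps)
               if g.root_id == ra and lo <= g.arc_start + g.span_px / 2 <= hi]
        if hit:
            rejoined_gaps.update(hit)
        else:
            wrong += 1

    n_gaps = len(truth.gaps)
    n_joins = len(list(joins))
    errors: dict[str, float] = {}
    if measured_traits:
        cal = truth.mm_per_px
        truth_vals = {"RTN": float(truth.n_roots),
                      "RTL_mm": truth.total_arc_px * cal,
                      "REL_mm": truth.rel_px * cal}
        for key, tv in truth_vals.items():
            if key in measured_traits and tv > 0:
                errors[key] = round(
                    100.0 * abs(measured_traits[key] - tv) / tv, 2)
    return RecoveryMetrics(
        n_gaps=n_gaps, n_joins=n_joins, rejoined=len(rejoined_gaps),
        wrong_joins=wrong,
        rejoin_rate=1.0 if n_gaps == 0 else len(rejoined_gaps) / n_gaps,
        wrong_join_rate=0.0 if n_joins == 0 else wrong / n_joins,
        trait_errors_pct=errors)
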