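"""Segment characterization, rule-based matching, and polynomial gap bridging.

A broken root appears as several skeleton arcs.  Whether two arcs are pieces
of the same root is decided by three continuity rules, each a thresholded
comparison of least-squares fits:

1. *internal continuity* — each arc is summarized by a least-squares line and
   by end derivatives estimated over a short window at each tip;
2. *segmental continuity* — a candidate pair must agree in overall line
   orientation (gate ``d1``/``d2``), in the derivative at the facing tips
   (gate ``d3``), and a single polynomial refit through the union of both
   arcs' pixels must have a small per-pixel squared loss (gate ``d4``);
3. *proximity* — among surviving candidates, tips pair with their nearest
   partner, each tip joining at most once (a segment may still be continued
   at both of its ends).

Matched tips are bridged with a quintic Hermite curve that matches position
and first derivative at both tips and has zero second derivative there, so
the bridge leaves each stump tangentially and straightens mid-gap.  Arcs not
longer than ``tiny_px`` pixels are discarded before matching; they are either
noise specks or fragments that a successful bridge will cover anyway.

The default thresholds are ``d1=4, d2=10, d3=50, d4=0.2`` with
``tiny_px=10``.  As printed, the slope rule ("difference < d1 and at the same
time > d2") is unsatisfiable for d1 < d2; this module reads the pair as
transposed and gates the angular slope difference at ``max(d1, d2)`` degrees.
The literal conjunction remains available via ``strict_slope_gate`` for
comparison (it matches nothing, by construction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import line as _line

from .corrosion import JUNCTION_LABEL, Segment
from .preprocess import as_mask

__all__ = [
    "PolyFit",
    "SegmentFeatures",
    "MatchConfig",
    "MatchedPair",
    "JoinCurve",
    "fit_polynomial",
    "loss",
    "segment_features",
    "match_segments",
    "join_pair",
    "prune_tiny",
    "repair_image",
]

_SLOPE_CLAMP = 1e6  # stand-in slope for a perfectly vertical end window


@dataclass(frozen=True)
class PolyFit:
    """Least-squares polynomial y = a0 + a1 x + ... + ak x^k.

    ``axis`` names the abscissa: ``"col"`` fits row as a function of column,
    ``"row"`` the transpose.  ``loss`` is the sum of squared residuals of the
    fitted points.
    """

    degree: int
    coeffs: tuple[float, ...]
    loss: float
    axis: str

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(x, self.coeffs)


@dataclass(frozen=True)
class SegmentFeatures:
    """Matching features of one arc: overall line angle and tip derivatives.

    ``line_angle`` is the orientation of the degree-1 fit in degrees within
    (-90, 90] (0 = horizontal).  ``end_derivs`` holds the d(row)/d(col)
    slope estimated over the ``deriv_window`` pixels nearest each end,
    ordered like ``Segment.ends``; a vertical window is clamped to a large
    positive constant so two vertical tips compare as equal.
    """

    line_angle: float
    end_derivs: tuple[float, float]


@dataclass
class MatchConfig:
    """Thresholds and knobs of the matching and joining stage.

    d1, d2 : slope-difference bounds (degrees); the effective gate is
        ``max(d1, d2)`` unless ``strict_slope_gate`` is set.
    d3 : bound on the tip-tangent mismatch at facing tips, compared as
        folded inclination angles (degrees), so near-vertical tips are
        handled symmetrically.
    d4 : bound on the per-pixel squared loss of the joint refit.
    tiny_px : arcs of at most this many pixels are pruned before matching.
    fit_degree : degree of the joint refit polynomial.
    deriv_window : pixels per tip used for derivative estimation.
    join_degree : degree of the bridge curve (1, 3 or 5).
    """

    d1: float = 4.0
    d2: float = 10.0
    d3: float = 50.0
    d4: float = 0.2
    tiny_px: int = 10
    fit_degree: int = 3
    deriv_window: int = 5
    join_degree: int = 5
    strict_slope_gate: bool = False

    def __post_init__(self):
        for name in ("d1", "d2", "d3", "d4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tiny_px < 1:
            raise ValueError("tiny_px must be >= 1")
        if self.join_degree not in (1, 3, 5):
            raise ValueError("join_degree must be 1, 3 or 5")

    @property
    def slope_gate_deg(self) -> float:
        return max(self.d1, self.d2)


@dataclass(frozen=True)
class MatchedPair:
    """A matched tip pair: segment ids, end indices and tip coordinates."""

    seg_a: int
    end_a: int
    seg_b: int
    end_b: int
    point_a: tuple[int, int]
    point_b: tuple[int, int]
    distance: float


@dataclass(frozen=True)
class JoinCurve:
    """A rasterized bridge between two matched tips."""

    seg_ids: tuple[int, int]
    end_pair: tuple[tuple[int, int], tuple[int, int]]
    path: tuple[tuple[int, int], ...]


def _xy(points: np.ndarray, axis: str) -> tuple[np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=float)
    if axis == "col":
        return points[:, 1], points[:, 0]
    return points[:, 0], points[:, 1]


def _auto_axis(points: np.ndarray) -> str:
    points = np.asarray(points, dtype=float)
    return "row" if np.ptp(points[:, 0]) >= np.ptp(points[:, 1]) else "col"


def fit_polynomial(points, k: int, axis: str | None = None) -> PolyFit:
    """Least-squares degree-k polynomial through ``points`` ((row, col) pairs).

    When ``axis`` is omitted, the coordinate with the greater extent along
    the point set serves as abscissa, which keeps near-vertical arcs
    single-valued.  A rank-deficient design (too few distinct abscissas) is
    resolved by swapping the axis and, failing that, by reducing the degree;
    either fallback is reported as a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a nonempty (n, 2) array")
    if axis is None:
        axis = _auto_axis(points)
    x, y = _xy(points, axis)
    if len(np.unique(x)) <= k:
        other = "row" if axis == "col" else "col"
        xo, yo = _xy(points, other)
        if len(np.unique(xo)) > k:
            warnings.warn(f"abscissa {axis!r} rank-deficient; swapped to {other!r}")
            axis, x, y = other, xo, yo
        else:
            k_new = max(0, len(np.unique(x)) - 1)
            warnings.warn(f"rank-deficient design; degree reduced {k} -> {k_new}")
            k = k_new
    # Solve the normal equations through a QR-based least-squares
    # factorization (same minimizer, better conditioned).
    design = np.vander(x, k + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    return PolyFit(degree=k, coeffs=tuple(float(a) for a in coeffs),
                   loss=float(resid @ resid), axis=axis)


def loss(points, fit: PolyFit) -> float:
    """Sum of squared residuals of ``points`` under ``fit``."""
    x, y = _xy(np.asarray(points, dtype=float), fit.axis)
    r = y - fit(x)
    return float(r @ r)


def _line_angle(points: np.ndarray) -> float:
    """Orientation of the degree-1 fit through ``points``, degrees in (-90, 90]."""
    fit = fit_polynomial(points, 1)
    m = fit.coeffs[1] if fit.degree >= 1 else 0.0
    if fit.axis == "col":
        v = (m, 1.0)           # (d_row, d_col) per unit col
    else:
        v = (1.0, m)           # per unit row
    ang = math.degrees(math.atan2(v[0], v[1]))
    if ang > 90:
        ang -= 180
    elif ang <= -90:
        ang += 180
    return ang


def _end_slope(window_points: np.ndarray) -> float:
    """d(row)/d(col) of the degree-1 fit over a tip window, clamped if vertical."""
    pts = np.asarray(window_points, dtype=float)
    if np.ptp(pts[:, 1]) == 0:
        return _SLOPE_CLAMP
    fit = fit_polynomial(pts, 1, axis="col")
    if fit.degree < 1:
        return 0.0
    return float(np.clip(fit.coeffs[1], -_SLOPE_CLAMP, _SLOPE_CLAMP))


def segment_features(seg: Segment, cfg: MatchConfig) -> SegmentFeatures:
    """Compute the line angle and tip derivatives of one arc.

    Arcs of a single pixel carry no direction and are excluded from matching
    upstream; requesting their features raises ``ValueError``.
    """
    if seg.length_px < 2:
        raise ValueError("features undefined for single-pixel segments")
    pts = np.asarray(seg.path, dtype=float)
    w = min(cfg.deriv_window, seg.length_px)
    return SegmentFeatures(
        line_angle=_line_angle(pts),
        end_derivs=(_end_slope(pts[:w][::-1]), _end_slope(pts[-w:])),
    )


def _angdiff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def match_segments(segs: list[Segment], feats: dict[int, SegmentFeatures],
                   cfg: MatchConfig,
                   endpoint_set: set[tuple[int, int]] | None = None
                   ) -> list[MatchedPair]:
    """Pair up arc tips that pass the continuity gates.

    ``endpoint_set`` restricts candidate tips to true skeleton endpoints
    (tips abutting a junction are anchored there and must not be re-joined);
    when omitted, every arc end is a candidate.  The returned pairing is
    symmetric and greedy-nearest: all gate-passing pairs are sorted by tip
    distance and accepted while both tips are unused.
    """
    by_id = {s.id: s for s in segs}
    candidates = []
    ids = sorted(by_id)
    for i, ia in enumerate(ids):
        for ib in ids[i + 1:]:
            sa, sb = by_id[ia], by_id[ib]
            fa, fb = feats.get(ia), feats.get(ib)
            if fa is None or fb is None:
                continue
            dslope = _angdiff(fa.line_angle, fb.line_angle)
            if cfg.strict_slope_gate:
                if not (dslope < cfg.d1 and dslope > cfg.d2):
                    continue
            elif dslope > cfg.slope_gate_deg:
                continue
            joint = None
            pair_combos = []
            for ea in (0, 1):
                pa = sa.ends[ea]
                if endpoint_set is not None and pa not in endpoint_set:
                    continue
                for eb in (0, 1):
                    pb = sb.ends[eb]
                    if endpoint_set is not None and pb not in endpoint_set:
                        continue
                    # compare tip derivatives as folded inclination angles:
                    # raw dy/dx differences blow up on near-vertical roots
                    da = math.degrees(math.atan(fa.end_derivs[ea]))
                    db = math.degrees(math.atan(fb.end_derivs[eb]))
                    if _angdiff(da, db) > cfg.d3:
                        continue
                    if joint is None:  # joint refit is per pair, not per tip
                        pts = np.vstack([np.asarray(sa.path, dtype=float),
                                         np.asarray(sb.path, dtype=float)])
                        fit = fit_polynomial(pts, cfg.fit_degree)
                        joint = fit.loss / len(pts)
                    if joint > cfg.d4:
                        continue
                    dist = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
                    pair_combos.append((dist, ia, ea, ib, eb, pa, pb))
            if pair_combos:
                # proximity rule: a segment pair connects only at its
                # nearest end combination
                candidates.append(min(pair_combos))
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4]))
    used: set[tuple[int, int]] = set()
    matches: list[MatchedPair] = []
    for dist, ia, ea, ib, eb, pa, pb in candidates:
        if (ia, ea) in used or (ib, eb) in used:
            continue
        used.add((ia, ea))
        used.add((ib, eb))
        matches.append(MatchedPair(ia, ea, ib, eb, pa, pb, dist))
    return matches


def _chord(p0, p1) -> tuple[tuple[int, int], ...]:
    rr, cc = _line(p0[0], p0[1], p1[0], p1[1])
    return tuple(zip(rr.tolist(), cc.tolist()))


def _hermite_coeffs(h: float, y0: float, y1: float, m0: float, m1: float,
                    degree: int) -> np.ndarray:
    """Coefficients of the bridge polynomial g(u) on u in [0, 1].

    Boundary conditions: g(0)=y0, g(1)=y1, g'(0)=m0*h, g'(1)=m1*h and, for
    the quintic, g''(0)=g''(1)=0.
    """
    if degree == 1:
        return np.array([y0, y1 - y0])
    rows = [[1, 0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 1, 0, 0, 0, 0],
            [0, 1, 2, 3, 4, 5],
            [0, 0, 2, 0, 0, 0],
            [0, 0, 2, 6, 12, 20]]
    rhs = [y0, y1, m0 * h, m1 * h, 0.0, 0.0]
    if degree == 3:
        rows = [r[:4] for r in rows[:4]]
        rhs = rhs[:4]
    return np.linalg.solve(np.array(rows, dtype=float), np.array(rhs))


def join_pair(seg_a: Segment, end_a, seg_b: Segment, end_b,
              cfg: MatchConfig | None = None) -> JoinCurve:
    """Bridge two matched tips with an odd-degree Hermite curve.

    ``end_a``/``end_b`` may be end indices (0 or 1) or the tip coordinates
    themselves.  The bridge matches position and first derivative at both
    tips (second derivative zero for the default quintic) and is rasterized
    into an 8-connected pixel path running exactly from tip to tip.  When
    both tip derivatives equal the chord slope the curve degenerates to the
    straight chord.
    """
    cfg = cfg or MatchConfig()
    pa = seg_a.ends[end_a] if end_a in (0, 1) else tuple(end_a)
    pb = seg_b.ends[end_b] if end_b in (0, 1) else tuple(end_b)
    ids = (seg_a.id, seg_b.id)
    if pa == pb:
        return JoinCurve(ids, (pa, pb), (pa,))
    if max(abs(pa[0] - pb[0]), abs(pa[1] - pb[1])) == 1:
        return JoinCurve(ids, (pa, pb), (pa, pb))

    axis = "row" if abs(pa[0] - pb[0]) >= abs(pa[1] - pb[1]) else "col"

    def tip_slope(seg: Segment, tip) -> float | None:
        path = np.asarray(seg.path, dtype=float)
        w = min(cfg.deriv_window, len(path))
        window = path[:w] if tuple(seg.path[0]) == tuple(tip) else path[-w:]
        x, y = _xy(window, axis)
        if np.ptp(x) == 0:
            return None
        f = fit_polynomial(window, 1, axis=axis)
        return float(f.coeffs[1]) if f.degree >= 1 else 0.0

    ma, mb = tip_slope(seg_a, pa), tip_slope(seg_b, pb)
    if axis == "row":
        x0, y0, x1, y1 = pa[0], pa[1], pb[0], pb[1]
    else:
        x0, y0, x1, y1 = pa[1], pa[0], pb[1], pb[0]
    chord_m = (y1 - y0) / (x1 - x0)
    # A tip window vertical in the bridge axis, or wildly steep, would make
    # the Hermite overshoot; fall back to the chord slope there.
    ma = chord_m if ma is None or abs(ma) > 5 else ma
    mb = chord_m if mb is None or abs(mb) > 5 else mb

    h = x1 - x0
    g = _hermite_coeffs(h, y0, y1, ma, mb, cfg.join_degree)
    n_samples = max(2, 4 * int(abs(h)) + 1)
    u = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + u * h
    ys = np.polynomial.polynomial.polyval(u, g)
    if axis == "row":
        pts = np.stack([xs, ys], axis=1)
    else:
        pts = np.stack([ys, xs], axis=1)
    pix = np.floor(pts + 0.5).astype(int)
    path: list[tuple[int, int]] = [pa]
    for r, c in pix.tolist():
        p = (int(r), int(c))
        if p == path[-1]:
            continue
        if max(abs(p[0] - path[-1][0]), abs(p[1] - path[-1][1])) > 1:
            path.extend(_chord(path[-1], p)[1:])
        else:
            path.append(p)
    if path[-1] != pb:
        if max(abs(pb[0] - path[-1][0]), abs(pb[1] - path[-1][1])) > 1:
            path.extend(_chord(path[-1], pb)[1:])
        else:
            path.append(pb)
    # drop accidental duplicates while preserving order
    seen: set[tuple[int, int]] = set()
    clean: list[tuple[int, int]] = []
    for p in path:
        if p not in seen:
            seen.add(p)
            clean.append(p)
    return JoinCurve(ids, (pa, pb), tuple(clean))


def prune_tiny(segs: list[Segment], cfg: MatchConfig | None = None) -> list[Segment]:
    """Drop arcs of at most ``tiny_px`` pixels (noise or coverable fragments)."""
    cfg = cfg or MatchConfig()
    return [s for s in segs if s.length_px > cfg.tiny_px]


_PALETTE = [
    (230, 60, 60), (60, 120, 230), (230, 180, 40), (170, 80, 220),
    (40, 200, 200), (240, 120, 30), (120, 220, 80), (220, 90, 160),
    (100, 100, 240), (180, 140, 60),
]


def repair_image(mask: np.ndarray, skel: np.ndarray, joins: list[JoinCurve],
                 labels: np.ndarray | None = None,
                 skeleton_only: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Paint the join curves into the mask and render a color overlay.

    The repaired mask is the union of the input mask with every bridge,
    dilated to the mean local root width at the two bridged tips (pass
    ``skeleton_only=True`` for 1-pixel bridges).  The overlay shows original
    foreground in gray, bridges in green, and — when an arc ``labels`` map is
    supplied — arcs chained into one root by the joins in a shared color.
    """
    from .phenotype import perpendicular_width  # local import; no cycle at module load

    mask = as_mask(mask)
    rows, cols = mask.shape
    repaired = mask.copy()
    overlay = np.zeros((rows, cols, 3), dtype=np.uint8)
    overlay[mask > 0] = (180, 180, 180)

    if labels is not None:
        parent: dict[int, int] = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for j in joins:
            ra, rb = find(j.seg_ids[0]), find(j.seg_ids[1])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        color_of: dict[int, tuple[int, int, int]] = {}
        lab = np.asarray(labels)
        for k in range(1, int(lab.max(initial=0)) + 1):
            root = find(k)
            if root not in color_of:
                color_of[root] = _PALETTE[len(color_of) % len(_PALETTE)]
            overlay[lab == k] = color_of[root]

    for j in joins:
        if skeleton_only:
            radius = 0
        else:
            widths = []
            for tip in j.end_pair:
                tangent = _bridge_tangent(j, tip)
                widths.append(perpendicular_width(mask, tip, tangent))
            radius = max(0, int(round((np.mean(widths) - 1) / 2)))
        for r, c in j.path:
            if radius == 0:
                if 0 <= r < rows and 0 <= c < cols:
                    repaired[r, c] = 1
                    overlay[r, c] = (0, 200, 0)
            else:
                rr, cc = _disk((r, c), radius + 0.5, shape=(rows, cols))
                repaired[rr, cc] = 1
                overlay[rr, cc] = (0, 200, 0)
    return repaired, overlay


def _bridge_tangent(j: JoinCurve, tip: tuple[int, int]) -> tuple[float, float]:
    if len(j.path) < 2:
        return (1.0, 0.0)
    other = j.path[1] if j.path[0] == tip else j.path[-2]
    v = (other[0] - tip[0], other[1] - tip[1])
    norm = math.hypot(*v) or 1.0
    return (v[0] / norm, v[1] / norm)
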