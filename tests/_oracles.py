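"""Independent reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (per-pixel
loops, exhaustive search, symbolic algebra, graph decomposition) and shares
no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np

# P2..P9 offsets, north then clockwise — restated independently.
OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def ring_of(img: np.ndarray, r: int, c: int) -> list[int]:
    h, w = img.shape
    out = []
    for dr, dc in OFFSETS:
        rr, cc = r + dr, c + dc
        out.append(int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0)
    return out


def reference_zhang_suen(mask: np.ndarray) -> np.ndarray:
    """Per-pixel two-subiteration thinning, straight from the rule text."""
    img = (np.asarray(mask) > 0).astype(int)
    h, w = img.shape
    changed = True
    while changed:
        changed = False
        for sub in (0, 1):
            marks = []
            for r in range(h):
                for c in range(w):
                    if not img[r, c]:
                        continue
                    p2, p3, p4, p5, p6, p7, p8, p9 = ring_of(img, r, c)
                    n = p2 + p3 + p4 + p5 + p6 + p7 + p8 + p9
                    ring = [p2, p3, p4, p5, p6, p7, p8, p9, p2]
                    s = sum(1 for a, b in zip(ring, ring[1:]) if (a, b) == (0, 1))
                    if not (2 <= n <= 6 and s == 1):
                        continue
                    if sub == 0:
                        ok = p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0
                    else:
                        ok = p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0
                    if ok:
                        marks.append((r, c))
            for rc in marks:
                img[rc] = 0
            if marks:
                changed = True
    return img.astype(np.uint8)


def neighbor_group_count(window: np.ndarray) -> tuple[int, int]:
    """(number of 8-connected neighbor groups, total foreground neighbors)
    for a 3x3 window, counted by flood fill over the 8 neighbor cells."""
    cells = {(dr, dc) for dr, dc in OFFSETS if window[1 + dr, 1 + dc]}
    groups = 0
    remaining = set(cells)
    while remaining:
        groups += 1
        stack = [remaining.pop()]
        while stack:
            a = stack.pop()
            touch = [b for b in remaining
                     if max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1]
            for b in touch:
                remaining.discard(b)
                stack.append(b)
    return groups, len(cells)


def arc_count(skel: np.ndarray) -> tuple[int, int]:
    """(number of arcs, number of junction pixels) by graph decomposition:
    build the pixel adjacency graph and delete nodes of degree >= 3."""
    import networkx as nx

    coords = [tuple(map(int, rc)) for rc in np.argwhere(np.asarray(skel) > 0)]
    g = nx.Graph()
    g.add_nodes_from(coords)
    cs = set(coords)
    for r, c in coords:
        for dr, dc in OFFSETS:
            q = (r + dr, c + dc)
            if q in cs:
                g.add_edge((r, c), q)
    junctions = [n for n in g if g.degree(n) >= 3]
    g.remove_nodes_from(junctions)
    return nx.number_connected_components(g), len(junctions)


def component_size_filter(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Brute-force 8-connected component labeling + size filter."""
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = [(r, c)]
                seen[r, c] = True
                i = 0
                while i < len(comp):
                    cr, cc = comp[i]
                    i += 1
                    for dr, dc in OFFSETS:
                        nr, nc = cr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                                and not seen[nr, nc]):
                            seen[nr, nc] = True
                            comp.append((nr, nc))
                if len(comp) >= min_px:
                    for rc in comp:
                        out[rc] = 1
    return out


def otsu_exhaustive(gray: np.ndarray) -> float:
    """Exhaustive threshold maximizing between-class variance."""
    vals = np.unique(np.asarray(gray, dtype=float))
    best_t, best_v = vals[0], -1.0
    for t in vals[:-1]:
        lo = gray[gray <= t]
        hi = gray[gray > t]
        w0, w1 = lo.size, hi.size
        if w0 == 0 or w1 == 0:
            continue
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)


def hermite_quintic_symbolic(x0, y0, x1, y1, m0, m1):
    """Symbolic quintic through the clamped boundary conditions; returns a
    callable evaluating it at arbitrary abscissas."""
    import sympy as sp

    x = sp.symbols("x")
    a = sp.symbols("a0:6")
    f = sum(a[i] * x ** i for i in range(6))
    eqs = [
        sp.Eq(f.subs(x, x0), y0),
        sp.Eq(f.subs(x, x1), y1),
        sp.Eq(sp.diff(f, x).subs(x, x0), m0),
        sp.Eq(sp.diff(f, x).subs(x, x1), m1),
        sp.Eq(sp.diff(f, x, 2).subs(x, x0), 0),
        sp.Eq(sp.diff(f, x, 2).subs(x, x1), 0),
    ]
    sol = sp.solve(eqs, a, dict=True)[0]
    fx = sp.lambdify(x, f.subs(sol), "numpy")
    return fx
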