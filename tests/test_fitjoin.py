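import math

import numpy as np
import pytest

from rootpcj import fitjoin
from rootpcj.corrosion import Segment
from rootpcj.fitjoin import MatchConfig
from _oracles import hermite_quintic_symbolic


def _seg(pts, sid=1):
    return Segment(id=sid, path=tuple(map(tuple, pts)))


def _hline(r, c0, c1, sid=1):
    step = 1 if c1 >= c0 else -1
    return _seg([(r, c) for c in range(c0, c1 + step, step)], sid)


class TestFitPolynomial:
    def test_exact_line(self):
        pts = [(2 * c + 1, c) for c in range(5)]  # row = 2*col + 1
        fit = fitjoin.fit_polynomial(pts, 1, axis="col")
        assert np.allclose(fit.coeffs, (1.0, 2.0))
        assert fit.loss == pytest.approx(0.0, abs=1e-18)

    def test_parabola_matches_normal_equation_oracle(self):
        pts = [(0, 0), (1, 1), (4, 2), (9, 3)]
        fit = fitjoin.fit_polynomial(pts, 2, axis="col")
        # normal-equations oracle: A = (X^T X)^-1 X^T Y
        x = np.array([0.0, 1, 2, 3])
        X = np.vander(x, 3, increasing=True)
        y = np.array([0.0, 1, 4, 9])
        a = np.linalg.inv(X.T @ X) @ X.T @ y
        assert np.allclose(fit.coeffs, a)
        assert np.allclose(fit.coeffs, (0, 0, 1), atol=1e-9)

    def test_degree_zero_is_mean(self, rng):
        pts = np.column_stack([rng.normal(5, 2, 10), np.arange(10)])
        fit = fitjoin.fit_polynomial(pts, 0, axis="col")
        assert fit.coeffs[0] == pytest.approx(pts[:, 0].mean())

    def test_vertical_points_swap_axis(self):
        pts = [(r, 3) for r in range(6)]
        with pytest.warns(UserWarning):
            fit = fitjoin.fit_polynomial(pts, 1, axis="col")
        assert fit.axis == "row"
        assert fit.loss == pytest.approx(0.0, abs=1e-18)

    def test_local_optimality_probe(self, rng):
        # perturbing any coefficient by +-1e-3 never lowers the loss
        for _ in range(50):
            pts = np.column_stack([rng.normal(0, 3, 8), np.arange(8.0)])
            fit = fitjoin.fit_polynomial(pts, 2, axis="col")
            base = fitjoin.loss(pts, fit)
            for i in range(3):
                for d in (-1e-3, 1e-3):
                    c = list(fit.coeffs)
                    c[i] += d
                    probe = fitjoin.PolyFit(2, tuple(c), 0.0, "col")
                    assert fitjoin.loss(pts, probe) >= base - 1e-12


class TestLoss:
    def test_perfect_interpolation(self):
        pts = [(c, c) for c in range(4)]
        fit = fitjoin.fit_polynomial(pts, 1)
        assert fitjoin.loss(pts, fit) == pytest.approx(0.0, abs=1e-18)

    def test_single_residual_squared(self):
        fit = fitjoin.PolyFit(0, (0.0,), 0.0, "col")
        assert fitjoin.loss([(3.0, 7.0)], fit) == pytest.approx(9.0)

    def test_matches_term_by_term_sum(self, rng):
        pts = np.column_stack([rng.normal(0, 2, 10), np.arange(10.0)])
        fit = fitjoin.fit_polynomial(pts, 1, axis="col")
        direct = sum((y - sum(a * x ** i for i, a in enumerate(fit.coeffs))) ** 2
                     for y, x in pts)
        assert fitjoin.loss(pts, fit) == pytest.approx(direct)


class TestSegmentFeatures:
    def test_horizontal(self):
        f = fitjoin.segment_features(_hline(4, 0, 9), MatchConfig())
        assert f.line_angle == pytest.approx(0.0, abs=1e-9)
        assert f.end_derivs == pytest.approx((0.0, 0.0))

    def test_diagonal_45(self):
        seg = _seg([(i, i) for i in range(8)])
        f = fitjoin.segment_features(seg, MatchConfig())
        assert f.line_angle == pytest.approx(45.0)

    def test_parabola_end_derivative(self):
        # rasterized row = col^2 / 8: analytic slope at col=16 is 4
        seg = _seg([(round(c * c / 8), c) for c in range(17)])
        f = fitjoin.segment_features(seg, MatchConfig(deriv_window=5))
        assert f.end_derivs[1] == pytest.approx(3.75, abs=0.75)

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            fitjoin.segment_features(_seg([(0, 0)]), MatchConfig())


class TestMatchSegments:
    def test_collinear_pair_matches(self):
        a, b = _hline(5, 0, 9, 1), _hline(5, 18, 27, 2)
        cfg = MatchConfig()
        feats = {s.id: fitjoin.segment_features(s, cfg) for s in (a, b)}
        (m,) = fitjoin.match_segments([a, b], feats, cfg)
        assert {m.point_a, m.point_b} == {(5, 9), (5, 18)}

    def test_perpendicular_pair_rejected(self):
        a = _hline(5, 0, 9, 1)
        b = _seg([(r, 14) for r in range(6, 16)], 2)
        cfg = MatchConfig()
        feats = {s.id: fitjoin.segment_features(s, cfg) for s in (a, b)}
        assert fitjoin.match_segments([a, b], feats, cfg) == []

    def test_empty_input(self):
        assert fitjoin.match_segments([], {}, MatchConfig()) == []

    def test_strict_literal_gate_matches_nothing(self):
        a, b = _hline(5, 0, 9, 1), _hline(5, 18, 27, 2)
        cfg = MatchConfig(strict_slope_gate=True)
        feats = {s.id: fitjoin.segment_features(s, cfg) for s in (a, b)}
        assert fitjoin.match_segments([a, b], feats, cfg) == []

    def test_symmetry_and_one_join_per_endpoint(self):
        a, b = _hline(5, 0, 9, 1), _hline(5, 18, 27, 2)
        c = _hline(5, 36, 45, 3)
        cfg = MatchConfig()
        feats = {s.id: fitjoin.segment_features(s, cfg) for s in (a, b, c)}
        matches = fitjoin.match_segments([a, b, c], feats, cfg)
        rev = fitjoin.match_segments([c, b, a], feats, cfg)
        assert {frozenset((m.seg_a, m.seg_b)) for m in matches} \
            == {frozenset((m.seg_a, m.seg_b)) for m in rev}
        ends = [(m.seg_a, m.end_a) for m in matches] \
            + [(m.seg_b, m.end_b) for m in matches]
        assert len(ends) == len(set(ends))
        # middle segment is continued at both of its ends
        b_ends = {e for s, e in ends if s == 2}
        assert b_ends == {0, 1}


class TestJoinPair:
    def test_collinear_degenerates_to_chord(self):
        a, b = _hline(5, 0, 9, 1), _hline(5, 18, 27, 2)
        j = fitjoin.join_pair(a, 1, b, 0)
        assert j.path[0] == (5, 9) and j.path[-1] == (5, 18)
        assert all(r == 5 for r, _ in j.path)

    def test_adjacent_endpoints(self):
        a, b = _hline(5, 0, 9, 1), _hline(5, 10, 19, 2)
        j = fitjoin.join_pair(a, 1, b, 0)
        assert j.path == ((5, 9), (5, 10))

    def test_coincident_endpoints(self):
        a = _hline(5, 0, 9, 1)
        b = _seg([(5, 9), (6, 10)], 2)
        j = fitjoin.join_pair(a, 1, b, 0)
        assert j.path == ((5, 9),)

    def test_path_is_8_connected(self):
        a = _seg([(r, 10 + r) for r in range(10)], 1)
        b = _seg([(r, 40 - r) for r in range(25, 35)], 2)
        j = fitjoin.join_pair(a, 1, b, 0)
        for p, q in zip(j.path, j.path[1:]):
            assert max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1

    def test_s_bend_matches_symbolic_quintic(self):
        # offset parallel horizontal segments: quintic S-bend
        a, b = _hline(10, 0, 19, 1), _hline(22, 40, 59, 2)
        j = fitjoin.join_pair(a, 1, b, 0)
        fx = hermite_quintic_symbolic(19, 10, 40, 22, 0.0, 0.0)
        for x in np.linspace(19, 40, 10):
            want = float(fx(x))
            # nearest path pixel at this abscissa must sit on the curve
            rows = [r for r, c in j.path if c == round(x)]
            assert rows, f"no path pixel at col {round(x)}"
            assert min(abs(r - want) for r in rows) <= 1.0
        # monotone from one row band to the other
        rows = [r for r, _ in j.path]
        assert rows == sorted(rows)


class TestPruneAndRepair:
    def test_tiny_boundary(self):
        ten = _hline(0, 0, 9, 1)
        eleven = _hline(2, 0, 10, 2)
        kept = fitjoin.prune_tiny([ten, eleven], MatchConfig())
        assert [s.id for s in kept] == [2]

    def test_empty_list(self):
        assert fitjoin.prune_tiny([], MatchConfig()) == []

    def test_no_joins_identity(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[3, 1:7] = 1
        repaired, overlay = fitjoin.repair_image(mask, mask, [])
        assert np.array_equal(repaired, mask)
        assert (overlay[mask > 0] == (180, 180, 180)).all()

    def test_join_merges_components(self):
        from scipy import ndimage

        mask = np.zeros((9, 30), dtype=np.uint8)
        mask[3:6, 1:11] = 1
        mask[3:6, 19:29] = 1
        a = _hline(4, 1, 10, 1)
        b = _hline(4, 19, 28, 2)
        j = fitjoin.join_pair(a, 1, b, 0)
        repaired, _ = fitjoin.repair_image(mask, mask, [j])
        eight = np.ones((3, 3), int)
        assert ndimage.label(mask, structure=eight)[1] == 2
        assert ndimage.label(repaired, structure=eight)[1] == 1
        # union: repaired foreground contains the original mask
        assert (repaired[mask > 0] == 1).all()
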