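import numpy as np
import pytest

from rootpcj import features, phenotype, thinning
from rootpcj.fitjoin import fit_polynomial
from rootpcj.phenotype import Calibration


CAL = Calibration(0.1)


class TestRootCount:
    def test_single_root_from_collar(self):
        skel = np.zeros((60, 20), dtype=np.uint8)
        skel[2:50, 10] = 1
        fps = features.extract_feature_points(skel)
        assert phenotype.root_count(skel, fps, collar=(2, 10)) == 1

    def test_empty_image(self):
        skel = np.zeros((10, 10), dtype=np.uint8)
        fps = features.extract_feature_points(skel)
        assert phenotype.root_count(skel, fps) == 0

    def test_synthetic_five_roots(self):
        from rootpcj import generate_root_system, repair

        mask, truth = generate_root_system(n_roots=5, rng_seed=3)
        res = repair(mask)
        fps = features.extract_feature_points(res.repaired_skeleton)
        assert phenotype.root_count(res.repaired_skeleton, fps,
                                    collar=truth.collar) == 5


class TestRootLength:
    def test_horizontal_line(self):
        skel = np.zeros((5, 110), dtype=np.uint8)
        skel[2, 5:105] = 1
        assert phenotype.root_length(skel, CAL) == pytest.approx(10.0)

    def test_diagonal_weighting_conventions(self):
        skel = np.zeros((110, 110), dtype=np.uint8)
        for i in range(101):
            skel[i, i] = 1
        # raw pixel count: 101 px -> 10.1 mm
        assert phenotype.root_length(skel, CAL) == pytest.approx(10.1)
        # sqrt(2)-weighted: 100 diagonal steps + first pixel
        want = (1 + 100 * np.sqrt(2)) * 0.1
        assert phenotype.root_length(skel, CAL, diagonal_weighted=True) \
            == pytest.approx(want)

    def test_empty(self):
        assert phenotype.root_length(np.zeros((5, 5)), CAL) == 0.0

    def test_scales_linearly_with_calibration(self):
        skel = np.zeros((5, 50), dtype=np.uint8)
        skel[2, 5:45] = 1
        l1 = phenotype.root_length(skel, Calibration(0.1))
        l2 = phenotype.root_length(skel, Calibration(0.2))
        assert l2 == pytest.approx(2 * l1)


class TestRootWidth:
    def test_vertical_bar_three_wide(self):
        mask = np.zeros((40, 11), dtype=np.uint8)
        mask[2:38, 4:7] = 1
        skel = np.zeros_like(mask)
        skel[4:36, 5] = 1
        w = phenotype.root_width(mask, skel, CAL)
        assert w == pytest.approx(3 * 0.1, rel=0.05)

    def test_unit_line(self):
        mask = np.zeros((5, 30), dtype=np.uint8)
        mask[2, 2:28] = 1
        assert phenotype.root_width(mask, mask, CAL) == pytest.approx(0.1)

    def test_empty(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert phenotype.root_width(z, z, CAL) == 0.0


class TestExtension:
    def test_column_span(self):
        mask = np.zeros((20, 150), dtype=np.uint8)
        mask[5, 10] = mask[9, 110] = 1
        assert phenotype.extension_length(mask, CAL) == pytest.approx(10.0)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        assert phenotype.extension_length(mask, CAL) == 0.0

    def test_matches_column_scan_oracle(self, rng):
        mask = (rng.random((30, 40)) < 0.1).astype(np.uint8)
        cols = [c for r in range(30) for c in range(40) if mask[r, c]]
        want = (max(cols) - min(cols)) * 0.1 if cols else 0.0
        assert phenotype.extension_length(mask, CAL) == pytest.approx(want)

    @pytest.mark.parametrize("m1, m2, want", [
        (1.0, -1.0, 90.0),
        (0.0, 1.0, 45.0),
    ])
    def test_extension_angle_slopes(self, m1, m2, want):
        assert phenotype.extension_angle(m1, m2) == pytest.approx(want)

    def test_extension_angle_matches_vector_oracle(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(0, 2, 2)
            got = phenotype.extension_angle(m1, m2)
            want = abs(np.degrees(np.arctan(m1) - np.arctan(m2)))
            assert got == pytest.approx(want)
            assert 0 <= got < 180

    def test_extension_angle_from_fits(self):
        fa = fit_polynomial([(c, c) for c in range(6)], 1, axis="col")
        fb = fit_polynomial([(0, c) for c in range(6)], 1, axis="col")
        assert phenotype.extension_angle(fa, fb) == pytest.approx(45.0)


class TestRelativeError:
    @pytest.mark.parametrize("measured, actual, want", [
        (82.4, 85.69, 4.0),
        (47.11, 47.11, 0.0),
        (45.6, 47.5, 4.2),
    ])
    def test_published_pairs(self, measured, actual, want):
        assert phenotype.relative_error(measured, actual) == want

    def test_nonpositive_measured_rejected(self):
        with pytest.raises(ValueError):
            phenotype.relative_error(0.0, 5.0)


class TestAgingRegressions:
    def test_intercepts(self):
        assert phenotype.regress_trait(0, "RTN") == pytest.approx(21.888)
        assert phenotype.regress_trait(0, "RTW") == pytest.approx(1.52)

    def test_rtn_day2_direct_arithmetic(self):
        want = 0.72 * 4 - 7.118 * 2 + 21.888
        assert phenotype.regress_trait(2, "RTN") == pytest.approx(want)
        assert phenotype.regress_trait(2, "RTN") == pytest.approx(10.532)

    def test_rtet_alias(self):
        assert phenotype.regress_trait(3, "RTET") \
            == phenotype.regress_trait(3, "REL")

    def test_unknown_trait(self):
        with pytest.raises(ValueError):
            phenotype.regress_trait(1, "XYZ")


class TestInvariances:
    def test_padding_invariance(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5:25, 14:17] = 1
        skel = thinning.thin(mask)
        padded_mask = np.pad(mask, 10)
        padded_skel = np.pad(skel, 10)
        assert phenotype.root_length(skel, CAL) \
            == phenotype.root_length(padded_skel, CAL)
        assert phenotype.extension_length(mask, CAL) \
            == phenotype.extension_length(padded_mask, CAL)
        assert phenotype.root_width(mask, skel, CAL) \
            == pytest.approx(phenotype.root_width(padded_mask, padded_skel, CAL))
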