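"""Texture families: hand-worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest

from conftest import make_q

from effusiontex.io import GrayImage, ROIMask
from effusiontex.normalization import quantize_roi
from effusiontex.texture import (
    CoocMatrix,
    DEFAULT_OFFSETS,
    OffsetSpec,
    ar_features,
    cooccurrence_features,
    cooccurrence_matrix,
    extract_all,
    feature_map,
    feature_names,
    gradient_features,
    histogram_features,
    runlength_features,
    runlength_matrix,
    wavelet_features,
)


def _random_q(rng, shape=(6, 6), ng=4, mask_p=1.0):
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[0, 0] = True
    return make_q(np.where(mask, levels, 0), ng=ng, mask=mask)


class TestHistogram:
    def test_constant_roi(self):
        f = histogram_features(make_q(np.full((4, 4), 7), ng=8))
        assert f["Mean"] == 7.0 and f["Variance"] == 0.0
        assert np.isnan(f["Skewness"]) and np.isnan(f["Kurtosis"])

    def test_uniform_four_levels(self):
        f = histogram_features(make_q([[1, 2], [3, 4]], ng=4))
        assert f["Mean"] == 2.5 and f["Variance"] == 1.25

    def test_median_nearest_rank(self):
        """Perc.50% of {1,1,2,3} is the 2nd smallest value under nearest rank."""
        f = histogram_features(make_q([[1, 1], [2, 3]], ng=4))
        assert f["Perc.50%"] == 1.0

    def test_percentile_extremes(self):
        f = histogram_features(make_q([[1, 2], [3, 4]], ng=4))
        assert f["Perc.01%"] == 1.0 and f["Perc.99%"] == 4.0


class TestGradient:
    def test_constant_roi(self):
        f = gradient_features(make_q(np.full((5, 5), 3), ng=4))
        assert f["GrMean"] == 0.0 and f["GrNonZeros"] == 0.0

    def test_ramp_unit_gradient(self, patterns):
        q = make_q(patterns["ramp"].astype(int), ng=8)
        f = gradient_features(q)
        assert f["GrMean"] == 1.0 and f["GrVariance"] == 0.0

    def test_checkerboard_zero_central_differences(self, patterns):
        q = make_q(patterns["checkerboard"].astype(int), ng=2)
        f = gradient_features(q)
        assert f["GrNonZeros"] == 0.0

    def test_no_interior_pixels_gives_nan(self):
        q = make_q([[1, 2], [2, 1]], ng=2)
        f = gradient_features(q)
        assert all(np.isnan(v) for v in f.values())


class TestCoocMatrix:
    def test_two_column_hand_count(self):
        """[[1,2],[1,2]] at offset (1,0): the two rightward pairs (1,2),
        symmetrized, put all mass on p(1,2)=p(2,1)=0.5."""
        m = cooccurrence_matrix(make_q([[1, 2], [1, 2]], ng=2), OffsetSpec(1, 0))
        assert m.n_pairs == 2
        assert m.p[0, 1] == 0.5 and m.p[1, 0] == 0.5
        assert m.p[0, 0] == 0.0 and m.p[1, 1] == 0.0

    def test_checkerboard_diagonal_offset_only_equal_pairs(self, patterns):
        q = make_q(patterns["checkerboard"].astype(int), ng=2)
        m = cooccurrence_matrix(q, OffsetSpec(1, 1))
        off_diag = m.p.sum() - np.trace(m.p)
        assert off_diag == 0.0

    def test_normalization_contract(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            q = _random_q(rng, mask_p=0.7)
            m = cooccurrence_matrix(q, OffsetSpec(2, -1))
            if m.n_pairs:
                assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.array_equal(m.p, m.p.T)

    def test_pairs_restricted_to_mask(self):
        mask = np.array([[True, False], [True, True]])
        q = make_q(np.where(mask, 1, 0), ng=2, mask=mask)
        m = cooccurrence_matrix(q, OffsetSpec(1, 0))
        assert m.n_pairs == 1  # only the bottom row pair


class TestCoocFeatures:
    def test_constant_roi_closed_forms(self):
        m = cooccurrence_matrix(make_q(np.full((4, 4), 3), ng=4), OffsetSpec(1, 0))
        f = cooccurrence_features(m)
        assert f["InvDfMom"] == 1.0 and f["Contrast"] == 0.0 and f["AngScMom"] == 1.0
        assert np.isnan(f["Correlat"])

    def test_two_cell_matrix_closed_forms(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        f = cooccurrence_features(CoocMatrix(p=p, offset=OffsetSpec(1, 0), n_pairs=2))
        assert f["InvDfMom"] == pytest.approx(0.5, abs=1e-15)
        assert f["Contrast"] == pytest.approx(1.0, abs=1e-15)
        assert f["Entropy"] == pytest.approx(np.log(2), abs=1e-15)

    def test_brute_force_oracle_equivalence(self, oracles):
        """All 11 features match an independent pair-enumeration
        implementation on 100 random 6x6 images at Ng=4."""
        rng = np.random.default_rng(123)
        offsets = [OffsetSpec(1, 0), OffsetSpec(0, 1), OffsetSpec(1, 1), OffsetSpec(1, -1),
                   OffsetSpec(2, 0), OffsetSpec(0, 2), OffsetSpec(2, 2), OffsetSpec(2, -2)]
        for i in range(100):
            q = _random_q(rng, mask_p=0.8 if i % 2 else 1.0)
            off = offsets[i % len(offsets)]
            m = cooccurrence_matrix(q, off)
            if m.empty:
                continue
            ref_p = oracles["cooc_matrix"](q.levels, q.mask, off.dx, off.dy, q.ng)
            assert np.allclose(m.p, ref_p, atol=1e-12)
            ref_f = oracles["cooc_features"](ref_p)
            got = cooccurrence_features(m)
            for name, want in ref_f.items():
                if np.isnan(want):
                    assert np.isnan(got[name])
                else:
                    assert got[name] == pytest.approx(want, abs=1e-12), name

    def test_invdfmom_decreases_when_mass_leaves_diagonal(self):
        """InvDfMom is 1 iff all pair mass sits on the diagonal and falls
        when fixed mass moves to |i-j| = 1."""
        for eps in (0.0, 0.1, 0.3):
            p = np.zeros((3, 3))
            p[1, 1] = 1.0 - eps
            p[0, 1] = p[1, 0] = eps / 2
            f = cooccurrence_features(CoocMatrix(p=p, offset=OffsetSpec(1, 0), n_pairs=10))
            assert f["InvDfMom"] == pytest.approx(1.0 - eps / 2, abs=1e-15)

    def test_rotation_maps_horizontal_onto_vertical_offsets(self):
        rng = np.random.default_rng(5)
        levels = rng.integers(1, 9, size=(10, 12))
        mask = rng.random((10, 12)) < 0.9
        q = make_q(np.where(mask, levels, 0), ng=8, mask=mask)
        q_rot = make_q(np.rot90(np.where(mask, levels, 0)), ng=8, mask=np.rot90(mask))
        for d in range(1, 6):
            f_h = cooccurrence_features(cooccurrence_matrix(q, OffsetSpec(d, 0)))
            f_v = cooccurrence_features(cooccurrence_matrix(q_rot, OffsetSpec(0, d)))
            for name in f_h:
                if np.isnan(f_h[name]):
                    assert np.isnan(f_v[name])
                else:
                    assert f_h[name] == pytest.approx(f_v[name], abs=1e-12)


class TestRunLength:
    def test_single_row_hand_count(self):
        """Row [1,1,2]: two runs; ShrtREmp = (1/4 + 1)/2, Fraction = 2/3."""
        q = make_q([[1, 1, 2]], ng=2)
        f = runlength_features(runlength_matrix(q, "Horzl"))
        assert f["ShrtREmp"] == pytest.approx(0.625, abs=1e-15)
        assert f["Fraction"] == pytest.approx(2 / 3, abs=1e-15)

    def test_constant_row_single_run(self):
        length = 7
        q = make_q([[3] * length], ng=4)
        f = runlength_features(runlength_matrix(q, "Horzl"))
        assert f["Fraction"] == pytest.approx(1 / length, abs=1e-15)
        assert f["LngREmph"] == pytest.approx(length**2, abs=1e-12)

    def test_total_run_length_equals_mask_area(self):
        rng = np.random.default_rng(3)
        q = _random_q(rng, shape=(8, 8), mask_p=0.7)
        for d in ("Horzl", "Vertl", "45dgr", "135dgr"):
            r = runlength_matrix(q, d)
            lengths = np.arange(1, r.counts.shape[1] + 1)
            assert (r.counts * lengths).sum() == q.mask.sum()

    def test_brute_force_oracle_equivalence(self, oracles):
        """All 5 features match an explicit run scanner on 100 random 6x6
        images in every direction."""
        rng = np.random.default_rng(321)
        for i in range(100):
            q = _random_q(rng, mask_p=0.8 if i % 2 else 1.0)
            d = ("Horzl", "Vertl", "45dgr", "135dgr")[i % 4]
            got = runlength_features(runlength_matrix(q, d))
            runs = oracles["runs"](q.levels, q.mask, d)
            ref = oracles["rl_features"](runs, int(q.mask.sum()))
            for name, want in ref.items():
                assert got[name] == pytest.approx(want, abs=1e-12), (name, d)


class TestAutoregressive:
    def test_constant_roi_degenerate(self):
        f = ar_features(make_q(np.full((10, 10), 5), ng=8))
        assert all(np.isnan(v) for v in f.values())

    def test_too_few_equations_gives_nan(self):
        f = ar_features(make_q(np.ones((4, 4), dtype=int), ng=2))
        assert all(np.isnan(v) for v in f.values())

    def test_parameter_recovery_on_ar_fixture(self, patterns):
        """Fitting the quantized AR realization recovers the generating
        coefficients within +/- 0.05; Sigma, rescaled from level units back
        to intensity units, recovers the innovation SD."""
        field = patterns["ar"]
        img = GrayImage(field)
        mask = ROIMask(np.ones_like(field, dtype=bool))
        q = quantize_roi(img, mask)
        f = ar_features(q)
        theta = np.array([f["Teta1"], f["Teta2"], f["Teta3"], f["Teta4"]])
        assert np.all(np.abs(theta - np.array([0.4, 0.3, -0.1, 0.05])) < 0.05)
        step = 6 * field.std() / q.ng  # intensity units per gray level
        assert abs(f["Sigma"] * step - 1.0) < 0.05

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(99)
        arr = rng.normal(size=(64, 64))
        q = quantize_roi(GrayImage(arr), ROIMask(np.ones((64, 64), bool)))
        f = ar_features(q)
        n_eq = 63 * 62
        bound = 3 / np.sqrt(n_eq)
        for k in ("Teta1", "Teta2", "Teta3", "Teta4"):
            assert abs(f[k]) < bound


class TestWavelet:
    def test_constant_roi_zero_detail_energy(self):
        f = wavelet_features(make_q(np.full((16, 16), 4), ng=8))
        for s in (1, 2, 3, 4):
            for b in ("LH", "HL", "HH"):
                assert f[f"WavEn{b}_s-{s}"] == 0.0

    def test_vertical_stripes_load_column_difference_subband(self):
        stripes = np.tile(np.array([1, 3] * 8), (16, 1))
        f = wavelet_features(make_q(stripes, ng=4))
        assert f["WavEnHL_s-1"] > 0
        assert f["WavEnLH_s-1"] == 0.0
        assert f["WavEnHH_s-1"] == 0.0

    def test_energy_conservation_per_scale(self):
        """Haar orthonormality: subband sums of squares reproduce the input
        energy at every scale."""
        import pywt

        rng = np.random.default_rng(11)
        levels = rng.integers(1, 65, size=(32, 32))
        f = wavelet_features(make_q(levels, ng=64))
        current = levels.astype(float)
        for s in (1, 2, 3, 4):
            total = (current**2).sum()
            ca, (ch, cv, cd) = pywt.dwt2(current, "haar", mode="periodization")
            n_sub = ca.size
            got = n_sub * (
                f[f"WavEnLL_s-{s}"] + f[f"WavEnLH_s-{s}"]
                + f[f"WavEnHL_s-{s}"] + f[f"WavEnHH_s-{s}"]
            )
            assert got == pytest.approx(total, rel=1e-9)
            current = ca

    def test_small_bounding_box_scales_are_nan(self):
        f = wavelet_features(make_q(np.ones((2, 2), dtype=int), ng=2))
        assert not np.isnan(f["WavEnLL_s-1"])
        assert np.isnan(f["WavEnLL_s-2"])


class TestExtractAll:
    def test_feature_count_and_order(self):
        names = feature_names()
        assert len(names) == 275
        q = make_q(np.arange(1, 65).reshape(8, 8), ng=64)
        out = extract_all(q)
        assert list(out.keys()) == names

    def test_invdfmom_in_unit_interval(self, default_cohort_table):
        col = default_cohort_table["S(4,4)InvDfMom"]
        assert ((col > 0) & (col <= 1)).all()

    def test_identical_inputs_identical_vectors(self):
        rng = np.random.default_rng(2)
        levels = rng.integers(1, 17, size=(12, 12))
        a = extract_all(make_q(levels, ng=16))
        b = extract_all(make_q(levels.copy(), ng=16))
        np.testing.assert_equal(a, b)

    def test_affine_intensity_invariance_end_to_end(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 500, size=(24, 24)).astype(float)
        mask = ROIMask(np.ones((24, 24), bool))
        fa = extract_all(quantize_roi(GrayImage(base), mask))
        fb = extract_all(quantize_roi(GrayImage(base * 2.0 + 16.0), mask))
        np.testing.assert_equal(fa, fb)


class TestFeatureMap:
    def test_constant_image_invdfmom_map_is_one(self):
        img = GrayImage(np.full((12, 12), 30.0))
        mask = ROIMask(np.ones((12, 12), bool))
        fmap = feature_map(img, mask, "S(1,0)InvDfMom", window_radius=2)
        assert np.all(fmap[mask.pixels] == 1.0)

    def test_out_of_mask_is_nan(self):
        img = GrayImage(np.random.default_rng(0).normal(size=(12, 12)))
        m = np.zeros((12, 12), bool)
        m[3:9, 3:9] = True
        fmap = feature_map(img, ROIMask(m), "Mean", window_radius=2)
        assert np.all(np.isnan(fmap[~m]))

    def test_window_larger_than_roi_warns_all_nan(self):
        img = GrayImage(np.random.default_rng(0).normal(size=(12, 12)))
        m = np.zeros((12, 12), bool)
        m[5:8, 5:8] = True
        with pytest.warns(UserWarning, match="bounding box"):
            fmap = feature_map(img, ROIMask(m), "Mean", window_radius=6)
        assert np.all(np.isnan(fmap))

    def test_unknown_feature_rejected(self):
        img = GrayImage(np.zeros((8, 8)))
        with pytest.raises(KeyError):
            feature_map(img, ROIMask(np.ones((8, 8), bool)), "NotAFeature", 2)

    def test_homogeneous_sample_has_higher_mean_invdfmom_map(self):
        """The class contrast is carried by patch-level variance, so the map
        window must be wide enough to straddle compartments (radius 12)."""
        from effusiontex.synthetic import (
            DEFAULT_HETEROGENEOUS,
            DEFAULT_HOMOGENEOUS,
            generate_effusion_image,
        )

        means = {}
        for spec in (DEFAULT_HETEROGENEOUS, DEFAULT_HOMOGENEOUS):
            img, mask = generate_effusion_image(spec, (72, 72), (24, 24), seed=6)
            fmap = feature_map(img, mask, "S(4,4)InvDfMom", window_radius=12)
            means[spec.label] = np.nanmean(fmap[mask.pixels])
        assert means["malignant"] > means["benign"]


def test_default_offsets_reproduce_naming_scheme():
    names = [o.name for o in DEFAULT_OFFSETS]
    assert "S(4,4)" in names and "S(4,-4)" in names and len(names) == 20
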