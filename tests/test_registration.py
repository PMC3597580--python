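"""Registration pipeline: translation search, pairing, affine fit, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cecalign as ca
from cecalign.errors import DegenerateFitError, InvalidInputError
from cecalign.registration import pairing_cap, score_cap


def _corr(moving_idx, fixed_idx, dist):
    return ca.Correspondences(
        np.asarray(moving_idx, dtype=int),
        np.asarray(fixed_idx, dtype=int),
        np.asarray(dist, dtype=float),
    )


class TestCoarseTranslate:
    def test_identical_copy_peaks_at_zero(self, mosaic150):
        cs = mosaic150.centroids
        top = ca.coarse_translate(cs, cs, 5)[0]
        assert (top.dx, top.dy) == (0.0, 0.0)

    def test_recovers_known_shift(self, mosaic150):
        cs = mosaic150.centroids
        shifted = ca.CentroidSet(cs.points + np.array([10.0, 7.0]),
                                 cs.frame_width, cs.frame_height)
        top = ca.coarse_translate(shifted, cs, 5)[0]
        bin_px = 0.5 * ca.mean_nn_spacing(cs)
        assert abs(top.dx - (-10.0)) <= bin_px and abs(top.dy - (-7.0)) <= bin_px

    def test_unrelated_sets_score_low(self):
        a, b = ca.make_unrelated_pair(
            ca.MosaicSpec(n_cells=200, seed=31), ca.MosaicSpec(n_cells=200, seed=32)
        )
        cfg = ca.RegistrationConfig()
        top = ca.coarse_translate(a, b, 1)[0]
        moved = ca.apply_transform(ca.AffineTransform.translation(top.dx, top.dy), a)
        score = ca.overlap_score(moved, b, score_cap(b, cfg))
        assert score.matched_pairs < 0.3 * len(a)

    def test_empty_input_rejected(self, mosaic150):
        empty = ca.CentroidSet(np.empty((0, 2)), 480, 480)
        with pytest.raises(InvalidInputError):
            ca.coarse_translate(empty, mosaic150.centroids, 5)


class TestPairNearest:
    def test_identity_pairs_everything(self, mosaic150):
        cs = mosaic150.centroids
        corr = ca.pair_nearest(cs, cs, cap=1.0)
        assert len(corr) == len(cs)
        assert np.array_equal(corr.moving_index, corr.fixed_index)
        assert np.all(corr.distance == 0)

    def test_far_sets_pair_nothing(self):
        a = ca.CentroidSet(np.array([[1.0, 1.0], [5.0, 1.0]]), 2000, 2000)
        b = ca.CentroidSet(np.array([[1500.0, 1500.0], [1505.0, 1500.0]]), 2000, 2000)
        assert len(ca.pair_nearest(a, b, cap=3.0)) == 0

    def test_worked_example(self):
        moving = ca.CentroidSet(np.array([[0.0, 0.0], [10.0, 0.0]]), 100, 100)
        fixed = ca.CentroidSet(np.array([[1.0, 0.0], [9.0, 0.0], [30.0, 0.0]]), 100, 100)
        corr = ca.pair_nearest(moving, fixed, cap=3.0)
        assert corr.pairs == [(0, 0, 1.0), (1, 1, 1.0)]

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 60), st.integers(2, 60))
    def test_matches_brute_force_mutual_nn(self, seed, n_m, n_f):
        """Oracle: exhaustive all-pairs mutual nearest neighbours with cap."""
        rng = np.random.default_rng(seed)
        pm = rng.uniform(0, 100, size=(n_m, 2))
        pf = rng.uniform(0, 100, size=(n_f, 2))
        cap = float(rng.uniform(2, 20))
        d = np.linalg.norm(pm[:, None, :] - pf[None, :, :], axis=2)
        expected = sorted(
            (i, int(np.argmin(d[i])))
            for i in range(n_m)
            if d[i].min() <= cap and int(np.argmin(d[:, np.argmin(d[i])])) == i
        )
        corr = ca.pair_nearest(
            ca.CentroidSet(pm, 100, 100), ca.CentroidSet(pf, 100, 100), cap
        )
        got = sorted(zip(corr.moving_index.tolist(), corr.fixed_index.tolist()))
        assert got == expected


class TestFitAffine:
    def test_exact_translation(self):
        moving = ca.CentroidSet(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), 10, 10)
        fixed = ca.CentroidSet(np.array([[1.0, 2.0], [2.0, 2.0], [1.0, 3.0]]), 10, 10)
        t, rms = ca.fit_affine(_corr([0, 1, 2], [0, 1, 2], [0, 0, 0]), moving, fixed)
        assert np.allclose(t.matrix()[:2], [[1, 0, 1], [0, 1, 2]], atol=1e-12)
        assert rms < 1e-12

    def test_exact_rotation_90(self):
        moving = ca.CentroidSet(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), 10, 10)
        fixed = ca.CentroidSet(np.array([[0.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]), 10, 10)
        t, _ = ca.fit_affine(_corr([0, 1, 2], [0, 1, 2], [0, 0, 0]), moving, fixed)
        assert np.allclose(t.linear, [[0, -1], [1, 0]], atol=1e-12)
        assert np.allclose(t.offset, [0, 0], atol=1e-12)

    def test_matches_normal_equations_oracle_and_recovers_truth(self):
        rng = np.random.default_rng(42)
        truth = ca.AffineTransform(1.03, -0.05, 0.04, 0.97, 12.0, -8.0)
        src = rng.uniform(0, 100, size=(20, 2))
        noise = rng.normal(0, 0.3, size=(20, 2))
        dst = truth.apply(src) + noise
        moving = ca.CentroidSet(src, 200, 200)
        fixed = ca.CentroidSet(dst, 200, 200)
        idx = np.arange(20)
        t, _ = ca.fit_affine(_corr(idx, idx, np.zeros(20)), moving, fixed)

        # independent normal-equations solve
        X = np.column_stack([np.ones(20), src])
        beta = np.linalg.solve(X.T @ X, X.T @ dst)
        oracle = ca.AffineTransform(beta[1, 0], beta[2, 0], beta[1, 1], beta[2, 1],
                                    beta[0, 0], beta[0, 1])
        assert np.allclose(t.matrix(), oracle.matrix(), atol=1e-9)

        # parameters within 3 standard errors of the truth
        resid = X @ beta - dst
        for j, (est, true_val) in enumerate(
            [(beta[1, 0], 1.03), (beta[2, 0], -0.05), (beta[0, 0], 12.0)]
        ):
            s2 = np.sum(resid[:, 0] ** 2) / (20 - 3)
            cov = s2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(np.diag(cov))[[1, 2, 0][j]]
            assert abs(est - true_val) <= 3 * se

    def test_degenerate_inputs_rejected(self):
        moving = ca.CentroidSet(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), 10, 10)
        fixed = ca.CentroidSet(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), 10, 10)
        with pytest.raises(DegenerateFitError):
            ca.fit_affine(_corr([0, 1], [0, 1], [0, 0]), moving, fixed)
        with pytest.raises(DegenerateFitError):
            ca.fit_affine(_corr([0, 1, 2], [0, 1, 2], [0, 0, 0]), moving, fixed)


class TestPlausibility:
    def test_identity_plausible(self):
        assert ca.check_plausibility(ca.AffineTransform.identity()).plausible

    def test_gross_scale_flagged(self):
        v = ca.check_plausibility(ca.AffineTransform(1.6, 0, 0, 1.6, 0, 0))
        assert not v.plausible
        assert any("scale" in s for s in v.violations)

    def test_small_rotation_and_scale_plausible(self):
        t = ca.AffineTransform.from_params(scale=1.02, rotation=5.0)
        assert ca.check_plausibility(t).plausible

    def test_relaxing_limits_is_monotone(self):
        """A transform plausible under tight limits stays plausible under looser ones."""
        rng = np.random.default_rng(0)
        tight = ca.PlausibilityLimits((0.9, 1.1), 0.05, 5.0)
        loose = ca.PlausibilityLimits((0.8, 1.25), 0.15, 15.0)
        for _ in range(200):
            t = ca.AffineTransform.from_params(
                scale=(rng.uniform(0.7, 1.4), rng.uniform(0.7, 1.4)),
                rotation=rng.uniform(-20, 20),
                shear=rng.uniform(-0.2, 0.2),
            )
            if ca.check_plausibility(t, tight).plausible:
                assert ca.check_plausibility(t, loose).plausible


class TestOverlapScore:
    def test_identical_sets(self, mosaic150):
        cs = mosaic150.centroids
        s = ca.overlap_score(cs, cs, cap=1.0)
        assert s.matched_fraction == 1.0 and s.residual_rms == 0.0

    def test_disjoint_sets(self):
        a = ca.CentroidSet(np.array([[1.0, 1.0], [5.0, 5.0]]), 4000, 4000)
        b = ca.CentroidSet(np.array([[3000.0, 3000.0], [3005.0, 3000.0]]), 4000, 4000)
        s = ca.overlap_score(a, b, cap=10.0)
        assert s.matched_pairs == 0 and s.matched_fraction == 0.0

    def test_ground_truth_overlap_accounting(self, mosaic250):
        """With the exact transform and zero noise the moving points all land on
        fixed points; the pair count equals the realized-overlap share of the
        fixed set."""
        w, h = mosaic250.frame
        truth = ca.AffineTransform.from_params(translation=(40.0, 25.0))
        pair = ca.make_pair(
            mosaic250, ca.PairSpec(true_transform=truth, overlap_fraction=0.6, seed=3)
        )
        moved = ca.apply_transform(pair.truth, pair.moving)
        s = ca.overlap_score(moved, pair.fixed, cap=1.0)
        assert s.matched_fraction == 1.0  # pairs / min(sizes)
        assert abs(s.matched_pairs / len(pair.fixed) - 0.6) <= 0.1
        assert s.residual_rms < 1e-9


class TestRegister:
    def test_self_registration_is_identity(self, mosaic150):
        cs = mosaic150.centroids
        res = ca.register(cs, cs)
        assert res.verdict == "match"
        assert res.matched_fraction == 1.0
        assert np.max(np.abs(res.transform.matrix() - np.eye(3))) < 1e-6

    def test_recovers_reference_pair_transform(self, spec_pair):
        res = ca.register(spec_pair.moving, spec_pair.fixed)
        assert res.verdict == "match"
        truth = spec_pair.truth
        assert abs(res.transform.tx - truth.tx) <= 1.0
        assert abs(res.transform.ty - truth.ty) <= 1.0
        rd, td = res.transform.decompose(), truth.decompose()
        assert abs(rd.rotation - td.rotation) <= 0.5
        assert abs(rd.scale_x - td.scale_x) <= 0.02
        assert abs(rd.scale_y - td.scale_y) <= 0.02

    def test_unrelated_mosaics_no_match(self):
        a, b = ca.make_unrelated_pair(
            ca.MosaicSpec(n_cells=180, seed=51), ca.MosaicSpec(n_cells=180, seed=52)
        )
        assert ca.register(a, b).verdict == "no_match"

    def test_symmetry_inverse_transforms(self, spec_pair):
        fwd = ca.register(spec_pair.moving, spec_pair.fixed)
        rev = ca.register(spec_pair.fixed, spec_pair.moving)
        assert fwd.verdict == "match" and rev.verdict == "match"
        rng = np.random.default_rng(9)
        pts = rng.uniform(50, 430, size=(50, 2))
        mapped = rev.transform.apply(fwd.transform.apply(pts))
        assert np.max(np.linalg.norm(mapped - pts, axis=1)) <= 2.0

    def test_deterministic(self, spec_pair):
        r1 = ca.register(spec_pair.moving, spec_pair.fixed)
        r2 = ca.register(spec_pair.moving, spec_pair.fixed)
        assert r1 == r2

    def test_low_count_flag_propagates(self):
        small = ca.generate_mosaic(ca.MosaicSpec(n_cells=73, seed=61)).centroids
        res = ca.register(small, small)
        assert res.low_count_flag
        assert res.verdict == "match"  # flag is a warning, not a veto

    def test_too_few_points_rejected(self):
        tiny = ca.CentroidSet(np.array([[1.0, 1.0], [5.0, 5.0]]), 100, 100)
        with pytest.raises(InvalidInputError):
            ca.register(tiny, tiny)

    def test_apply_transform_keeps_out_of_frame_points(self, mosaic150):
        cs = mosaic150.centroids
        t = ca.AffineTransform.translation(450.0, 0.0)
        moved = ca.apply_transform(t, cs)
        assert len(moved) == len(cs)
        assert not np.all(moved.in_frame_mask)
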