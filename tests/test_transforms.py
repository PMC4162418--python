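"""Affine/TPS fitting, application, inversion and consistency scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atlasdai import (
    AffineTransform,
    PointSet,
    apply_transform,
    compose,
    fit_affine,
    fit_tps,
    inverse_consistency,
    invert_transform,
    TransformationRecord,
)
from atlasdai.errors import (
    ChainMismatch,
    ComplexAxisError,
    DimensionMismatch,
    InvalidLambda,
    InvalidSampleCount,
    SingularMatrix,
    SingularSystem,
    SRSMismatch,
    Underdetermined,
)
from atlasdai.transforms import load_tie_points, save_tie_points

from conftest import minimal_srs
import dataclasses


def random_affine(rng, dim):
    """Seeded well-conditioned random affine."""
    while True:
        lin = rng.uniform(-2, 2, (dim, dim))
        if abs(np.linalg.det(lin)) > 0.2:
            break
    m = np.eye(dim + 1)
    m[:dim, :dim] = lin
    m[:dim, dim] = rng.uniform(-5, 5, dim)
    return AffineTransform(m)


class TestFitAffine:
    def test_identity_pairs_recover_identity(self, rng):
        src = rng.uniform(0, 10, (6, 2))
        t = fit_affine(list(zip(src, src)), dim=2)
        assert np.allclose(t.matrix, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_exact_pairs_recover_generator(self, rng, dim):
        gen = random_affine(rng, dim)
        src = rng.uniform(-5, 5, (dim + 4, dim))
        t = fit_affine(list(zip(src, gen(src))), dim=dim)
        assert np.abs(t.matrix - gen.matrix).max() <= 1e-9

    def test_too_few_pairs_underdetermined(self):
        with pytest.raises(Underdetermined):
            fit_affine([((0, 0), (1, 1)), ((1, 1), (2, 2))], dim=2)

    def test_collinear_sources_degenerate(self):
        src = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        with pytest.raises(Exception) as exc:
            fit_affine(list(zip(src, src)), dim=2)
        assert "affinely dependent" in str(exc.value)

    def test_complex_axis_srs_refused(self, rng):
        ax = dataclasses.replace(
            minimal_srs("LOCAL:0001", "Dev").axes[2],
            anatomical_direction="complex")
        desc = minimal_srs("LOCAL:0001", "Dev")
        desc = dataclasses.replace(desc, axes=desc.axes[:2] + (ax,))
        src = rng.uniform(0, 1, (4, 2))
        with pytest.raises(ComplexAxisError):
            fit_affine(list(zip(src, src)), dim=2, source_srs=desc)


class TestFitTPS:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), dim=st.sampled_from([2, 3]),
           n=st.integers(4, 30))
    def test_interpolates_landmarks_exactly_at_lambda_zero(self, seed, dim,
                                                           n):
        rng = np.random.default_rng(seed)
        src = rng.uniform(-10, 10, (n, dim))
        dst = src + rng.normal(0, 1.5, (n, dim))
        tps = fit_tps(list(zip(src, dst)), dim=dim)
        assert np.abs(tps(src) - dst).max() <= 1e-9
        assert tps.side_condition_residual() <= 1e-9

    def test_affine_data_yields_affine_predictions(self, rng):
        gen = random_affine(rng, 2)
        src = rng.uniform(0, 10, (12, 2))
        tps = fit_tps(list(zip(src, gen(src))), dim=2)
        probes = rng.uniform(0, 10, (100, 2))
        assert np.abs(tps(probes) - gen(probes)).max() <= 1e-6

    def test_scipy_rbf_agrees_as_independent_cross_check(self, rng):
        from scipy.interpolate import RBFInterpolator
        src = rng.uniform(0, 10, (15, 2))
        dst = src + rng.normal(0, 1.0, (15, 2))
        ours = fit_tps(list(zip(src, dst)), dim=2)
        ref = RBFInterpolator(src, dst, kernel="thin_plate_spline")
        probes = rng.uniform(1, 9, (50, 2))
        assert np.abs(ours(probes) - ref(probes)).max() <= 1e-6

    def test_duplicate_source_landmark_singular(self):
        src = [(0.0, 0.0), (0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]
        dst = [(0.0, 0.0), (1.0, 1.0), (1.0, 0.0), (0.0, 1.0)]
        with pytest.raises(SingularSystem):
            fit_tps(list(zip(src, dst)), dim=2)

    def test_negative_lambda_invalid(self, rng):
        src = rng.uniform(0, 1, (5, 2))
        with pytest.raises(InvalidLambda):
            fit_tps(list(zip(src, src)), dim=2, lam=-0.1)

    def test_regularized_fit_smooths_but_keeps_side_conditions(self, rng):
        src = rng.uniform(0, 10, (20, 2))
        dst = src + rng.normal(0, 1.0, (20, 2))
        smooth = fit_tps(list(zip(src, dst)), dim=2, lam=10.0)
        exact = fit_tps(list(zip(src, dst)), dim=2)
        assert smooth.side_condition_residual() <= 1e-9
        # regularization shrinks the bending (kernel) coefficients
        assert np.abs(smooth.weights).sum() < np.abs(exact.weights).sum()


class TestApply:
    def test_identity_preserves_points_and_flags(self, rng):
        ps = PointSet(srs_name="A", points=rng.uniform(0, 1, (5, 3)))
        out = apply_transform(AffineTransform.identity(3), ps)
        assert np.array_equal(out.points, ps.points)
        assert out.out_of_validity_flags is None or \
            not out.out_of_validity_flags.any()

    def test_translation_moves_origin(self):
        t = AffineTransform.translation([1.0, 0.0, 0.0])
        ps = PointSet(srs_name="A", points=np.zeros((1, 3)))
        assert np.allclose(apply_transform(t, ps).points, [[1, 0, 0]])

    def test_round_trip_through_inverse(self, rng):
        t = random_affine(rng, 3)
        ps = PointSet(srs_name="A", points=rng.uniform(-5, 5, (10, 3)))
        back = apply_transform(invert_transform(t), apply_transform(t, ps))
        assert np.abs(back.points - ps.points).max() <= 1e-9

    def test_input_point_set_never_mutated(self, rng):
        pts = rng.uniform(0, 1, (4, 2))
        ps = PointSet(srs_name="A", points=pts.copy())
        apply_transform(random_affine(rng, 2), ps)
        assert np.array_equal(ps.points, pts)

    def test_record_checks_srs_and_retags_output(self, table1):
        reg, graph = table1
        rec = graph.get_transformation("TX:0102-0001")
        ps = PointSet(srs_name="INCF:0102", points=np.array([[1.0, 2, 3]]))
        out = apply_transform(rec, ps, registry=reg)
        assert reg.resolve_code(out.srs_name) == "INCF:0001"
        wrong = PointSet(srs_name="INCF:0200", points=ps.points)
        with pytest.raises(SRSMismatch):
            apply_transform(rec, wrong, registry=reg)

    def test_out_of_extent_points_flagged_not_refused(self, table1):
        reg, graph = table1
        rec = graph.get_transformation("TX:0102-0001")
        pts = np.array([[5.0, 5.0, 5.0], [999.0, 5.0, 5.0]])
        ps = PointSet(srs_name="INCF:0102", points=pts)
        out = apply_transform(rec, ps, registry=reg)
        assert list(out.out_of_validity_flags) == [False, True]

    def test_dimension_mismatch_raises(self, rng):
        ps = PointSet(srs_name="A", points=rng.uniform(0, 1, (3, 2)))
        with pytest.raises(DimensionMismatch):
            apply_transform(AffineTransform.identity(3), ps)


class TestInversion:
    def test_tps_inverse_round_trip_small_warp(self, rng):
        src = np.array(np.meshgrid(np.linspace(0, 10, 5),
                                   np.linspace(0, 10, 5))
                       ).reshape(2, -1).T
        dst = src + 0.4 * np.sin(src / 3.0)
        fwd = fit_tps(list(zip(src, dst)), dim=2)
        inv = invert_transform(fwd)
        assert inv.approximate
        xs = np.linspace(0.5, 9.5, 50)
        grid = np.array(np.meshgrid(xs, xs)).reshape(2, -1).T
        err = np.linalg.norm(inv(fwd(grid)) - grid, axis=1)
        max_disp = np.linalg.norm(dst - src, axis=1).max()
        assert err.max() <= 0.1 * max_disp

    def test_singular_matrix_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        m[0, 1] = 0.0
        with pytest.raises(SingularMatrix):
            AffineTransform(m).inverse()


class TestInverseConsistency:
    def test_exact_affine_pair_scores_zero(self, rng):
        t = random_affine(rng, 3)
        stats = inverse_consistency(t, invert_transform(t),
                                    [[0, 10]] * 3, n=200, seed=4)
        assert stats.mean_error <= 1e-9
        assert stats.max_error <= 1e-9

    def test_deterministic_for_fixed_seed(self, rng):
        t = random_affine(rng, 2)
        inv = invert_transform(t)
        a = inverse_consistency(t, inv, [[0, 5]] * 2, n=100, seed=7)
        b = inverse_consistency(t, inv, [[0, 5]] * 2, n=100, seed=7)
        assert a == b

    def test_matches_brute_force_recomputation(self, rng):
        src = rng.uniform(0, 10, (9, 2))
        dst = src + rng.normal(0, 0.5, (9, 2))
        fwd = fit_tps(list(zip(src, dst)), dim=2)
        inv = invert_transform(fwd)
        stats = inverse_consistency(fwd, inv, [[0, 10]] * 2, n=64, seed=3)
        # independent loop over the same seeded sample
        pts = np.random.default_rng(3).uniform([0, 0], [10, 10], (64, 2))
        errs = [float(np.linalg.norm(inv(fwd(p[None]))[0] - p))
                for p in pts]
        assert np.isclose(stats.mean_error, np.mean(errs))
        assert np.isclose(stats.max_error, np.max(errs))
        assert np.isclose(stats.rms_error,
                          np.sqrt(np.mean(np.square(errs))))

    def test_sample_count_validated(self, rng):
        t = random_affine(rng, 2)
        with pytest.raises(InvalidSampleCount):
            inverse_consistency(t, t, [[0, 1]] * 2, n=0)


class TestCompose:
    def test_transform_then_inverse_is_identity(self, rng):
        t = random_affine(rng, 3)
        c = compose([t, invert_transform(t)])
        pts = rng.uniform(-3, 3, (20, 3))
        assert np.abs(c(pts) - pts).max() <= 1e-9

    def test_two_affines_collapse_to_matrix_product(self, rng):
        a, b = random_affine(rng, 2), random_affine(rng, 2)
        c = compose([a, b])
        assert isinstance(c, AffineTransform)
        pts = rng.uniform(0, 1, (10, 2))
        assert np.abs(c(pts) - b(a(pts))).max() <= 1e-9

    def test_mismatched_record_srs_raises(self, table1):
        _, graph = table1
        fwd = graph.get_transformation("TX:0102-0001")
        with pytest.raises(ChainMismatch):
            compose([fwd, graph.get_transformation("TX:0100-0001")])


class TestTiePointIO:
    def test_csv_round_trip(self, tmp_path, rng):
        pairs = [(tuple(rng.uniform(0, 5, 2)), tuple(rng.uniform(0, 5, 2)))
                 for _ in range(6)]
        path = tmp_path / "tp.csv"
        save_tie_points(path, pairs)
        loaded = load_tie_points(path, dim=2)
        assert np.allclose(np.asarray(loaded, dtype=object).tolist(),
                           np.asarray(pairs, dtype=object).tolist())
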