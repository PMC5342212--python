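import itertools

import numpy as np
import pytest

from morphoscape.core import DistanceMatrix
from morphoscape.regression import (
    PredictorSet,
    bh_adjust,
    commonality_analysis,
    detect_suppressors,
    lr_fit,
    mrdm_fit,
    two_stage_analysis,
    vectorize,
)


def random_dm(rng, n, prefix="o"):
    vals = np.abs(rng.standard_normal((n, n)))
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix([f"{prefix}{i}" for i in range(n)], vals)


def intra_set(rng, n, p, beta=None, noise=1.0):
    x = rng.standard_normal((n, p))
    if beta is None:
        beta = rng.standard_normal(p)
    y = x @ beta + noise * rng.standard_normal(n)
    return PredictorSet(
        response_name="y",
        response=y,
        predictors={f"x{j}": x[:, j] for j in range(p)},
        level="intra_population",
    )


class TestVectorize:
    def test_3x3_order(self):
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        d = DistanceMatrix(["a", "b", "c"], vals)
        np.testing.assert_array_equal(vectorize(d), [1, 2, 3])

    def test_round_trip(self, rng):
        d = random_dm(rng, 5)
        back = DistanceMatrix.from_condensed(d.labels, vectorize(d))
        np.testing.assert_allclose(back.values, d.values, atol=1e-12)

    def test_6x6_matches_loop_oracle(self, rng):
        d = random_dm(rng, 6)
        v = vectorize(d)
        assert len(v) == 15
        expected = []
        for i in range(6):
            for j in range(i + 1, 6):
                expected.append(d.values[i, j])
        np.testing.assert_array_equal(v, expected)


class TestMrdmFit:
    def test_perfect_fit(self, rng):
        d = random_dm(rng, 8)
        ps = PredictorSet.from_distance_matrices(d, {"same": d})
        rep = mrdm_fit(ps, n_perm=99, seed=1)
        assert rep.stats_for("same").beta == pytest.approx(1.0, abs=1e-10)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
        assert rep.r_squared_p == pytest.approx(1 / 100)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        n = 4
        resp = random_dm(rng, n)
        pred = random_dm(rng, n)
        ps = PredictorSet.from_distance_matrices(resp, {"x": pred})
        rep = mrdm_fit(ps, permutations="all")
        # independent oracle: refit for each of the 24 relabelings
        def fit_beta_r2(y):
            ys = (y - y.mean()) / y.std(ddof=1)
            x = pred.condensed()
            xs = (x - x.mean()) / x.std(ddof=1)
            b = float(xs @ ys / (xs @ xs))
            r2 = 1 - float(((ys - xs * b) ** 2).sum()) / float((ys**2).sum())
            return b, r2

        b_obs, r2_obs = fit_beta_r2(resp.condensed())
        count_b = 0
        count_r2 = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm = list(perm)
            shuffled = resp.values[np.ix_(perm, perm)]
            y = shuffled[np.triu_indices(n, k=1)]
            b, r2 = fit_beta_r2(y)
            total += 1
            if abs(b) >= abs(b_obs) - 1e-12:
                count_b += 1
            if r2 >= r2_obs - 1e-12:
                count_r2 += 1
        assert rep.stats_for("x").beta_p == pytest.approx(count_b / total)
        assert rep.r_squared_p == pytest.approx(count_r2 / total)

    def test_seed_reproducibility(self, rng):
        resp = random_dm(rng, 10)
        preds = {"a": random_dm(rng, 10), "b": random_dm(rng, 10)}
        ps = PredictorSet.from_distance_matrices(resp, preds)
        r1 = mrdm_fit(ps, n_perm=200, seed=42)
        r2 = mrdm_fit(ps, n_perm=200, seed=42)
        for p1, p2 in zip(r1.predictors, r2.predictors):
            assert p1.beta_p == p2.beta_p
        assert r1.r_squared_p == r2.r_squared_p

    def test_null_type_one_error_small(self, rng):
        # scaled-down version of the acceptance simulation
        rejections = 0
        reps = 120
        for _ in range(reps):
            resp = random_dm(rng, 15)
            pred = random_dm(rng, 15)
            ps = PredictorSet.from_distance_matrices(resp, {"x": pred})
            rep = mrdm_fit(ps, n_perm=99, seed=int(rng.integers(1 << 30)))
            if rep.r_squared_p <= 0.05:
                rejections += 1
        assert 0.0 <= rejections / reps <= 0.12

    def test_collinear_predictors_error(self, rng):
        resp = random_dm(rng, 8)
        pred = random_dm(rng, 8)
        ps = PredictorSet.from_distance_matrices(
            resp, {"a": pred, "b": DistanceMatrix(pred.labels, pred.values * 2.0)}
        )
        with pytest.raises(ValueError, match="collinear"):
            mrdm_fit(ps, n_perm=9, seed=0)

    def test_power_recovery_small(self, rng):
        # response = 0.5 * predictor + noise at 30 objects; expect detection
        detected = 0
        reps = 30
        for _ in range(reps):
            n = 30
            pred = random_dm(rng, n)
            noise = random_dm(rng, n)
            vals = 0.5 * (pred.values - pred.values.mean()) / pred.values.std() + \
                0.5 * (noise.values - noise.values.mean()) / noise.values.std()
            vals = vals - vals.min() + 0.0
            np.fill_diagonal(vals, 0.0)
            resp = DistanceMatrix(pred.labels, 0.5 * (vals + vals.T))
            ps = PredictorSet.from_distance_matrices(resp, {"x": pred})
            rep = mrdm_fit(ps, n_perm=99, seed=int(rng.integers(1 << 30)))
            if rep.stats_for("x").beta_p < 0.05:
                detected += 1
        assert detected / reps >= 0.9


class TestLrFit:
    def test_exact_identity(self, rng):
        x = rng.standard_normal(20)
        ps = PredictorSet("y", x.copy(), {"x": x}, "intra_population")
        rep = lr_fit(ps)
        assert rep.stats_for("x").beta == pytest.approx(1.0, abs=1e-10)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictors_beta_equals_r(self, rng):
        n = 40
        x1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        x2 = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to x1
        y = 0.7 * x1 + 0.2 * x2 + rng.standard_normal(n)
        ps = PredictorSet("y", y, {"x1": x1, "x2": x2}, "intra_population")
        rep = lr_fit(ps)
        for name in ("x1", "x2"):
            s = rep.stats_for(name)
            assert s.beta == pytest.approx(s.r, abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        ps = intra_set(rng, 20, 3)
        rep = lr_fit(ps)
        # independent normal-equations solve on standardized data
        y = ps.response
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = np.column_stack(
            [(v - v.mean()) / v.std(ddof=1) for v in ps.predictors.values()]
        )
        beta = np.linalg.solve(xs.T @ xs, xs.T @ ys)
        for b, p in zip(beta, rep.predictors):
            assert p.beta == pytest.approx(float(b), abs=1e-10)
        resid = ys - xs @ beta
        r2 = 1 - float(resid @ resid) / float(ys @ ys)
        assert rep.r_squared == pytest.approx(r2, abs=1e-10)

    def test_pvalues_match_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        ps = intra_set(rng, 25, 2)
        rep = lr_fit(ps)
        x = np.column_stack(list(ps.predictors.values()))
        model = sm.OLS(ps.response, sm.add_constant(x)).fit()
        for i, p in enumerate(rep.predictors):
            assert p.beta_p == pytest.approx(model.pvalues[i + 1], abs=1e-10)
        assert rep.r_squared_p == pytest.approx(model.f_pvalue, abs=1e-10)

    def test_too_few_observations(self, rng):
        ps = intra_set(rng, 4, 3)
        with pytest.raises(ValueError, match="too few"):
            lr_fit(ps)


def brute_force_commonality(y, xcols, names):
    """Independent all-subsets commonality oracle using raw OLS R² values.

    For each predictor k: U = R2(full) - R2(without k); T = r_k^2; C = T - U.
    Subset coefficients via direct inclusion-exclusion over R² of
    complement-based submodels.
    """
    import numpy.linalg as la

    n, p = xcols.shape

    def r2_of(idx):
        if not idx:
            return 0.0
        x = np.column_stack([np.ones(n), xcols[:, idx]])
        b, *_ = la.lstsq(x, y, rcond=None)
        resid = y - x @ b
        yc = y - y.mean()
        return 1.0 - float(resid @ resid) / float(yc @ yc)

    full = r2_of(list(range(p)))
    out = {}
    for k in range(p):
        u = full - r2_of([j for j in range(p) if j != k])
        r = np.corrcoef(xcols[:, k], y)[0, 1]
        t = float(r**2)
        out[names[k]] = (u, t - u, t)
    return out, full, r2_of


class TestCommonalityAnalysis:
    def test_orthogonal_predictors(self, rng):
        n = 40
        x1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        x2 = np.tile([1.0, -1.0], n // 2)
        y = 0.6 * x1 - 0.3 * x2 + rng.standard_normal(n)
        ps = PredictorSet("y", y, {"x1": x1, "x2": x2}, "intra_population")
        per_pred, coeffs = commonality_analysis(ps)
        for name in ("x1", "x2"):
            u, c, t = per_pred[name]
            assert c == pytest.approx(0.0, abs=1e-10)
            assert u == pytest.approx(t, abs=1e-10)

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_matches_brute_force_oracle(self, rng, p):
        ps = intra_set(rng, 30, p, noise=0.8)
        per_pred, coeffs = commonality_analysis(ps)
        x = np.column_stack(list(ps.predictors.values()))
        oracle, full, r2_of = brute_force_commonality(ps.response, x, ps.names)
        for name in ps.names:
            u, c, t = per_pred[name]
            uo, co, to = oracle[name]
            assert u == pytest.approx(uo, abs=1e-10)
            assert c == pytest.approx(co, abs=1e-10)
            assert t == pytest.approx(to, abs=1e-10)
        assert sum(coeffs.values()) == pytest.approx(full, abs=1e-10)
        assert len(coeffs) == 2**p - 1

    def test_identities_on_random_fixtures(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 6))
            ps = intra_set(rng, 25, p)
            per_pred, coeffs = commonality_analysis(ps)
            rep = lr_fit(ps, with_commonality=False)
            assert sum(coeffs.values()) == pytest.approx(rep.r_squared, abs=1e-10)
            for name in ps.names:
                u, c, t = per_pred[name]
                assert u + c == pytest.approx(t, abs=1e-10)

    def test_too_many_predictors_guard(self, rng):
        ps = intra_set(rng, 60, 13)
        with pytest.raises(ValueError, match="limited"):
            commonality_analysis(ps)


def make_suppression_set(rng, n=60):
    """Classic total suppression: y = s, x1 = s + v, x2 = v."""
    s = rng.standard_normal(n)
    v = rng.standard_normal(n)
    y = s + 0.3 * rng.standard_normal(n)
    return PredictorSet(
        "y", y, {"signal_plus_noise": s + v, "pure_noise": v}, "intra_population"
    )


class TestDetectSuppressors:
    def report(self, rng, ps):
        return lr_fit(ps)

    def test_opposite_signs_flagged(self, rng):
        rep = lr_fit(intra_set(rng, 20, 2))
        rep.predictors[0].r = 0.2
        rep.predictors[0].beta = -0.15
        assert rep.predictors[0].name in detect_suppressors(rep)

    def test_consonant_predictor_not_flagged(self, rng):
        rep = lr_fit(intra_set(rng, 20, 2))
        p = rep.predictors[0]
        p.r, p.beta, p.u, p.c, p.t = 0.3, 0.29, 0.08, 0.01, 0.09
        q = rep.predictors[1]
        q.r, q.beta, q.u, q.c, q.t = 0.5, 0.45, 0.2, 0.05, 0.25
        assert detect_suppressors(rep) == []

    def test_counterbalanced_flagged(self, rng):
        rep = lr_fit(intra_set(rng, 20, 2))
        p = rep.predictors[0]
        p.r, p.beta = 0.01, 0.3
        p.u, p.c, p.t = 0.05, -0.049, 0.001
        assert p.name in detect_suppressors(rep)

    def test_constructed_suppression_fixture(self, rng):
        ps = make_suppression_set(rng)
        rep = lr_fit(ps)
        flagged = detect_suppressors(rep)
        assert "pure_noise" in flagged


class TestBhAdjust:
    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([0.01]), [0.01])

    def test_two_values_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.02, 0.04]), [0.04, 0.04])

    def test_matches_reference_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 10)
        adjusted = bh_adjust(p)
        # reference oracle: sort, p*m/rank, cumulative min from the right
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(adjusted, expected, atol=1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 25)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_monotone_in_input_order_preserved(self, rng):
        p = np.sort(rng.uniform(0, 1, 8))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)


class TestTwoStage:
    def test_no_suppressors_is_fixed_point(self, rng):
        n = 50
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = x1 + x2 + 0.1 * rng.standard_normal(n)
        ps = PredictorSet("y", y, {"x1": x1, "x2": x2}, "intra_population")
        initial, final = two_stage_analysis(ps)
        assert final.suppressors_removed == []
        assert final.r_squared == initial.r_squared
        assert [p.beta for p in final.predictors] == [
            p.beta for p in initial.predictors
        ]

    def test_constructed_suppressor_removed(self, rng):
        ps = make_suppression_set(rng)
        initial, final = two_stage_analysis(ps)
        assert "pure_noise" in final.suppressors_removed
        assert "pure_noise" not in [p.name for p in final.predictors]
        assert final.r_squared <= initial.r_squared + 1e-12

    def test_synthetic_ibd_recovery(self, rng):
        # shape distance built from geographic distance plus noise
        n = 20
        geo = random_dm(rng, n)
        noise = random_dm(rng, n)
        vals = geo.values + 0.2 * noise.values
        resp = DistanceMatrix(geo.labels, vals)
        other = random_dm(rng, n)
        ps = PredictorSet.from_distance_matrices(
            resp, {"geographic_distance": geo, "other": other}
        )
        initial, final = two_stage_analysis(ps, n_perm=199, seed=7)
        s = final.stats_for("geographic_distance")
        assert s.beta > 0
        assert s.beta_p < 0.05

    def test_all_flagged_empty_final(self, rng):
        ps = make_suppression_set(rng)
        # force both predictors flagged via tau covering everything
        initial, final = two_stage_analysis(ps, tau=1e9)
        if len(final.predictors) == 0:
            assert final.r_squared == 0.0
            assert set(final.suppressors_removed) == set(ps.names)
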