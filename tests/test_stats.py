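"""Paired t-tests, OLS R² and the cohort regression endpoints."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import hyp2f1

from petmr_hypoxia.geometry import GridGeometry
from petmr_hypoxia.images import RoiMask, SuvImage
from petmr_hypoxia.stats import (PairedSample, correlation_endpoints,
                                 linear_regression_r2, paired_t_test, suv_max)


def _paired(a, b):
    return PairedSample(labels=[f"p{i}" for i in range(len(a))],
                        a=np.asarray(a, float), b=np.asarray(b, float))


class TestPairedT:
    def test_identical_samples_t_zero_p_one(self):
        t, p, df = paired_t_test(_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert t == 0.0 and p == 1.0 and df == 2

    def test_hand_computed_example(self):
        # d = (1, 2, 3): mean 2, sd 1, t = 2*sqrt(3), df 2
        t, p, df = paired_t_test(_paired([2.0, 4.0, 6.0], [1.0, 2.0, 3.0]))
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2
        assert p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), 2), rel=1e-12)

    def test_matches_scipy_ttest_rel(self, rng):
        a, b = rng.normal(10, 2, 15), rng.normal(9, 2, 15)
        t, p, df = paired_t_test(_paired(a, b))
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetric_in_arguments(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        t_ab, p_ab, _ = paired_t_test(_paired(a, b))
        t_ba, p_ba, _ = paired_t_test(_paired(b, a))
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_variance_nonzero_mean_infinite_t(self):
        t, p, _ = paired_t_test(_paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]))
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 complete pairs"):
            _paired([1.0], [2.0])

    def test_incomplete_pairs_dropped(self):
        s = _paired([1.0, np.nan, 3.0, 4.0], [1.0, 2.0, np.nan, 5.0])
        assert s.a.size == 2 and s.labels == ["p0", "p3"]


class TestRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = linear_regression_r2(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_y_r2_zero(self):
        res = linear_regression_r2(np.arange(5.0), np.full(5, 3.0))
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_quarter(self):
        # x=(1,2,3), y=(1,3,2): slope 0.5, SSres 1.5, SStot 2 -> R² = 0.25
        res = linear_regression_r2(np.array([1.0, 2, 3]), np.array([1.0, 3, 2]))
        assert res.r_squared == pytest.approx(0.25, rel=1e-12)

    def test_r2_equals_squared_correlation(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = linear_regression_r2(x, y)
        assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                              abs=1e-12)

    def test_affine_invariance_of_r2(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = linear_regression_r2(x, y).r_squared
        assert linear_regression_r2(3 * x + 5, y).r_squared == pytest.approx(base)
        assert linear_regression_r2(x, -2 * y + 1).r_squared == pytest.approx(base)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression_r2(np.full(5, 2.0), np.arange(5.0))

    def test_ols_p_covered_by_permutation_distribution(self, rng):
        """With independent noise the slope's t-test p agrees with a
        permutation null within Monte-Carlo error."""
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = linear_regression_r2(x, y)
        n_perm = 4000
        r2_obs = res.r_squared
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            count += np.corrcoef(x, yp)[0, 1] ** 2 >= r2_obs - 1e-15
        p_perm = count / n_perm
        se = np.sqrt(res.p_value * (1 - res.p_value) / n_perm)
        assert abs(p_perm - res.p_value) < max(5 * se, 0.05)

    def test_mean_r2_matches_analytic_expectation(self):
        """Mean recovered R² over 500 seeded bivariate-normal replicates at
        n=10 sits within 0.05 of the analytic E[R²] for the latent rho."""
        rho, n, reps = 0.6, 10, 500
        rng = np.random.default_rng(7)
        cov = [[1.0, rho], [rho, 1.0]]
        r2 = np.empty(reps)
        for i in range(reps):
            z = rng.multivariate_normal([0, 0], cov, size=n)
            r2[i] = linear_regression_r2(z[:, 0], z[:, 1]).r_squared
        analytic = 1 - ((n - 2) / (n - 1)) * (1 - rho**2) * hyp2f1(
            1, 1, (n + 1) / 2, rho**2)
        assert abs(r2.mean() - analytic) < 0.05


class TestSuvMax:
    def test_constant_image(self):
        g = GridGeometry.isotropic((5, 5, 5))
        img = SuvImage(values=np.full(g.shape, 2.0), tracer="FMISO", geometry=g)
        assert suv_max(img, RoiMask(np.ones(g.shape, bool), "GTV-T", g)) == 2.0

    def test_max_within_mask_only(self):
        g = GridGeometry.isotropic((5, 5, 5))
        values = np.ones(g.shape)
        values[0, 0, 0] = 9.0   # outside mask
        values[2, 2, 2] = 3.5
        mask = np.zeros(g.shape, bool)
        mask[2, 2, :] = True
        img = SuvImage(values=values, tracer="FMISO", geometry=g)
        assert suv_max(img, RoiMask(mask, "GTV-T", g)) == 3.5

    def test_empty_mask_rejected(self):
        g = GridGeometry.isotropic((5, 5, 5))
        img = SuvImage(values=np.ones(g.shape), tracer="FMISO", geometry=g)
        with pytest.raises(ValueError, match="empty"):
            suv_max(img, RoiMask(np.zeros(g.shape, bool), "GTV-T", g))


class TestCorrelationEndpoints:
    def _endpoints(self, n=8, collinear=False, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            fm = rng.uniform(1.5, 3.0)
            rows.append({"patient": f"p{i}", "week": 0, "structure": "GTV-T",
                         "fmiso_ratio": fm,
                         "fdg_ratio": 2 * fm + 1 if collinear else rng.uniform(3, 9),
                         "t2star_mean": rng.uniform(14, 22)})
            rows.append({"patient": f"p{i}", "week": 0, "structure": "GTV-LN",
                         "fmiso_ratio": rng.uniform(1.5, 3.0),
                         "fdg_ratio": rng.uniform(3, 9),
                         "t2star_mean": rng.uniform(14, 22)})
        return pd.DataFrame(rows)

    def test_collinear_endpoints_give_r2_one(self):
        out = correlation_endpoints(self._endpoints(collinear=True), week=0)
        row = out[(out.structure == "GTV-T") & (out.pair == "FMISO-vs-FDG")]
        assert row["r_squared"].item() == pytest.approx(1.0)

    def test_rows_per_structure_and_pair(self):
        out = correlation_endpoints(self._endpoints(), week=0)
        assert len(out) == 4  # 2 structures x (T2*, FDG)
        assert set(out["pair"]) == {"FMISO-vs-T2*", "FMISO-vs-FDG"}

    def test_insufficient_cases_flagged(self):
        df = self._endpoints(n=2)
        out = correlation_endpoints(df, week=0)
        assert (out["error"] == "insufficient complete cases").all()
        assert out["r_squared"].isna().all()

    def test_fdg_pair_absent_when_fdg_missing(self):
        df = self._endpoints()
        df["week"] = 2
        df["fdg_ratio"] = np.nan
        out = correlation_endpoints(df, week=2)
        assert set(out["pair"]) == {"FMISO-vs-T2*"}
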