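"""M-A normalization and the exact conditional count test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from bivalstate import (
    MAnormScaler,
    call_differential,
    exact_count_pvalue,
    ma_transform,
    null_count_log_pmf,
)


class TestMATransform:
    def test_basic_log2_arithmetic(self):
        M, A = ma_transform(4.0, 1.0, pseudocount=0.0)
        assert M == pytest.approx(2.0) and A == pytest.approx(1.0)

    def test_equal_inputs_give_zero_m(self):
        for c in (0.5, 1.0, 2.0):
            M, _ = ma_transform(3.7, 3.7, pseudocount=c)
            assert M == 0.0

    def test_double_zero_with_unit_pseudocount(self):
        M, A = ma_transform(0.0, 0.0, pseudocount=1.0)
        assert M == 0.0 and A == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ma_transform(-1.0, 2.0)


class TestExactCountTest:
    def test_zero_zero_is_one(self):
        assert exact_count_pvalue(0, 0) == 1.0

    def test_more_imbalance_smaller_p_at_fixed_total(self):
        assert exact_count_pvalue(10, 0) < exact_count_pvalue(6, 4)

    def test_symmetry_on_grid(self):
        g = np.arange(201)
        x1, x2 = np.meshgrid(g, g, indexing="ij")
        p = exact_count_pvalue(x1, x2)
        assert np.abs(p - p.T).max() < 1e-12

    def test_null_pmf_sums_to_one(self):
        """sum_y P(y | x1) = 1 within 1e-9 for every x1 <= 200."""
        y = np.arange(0, 6000)
        for x1 in range(0, 201):
            total = np.exp(logsumexp(null_count_log_pmf(y, x1)))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_pmf_matches_closed_form_small_counts(self):
        from math import factorial

        for x in range(6):
            for y in range(6):
                expected = factorial(x + y) / (
                    factorial(x) * factorial(y) * 2 ** (x + y + 1)
                )
                assert np.exp(null_count_log_pmf(y, x)) == pytest.approx(expected)

    def test_agrees_with_scipy_binomtest(self):
        from scipy.stats import binomtest

        rng = np.random.default_rng(0)
        for _ in range(50):
            x1, x2 = rng.integers(0, 200, size=2)
            expected = binomtest(int(x1), int(x1 + x2), 0.5).pvalue if x1 + x2 else 1.0
            assert exact_count_pvalue(int(x1), int(x2)) == pytest.approx(
                min(1.0, expected), rel=1e-9
            )

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            exact_count_pvalue(1.5, 2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            exact_count_pvalue(-1, 2)

    def test_null_calibration(self):
        """Type-I error at p<0.05 on equal-mean Poisson pairs in [0.03, 0.07]."""
        rng = np.random.default_rng(42)
        fractions = []
        for _ in range(10):
            x1 = rng.poisson(50, 5000)
            x2 = rng.poisson(50, 5000)
            fractions.append((exact_count_pvalue(x1, x2) < 0.05).mean())
        assert 0.03 <= np.mean(fractions) <= 0.07


class TestMAnormScaler:
    def test_global_2x_scaling_recovered(self):
        rng = np.random.default_rng(1)
        x1 = rng.uniform(5, 200, size=300)
        X = np.column_stack([x1, 2 * x1])
        scaler = MAnormScaler().fit(X)
        assert scaler.scale_factor_ == pytest.approx(2.0, rel=0.01)
        Xn = scaler.transform(X)
        lfc = np.log2(Xn[:, 0] / Xn[:, 1])
        assert np.abs(lfc).max() < 1e-6
        assert abs(scaler.median_m_) <= 0.05

    def test_identical_conditions_give_null_model(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 100, size=100)
        scaler = MAnormScaler().fit(np.column_stack([x, x]))
        assert abs(scaler.intercept_) < 1e-9 and abs(scaler.slope_) < 1e-9

    def test_idempotent_on_normalized_data(self):
        rng = np.random.default_rng(3)
        x1 = rng.uniform(5, 100, size=200)
        X = np.column_stack([x1, 3.0 * x1])
        Xn = MAnormScaler().fit(X).transform(X)
        refit = MAnormScaler().fit(Xn)
        assert abs(refit.intercept_) < 1e-6 and abs(refit.slope_) < 1e-6

    def test_too_few_common_points(self):
        X = np.column_stack([np.arange(5) + 1.0, np.arange(5) + 2.0])
        with pytest.raises(ValueError, match="common"):
            MAnormScaler().fit(X)

    def test_constant_a_rejected(self):
        X = np.tile([4.0, 4.0], (50, 1))
        with pytest.raises(ValueError, match="degenerate"):
            MAnormScaler().fit(X)

    def test_robust_pass_ignores_changed_outliers(self):
        rng = np.random.default_rng(4)
        x1 = rng.uniform(20, 200, size=500)
        x2 = 2.0 * x1
        changed = rng.choice(500, size=25, replace=False)
        x2[changed] *= 8.0
        scaler = MAnormScaler().fit(np.column_stack([x1, x2]))
        assert scaler.scale_factor_ == pytest.approx(2.0, rel=0.02)


class TestCallDifferential:
    def _series(self, values, prefix="g"):
        return pd.Series(
            values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float
        )

    def test_significance_rule(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(30, 300, size=400)
        x2 = base.copy()
        x1 = base.copy()
        x1[:20] *= 4.0  # strong up changes
        res = call_differential(self._series(x1), self._series(x2))
        assert (res["direction"].iloc[:20] == "up").mean() > 0.9
        assert (
            res["significant"]
            == ((res["p_value"] < 0.05) & (res["log2FC"].abs() >= 0.58))
        ).all()

    def test_fc_boundary_inclusive_p_strict(self):
        # synthetic result frame via the public invariant: |lfc| >= 0.58
        # inclusive, p < 0.05 strict
        res = pd.DataFrame(
            {
                "log2FC": [0.60, 0.50, -0.58, 0.60],
                "p_value": [0.01, 0.001, 0.04, 0.05],
            }
        )
        sig = (res["p_value"] < 0.05) & (res["log2FC"].abs() >= 0.58)
        assert sig.tolist() == [True, False, True, False]

    def test_mismatched_universes_error(self):
        a = self._series(np.arange(20) + 10.0)
        b = self._series(np.arange(20) + 10.0, prefix="h")
        with pytest.raises(ValueError, match="universes"):
            call_differential(a, b)

    def test_gene_subset_restricts_output(self):
        rng = np.random.default_rng(6)
        x = self._series(rng.uniform(10, 100, size=50))
        res = call_differential(x, x * 1.0, genes={f"g{i}" for i in range(30)})
        assert len(res) == 30

    def test_fdr_flag_adds_q_values(self):
        rng = np.random.default_rng(7)
        x = self._series(rng.uniform(10, 100, size=60))
        res = call_differential(x, x.sample(frac=1.0).sort_index(), fdr=True)
        assert "q_value" in res.columns
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()


class TestPlantedPower:
    def test_lfc1_changes_detected(self):
        """Planted 2-fold changes at base intensity >= 20 are called
        significant under p<0.05 and |log2FC|>=0.58 in >= 90% of genes."""
        rng = np.random.default_rng(11)
        n = 1000
        mu = np.exp(rng.uniform(np.log(20), np.log(200), size=n))
        x1 = rng.poisson(2 * mu).astype(float)
        x2 = rng.poisson(mu).astype(float)
        # mostly-unchanged background so the normalization sees null genes
        bg = np.exp(rng.uniform(np.log(20), np.log(200), size=9 * n))
        x1 = np.concatenate([x1, rng.poisson(bg).astype(float)])
        x2 = np.concatenate([x2, rng.poisson(bg).astype(float)])
        idx = [f"g{i}" for i in range(10 * n)]
        res = call_differential(
            pd.Series(x1, index=idx), pd.Series(x2, index=idx)
        )
        detected = res["significant"].iloc[:n].mean()
        assert detected >= 0.90


@given(
    st.integers(0, 80),
    st.integers(0, 80),
)
@settings(max_examples=200, deadline=None)
def test_pvalue_bounds_and_symmetry_property(x1, x2):
    p = exact_count_pvalue(x1, x2)
    assert 0 < p <= 1
    assert p == exact_count_pvalue(x2, x1)
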