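"""CBS classification, transitions, switch-expression coupling, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bivalstate import (
    CBSClassifier,
    SimulationConfig,
    StateAssignment,
    assign_states,
    bivalency_expression_correlation,
    classify_cbs,
    kmeans_crosscheck,
    simulate_chip,
    simulate_genome,
    switch_expression_fraction,
    transition_table,
)
from bivalstate.states import (
    CLUSTER_I,
    CLUSTER_II,
    CLUSTER_III,
    NONBIVALENT,
)


class TestClassifyCbs:
    def test_k4_high(self):
        assert classify_cbs(3.0, 1.5, pseudocount=0.0) == CLUSTER_I

    def test_k27_high(self):
        assert classify_cbs(1.0, 1.6, pseudocount=0.0) == CLUSTER_II

    def test_boundary_ratio_exactly_1_5_is_high_cluster(self):
        # inclusive threshold on both sides
        assert classify_cbs(1.5, 1.0, pseudocount=0.0) == CLUSTER_I
        assert classify_cbs(1.0, 1.5, pseudocount=0.0) == CLUSTER_II

    def test_near_equal_is_cluster_iii(self):
        assert classify_cbs(5.0, 5.0) == CLUSTER_III

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            classify_cbs(-1.0, 2.0)

    @given(
        st.floats(0.01, 1e4, allow_nan=False),
        st.floats(0.01, 1e4, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_partition_and_swap_symmetry(self, k4, k27):
        """Exactly one label per pair; swapping marks swaps I and II and
        fixes III."""
        lab = classify_cbs(k4, k27)
        swapped = classify_cbs(k27, k4)
        assert lab in {CLUSTER_I, CLUSTER_II, CLUSTER_III}
        expected = {
            CLUSTER_I: CLUSTER_II,
            CLUSTER_II: CLUSTER_I,
            CLUSTER_III: CLUSTER_III,
        }[lab]
        assert swapped == expected


class TestRecovery:
    def _recovery(self, sigma: float) -> float:
        ann = simulate_genome(2000, seed=13)
        cfg = SimulationConfig(n_genes=2000, noise_sigma=sigma, seed=13)
        chip = simulate_chip(ann, cfg)
        truth = chip.truth
        biv = truth.bivalent_genes
        sa = assign_states(
            chip.signal["A"].column("H3K4me3"),
            chip.signal["A"].column("H3K27me3"),
            biv,
            condition="A",
        )
        mapping = {"K4_HIGH": CLUSTER_I, "K27_HIGH": CLUSTER_II, "EQUAL": CLUSTER_III}
        planted = truth.table.loc[sorted(biv), "state_a"].map(mapping)
        return float((sa.labels.loc[sorted(biv)] == planted).mean())

    def test_perfect_at_zero_noise(self):
        assert self._recovery(0.0) == 1.0

    def test_at_least_95pct_at_sigma_03(self):
        assert self._recovery(0.3) >= 0.95


class TestTransitions:
    def _assign(self, cond, mapping):
        return StateAssignment(cond, pd.Series(mapping))

    def test_counts(self):
        a = self._assign("A", {"g1": CLUSTER_II, "g2": CLUSTER_III, "g3": CLUSTER_I})
        b = self._assign("B", {"g1": CLUSTER_I, "g2": CLUSTER_I, "g3": CLUSTER_I})
        t = transition_table(a, b)
        assert t.counts.loc[CLUSTER_II, CLUSTER_I] == 1
        assert t.counts.loc[CLUSTER_III, CLUSTER_I] == 1
        assert t.counts.loc[CLUSTER_I, CLUSTER_I] == 1
        assert t.counts.to_numpy().sum() == 3

    def test_one_sided_gene_becomes_nonbivalent(self):
        a = self._assign("A", {"g1": CLUSTER_I, "g2": CLUSTER_II})
        b = self._assign("B", {"g1": CLUSTER_I})
        t = transition_table(a, b)
        assert t.counts.loc[CLUSTER_II, NONBIVALENT] == 1

    def test_identical_assignments_are_diagonal(self):
        m = {"g1": CLUSTER_I, "g2": CLUSTER_II, "g3": CLUSTER_III}
        t = transition_table(self._assign("A", m), self._assign("B", m))
        off_diag = t.counts.to_numpy().sum() - np.trace(t.counts.to_numpy())
        assert off_diag == 0

    def test_row_sums_conserve_condition_a_counts(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([CLUSTER_I, CLUSTER_II, CLUSTER_III], size=50)
        labels2 = rng.choice([CLUSTER_I, CLUSTER_II, CLUSTER_III], size=50)
        idx = [f"g{i}" for i in range(50)]
        a = self._assign("A", dict(zip(idx, labels)))
        b = self._assign("B", dict(zip(idx, labels2)))
        t = transition_table(a, b)
        row_sums = t.counts.sum(axis=1)
        for lab, n in a.counts().items():
            assert row_sums[lab] == n

    def test_disjoint_universes_error(self):
        a = self._assign("A", {"g1": CLUSTER_I})
        b = self._assign("B", {"h1": CLUSTER_I})
        with pytest.raises(ValueError, match="share no genes"):
            transition_table(a, b)


class TestSwitchExpression:
    def _table(self, froms, tos):
        idx = [f"g{i}" for i in range(len(froms))]
        a = StateAssignment("A", pd.Series(dict(zip(idx, froms))))
        b = StateAssignment("B", pd.Series(dict(zip(idx, tos))))
        return transition_table(a, b)

    def test_9_of_10_up(self):
        t = self._table([CLUSTER_II] * 10, [CLUSTER_I] * 10)
        lfc = pd.Series([1.0] * 9 + [-1.0], index=[f"g{i}" for i in range(10)])
        frac, n = switch_expression_fraction(t, lfc)
        assert frac == pytest.approx(0.9) and n == 10

    def test_no_switch_genes_errors(self):
        t = self._table([CLUSTER_I] * 3, [CLUSTER_I] * 3)
        lfc = pd.Series(1.0, index=[f"g{i}" for i in range(3)])
        with pytest.raises(ValueError, match="switch"):
            switch_expression_fraction(t, lfc)

    def test_missing_expression_errors(self):
        t = self._table([CLUSTER_III], [CLUSTER_I])
        with pytest.raises(ValueError, match="lack expression"):
            switch_expression_fraction(t, pd.Series(dtype=float))


class TestCorrelation:
    def test_exact_linear(self):
        x = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        res = bivalency_expression_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res = bivalency_expression_correlation(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        """Five fixed points: r agrees with the closed-form sum computation
        to 1e-12."""
        xv = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        yv = np.array([0.3, -1.2, 2.5, 3.1, 8.0])
        n = 5
        direct = (n * (xv * yv).sum() - xv.sum() * yv.sum()) / np.sqrt(
            (n * (xv**2).sum() - xv.sum() ** 2) * (n * (yv**2).sum() - yv.sum() ** 2)
        )
        idx = [f"g{i}" for i in range(5)]
        res = bivalency_expression_correlation(
            pd.Series(xv, index=idx), pd.Series(yv, index=idx)
        )
        assert res.r == pytest.approx(direct, abs=1e-12)
        assert res.n == 5 and 0 < res.p_value <= 1

    def test_zero_variance_errors(self):
        idx = [f"g{i}" for i in range(5)]
        x = pd.Series(1.0, index=idx)
        y = pd.Series(np.arange(5.0), index=idx)
        with pytest.raises(ValueError, match="variance"):
            bivalency_expression_correlation(x, y)

    def test_too_few_points_errors(self):
        idx = ["g0", "g1"]
        with pytest.raises(ValueError, match=">= 3"):
            bivalency_expression_correlation(
                pd.Series([1.0, 2.0], index=idx), pd.Series([2.0, 1.0], index=idx)
            )


class TestKmeansCrosscheck:
    def test_agreement_with_threshold_rule(self):
        ann = simulate_genome(1500, seed=21)
        cfg = SimulationConfig(n_genes=1500, noise_sigma=0.3, seed=21)
        chip = simulate_chip(ann, cfg)
        agreement = kmeans_crosscheck(
            chip.signal["A"].column("H3K4me3"),
            chip.signal["A"].column("H3K27me3"),
            chip.truth.bivalent_genes,
            seed=0,
        )
        assert agreement >= 0.90
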