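import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from axonedit.differential import (
    CALL_A_HIGHER,
    CALL_B_HIGHER,
    CALL_NO_CHANGE,
    bh_adjust,
    call_sites,
    differential_test,
    one_tailed_t_pair,
    paired_one_tailed,
    summarize_differential,
    welch_one_tailed,
)
from axonedit.model import CompartmentDesign, ThresholdConfig, ValidationError
from axonedit.simulate import CompartmentSimSpec, simulate_compartment_counts


def welch_oracle(a, b):
    """Textbook Welch computation, independent of the package path."""
    a, b = list(a), list(b)
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2**0.5
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


class TestOneTailedPair:
    A = [0.5, 0.6, 0.55, 0.65]
    B = [0.10, 0.20, 0.15, 0.12]

    def test_matches_textbook_welch(self):
        t, df = welch_oracle(self.A, self.B)
        p_a, p_b = one_tailed_t_pair(self.A, self.B)
        assert p_a == pytest.approx(float(stats.t.sf(t, df)), rel=1e-12)
        assert p_b == pytest.approx(float(stats.t.cdf(t, df)), rel=1e-12)
        assert p_a < 0.01
        assert p_b > 0.99

    def test_identical_vectors_give_half(self):
        p_a, p_b = one_tailed_t_pair(self.A, self.A)
        assert p_a == pytest.approx(0.5)
        assert p_b == pytest.approx(0.5)

    def test_swapping_groups_swaps_pvalues(self):
        p_a, p_b = one_tailed_t_pair(self.A, self.B)
        q_a, q_b = one_tailed_t_pair(self.B, self.A)
        assert p_a == pytest.approx(q_b, rel=1e-12)
        assert p_b == pytest.approx(q_a, rel=1e-12)

    def test_tails_are_complementary(self):
        p_a, p_b = one_tailed_t_pair(self.A, self.B)
        assert p_a + p_b == pytest.approx(1.0)

    def test_degenerate_equal_constants(self):
        p_a, p_b = one_tailed_t_pair([0.3, 0.3], [0.3, 0.3])
        assert (p_a, p_b) == (0.5, 0.5)

    def test_degenerate_different_constants(self):
        p_a, p_b = one_tailed_t_pair([0.9, 0.9], [0.1, 0.1])
        assert (p_a, p_b) == (0.0, 1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            one_tailed_t_pair([0.5], [0.1, 0.2])

    def test_matches_scipy_reference(self, rng):
        a = rng.random((20, 4))
        b = rng.random((20, 4))
        p_a, p_b = welch_one_tailed(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False, alternative="greater")
        np.testing.assert_allclose(p_a, ref.pvalue, rtol=1e-10)

    def test_paired_matches_scipy(self, rng):
        a = rng.random((20, 4))
        b = rng.random((20, 4))
        p_a, _ = paired_one_tailed(a, b)
        ref = stats.ttest_rel(a, b, axis=1, alternative="greater")
        np.testing.assert_allclose(p_a, ref.pvalue, rtol=1e-10)


def bh_brute(p):
    """Direct step-up definition: q_i = min_{j: p_(j)>=p_(i)} p_(j)*m/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = min(min(p[order[k]] * m / (k + 1) for k in range(rank, m)), 1.0)
    return q


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0

    def test_matches_brute_force_random(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(bh_adjust(p), bh_brute(p), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        q = bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-15) | np.isclose(q, 1.0)).all()
        assert (q <= 1.0).all()
        # order preservation: smaller p never gets larger q
        idx = np.argsort(p, kind="mergesort")
        assert (np.diff(q[idx]) >= -1e-15).all()


class TestCallSites:
    def _results(self, p_a, p_b):
        return pd.DataFrame(
            {
                "p_a_greater": p_a,
                "p_b_greater": p_b,
                "delta": np.zeros(len(p_a)),
            }
        )

    def test_boundary_q_equal_fdr_is_called(self):
        out = call_sites(self._results([0.1], [0.9]), ThresholdConfig())
        assert out.call.iloc[0] == CALL_A_HIGHER

    def test_just_above_fdr_is_no_change(self):
        out = call_sites(self._results([0.11], [0.89]), ThresholdConfig())
        assert out.call.iloc[0] == CALL_NO_CHANGE

    def test_all_p_one_no_calls(self):
        out = call_sites(self._results([1.0] * 5, [0.5] * 5), ThresholdConfig())
        assert (out.call != CALL_A_HIGHER).all()

    def test_tails_adjusted_separately(self):
        out = call_sites(
            self._results([0.001, 0.9, 0.99], [0.999, 0.5, 0.01]), ThresholdConfig()
        )
        # BH over p_a: q = [0.003, 1, 1]; over p_b: q = [1, 0.75, 0.03]
        assert out.call.iloc[0] == CALL_A_HIGHER
        assert out.call.iloc[1] == CALL_NO_CHANGE
        assert out.call.iloc[2] == CALL_B_HIGHER


class TestDifferentialPipeline:
    def test_planted_signal_recovered(self):
        spec = CompartmentSimSpec(
            n_sites=400,
            frac_a_higher=1.0,
            delta_range=(0.25, 0.35),
            base_level_range=(0.1, 0.4),
            coverage_mean=200.0,
            seed=21,
        )
        _, counts, design, _ = simulate_compartment_counts(spec)
        res = differential_test(counts, design)
        summary = summarize_differential(res)
        # strong signal: high power, essentially no wrong-direction calls
        assert summary["n_a_higher_significant"] / summary["n_sites_tested"] > 0.9
        assert summary["n_b_higher_significant"] <= 2

    def test_partition_always_exact(self):
        spec = CompartmentSimSpec(n_sites=300, seed=3)
        _, counts, design, _ = simulate_compartment_counts(spec)
        summary = summarize_differential(differential_test(counts, design))
        assert (
            summary["n_a_higher_significant"]
            + summary["n_b_higher_significant"]
            + summary["n_no_change"]
            == summary["n_sites_tested"]
        )

    def test_missing_sample_errors(self):
        spec = CompartmentSimSpec(n_sites=20, seed=3)
        _, counts, design, _ = simulate_compartment_counts(spec)
        bad = CompartmentDesign(
            design.compartment_a_samples + ("ghost",), design.compartment_b_samples
        )
        with pytest.raises(ValidationError, match="ghost"):
            differential_test(counts, bad)

    def test_paired_variant_runs(self):
        spec = CompartmentSimSpec(n_sites=50, seed=13)
        _, counts, design, _ = simulate_compartment_counts(spec)
        res = differential_test(counts, design, paired=True)
        assert {"q_a_greater", "q_b_greater", "call"} <= set(res.columns)

    def test_summary_raw_direction(self):
        res = pd.DataFrame(
            {
                "delta": [0.1] * 9 + [-0.1],
                "call": [CALL_NO_CHANGE] * 10,
            }
        )
        s = summarize_differential(res)
        assert s["fraction_a_higher_raw"] == pytest.approx(0.9)
        assert s["n_a_higher_raw"] == 9

    def test_summary_all_zero_deltas(self):
        res = pd.DataFrame({"delta": [0.0] * 4, "call": [CALL_NO_CHANGE] * 4})
        s = summarize_differential(res)
        assert s["n_a_higher_raw"] == 0
        assert s["n_ties_raw"] == 4

    def test_histogram_counts_sum_to_n(self):
        res = pd.DataFrame(
            {"delta": np.linspace(-0.9, 0.9, 37), "call": [CALL_NO_CHANGE] * 37}
        )
        s = summarize_differential(res)
        assert sum(s["delta_histogram"]["counts"]) == 37
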