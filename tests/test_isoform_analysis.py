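"""Junction-read binomial test, fold-changes and filtering."""

import io
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptbseq.isoform_analysis import (
    LARGE,
    JunctionEvent,
    UntestableEventError,
    bayes_factor_to_null_probability,
    binomial_isoform_test,
    call_differential_isoforms,
    isoform_fold_change,
    isoform_fraction,
    log_odds_from_p,
    read_junction_counts,
    write_isoform_calls,
    write_junction_counts,
)
from ptbseq.synthetic_data import SimConfig, simulate_junction_counts

from _oracles import binomial_pvalue_oracle


def event(a_inc, a_exc, b_inc, b_exc, event_id="e"):
    return JunctionEvent(event_id, "g", "skipped_exon", a_inc, a_exc, b_inc, b_exc)


class TestIsoformFraction:
    @pytest.mark.parametrize(
        "inc,exc,expected", [(30, 10, 0.75), (0, 7, 0.0), (7, 0, 1.0)]
    )
    def test_ratio(self, inc, exc, expected):
        assert isoform_fraction(inc, exc) == expected

    def test_zero_reads_is_untestable(self):
        with pytest.raises(UntestableEventError):
            isoform_fraction(0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            isoform_fraction(-1, 5)


class TestBinomialTest:
    def test_symmetric_null_observation_gives_p_one(self):
        p, log_odds = binomial_isoform_test(event(5, 5, 5, 5))
        assert p == 1.0
        assert log_odds == 0.0

    def test_complete_separation_small_counts(self):
        # pooled p_hat = 0.5; one tail = P(X <= 0 | Bin(20, 0.5)) = 2^-20, doubled
        p, _ = binomial_isoform_test(event(20, 0, 0, 20))
        assert p == pytest.approx(2.0 * 0.5**20, rel=1e-12)

    def test_zero_inclusion_in_mutant(self):
        # mirrors a 27% vs 0% alternative 5'SS pattern
        p, _ = binomial_isoform_test(event(27, 73, 0, 100))
        assert p == pytest.approx(binomial_pvalue_oracle(27, 73, 0, 100), abs=1e-12)

    @pytest.mark.parametrize(
        "counts",
        [(5, 5, 5, 5), (20, 0, 0, 20), (27, 73, 0, 100), (3, 0, 0, 2), (1, 9, 9, 1), (0, 8, 4, 4)],
    )
    def test_agrees_with_pmf_summation_oracle(self, counts):
        p, _ = binomial_isoform_test(event(*counts))
        assert p == pytest.approx(binomial_pvalue_oracle(*counts), abs=1e-12)

    def test_untestable_event_raises(self):
        with pytest.raises(UntestableEventError):
            binomial_isoform_test(event(0, 0, 5, 5))

    def test_one_sided_alternatives_bracket_two_sided(self):
        ev = event(30, 10, 10, 30)
        two, _ = binomial_isoform_test(ev)
        less, _ = binomial_isoform_test(ev, alternative="less")
        greater, _ = binomial_isoform_test(ev, alternative="greater")
        assert less < greater
        assert two == pytest.approx(min(1.0, 2 * less))

    @given(n=st.integers(1, 80), b_inc=st.integers(0, 80))
    def test_swap_symmetry_at_balanced_pooled_fraction(self, n, b_inc):
        # the statistic tests the mutant library against the pooled
        # fraction; swapping conditions is an exact no-op whenever the
        # pooled fraction is 1/2 at equal library totals, where the
        # binomial tails mirror
        if b_inc > n:
            return
        ev = event(n - b_inc, b_inc, b_inc, n - b_inc)
        p_fwd, _ = binomial_isoform_test(ev)
        p_rev, _ = binomial_isoform_test(ev.swapped())
        assert p_fwd == pytest.approx(p_rev, abs=1e-12)

    @given(
        a_inc=st.integers(0, 60), a_exc=st.integers(0, 60),
        b_inc=st.integers(0, 60), b_exc=st.integers(0, 60),
    )
    def test_swapping_conditions_negates_delta_psi(self, a_inc, a_exc, b_inc, b_exc):
        ev = event(a_inc, a_exc, b_inc, b_exc)
        if not ev.testable:
            return
        (fwd,) = call_differential_isoforms([ev])
        (rev,) = call_differential_isoforms([ev.swapped()])
        assert fwd.delta_psi == pytest.approx(-rev.delta_psi, abs=1e-12)


class TestLogOdds:
    def test_bayes_factor_ten_maps_to_log_odds_one(self):
        assert log_odds_from_p(1.0 / 11.0) == pytest.approx(1.0)

    def test_p_of_one_maps_to_zero(self):
        assert log_odds_from_p(1.0) == 0.0

    def test_underflow_is_finite(self):
        assert math.isfinite(log_odds_from_p(0.0))
        assert log_odds_from_p(0.0) > 15


class TestFoldChange:
    @pytest.mark.parametrize(
        "psi_a,psi_b,expected",
        [(0.42, 0.20, 2.1), (0.5, 0.5, 1.0), (0.2, 0.42, 2.1), (0.0, 0.0, 1.0)],
    )
    def test_unsigned_ratio(self, psi_a, psi_b, expected):
        assert isoform_fold_change(psi_a, psi_b) == pytest.approx(expected)

    def test_single_zero_fraction_is_large(self):
        # a 27% vs 0% event has an unbounded fold-change
        assert isoform_fold_change(0.27, 0.0) == LARGE
        assert isoform_fold_change(0.0, 0.27) == LARGE

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            isoform_fold_change(1.2, 0.5)

    @given(
        psi_a=st.floats(0.01, 1.0), psi_b=st.floats(0.01, 1.0)
    )
    def test_fold_one_iff_equal_fractions(self, psi_a, psi_b):
        fold = isoform_fold_change(psi_a, psi_b)
        assert (fold == 1.0) == (psi_a == psi_b)
        assert fold >= 1.0


class TestBayesFactorConversion:
    def test_threshold_of_ten(self):
        assert bayes_factor_to_null_probability(10) == pytest.approx(0.0909, abs=5e-5)

    def test_even_odds(self):
        assert bayes_factor_to_null_probability(1) == 0.5

    def test_very_large_factor_is_reciprocal(self):
        assert bayes_factor_to_null_probability(1e9) == pytest.approx(1e-9, rel=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_to_null_probability(0)


class TestCallDifferentialIsoforms:
    def test_both_filters_must_pass(self):
        # large delta psi and strong evidence -> significant
        calls = call_differential_isoforms([event(80, 20, 20, 80, "big")])
        assert calls[0].significant
        # strong evidence but small delta psi -> filtered out
        calls = call_differential_isoforms([event(500, 500, 400, 600, "small_delta")])
        assert abs(calls[0].delta_psi) < 0.2
        assert calls[0].log_odds >= 1.0
        assert not calls[0].significant

    def test_untestable_events_flagged_not_dropped(self):
        calls = call_differential_isoforms([event(0, 0, 5, 5, "dead"), event(8, 2, 2, 8, "ok")])
        assert len(calls) == 2
        by_id = {c.event_id: c for c in calls}
        assert by_id["dead"].status == "untestable"
        assert not by_id["dead"].significant
        assert by_id["ok"].status == "ok"

    def test_sorted_by_descending_log_odds_then_event_id(self):
        calls = call_differential_isoforms(
            [event(5, 5, 5, 5, "b_null"), event(5, 5, 5, 5, "a_null"), event(80, 20, 20, 80, "strong")]
        )
        assert [c.event_id for c in calls] == ["strong", "a_null", "b_null"]

    def test_null_significant_rate_consistent_with_filter_level(self):
        events, _ = simulate_junction_counts(
            SimConfig(seed=11, n_events=100, depth=50, psi_pairs=[(0.5, 0.5)])
        )
        calls = call_differential_isoforms(events)
        n_sig = sum(c.significant for c in calls)
        # the log-odds >= 1 filter alone passes events with p <= 1/11; at
        # 100 events allow 3 binomial SEs above that level
        level = 1.0 / 11.0
        assert n_sig / 100 <= level + 3 * (level * (1 - level) / 100) ** 0.5

    def test_fdr_flag_attaches_adjusted_p_values(self):
        calls = call_differential_isoforms(
            [event(80, 20, 20, 80, "x"), event(5, 5, 5, 5, "y")], fdr=True
        )
        assert all(c.p_adjusted is not None for c in calls if c.status == "ok")
        assert all(c.p_adjusted >= c.p_value - 1e-15 for c in calls if c.status == "ok")


class TestTsvInterface:
    def test_round_trip_counts(self):
        events = [event(3, 4, 5, 6, "e1"), event(0, 1, 2, 0, "e2")]
        buf = io.StringIO()
        write_junction_counts(events, buf)
        buf.seek(0)
        assert read_junction_counts(buf) == events

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_junction_counts(io.StringIO("event_id\tgene_id\n1\t2\n"))

    def test_large_fold_change_serialized_as_literal(self):
        calls = call_differential_isoforms([event(27, 73, 0, 100, "cg")])
        buf = io.StringIO()
        write_isoform_calls(calls, buf)
        row = buf.getvalue().splitlines()[1].split("\t")
        assert row[8] == "Large"
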