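"""Error-rate formula, spectrum tallies, fidelity summary, rate intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from xnafidelity import (
    align_global,
    build_spectrum,
    call_mutations,
    error_rate,
    left_normalize_indels,
    rate_interval,
    simulate_dataset,
    summarize,
    uniform_model,
)
from xnafidelity.stats import SUBSTITUTION_TYPES, SpectrumTable, UndefinedRateError


class TestErrorRate:
    @pytest.mark.parametrize(
        "obs,exp,rate", [(0, 1000, 0.0), (2, 1000, 2.0), (3, 1500, 2.0)]
    )
    def test_formula(self, obs, exp, rate):
        assert error_rate(obs, exp) == pytest.approx(rate)

    @given(
        obs=st.integers(0, 100),
        exp=st.integers(100, 10**6),
        k=st.integers(1, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_scale_invariance(self, obs, exp, k):
        assert error_rate(k * obs, k * exp) == pytest.approx(error_rate(obs, exp))

    def test_zero_expected_is_not_estimable(self):
        with pytest.raises(UndefinedRateError):
            error_rate(0, 0)

    def test_observed_above_expected_rejected(self):
        with pytest.raises(ValueError):
            error_rate(5, 4)


class TestRateInterval:
    def test_zero_observed_lower_bound_is_zero(self):
        low, high = rate_interval(0, 1000)
        assert low == 0.0
        assert high > 0.0

    @given(obs=st.integers(0, 200), exp=st.integers(50, 10**5))
    @settings(max_examples=60, deadline=None)
    def test_contains_point_estimate(self, obs, exp):
        low, high = rate_interval(obs, exp)
        point = obs / exp * 1000.0
        assert low <= point <= high

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            rate_interval(1, 100, level=1.0)

    def test_coverage_at_least_nominal(self):
        """Monte-Carlo coverage of the exact Poisson interval at a true rate
        of 2 per 1000 over 10,000 replicates."""
        rng = np.random.default_rng(7)
        expected = 1000
        true_rate = 2.0
        counts = rng.poisson(true_rate / 1000 * expected, size=10_000)
        covered = 0
        for k, n in zip(*np.unique(counts, return_counts=True)):
            low, high = rate_interval(int(k), expected)
            covered += n * (low <= true_rate <= high)
        assert covered / 10_000 >= 0.95


def _passing_maps(design, records):
    alignments, events = {}, {}
    for rec in records:
        aln = left_normalize_indels(align_global(design.template, rec.sequence))
        alignments[rec.id] = aln
        events[rec.id] = call_mutations(aln, design)
    return events, alignments


class TestBuildSpectrum:
    def test_error_free_clones_give_balanced_expected(self, design):
        recs, _ = simulate_dataset(design, uniform_model(0.0), n=10, seed=1)
        events, alignments = _passing_maps(design, recs)
        spec = build_spectrum(events, alignments, design)
        assert spec.expected == {"A": 140, "C": 140, "G": 140, "T": 140}
        assert all(v == 0 for v in spec.observed.values())
        assert spec.total_positions == 560

    def test_single_event_tally(self, design):
        conv = design.converted_template()
        pos = next(p for p in range(*design.analysis_span) if conv[p] == "G")
        seq = conv[:pos] + "A" + conv[pos + 1 :]
        aln = left_normalize_indels(align_global(design.template, seq))
        spec = build_spectrum({"c": call_mutations(aln, design)}, {"c": aln}, design)
        assert spec.observed[("G", "A")] == 1
        assert sum(spec.observed.values()) == 1

    def test_matches_truth_table_tally(self, design):
        recs, truth = simulate_dataset(design, uniform_model(0.02), n=300, seed=12)
        events, alignments = _passing_maps(design, recs)
        spec = build_spectrum(events, alignments, design)
        for src, dst in SUBSTITUTION_TYPES:
            planted = sum(
                1
                for evs in truth.events.values()
                for e in evs
                if e.kind == "substitution" and (e.from_base, e.to_base) == (src, dst)
            )
            assert spec.observed[(src, dst)] == planted

    def test_deleted_positions_leave_expected(self, design):
        recs, truth = simulate_dataset(
            design, uniform_model(0.0, del_rate=0.05), n=50, seed=3
        )
        events, alignments = _passing_maps(design, recs)
        spec = build_spectrum(events, alignments, design)
        n_deleted = sum(
            e.length for evs in truth.events.values() for e in evs if e.kind == "deletion"
        )
        assert spec.total_positions == 50 * design.analysis_length - n_deleted
        assert spec.del_count == n_deleted


def _spectrum(observed=None, expected=None, ins=0, dele=0, passed=1, failed=0):
    obs = {t: 0 for t in SUBSTITUTION_TYPES}
    obs.update(observed or {})
    exp = {"A": 0, "C": 0, "G": 0, "T": 0}
    exp.update(expected or {})
    return SpectrumTable(
        observed=obs,
        expected=exp,
        ins_count=ins,
        del_count=dele,
        total_positions=sum(exp.values()),
        n_clones_passed=passed,
        n_clones_failed=failed,
    )


class TestSummarize:
    def test_all_zero_spectrum_is_perfect(self):
        report = summarize(_spectrum(expected={b: 1000 for b in "ACGT"}))
        assert report.mu_total == 0.0
        assert report.aggregate_fidelity_pct == 100.0
        assert all(v == 0.0 for v in report.mu.values())

    def test_worked_arithmetic(self):
        report = summarize(
            _spectrum(observed={("G", "A"): 2}, expected={b: 1000 for b in "ACGT"})
        )
        assert report.mu[("G", "A")] == pytest.approx(2.0)
        assert report.mu_total == pytest.approx(2.0)
        # (1 - 2/4000) * 100 = 99.95 exactly: round-half-even to one decimal
        # picks the even tenth, 100.0
        assert report.aggregate_fidelity_raw == pytest.approx(99.95)
        assert report.aggregate_fidelity_pct == 100.0

    def test_mu_total_is_sum_of_types(self):
        report = summarize(
            _spectrum(
                observed={("G", "A"): 2, ("A", "C"): 4, ("T", "G"): 1},
                expected={b: 500 for b in "ACGT"},
            )
        )
        assert report.mu_total == pytest.approx(
            sum(v for v in report.mu.values() if v is not None)
        )
        assert report.mu_total == pytest.approx((2 + 4 + 1) / 500 * 1000)

    def test_indel_bases_count_toward_fidelity_but_not_mu_total(self):
        report = summarize(
            _spectrum(expected={b: 1000 for b in "ACGT"}, ins=3, dele=2)
        )
        assert report.mu_total == 0.0
        assert report.indel_rate == pytest.approx(5 / 4000 * 1000)
        assert report.aggregate_fidelity_raw == pytest.approx((1 - 5 / 4000) * 100)

    def test_absent_source_base_not_estimable(self):
        report = summarize(_spectrum(expected={"A": 100, "C": 100, "G": 100}))
        assert report.mu[("T", "A")] is None
        assert report.ci[("T", "A")] is None

    def test_low_coverage_flag(self):
        report = summarize(_spectrum(expected={"A": 100}))
        assert report.low_coverage
        report = summarize(_spectrum(expected={b: 1000 for b in "ACGT"}))
        assert not report.low_coverage

    def test_empty_spectrum_rejected(self):
        with pytest.raises(UndefinedRateError):
            summarize(_spectrum())


@pytest.mark.parametrize("p_sub", [0.001, 0.003, 0.014, 0.021])
def test_parameter_recovery_at_assay_rates(design, p_sub):
    """The end-to-end substitution-rate estimate must sit within 3 binomial
    standard errors of the planted per-site probability.  On the balanced
    bundled design this is equivalently checked as mu_total/4000 (the 12
    per-opportunity rates sum to 4x the per-position rate when each base
    supplies a quarter of the opportunities)."""
    n = 2000  # 2000 x 56 = 112,000 sites: SE small enough to resolve all rates
    recs, _ = simulate_dataset(design, uniform_model(p_sub), n=n, seed=21)
    events, alignments = _passing_maps(design, recs)
    report = summarize(build_spectrum(events, alignments, design))
    sites = report.total_positions
    p_hat = 1.0 - report.aggregate_fidelity_raw / 100.0
    se = np.sqrt(p_sub * (1 - p_sub) / sites)
    assert abs(p_hat - p_sub) <= 3 * se
    assert report.mu_total / 4000.0 == pytest.approx(p_hat)
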