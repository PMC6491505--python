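"""Percept encoding, decision rules, d-prime, and the noise x difference
crossover of the precision-weighted observer."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from precistim.observer import (
    ObserverParams,
    Percept,
    cell_accuracies,
    decide_different,
    decide_faster,
    dprime,
    encode_percept,
    simulate_session,
    stimulus_noise_sd_hz,
)
from precistim.synthetic_data import GroupConfig, generate_schedule


class TestEncoding:
    def test_noise_free_limit_is_deterministic(self, rng):
        p = encode_percept(30.0, 0.0, ObserverParams(perceptual_sd=0.0), rng)
        assert p.value == 30.0 and p.known_sd == 0.0

    def test_known_sd_is_pythagorean_sum(self, rng):
        params = ObserverParams(perceptual_sd=3.0, stim_noise_coupling=1.0)
        p = encode_percept(30.0, 4.0, params, rng)
        assert p.known_sd == pytest.approx(5.0)

    def test_bias_shifts_mean_percept(self, rng):
        params = ObserverParams(perceptual_sd=1.0, bias=2.5)
        vals = [encode_percept(30.0, 0.0, params, rng).value
                for _ in range(4000)]
        assert np.mean(vals) == pytest.approx(32.5, abs=3 / np.sqrt(4000))

    def test_invalid_inputs_raise(self, rng):
        with pytest.raises(ValueError):
            encode_percept(-1.0, 0.0, ObserverParams(), rng)
        with pytest.raises(ValueError):
            encode_percept(30.0, -1.0, ObserverParams(), rng)

    def test_roughness_scales_with_frequency_and_cycle_count(self):
        # sd of the mean period over n cycles: f * noise / sqrt(f * dur)
        s = stimulus_noise_sd_hz(40.0, 0.08, 512.0)
        assert s == pytest.approx(0.08 * 40.0 / np.sqrt(40.0 * 0.512))


class TestFasterSlower:
    def test_sign_of_difference(self, rng):
        assert decide_faster(Percept(30.0, 1.0), Percept(33.0, 1.0), rng)
        assert not decide_faster(Percept(33.0, 1.0), Percept(30.0, 1.0), rng)

    def test_tie_broken_by_fair_coin(self, rng):
        picks = [decide_faster(Percept(30.0, 1.0), Percept(30.0, 1.0), rng)
                 for _ in range(2000)]
        assert 0.45 < np.mean(picks) < 0.55

    def test_accuracy_matches_gaussian_closed_form(self, rng):
        s1, s2, df = 1.0, 2.0, 1.5
        n = 20_000
        p1 = 30.0 + rng.normal(0, s1, n)
        p2 = 30.0 + df + rng.normal(0, s2, n)
        acc = np.mean(p2 > p1)
        expected = norm.cdf(df / np.hypot(s1, s2))
        assert acc == pytest.approx(expected, abs=3 * 0.5 / np.sqrt(n))


class TestSameDifferent:
    def test_boundary_equality_answers_same(self):
        params = ObserverParams(criterion=1.0)
        # pooled sd hypot(3, 4) = 5 and |dv| = 5 give |z| = c exactly -> "no"
        assert not decide_different(Percept(30.0, 3.0),
                                    Percept(35.0, 4.0), params)

    def test_zero_spread_zero_difference_is_same(self):
        params = ObserverParams(perceptual_sd=0.0, criterion=1.0)
        assert not decide_different(Percept(30.0, 0.0), Percept(30.0, 0.0),
                                    params)

    def test_wider_known_sd_suppresses_different_responses(self, rng):
        params = ObserverParams(criterion=1.0)
        narrow = [decide_different(Percept(30.0, 1.0),
                                   Percept(30.0 + d, 1.0), params)
                  for d in rng.normal(0, 1.5, 3000)]
        wide = [decide_different(Percept(30.0, 3.0),
                                 Percept(30.0 + d, 3.0), params)
                for d in rng.normal(0, 1.5, 3000)]
        assert np.mean(wide) < np.mean(narrow)

    def test_raw_difference_rule_uses_hz_criterion(self):
        params = ObserverParams(rule="raw_difference", criterion=2.0)
        assert decide_different(Percept(30.0, 5.0), Percept(33.0, 5.0), params)
        assert not decide_different(Percept(30.0, 5.0), Percept(31.0, 5.0),
                                    params)


class TestDprime:
    def test_chance_rates_give_zero(self):
        assert dprime(0.5, 0.5) == 0.0

    def test_one_sigma_rates_give_two(self):
        assert dprime(norm.cdf(1.0), norm.cdf(-1.0)) == pytest.approx(2.0)

    def test_edge_rates_corrected_to_finite_value(self):
        val = dprime(1.0, 0.0, n_trials=50)
        assert np.isfinite(val)
        assert val == pytest.approx(2 * norm.ppf(1 - 1 / 100), abs=1e-9)

    def test_edge_rates_without_n_raise(self):
        with pytest.raises(ValueError):
            dprime(1.0, 0.2)

    def test_invariant_to_criterion_shift_along_equal_variance_roc(self):
        d = 1.3
        for c in (-0.5, 0.0, 0.8):
            assert dprime(norm.cdf(d / 2 - c), norm.cdf(-d / 2 - c)) == \
                pytest.approx(d)


@pytest.fixture(scope="module")
def session_tables():
    """Same-different + fast-slow sessions for both decision rules."""
    sd_sched = generate_schedule(12000, GroupConfig(), seed=21)
    fs_sched = generate_schedule(4000, GroupConfig(context="fast_slow"),
                                 seed=22)
    pw = ObserverParams()  # precision-weighted
    raw = ObserverParams(rule="raw_difference",
                         criterion=float(np.sqrt(2.0)))  # matched operating point
    tables = {}
    for name, params in (("pw", pw), ("raw", raw)):
        tables[name] = pd.concat(
            [simulate_session(sd_sched, params, seed=31),
             simulate_session(fs_sched, params, seed=32)],
            ignore_index=True)
    return tables


class TestSession:
    def test_table_is_complete_and_reproducible(self):
        sched = generate_schedule(60, GroupConfig(), seed=5)
        a = simulate_session(sched, ObserverParams(), seed=8)
        b = simulate_session(sched, ObserverParams(), seed=8)
        assert len(a) == 60
        assert not a[["percept1", "percept2", "choice", "correct"]].isna().any().any()
        pd.testing.assert_frame_equal(a, b)

    def test_malformed_schedule_errors_name_the_row(self):
        bad = pd.DataFrame({"context": ["same_different"], "condition": ["x"],
                            "f1": [34.0], "f2": [34.0]})
        with pytest.raises(ValueError, match="row 0"):
            simulate_session(bad, ObserverParams(), seed=1)

    def test_fast_slow_more_accurate_than_same_different(self, session_tables):
        t = session_tables["pw"]
        fs = t[t.context == "fast_slow"].correct.mean()
        sd = t[t.context == "same_different"].correct.mean()
        assert fs > sd

    def test_fast_slow_accuracy_ignores_criterion(self):
        sched = generate_schedule(500, GroupConfig(context="fast_slow"), seed=3)
        a = simulate_session(sched, ObserverParams(criterion=0.2), seed=4)
        b = simulate_session(sched, ObserverParams(criterion=3.0), seed=4)
        assert (a.correct == b.correct).all()


class TestCellAccuracies:
    def test_precision_weighted_crossover(self, session_tables):
        acc = cell_accuracies(session_tables["pw"])
        assert acc["same_noisy"] > acc["same_regular"]
        assert acc["different_regular"] > acc["different_noisy"]
        assert acc["interaction"] > 0

    def test_raw_difference_rule_lacks_same_noisy_benefit(self, session_tables):
        # verbatim jitter reuse cancels from the raw difference, so the raw
        # rule shows no same-trial noise benefit (3-sigma Monte-Carlo margin),
        # while the precision-weighted rule shows a clear one
        raw = cell_accuracies(session_tables["raw"])
        pw = cell_accuracies(session_tables["pw"])
        raw_benefit = raw["same_noisy"] - raw["same_regular"]
        pw_benefit = pw["same_noisy"] - pw["same_regular"]
        assert raw_benefit < 0.035
        assert pw_benefit > raw_benefit + 0.02

    def test_fast_slow_dprime_exceeds_same_different(self, session_tables):
        acc = cell_accuracies(session_tables["pw"])
        assert acc["dprime_fast_slow"] > acc["dprime_same_different"]

    def test_missing_cell_raises_with_cell_name(self):
        sched = generate_schedule(40, GroupConfig(), seed=2)
        t = simulate_session(sched, ObserverParams(), seed=2)
        t = t[~((t.condition == "noisy") & (t.truth == "same"))]
        with pytest.raises(ValueError, match="noisy"):
            cell_accuracies(t)
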