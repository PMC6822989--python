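import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from striaseq import psth, units
from striaseq.config import RESPONSE_WINDOWS, AnalysisConfig
from striaseq.core_data import Unit


def brute_force_align(spikes, events, window, bin_width, n_bins):
    """O(n*m) interval-membership oracle for event-aligned binning."""
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_width
    out = np.zeros((len(events), n_bins), dtype=int)
    for i, ev in enumerate(events):
        for s in spikes:
            rel = s - ev
            for j in range(n_bins):
                if edges[j] <= rel < edges[j + 1]:
                    out[i, j] += 1
    return out


class TestAlign:
    def test_no_spikes_gives_zero_matrix(self):
        out = psth.align(np.array([]), [10.0, 20.0])
        assert out.shape == (2, 51) and not out.any()

    def test_single_spike_lands_in_correct_bin(self):
        # +5 ms falls in the center bin, which spans [-5, +5) ms
        out = psth.align(np.array([10.005]), [10.0])
        assert out.sum() == 1 and out[0, 26] == 1
        out = psth.align(np.array([10.0049]), [10.0])
        assert out[0, 25] == 1

    def test_half_open_bins(self):
        # the grid spans [-255, 255) ms: a spike exactly on the outer edge
        # is excluded, one exactly on the inner edge is included
        assert psth.align(np.array([10.255]), [10.0]).sum() == 0
        assert psth.align(np.array([9.745]), [10.0])[0, 0] == 1

    @given(
        n_spikes=st.integers(0, 60),
        n_events=st.integers(1, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle(self, n_spikes, n_events, seed):
        rng = np.random.default_rng(seed)
        spikes = np.sort(rng.uniform(0, 30, n_spikes))
        events = rng.uniform(1, 29, n_events)
        fast = psth.align(spikes, events, 0.25, 0.01, 51)
        slow = brute_force_align(spikes, events, 0.25, 0.01, 51)
        assert (fast == slow).all()

    def test_empty_event_list_is_an_error(self):
        with pytest.raises(ValueError, match="at least one event"):
            psth.align(np.array([1.0]), [])


class TestZscore:
    def test_rate_equal_to_baseline_mean_is_zero(self):
        assert psth.zscore(np.array([10.0]), (10.0, 2.0))[0] == 0.0

    def test_arithmetic(self):
        assert psth.zscore(np.array([14.0]), (10.0, 2.0))[0] == pytest.approx(2.0)

    def test_linear_in_rates(self, rng):
        rates = rng.uniform(0, 20, 50)
        z1 = psth.zscore(rates, (5.0, 2.0))
        z2 = psth.zscore(2 * rates, (5.0, 2.0))
        assert np.allclose(z2 - z1, rates / 2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="SD must be positive"):
            psth.zscore(np.array([1.0]), (1.0, 0.0))


class TestBaselineStats:
    def test_homogeneous_poisson_recovers_rate(self, rng):
        # constant 5 Hz unit over a fabricated 3-trial session
        from conftest import make_trial
        from striaseq.core_data import Session

        span = 400.0
        spikes = np.sort(rng.uniform(0, span, rng.poisson(5.0 * span)))
        trials = [make_trial(t0=100.0 * (i + 1)) for i in range(3)]
        s = Session("s", "DT5_early", 5, trials, [])
        u = Unit("u", "DLS", spikes, 5.0, 0.3)
        f_mean, f_sd = psth.baseline_stats(u, s)
        # 3 windows x 5 s at 5 Hz: SE of the mean ~ sqrt(5/15)
        assert abs(f_mean - 5.0) < 4 * np.sqrt(5.0 / 15.0)
        assert u.baseline_mean == f_mean

    def test_silent_unit_gives_zero_stats(self, small_session):
        u = Unit("mute", "DLS", np.array([]), 0.0, 0.3)
        f_mean, f_sd = psth.baseline_stats(u, small_session)
        assert f_mean == 0.0 and f_sd == 0.0
        assert units.baseline_filter(u) is False

    def test_mean_z_over_population_near_zero_for_null_units(self, rng):
        # z-scored PSTH of non-responsive units averages to ~0
        from striaseq.synthetic_data import CohortSpec, generate_session

        spec = CohortSpec(
            n_units={"DLS": 12, "DMS": 12},
            mixture={r: {"non_responsive": 1.0} for r in ("DLS", "DMS")},
            seed=21,
        )
        s = generate_session(spec, 0)
        zs = [
            psth.peri_event_matrix(u, s).concat_vector.mean() for u in s.units
        ]
        assert abs(np.mean(zs)) < 4 / np.sqrt(357 * len(zs))


class TestWindowResponseTest:
    def test_null_pvalues_are_uniform(self, rng):
        # same-distribution samples: KS test of the p-value distribution
        pvals = [
            psth.window_response_test(rng.normal(5, 1, 30), rng.normal(5, 1, 30))
            for _ in range(300)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_doubled_rate(self, rng):
        # +100% rate step, 30 trials: p < 0.01 in nearly all replicates
        hits = 0
        for _ in range(100)            :
            win = rng.poisson(10.0 * 0.25, 30) / 0.25
            base = rng.poisson(5.0 * 5.0, 30) / 5.0
            hits += psth.window_response_test(win, base) < 0.01
        assert hits >= 95

    def test_degenerate_zero_variance_returns_one(self):
        assert psth.window_response_test(np.ones(5), np.ones(8)) == 1.0

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            psth.window_response_test(np.array([1.0]), np.ones(5))


class TestDetectTrn:
    @pytest.fixture(scope="class")
    def sustained_session(self):
        from striaseq.synthetic_data import CohortSpec, generate_session

        spec = CohortSpec(
            stage="extended",
            n_units={"DLS": 4, "DMS": 4},
            mixture={
                r: {"sustained_exc": 0.5, "sustained_inh": 0.5}
                for r in ("DLS", "DMS")
            },
            seed=31,
        )
        return generate_session(spec, 0)

    def test_sustained_excitation_is_trn_exc(self, sustained_session, config):
        found = 0
        for u in sustained_session.units:
            if u.archetype != "sustained_exc":
                continue
            rec = psth.detect_trn(u, sustained_session, config)
            assert rec.trn and rec.sign == "EXC"
            found += 1
        assert found > 0

    def test_sign_of_negative_z_vector_is_inh(self, sustained_session, config):
        found = 0
        for u in sustained_session.units:
            if u.archetype != "sustained_inh":
                continue
            rec = psth.detect_trn(u, sustained_session, config)
            assert rec.trn and rec.sign == "INH"
            found += 1
        assert found > 0

    def test_twelve_windows_tested(self, small_session, config):
        u = small_session.units[0]
        rec = psth.detect_trn(u, small_session, config)
        assert rec.p_values.shape == (12,)
        assert len(RESPONSE_WINDOWS) == 12


def test_peri_event_matrix_shapes(small_pems, config):
    pem = small_pems[0]
    assert pem.counts.shape[1:] == (7, 51)
    assert pem.concat_vector.shape == (357,)
    assert pem.window_means(config).shape == (12,)


def test_alignment_invariant_to_event_order(rng):
    # relabeling trials permutes count-matrix rows, leaving the trial
    # average (hence the z-scores built from it) unchanged
    spikes = np.sort(rng.uniform(0, 100, 300))
    events = rng.uniform(5, 95, 10)
    perm = rng.permutation(10)
    a = psth.align(spikes, events)
    b = psth.align(spikes, events[perm])
    assert np.allclose(a[perm], b)
    assert np.allclose(a.mean(axis=0), b.mean(axis=0))
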