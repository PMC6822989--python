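import math

import numpy as np
import pytest
from scipy.integrate import quad

from striaseq.core_data import sessions_equal
from striaseq.synthetic_data import (
    ArchetypeSpec,
    CohortSpec,
    CouplingSpec,
    DEFAULT_ARCHETYPES,
    extended_cohort_spec,
    generate_cohorts,
    generate_session,
    rate_profile,
)
from striaseq import correlation

from conftest import make_trial
from dataclasses import replace


class TestRateProfile:
    def test_non_responsive_is_constant_baseline(self, trial):
        prof = rate_profile(DEFAULT_ARCHETYPES["non_responsive"], trial, baseline=5.0)
        t = np.linspace(0.0, 200.0, 1000)
        assert np.allclose(prof(t), 5.0)

    def test_sustained_exc_gain_doubles_rate_in_sequence(self, trial):
        arch = ArchetypeSpec("sustained_exc", modulation_gain=2.0)
        prof = rate_profile(arch, trial, baseline=5.0)
        mid_seq = 0.5 * (trial.first_press + trial.last_press)
        assert prof(np.array([mid_seq]))[0] == pytest.approx(10.0)
        # baseline window far before the trial
        assert prof(np.array([trial.lever_insertion - 30.0]))[0] == pytest.approx(5.0)

    def test_phasic_start_bump_integrates_to_expected_extra_spikes(self, trial):
        arch = replace(DEFAULT_ARCHETYPES["phasic_start"], rebound=0.0)
        b = 5.0
        prof = rate_profile(arch, trial, baseline=b)
        extra, _ = quad(
            lambda t: prof(np.array([t]))[0] - b,
            trial.lever_insertion - 1.0,
            trial.lever_insertion + 1.5,
            limit=200,
        )
        amp = arch.amp_z * math.sqrt(b / arch.z_norm_s)
        expected = amp * arch.peak_width * math.sqrt(2 * math.pi)
        assert extra == pytest.approx(expected, rel=1e-4)

    def test_rebound_cancels_the_stated_mass_fraction(self, trial):
        b = 20.0  # high baseline: the suppression depth cap does not bind
        arch = replace(DEFAULT_ARCHETYPES["phasic_start"], rebound=0.5, amp_z=2.0)
        prof = rate_profile(arch, trial, baseline=b)
        extra, _ = quad(
            lambda t: prof(np.array([t]))[0] - b,
            trial.lever_insertion - 2.0,
            trial.lever_insertion + 2.5,
            limit=400,
        )
        amp = arch.amp_z * math.sqrt(b / arch.z_norm_s)
        bump_mass = amp * arch.peak_width * math.sqrt(2 * math.pi)
        assert extra == pytest.approx(bump_mass * 0.5, rel=0.01)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="negative rate"):
            ArchetypeSpec("sustained_inh", modulation_gain=-0.5)

    def test_rate_never_negative(self, trial, rng):
        for name, arch in DEFAULT_ARCHETYPES.items():
            prof = rate_profile(arch, trial, baseline=3.0, rng=rng)
            t = np.linspace(trial.lever_insertion - 5, trial.lever_insertion + 10, 4000)
            assert (prof(t) >= 0).all(), name


class TestGenerateSession:
    def test_same_seed_gives_identical_sessions(self):
        spec = extended_cohort_spec(seed=4, n_units={"DLS": 3, "DMS": 3})
        assert sessions_equal(generate_session(spec, 2), generate_session(spec, 2))

    def test_different_session_index_differs(self):
        spec = extended_cohort_spec(seed=4, n_units={"DLS": 3, "DMS": 3})
        assert not sessions_equal(generate_session(spec, 0), generate_session(spec, 1))

    def test_non_responsive_unit_count_is_poisson_consistent(self):
        spec = CohortSpec(
            stage="extended",
            n_units={"DLS": 1, "DMS": 1},
            mixture={r: {"non_responsive": 1.0} for r in ("DLS", "DMS")},
            baseline_mu=math.log(5.0),
            baseline_sigma=1e-9,  # pin the baseline at 5 Hz
            seed=8,
        )
        s = generate_session(spec, 0)
        duration = max(u.spikes[-1] for u in s.units if len(u.spikes))
        span = s.trials[-1].reward_port_entry + spec.behavior.iti_duration
        for u in s.units:
            lam = 5.0 * span
            assert abs(len(u.spikes) - lam) < 4 * math.sqrt(lam)

    def test_empirical_rate_tracks_profile_in_windows(self):
        # Poisson thinning check: counts in 250 ms windows around the first
        # press match the profile integral across many trials
        arch = ArchetypeSpec("sustained_exc", modulation_gain=2.0)
        spec = CohortSpec(
            stage="extended",
            n_units={"DLS": 18, "DMS": 18},
            mixture={r: {"sustained_exc": 1.0} for r in ("DLS", "DMS")},
            archetypes={**DEFAULT_ARCHETYPES, "sustained_exc": arch},
            baseline_mu=math.log(5.0),
            baseline_sigma=1e-9,
            gain_jitter=1e-9,
            seed=9,
        )
        s = generate_session(spec, 0)
        counts, n_windows = 0, 0
        for u in s.units:
            for t in s.rewarded_trials:
                t0 = t.press_times[0] - 0.125
                counts += np.searchsorted(u.spikes, t0 + 0.25) - np.searchsorted(
                    u.spikes, t0
                )
                n_windows += 1
        lam = 10.0 * 0.25  # gain 2 on 5 Hz
        total = lam * n_windows
        assert abs(counts - total) < 4 * math.sqrt(total)

    def test_ground_truth_labels_present_for_every_unit(self, small_session):
        assert all(u.archetype for u in small_session.units)
        prov = small_session.provenance["archetypes"]
        assert set(prov) == {u.unit_id for u in small_session.units}

    def test_coupling_yields_negative_epoch_latency_correlation(self, config):
        # negative coupling of post-insertion firing with first-press
        # latency recovers a negative Spearman rho in nearly all units
        spec = CohortSpec(
            stage="extended",
            n_units={"DLS": 20, "DMS": 20},
            mixture={r: {"non_responsive": 1.0} for r in ("DLS", "DMS")},
            coupling=(
                CouplingSpec(
                    "non_responsive", "post_insertion", "first_press_latency", -1, 0.5
                ),
            ),
            seed=10,
        )
        s = generate_session(spec, 0)
        rhos = []
        for u in s.units:
            rec = correlation.unit_correlation(u, s, "first_press_latency", config)
            if np.isfinite(rec.rho):
                rhos.append(rec.rho)
        assert np.mean(np.array(rhos) < 0) >= 0.9

    def test_mixture_must_sum_to_one(self):
        spec = CohortSpec(
            mixture={"DLS": {"non_responsive": 0.7}, "DMS": {"non_responsive": 1.0}}
        )
        with pytest.raises(ValueError, match="sums to"):
            spec.validate()


def test_generate_cohorts_structure():
    early_spec = CohortSpec(
        stage="DT5_early",
        n_units={"DLS": 3, "DMS": 4},
        mixture={
            "DLS": {"sustained_exc": 1.0},
            "DMS": {"sustained_inh": 1.0},
        },
        seed=1,
    )
    ext_spec = extended_cohort_spec(seed=2, n_units={"DLS": 5, "DMS": 6})
    early, extended = generate_cohorts(early_spec, ext_spec, n_dt1=2, n_dt5=3)
    assert len(early) == 5
    assert [s.stage for s in early] == ["DT1"] * 2 + ["DT5_early"] * 3
    assert all(s.ratio == 1 for s in early[:2])
    regions = [u.region for u in extended.units]
    assert regions.count("DLS") == 5 and regions.count("DMS") == 6
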