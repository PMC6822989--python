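"""Synthetic discrete-trial fixed-ratio sessions with known ground truth.

The generator emulates the statistical structure of striatal single-unit
recordings during a cued lever-press sequence task: each trial starts with
lever insertion, the animal completes the fixed ratio of presses, the lever
retracts and the animal collects reward at the port. Units spike as
inhomogeneous Poisson processes whose rate profiles follow one of six
archetypes:

``phasic_start``    transient excitation just after lever insertion
``phasic_stop``     transient excitation just before the reward port entry
``phasic_middle``   transient excitations around each lever press
``sustained_exc``   multiplicative rate increase from insertion to port entry
``sustained_inh``   multiplicative rate decrease over the same span
``non_responsive``  constant baseline

Cohort mixtures are configurable per region; the defaults reproduce the two
recording stages of the study design this package targets — an early stage
in which lateral-striatum units are dominated by sustained excitation while
medial units are dominated by sustained inhibition with excitation at the
sequence boundaries, and an extended stage in which the two regions share a
matched mixture. Trial-by-trial firing-behavior coupling is implemented by
scaling a unit's rate within a behavioral epoch by an affine function of the
trial's realized behavioral value (clipped at zero), which gives transparent
ground truth for correlation recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core_data import Session, Trial, Unit

ARCHETYPES = (
    "phasic_start",
    "phasic_stop",
    "phasic_middle",
    "sustained_exc",
    "sustained_inh",
    "non_responsive",
)

PHASIC = ("phasic_start", "phasic_stop", "phasic_middle")

COUPLING_EPOCHS = ("post_insertion", "execution", "post_retraction")
COUPLING_VARIABLES = ("first_press_latency", "response_rate", "port_entry_latency")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Rate-profile template for one response archetype.

    ``modulation_gain`` is the peak (phasic) or sustained multiplicative
    rate factor relative to baseline; ``peak_width`` is the Gaussian SD of a
    phasic bump in seconds.
    """

    name: str
    baseline_rate: float = 5.0
    modulation_gain: float = 1.0
    # phasic amplitude in trial-averaged z units (preferred over gain for
    # phasic archetypes: detectability is a unit property, not proportional
    # to baseline rate); converted via amp = amp_z * sqrt(b / z_norm_s)
    amp_z: Optional[float] = None
    z_norm_s: float = 0.3  # bin width x trial count of the target analysis
    peak_width: float = 0.050
    peak_offset: float = 0.125  # bump center relative to its anchor event (s)
    baseline_scale: float = 1.0  # multiplier on the cohort-drawn baseline
    press_prob: float = 1.0  # phasic_middle: chance each press gets a bump
    amp_jitter: float = 0.0  # log-normal sigma of per-bump amplitude noise
    ramp_tau: float = 0.0  # sustained archetypes: edge-smoothing SD (s)
    # sustained archetypes: how far the modulation extends beyond the
    # sequence (anticipatory onset before lever insertion, persistence
    # after the reward port entry), seconds
    span_pad: float = 0.0
    # sustained archetypes: amplitude of press-locked transients riding on
    # the plateau, as a fraction of the sustained rate change (transient
    # releases for inhibited units, extra peaks for excited ones)
    ripple_frac: float = 0.0
    # phasic_middle: press-locked modulations may be excitatory or
    # inhibitory, drawn per press
    bipolar: bool = False
    # phasic archetypes: fraction of the bump's spike mass cancelled by a
    # broad rebound suppression following the peak (biphasic response);
    # suppression depth is floor-limited by the baseline rate
    rebound: float = 0.0
    rebound_width: float = 0.12  # SD (s) of the suppression lobe
    # per-unit realization (filled by the generator): which press slots the
    # unit modulates, and with which sign — fixed across trials
    press_mask: Optional[tuple] = None
    press_signs: Optional[tuple] = None

    def __post_init__(self):
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.modulation_gain < 0:
            raise ValueError(
                f"{self.name}: gain {self.modulation_gain} would yield a negative rate"
            )


DEFAULT_ARCHETYPES = {
    "phasic_start": ArchetypeSpec("phasic_start", amp_z=6.0,
                                  peak_width=0.040, peak_offset=0.125,
                                  amp_jitter=0.1, rebound=0.8,
                                  rebound_width=0.20),
    "phasic_stop": ArchetypeSpec("phasic_stop", amp_z=6.0,
                                 peak_width=0.040, peak_offset=-0.125,
                                 amp_jitter=0.1, rebound=0.8,
                                 rebound_width=0.20),
    "phasic_middle": ArchetypeSpec("phasic_middle", amp_z=2.4,
                                   peak_width=0.040, peak_offset=0.0,
                                   press_prob=1.0, amp_jitter=0.1,
                                   rebound=0.65, rebound_width=0.20),
    # sustained modulation ramps on and off rather than stepping; gains are
    # set so excitation and inhibition have matched modulation magnitude
    # (spectral power is sign-blind, so they form one sustained class),
    # with press-locked transients riding on the plateau
    "sustained_exc": ArchetypeSpec("sustained_exc", modulation_gain=1.9,
                                   baseline_scale=2.0, ramp_tau=0.25,
                                   span_pad=1.0, ripple_frac=0.6,
                                   peak_width=0.055),
    # inhibition is floor-limited: only units with appreciable baseline
    # firing can express a visible sustained decrease
    "sustained_inh": ArchetypeSpec("sustained_inh", modulation_gain=0.05,
                                   baseline_scale=2.2, ramp_tau=0.25,
                                   span_pad=1.0, ripple_frac=0.20,
                                   peak_width=0.055),
    "non_responsive": ArchetypeSpec("non_responsive", modulation_gain=1.0),
}


@dataclass(frozen=True)
class BehaviorModel:
    """Log-normal trial-timing model (parameters in log-space)."""

    first_press_mu: float = math.log(1.2)
    first_press_sigma: float = 0.5
    ipi_mu: float = math.log(0.4)
    ipi_sigma: float = 0.35
    port_entry_mu: float = math.log(1.0)
    port_entry_sigma: float = 0.4
    omission_prob: float = 0.0
    within_seq_pe_mean: float = 0.1  # Poisson mean per trial
    iti_pe_mean: float = 2.0  # Poisson mean per inter-trial interval
    iti_duration: float = 60.0
    omission_timeout: float = 60.0


@dataclass(frozen=True)
class CouplingSpec:
    """Firing-behavior coupling for all units of one archetype."""

    archetype: str
    epoch: str  # post_insertion | execution | post_retraction
    variable: str  # first_press_latency | response_rate | port_entry_latency
    sign: int  # +1 or -1
    strength: float  # rate slope per SD of the behavioral value

    def __post_init__(self):
        if self.epoch not in COUPLING_EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.variable not in COUPLING_VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


# class proportions of the extended-stage taxonomy (pooled across regions):
# Start 110, Stop 163, Middle 362, INH 53, EXC 60 of 748 units
EXTENDED_MIXTURE = {
    "phasic_start": 110 / 748,
    "phasic_stop": 163 / 748,
    "phasic_middle": 362 / 748,
    "sustained_inh": 53 / 748,
    "sustained_exc": 60 / 748,
}

# early stage: DLS predominantly excited during the sequence, DMS
# predominantly inhibited with excitation at the sequence boundaries
EARLY_MIXTURE = {
    "DLS": {
        "phasic_start": 0.10,
        "phasic_stop": 0.10,
        "phasic_middle": 0.14,
        "sustained_exc": 0.36,
        "sustained_inh": 0.08,
        "non_responsive": 0.22,
    },
    "DMS": {
        "phasic_start": 0.12,
        "phasic_stop": 0.12,
        "phasic_middle": 0.06,
        "sustained_exc": 0.08,
        "sustained_inh": 0.42,
        "non_responsive": 0.20,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one session (or a pooled stage)."""

    stage: str = "extended"  # DT1 | DT5_early | extended
    n_units: dict = field(
        default_factory=lambda: {"DLS": 338, "DMS": 410}
    )
    mixture: dict = field(
        default_factory=lambda: {
            "DLS": dict(EXTENDED_MIXTURE),
            "DMS": dict(EXTENDED_MIXTURE),
        }
    )
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    coupling: tuple[CouplingSpec, ...] = ()
    archetypes: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    # per-unit baseline rates are log-normal across the cohort
    baseline_mu: float = math.log(5.0)
    baseline_sigma: float = 0.4
    # per-unit heterogeneity: log-normal jitter of the archetype's gain and
    # peak width, Gaussian jitter (s) of the peak offset — response classes
    # are continua, not point templates
    gain_jitter: float = 0.06
    width_jitter: float = 0.10
    offset_jitter: float = 0.04
    # every task-responsive unit additionally carries a weak unit-specific
    # slow modulation across the sequence (random sign), emulating the
    # global movement/arousal-related drift seen in real recordings
    common_mod_z: float = 0.0
    common_mod_jitter: float = 0.15
    n_trials: int = 30
    seed: int = 0

    @property
    def ratio(self) -> int:
        return 1 if self.stage == "DT1" else 5

    def validate(self) -> None:
        for region, mix in self.mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{region} mixture sums to {total}, not 1")
            unknown = set(mix) - set(ARCHETYPES)
            if unknown:
                raise ValueError(f"unknown archetypes {sorted(unknown)}")
        b = self.behavior
        for name in ("first_press_sigma", "ipi_sigma", "port_entry_sigma"):
            if getattr(b, name) <= 0:
                raise ValueError(f"{name} must be positive")


def early_cohort_spec(stage: str = "DT5_early", seed: int = 0,
                      n_units: Optional[dict] = None) -> CohortSpec:
    """Early-training cohort: region-distinct mixtures, per-session unit
    counts matching the recorded averages (37 DLS, 81 DMS)."""
    return CohortSpec(
        stage=stage,
        n_units=n_units or {"DLS": 37, "DMS": 81},
        mixture={r: dict(m) for r, m in EARLY_MIXTURE.items()},
        behavior=BehaviorModel(first_press_mu=math.log(1.6)),
        seed=seed,
    )


def extended_cohort_spec(seed: int = 0, n_units: Optional[dict] = None) -> CohortSpec:
    """Extended-training cohort: matched mixtures, pooled unit counts."""
    return CohortSpec(stage="extended", n_units=n_units or {"DLS": 338, "DMS": 410},
                      seed=seed)


# ---------------------------------------------------------------------------
# rate profiles


class RateProfile:
    """Piecewise rate function: ``(baseline * prod steps + sum bumps) * prod
    coupling steps``, evaluated vectorized over time."""

    def __init__(self, baseline: float):
        if baseline <= 0:
            raise ValueError("baseline must be positive")
        self.baseline = float(baseline)
        # steps are (t0, t1, gain, tau): tau > 0 smooths the on/off edges
        # with a Gaussian-integral ramp of SD tau seconds
        self.steps: list[tuple[float, float, float, float]] = []
        self.bumps: list[tuple[float, float, float]] = []  # (center, sd, amp)
        self.coupling_steps: list[tuple[float, float, float]] = []

    def add_step(self, t0: float, t1: float, gain: float, tau: float = 0.0) -> None:
        if gain < 0:
            raise ValueError(f"step gain {gain} would yield a negative rate")
        self.steps.append((t0, t1, gain, tau))

    def add_bump(self, center: float, sd: float, amp: float) -> None:
        if amp < -self.baseline:
            raise ValueError("bump amplitude would yield a negative rate")
        self.bumps.append((center, sd, amp))

    def add_coupling(self, t0: float, t1: float, gain: float) -> None:
        self.coupling_steps.append((t0, t1, max(0.0, gain)))

    def __call__(self, t) -> np.ndarray:
        from scipy.special import erf

        t = np.asarray(t, dtype=float)
        rate = np.full(t.shape, self.baseline)
        for t0, t1, g, tau in self.steps:
            if tau > 0:
                s = 0.5 * (
                    erf((t - t0) / (np.sqrt(2) * tau))
                    - erf((t - t1) / (np.sqrt(2) * tau))
                )
                rate *= 1.0 + (g - 1.0) * s
            else:
                rate[(t >= t0) & (t < t1)] *= g
        for c, sd, amp in self.bumps:
            m = np.abs(t - c) < 6 * sd
            rate[m] += amp * np.exp(-0.5 * ((t[m] - c) / sd) ** 2)
        for t0, t1, g in self.coupling_steps:
            rate[(t >= t0) & (t < t1)] *= g
        return np.maximum(rate, 0.0)

    @property
    def max_rate(self) -> float:
        gmax = max([1.0] + [g for _, _, g, _ in self.steps])
        cmax = max([1.0] + [g for _, _, g in self.coupling_steps])
        pos_amp = max([0.0] + [a for _, _, a in self.bumps])
        # neighbouring press bumps can overlap in their tails
        return (self.baseline * gmax + 2.5 * pos_amp) * cmax


def rate_profile(
    archetype: ArchetypeSpec,
    trial: Trial,
    baseline: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> RateProfile:
    """Rate function of one archetype over one realized trial.

    The profile equals the baseline everywhere outside the archetype's
    modulation; phasic bumps are Gaussian with total extra spike count
    ``baseline * (gain - 1) * peak_width * sqrt(2*pi)`` per anchor. With an
    ``rng``, bump amplitudes get log-normal jitter and middle-type units
    modulate at a random subset of presses; without one the profile is the
    deterministic template (every press, no jitter).
    """
    b = (baseline if baseline is not None else archetype.baseline_rate)
    b *= archetype.baseline_scale
    prof = RateProfile(b)
    if archetype.amp_z is not None:
        amp = archetype.amp_z * math.sqrt(b / archetype.z_norm_s)
    else:
        amp = b * (archetype.modulation_gain - 1.0)
    end = trial.reward_port_entry or trial.lever_retraction or trial.lever_insertion

    def jitter(a: float) -> float:
        if rng is None or archetype.amp_jitter <= 0:
            return a
        return a * rng.lognormal(0.0, archetype.amp_jitter)

    def add_phasic(center: float, a: float) -> None:
        prof.add_bump(center, archetype.peak_width, a)
        if archetype.rebound > 0 and a > 0:
            # rebound suppression carrying `rebound` of the bump's mass
            depth = min(
                archetype.rebound * a * archetype.peak_width / archetype.rebound_width,
                0.9 * b,
            )
            prof.add_bump(center, archetype.rebound_width, -depth)

    if archetype.name == "non_responsive":
        pass
    elif archetype.name == "phasic_start":
        add_phasic(trial.lever_insertion + archetype.peak_offset, jitter(amp))
    elif archetype.name == "phasic_stop":
        if trial.reward_port_entry is not None:
            add_phasic(trial.reward_port_entry + archetype.peak_offset, jitter(amp))
    elif archetype.name == "phasic_middle":
        for slot, p in enumerate(trial.press_times):
            mask = archetype.press_mask
            if mask is not None and not mask[slot % len(mask)]:
                continue
            a = jitter(amp)
            signs = archetype.press_signs
            if signs is not None and signs[slot % len(signs)] < 0:
                # inhibitory transient, floor-limited by the baseline rate
                a = -min(abs(a), 0.9 * b)
            add_phasic(p + archetype.peak_offset, a)
    elif archetype.name in ("sustained_exc", "sustained_inh"):
        if end > trial.lever_insertion:
            prof.add_step(trial.lever_insertion - archetype.span_pad,
                          end + archetype.span_pad,
                          archetype.modulation_gain, tau=archetype.ramp_tau)
            if archetype.ripple_frac > 0:
                # press-locked transients riding on the plateau; per-unit
                # fixed signs, depth-limited by the plateau rate
                ramp = b * abs(archetype.modulation_gain - 1.0)
                plateau = b * archetype.modulation_gain
                signs = archetype.press_signs
                for slot, p in enumerate(trial.press_times):
                    a = jitter(archetype.ripple_frac * ramp)
                    if signs is not None and signs[slot % len(signs)] < 0:
                        a = -min(a, 0.9 * min(plateau, b))
                    prof.add_bump(p, archetype.peak_width, a)
    return prof


# ---------------------------------------------------------------------------
# behavior


def _draw_trial(rng: np.random.Generator, t0: float, ratio: int,
                bm: BehaviorModel) -> Trial:
    if rng.random() < bm.omission_prob:
        n = rng.integers(0, ratio)  # incomplete ratio
        presses = []
        t = t0 + rng.lognormal(bm.first_press_mu, bm.first_press_sigma)
        for _ in range(n):
            presses.append(t)
            t += rng.lognormal(bm.ipi_mu, bm.ipi_sigma)
        presses = [p for p in presses if p < t0 + bm.omission_timeout]
        return Trial(lever_insertion=t0, press_times=presses,
                     lever_retraction=t0 + bm.omission_timeout, omission=True)
    presses = [t0 + rng.lognormal(bm.first_press_mu, bm.first_press_sigma)]
    for _ in range(ratio - 1):
        presses.append(presses[-1] + rng.lognormal(bm.ipi_mu, bm.ipi_sigma))
    retraction = presses[-1] + 0.05
    port_entry = retraction + rng.lognormal(bm.port_entry_mu, bm.port_entry_sigma)
    n_wspe = rng.poisson(bm.within_seq_pe_mean) if ratio > 1 else 0
    wspe = sorted(rng.uniform(presses[0], presses[-1], n_wspe)) if n_wspe else []
    return Trial(lever_insertion=t0, press_times=presses,
                 lever_retraction=retraction, reward_port_entry=port_entry,
                 within_sequence_port_entries=list(wspe))


def _behavior_z(trial: Trial, variable: str, bm: BehaviorModel) -> float:
    """Standardized behavioral value of a trial under the generative model
    (monotone in the raw value; used to drive coupling)."""
    if variable == "first_press_latency":
        v = trial.first_press - trial.lever_insertion
        return (math.log(v) - bm.first_press_mu) / bm.first_press_sigma
    if variable == "port_entry_latency":
        v = trial.reward_port_entry - trial.lever_retraction
        return (math.log(v) - bm.port_entry_mu) / bm.port_entry_sigma
    # response rate ~ inverse mean IPI; standardize via the summed log-IPIs
    if trial.n_presses < 2:
        return 0.0
    mean_log_ipi = math.log(
        (trial.last_press - trial.first_press) / (trial.n_presses - 1)
    )
    return -(mean_log_ipi - bm.ipi_mu) / (bm.ipi_sigma / math.sqrt(trial.n_presses - 1))


def _epoch_span(trial: Trial, epoch: str, window: float = 0.5):
    if epoch == "post_insertion":
        return trial.lever_insertion, trial.lever_insertion + window
    if epoch == "execution":
        if trial.n_presses < 2:
            return None
        return trial.first_press, trial.last_press
    if trial.lever_retraction is None:
        return None
    return trial.lever_retraction, trial.lever_retraction + window


# ---------------------------------------------------------------------------
# session generation


def _draw_unit_archetype(
    rng: np.random.Generator, template: ArchetypeSpec, spec: "CohortSpec"
) -> ArchetypeSpec:
    """Per-unit realization of an archetype template."""
    if template.name == "non_responsive":
        return template
    kwargs = {}
    if template.amp_z is not None:
        kwargs["amp_z"] = template.amp_z * rng.lognormal(0.0, spec.gain_jitter)
    else:
        g = template.modulation_gain
        if g >= 1.0:
            # jitter the modulation depth (gain - 1), keeping gain >= 1
            g = 1.0 + (g - 1.0) * rng.lognormal(0.0, spec.gain_jitter)
        else:
            # inhibition: jitter the residual rate fraction, keeping gain < 1
            g = float(
                np.clip(g * rng.lognormal(0.0, 2 * spec.gain_jitter), 0.0, 0.8)
            )
        kwargs["modulation_gain"] = g
    if template.name in PHASIC:
        kwargs["peak_width"] = template.peak_width * rng.lognormal(
            0.0, spec.width_jitter
        )
        kwargs["peak_offset"] = template.peak_offset + rng.normal(
            0.0, spec.offset_jitter
        )
        if template.name == "phasic_middle":
            # modulation at "one or more" presses: a fixed per-unit subset
            # of press slots, each with a fixed sign
            mask = rng.random(5) < template.press_prob
            if not mask.any():
                mask[rng.integers(5)] = True
            kwargs["press_mask"] = tuple(bool(m) for m in mask)
            if template.bipolar:
                # near-balanced sign pattern in random order
                base = [1, 1, 1, -1, -1] if rng.random() < 0.5 else [1, 1, -1, -1, -1]
                kwargs["press_signs"] = tuple(
                    int(s) for s in rng.permutation(base)
                )
    if template.ripple_frac > 0:
        if template.name == "sustained_inh":
            # transient releases: inhibition cannot deepen below zero rate
            kwargs["press_signs"] = (1, 1, 1, 1, 1)
        else:
            kwargs["press_signs"] = tuple(
                int(s) for s in rng.choice([-1, 1], size=5)
            )
    return replace(template, **kwargs)


def _simulate_unit(rng: np.random.Generator, profile_for_trial,
                   session_end: float) -> np.ndarray:
    """Inhomogeneous Poisson spikes over [0, session_end) by thinning."""
    prof = RateProfile(profile_for_trial[0].baseline)
    for p in profile_for_trial:
        prof.steps.extend(p.steps)
        prof.bumps.extend(p.bumps)
        prof.coupling_steps.extend(p.coupling_steps)
    rmax = prof.max_rate
    n_cand = rng.poisson(rmax * session_end)
    times = rng.uniform(0.0, session_end, n_cand)
    keep = rng.random(n_cand) * rmax < prof(times)
    spikes = np.sort(times[keep])
    # strictly increasing timestamps (ties have measure zero but guard anyway)
    if len(spikes) > 1:
        dup = np.diff(spikes) <= 0
        while dup.any():
            spikes = np.delete(spikes, np.nonzero(dup)[0] + 1)
            dup = np.diff(spikes) <= 0
    return spikes


def generate_session(spec: CohortSpec, session_index: int = 0) -> Session:
    """Simulate one session: behavior first, then unit spike trains.

    Deterministic given ``(spec.seed, session_index)``. Ground-truth
    archetype and coupling labels are stored in the session provenance and
    on each unit's ``archetype`` field.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed % (2**31), session_index])
    bm = spec.behavior

    trials: list[Trial] = []
    t = bm.iti_duration + 10.0  # leave room for the first baseline window
    iti_pe: list[float] = []
    prev_end = 0.0
    for _ in range(spec.n_trials):
        n_pe = rng.poisson(bm.iti_pe_mean)
        if n_pe and t - 2.0 > prev_end + 2.0:
            iti_pe.extend(np.sort(rng.uniform(prev_end + 2.0, t - 2.0, n_pe)))
        trial = _draw_trial(rng, t, spec.ratio, bm)
        trials.append(trial)
        prev_end = max(
            [trial.lever_insertion]
            + trial.press_times
            + [x for x in (trial.lever_retraction, trial.reward_port_entry) if x]
        )
        t = prev_end + bm.iti_duration
    session_end = prev_end + bm.iti_duration

    coupling_by_arch = {}
    for c in spec.coupling:
        coupling_by_arch.setdefault(c.archetype, []).append(c)

    units: list[Unit] = []
    for region in sorted(spec.n_units):
        mix = spec.mixture[region]
        names = sorted(mix)
        probs = np.array([mix[n] for n in names])
        draws = rng.choice(len(names), size=spec.n_units[region], p=probs / probs.sum())
        for j, k in enumerate(draws):
            arch_name = names[k]
            arch = _draw_unit_archetype(rng, spec.archetypes[arch_name], spec)
            # cap the effective rate so units stay under the 12.5 Hz
            # MSN screening boundary after any archetype baseline scaling
            hi = 11.5 / max(arch.baseline_scale, 1.0)
            baseline = float(
                np.clip(rng.lognormal(spec.baseline_mu, spec.baseline_sigma), 1.0, hi)
            )
            # weak unit-specific slow task modulation (not for units that
            # are non-responsive by construction)
            cm_gain = None
            if arch_name != "non_responsive" and spec.common_mod_z > 0:
                b_eff = baseline * arch.baseline_scale
                cm = (
                    spec.common_mod_z
                    * rng.lognormal(0.0, spec.common_mod_jitter)
                    * rng.choice([-1.0, 1.0])
                )
                cm_gain = max(0.0, 1.0 + cm / math.sqrt(0.3 * b_eff))
            profiles = []
            for trial in trials:
                prof = rate_profile(arch, trial, baseline=baseline, rng=rng)
                if cm_gain is not None:
                    end = (trial.reward_port_entry or trial.lever_retraction
                           or trial.lever_insertion)
                    if end > trial.lever_insertion:
                        prof.add_step(trial.lever_insertion, end, cm_gain, tau=0.10)
                for c in coupling_by_arch.get(arch_name, []):
                    span = _epoch_span(trial, c.epoch)
                    if span is None or trial.omission:
                        continue
                    z = _behavior_z(trial, c.variable, bm)
                    prof.add_coupling(span[0], span[1],
                                      1.0 + c.sign * c.strength * z)
                profiles.append(prof)
            spikes = _simulate_unit(rng, profiles, session_end)
            mean_rate = len(spikes) / session_end
            units.append(
                Unit(
                    unit_id=f"{region}_{session_index:02d}_{j:03d}",
                    region=region,
                    spikes=spikes,
                    mean_rate=mean_rate,
                    half_valley_width=float(np.clip(rng.normal(0.30, 0.04), 0.18, 0.5)),
                    rat_id=f"rat{session_index % 9}",
                    archetype=arch_name,
                )
            )

    session = Session(
        session_id=f"{spec.stage}_{session_index:02d}",
        stage=spec.stage,
        ratio=spec.ratio,
        trials=trials,
        units=units,
        iti_port_entries=[p for p in iti_pe if p < session_end],
        rat_id=f"rat{session_index % 9}",
        stage_index=session_index + 1 if spec.stage != "extended" else None,
        provenance={
            "generator": "striaseq.synthetic_data",
            "seed": spec.seed,
            "session_index": session_index,
            "archetypes": {u.unit_id: u.archetype for u in units},
            "coupling": [c.__dict__ for c in spec.coupling],
        },
    )
    session.validate()
    return session


def generate_cohorts(
    early_spec: Optional[CohortSpec] = None,
    extended_spec: Optional[CohortSpec] = None,
    n_dt1: int = 3,
    n_dt5: int = 10,
) -> tuple[list[Session], Session]:
    """Generate the two recording stages: 13 early sessions (3 fixed-ratio-1
    then 10 fixed-ratio-5) and one pooled extended-stage session."""
    early_spec = early_spec or early_cohort_spec()
    extended_spec = extended_spec or extended_cohort_spec(seed=early_spec.seed + 1)
    early: list[Session] = []
    for i in range(n_dt1):
        early.append(generate_session(replace(early_spec, stage="DT1"), i))
    for i in range(n_dt5):
        early.append(generate_session(replace(early_spec, stage="DT5_early"), n_dt1 + i))
    extended = generate_session(extended_spec, 99)
    return early, extended
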