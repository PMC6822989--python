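"""Peri-event alignment, baseline statistics, z-scoring and
task-responsiveness screening.

Each unit's activity is summarized around the seven sequence events (lever
insertion, presses 1-5, reward port entry) in 51 bins of 10 ms whose centers
run from -250 to +250 ms. Rates are normalized as ``(F_i - F_mean) / F_sd``
with the baseline mean and SD taken from a 5 s inter-trial window starting
20 s before the anchor event. A unit is task-responsive (TRN) when any of
the twelve 250 ms response windows (post-insertion, pre/post each press,
pre-port-entry) differs from baseline at p < 0.01 by t-test, and its sign
(EXC/INH) is the sign of its mean z-score across the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import RESPONSE_WINDOWS, SEQUENCE_EVENTS, AnalysisConfig
from .core_data import Session, Trial, Unit


def align(
    spikes: np.ndarray,
    event_times: Sequence[float],
    window: float = 0.250,
    bin_width: float = 0.010,
    n_bins: Optional[int] = None,
) -> np.ndarray:
    """Event-aligned spike counts.

    Returns an ``(n_events, n_bins)`` count matrix. With the defaults the
    grid has 51 bins whose centers are -250, -240, ..., +250 ms; every bin
    is half-open ``[t0, t1)`` relative to its event.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("align requires at least one event")
    if bin_width <= 0 or window <= 0:
        raise ValueError("window and bin_width must be positive")
    if n_bins is None:
        n_bins = int(round(2 * window / bin_width)) + 1
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_width
    spikes = np.asarray(spikes, dtype=float)
    out = np.empty((event_times.size, n_bins), dtype=np.int64)
    for i, ev in enumerate(event_times):
        idx = np.searchsorted(spikes, ev + edges, side="left")
        out[i] = np.diff(idx)
    return out


def event_bin_edges(config: AnalysisConfig) -> np.ndarray:
    """Bin edges (s, relative to the event) of the peri-event grid."""
    n = config.n_bins_per_event
    return (np.arange(n + 1) - n / 2) * config.bin_width


def trial_events(trial: Trial, ratio: int) -> Optional[np.ndarray]:
    """The seven sequence-event times of a rewarded trial (or ``None``)."""
    if trial.omission or trial.n_presses != ratio or trial.reward_port_entry is None:
        return None
    if ratio == 5:
        presses = trial.press_times
    else:
        # ratio-1 stage: a single press anchors all five press slots
        presses = [trial.press_times[0]] * 5
    return np.array(
        [trial.lever_insertion] + list(presses) + [trial.reward_port_entry]
    )


def baseline_stats(
    unit: Unit, session: Session, config: AnalysisConfig = AnalysisConfig()
) -> tuple[float, float]:
    """Baseline mean and SD of the binned, trial-averaged firing rate (Hz).

    One 5 s window per rewarded trial, starting ``baseline_offset`` seconds
    before the lever insertion (or before every event when
    ``config.baseline_per_event``); windows preceding the session start are
    dropped. Rates are binned at ``bin_width``, averaged across windows at
    each bin offset, and the mean/SD taken over bin offsets — the same
    trial-averaged scale as the PSTH itself.
    """
    anchors = []
    for trial in session.rewarded_trials:
        evs = trial_events(trial, session.ratio)
        if evs is None:
            continue
        if config.baseline_per_event:
            anchors.extend(evs)
        else:
            anchors.append(trial.lever_insertion)
    starts = np.asarray(anchors) - config.baseline_offset
    starts = starts[starts >= 0.0]
    if starts.size == 0:
        raise ValueError("no usable baseline windows in session")
    n_bins = int(round(config.baseline_duration / config.bin_width))
    edges = np.arange(n_bins + 1) * config.bin_width
    counts = np.empty((starts.size, n_bins))
    for i, s in enumerate(starts):
        idx = np.searchsorted(unit.spikes, s + edges, side="left")
        counts[i] = np.diff(idx)
    rates = counts.mean(axis=0) / config.bin_width
    f_mean = float(rates.mean())
    f_sd = float(rates.std(ddof=0))
    unit.baseline_mean = f_mean
    unit.baseline_sd = f_sd
    return f_mean, f_sd


def baseline_trial_rates(
    unit: Unit, session: Session, config: AnalysisConfig = AnalysisConfig()
) -> np.ndarray:
    """Per-trial baseline firing rates (Hz) over the 5 s windows; the
    comparison sample for the window response t-tests."""
    starts = np.array(
        [t.lever_insertion - config.baseline_offset for t in session.rewarded_trials]
    )
    starts = starts[starts >= 0.0]
    if starts.size == 0:
        raise ValueError("no usable baseline windows in session")
    idx0 = np.searchsorted(unit.spikes, starts, side="left")
    idx1 = np.searchsorted(unit.spikes, starts + config.baseline_duration, side="left")
    return (idx1 - idx0) / config.baseline_duration


@dataclass
class PeriEventMatrix:
    """Binned, baseline-normalized peri-event activity of one unit."""

    unit_id: str
    region: str
    counts: np.ndarray  # (n_trials, 7, n_bins) spike counts
    rates: np.ndarray  # (7, n_bins) trial-averaged rates, Hz
    f_mean: float
    f_sd: float
    z: np.ndarray  # (7, n_bins) z-scored rates
    archetype: Optional[str] = None

    @property
    def concat_vector(self) -> np.ndarray:
        """The 7 x 51 = 357-element concatenated z-score vector."""
        return self.z.reshape(-1)

    def window_means(self, config: AnalysisConfig = AnalysisConfig()) -> np.ndarray:
        """Mean z per response window: the 12-element decoding vector."""
        return np.array(
            [self.z[ev, _window_slice(side, config)].mean()
             for ev, side in RESPONSE_WINDOWS]
        )


def _window_slice(side: str, config: AnalysisConfig) -> slice:
    """Bins of the pre ([-250, 0) ms) or post ([0, +250) ms) window.

    The center bin (bin 25, spanning -5..+5 ms) straddles the event and is
    assigned to neither window.
    """
    half = config.n_bins_per_event // 2
    n = int(round(config.event_window / config.bin_width))
    return slice(half - n, half) if side == "pre" else slice(half + 1, half + 1 + n)


def zscore(rates: np.ndarray, baseline: tuple[float, float]) -> np.ndarray:
    """``(F_i - F_mean) / F_sd`` applied elementwise."""
    f_mean, f_sd = baseline
    if f_sd <= 0:
        raise ValueError("baseline SD must be positive to z-score")
    return (np.asarray(rates, dtype=float) - f_mean) / f_sd


def peri_event_matrix(
    unit: Unit, session: Session, config: AnalysisConfig = AnalysisConfig()
) -> Optional[PeriEventMatrix]:
    """Full peri-event summary of one unit, or ``None`` when the baseline SD
    is zero (the unit is flagged for exclusion)."""
    event_rows = [trial_events(t, session.ratio) for t in session.rewarded_trials]
    events = np.array([e for e in event_rows if e is not None])
    if events.size == 0:
        raise ValueError("session has no usable rewarded trials")
    counts = np.stack(
        [
            align(unit.spikes, events[:, ev], config.event_window, config.bin_width,
                  config.n_bins_per_event)
            for ev in range(len(SEQUENCE_EVENTS))
        ],
        axis=1,
    )  # (n_trials, 7, n_bins)
    rates = counts.mean(axis=0) / config.bin_width
    f_mean, f_sd = baseline_stats(unit, session, config)
    if f_sd <= 0:
        return None
    return PeriEventMatrix(
        unit_id=unit.unit_id,
        region=unit.region,
        counts=counts,
        rates=rates,
        f_mean=f_mean,
        f_sd=f_sd,
        z=zscore(rates, (f_mean, f_sd)),
        archetype=unit.archetype,
    )


def window_response_test(
    window_rates: np.ndarray,
    baseline_rates: np.ndarray,
    welch: bool = True,
    alternative: str = "two-sided",
) -> float:
    """t-test p-value comparing per-trial window rates against per-trial
    baseline rates. Zero-variance degenerate input returns p = 1."""
    window_rates = np.asarray(window_rates, dtype=float)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    if window_rates.size < 2 or baseline_rates.size < 2:
        raise ValueError("need at least two trials per sample")
    if np.var(window_rates) == 0 and np.var(baseline_rates) == 0:
        return 1.0
    res = stats.ttest_ind(
        window_rates, baseline_rates, equal_var=not welch, alternative=alternative
    )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


@dataclass
class TRNRecord:
    unit_id: str
    p_values: np.ndarray  # one per response window
    trn: bool
    sign: Optional[str]  # EXC | INH, defined only for TRNs


def detect_trn(
    unit: Unit,
    session: Session,
    config: AnalysisConfig = AnalysisConfig(),
    pem: Optional[PeriEventMatrix] = None,
) -> TRNRecord:
    """Task-responsiveness of one unit: any of the 12 response windows
    significant at ``trn_alpha`` versus baseline."""
    pem = pem if pem is not None else peri_event_matrix(unit, session, config)
    if pem is None:
        raise ValueError(f"unit {unit.unit_id}: zero baseline SD")
    base = baseline_trial_rates(unit, session, config)
    n = int(round(config.event_window / config.bin_width))
    half = config.n_bins_per_event // 2
    pvals = []
    for ev, side in RESPONSE_WINDOWS:
        sl = _window_slice(side, config)
        win_counts = pem.counts[:, ev, sl].sum(axis=1)
        win_rates = win_counts / (n * config.bin_width)
        pvals.append(window_response_test(win_rates, base, welch=config.welch))
    pvals = np.array(pvals)
    trn = bool(pvals.min() < config.trn_alpha)
    sign = None
    if trn:
        sign = "EXC" if pem.concat_vector.mean() > 0 else "INH"
    return TRNRecord(unit_id=unit.unit_id, p_values=pvals, trn=trn, sign=sign)
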