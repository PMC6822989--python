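"""Per-trial and per-session behavioral metrics, and the devaluation split.

Response rate follows the lever-availability definition: presses per trial
divided by the time the lever was available (insertion to retraction). The
``(n_presses - 1) / sequence_duration`` alternative is available through
``AnalysisConfig.rate_per_sequence_duration``. The devaluation ratio is
``devalued / (valued + devalued)``, so 0.5 means equal responding in the two
conditions; animals above 0.45 are read as insensitive to outcome
devaluation (habit-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .core_data import Session, Trial


@dataclass
class TrialMetrics:
    first_press_latency: Optional[float]
    sequence_duration: Optional[float]
    within_sequence_response_rate: Optional[float]
    n_within_sequence_port_entries: int
    port_entry_latency: Optional[float]
    omission: bool = False


@dataclass
class SessionSummary:
    total_presses: int
    mean_response_rate: float
    cv_response_rate: float
    mean_first_press_latency: float
    mean_port_entry_latency: Optional[float]
    total_within_sequence_port_entries: int
    omission_count: int


def trial_metrics(trial: Trial, config: AnalysisConfig = AnalysisConfig()) -> TrialMetrics:
    """Metrics of one trial; omission trials yield a flagged, mostly-empty
    record."""
    n_wspe = len(
        [
            p
            for p in trial.within_sequence_port_entries
            if trial.first_press is not None
            and trial.lever_retraction is not None
            and trial.first_press <= p < trial.lever_retraction
        ]
    )
    if trial.omission:
        fpl = (
            trial.first_press - trial.lever_insertion
            if trial.first_press is not None
            else None
        )
        return TrialMetrics(fpl, None, None, n_wspe, None, omission=True)

    fpl = trial.first_press - trial.lever_insertion
    seq = trial.last_press - trial.first_press
    if config.rate_per_sequence_duration:
        rate = (trial.n_presses - 1) / seq if seq > 0 else None
    else:
        avail = (trial.lever_retraction or trial.last_press) - trial.lever_insertion
        rate = trial.n_presses / avail if avail > 0 else None
    pel = (
        trial.reward_port_entry - trial.lever_retraction
        if trial.reward_port_entry is not None and trial.lever_retraction is not None
        else None
    )
    return TrialMetrics(fpl, seq, rate, n_wspe, pel)


def session_summary(session: Session, config: AnalysisConfig = AnalysisConfig()) -> SessionSummary:
    """Means and variability over the non-omission trials of a session."""
    rewarded = session.rewarded_trials
    if not rewarded:
        raise ValueError("session has no non-omission trials to summarize")
    tm = [trial_metrics(t, config) for t in rewarded]
    rates = np.array([m.within_sequence_response_rate for m in tm
                      if m.within_sequence_response_rate is not None])
    pels = [m.port_entry_latency for m in tm if m.port_entry_latency is not None]
    mean_rate = float(rates.mean())
    cv = float(rates.std(ddof=0) / mean_rate) if mean_rate > 0 else 0.0
    all_tm = [trial_metrics(t, config) for t in session.trials]
    return SessionSummary(
        total_presses=sum(t.n_presses for t in session.trials),
        mean_response_rate=mean_rate,
        cv_response_rate=cv,
        mean_first_press_latency=float(
            np.mean([m.first_press_latency for m in tm])
        ),
        mean_port_entry_latency=float(np.mean(pels)) if pels else None,
        total_within_sequence_port_entries=sum(
            m.n_within_sequence_port_entries for m in all_tm
        ),
        omission_count=sum(t.omission for t in session.trials),
    )


def devaluation_ratio(
    valued_presses: int,
    devalued_presses: int,
    threshold: float = 0.45,
) -> tuple[float, str]:
    """Devaluation ratio and its sensitivity label.

    ratio = devalued / (valued + devalued); above the threshold the animal
    is labelled ``insensitive`` (habit-like), otherwise ``sensitive``.
    """
    if valued_presses < 0 or devalued_presses < 0:
        raise ValueError("press counts must be non-negative")
    total = valued_presses + devalued_presses
    if total == 0:
        raise ValueError("devaluation ratio undefined when both counts are zero")
    ratio = devalued_presses / total
    return ratio, ("insensitive" if ratio > threshold else "sensitive")
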