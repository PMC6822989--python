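"""Trial-by-trial spike-behavior Spearman correlations with shuffle nulls.

Three fixed epoch/variable pairings are tested per unit: firing in the
500 ms after lever insertion against first-press latency, firing between
the first and last press (normalized to sequence duration) against the
trial's response rate, and firing in the 500 ms after lever retraction
against port-entry latency. Population-level deviation from chance is
quantified by shuffling each unit's behavior vector 1000 times and asking
where the observed count of significant units (p < 0.05) falls in the null
distribution of counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import trial_metrics
from .config import AnalysisConfig
from .core_data import Session, Trial, Unit

#: fixed epoch -> behavioral variable pairing
PAIRINGS = {
    "first_press_latency": "post_insertion",
    "response_rate": "execution",
    "port_entry_latency": "post_retraction",
}


@dataclass
class CorrelationRecord:
    unit_id: str
    region: str
    variable: str
    epoch: str
    rho: float
    p: float
    significant: bool
    n_trials: int


def epoch_rate(
    spikes: np.ndarray, trial: Trial, epoch: str, window: float = 0.5
) -> Optional[float]:
    """Firing rate (Hz) of one unit in one trial's epoch, or ``None`` when
    the epoch is undefined for that trial."""
    spikes = np.asarray(spikes, dtype=float)
    if trial.omission:
        return None
    if epoch == "post_insertion":
        t0, t1 = trial.lever_insertion, trial.lever_insertion + window
    elif epoch == "execution":
        if trial.n_presses < 2:
            return None
        t0, t1 = trial.first_press, trial.last_press
        if t1 <= t0:
            warnings.warn("zero-duration press sequence; trial dropped", stacklevel=2)
            return None
    elif epoch == "post_retraction":
        if trial.lever_retraction is None:
            return None
        t0, t1 = trial.lever_retraction, trial.lever_retraction + window
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    count = int(np.searchsorted(spikes, t1) - np.searchsorted(spikes, t0))
    return count / (t1 - t0)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t-approximation for n >= 10 and an exact
    permutation distribution below that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 trials")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    if x.size < 10:
        from itertools import permutations

        rho = float(stats.spearmanr(x, y).statistic)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        null = [
            float(np.corrcoef(rx, np.asarray(p))[0, 1])
            for p in permutations(ry)
        ]
        p = float(np.mean([abs(r) >= abs(rho) - 1e-12 for r in null]))
        return rho, p
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _trial_variable(trial: Trial, variable: str, config: AnalysisConfig) -> Optional[float]:
    m = trial_metrics(trial, config)
    return {
        "first_press_latency": m.first_press_latency,
        "response_rate": m.within_sequence_response_rate,
        "port_entry_latency": m.port_entry_latency,
    }[variable]


def unit_series(
    unit: Unit, session: Session, variable: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (epoch rate, behavior) series over usable trials."""
    epoch = PAIRINGS[variable]
    rates, values = [], []
    for trial in session.rewarded_trials:
        r = epoch_rate(unit.spikes, trial, epoch, config.epoch_window)
        v = _trial_variable(trial, variable, config)
        if r is not None and v is not None:
            rates.append(r)
            values.append(v)
    return np.array(rates), np.array(values)


def unit_correlation(
    unit: Unit, session: Session, variable: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> CorrelationRecord:
    """Spearman correlation of one unit's epoch firing with one behavioral
    variable; constant series yield a flagged NaN record."""
    rates, values = unit_series(unit, session, variable, config)
    if rates.size < config.min_trials:
        raise ValueError(
            f"unit {unit.unit_id}: only {rates.size} usable trials "
            f"(need {config.min_trials})"
        )
    rho, p = spearman(rates, values)
    return CorrelationRecord(
        unit_id=unit.unit_id,
        region=unit.region,
        variable=variable,
        epoch=PAIRINGS[variable],
        rho=rho,
        p=p,
        significant=bool(p < config.corr_alpha) if np.isfinite(p) else False,
        n_trials=int(rates.size),
    )


def cohort_correlations(
    session: Session,
    pems=None,
    config: AnalysisConfig = AnalysisConfig(),
    units: Optional[Sequence[Unit]] = None,
) -> pd.DataFrame:
    """All three correlations for every analyzable unit of a session."""
    if units is None:
        keep = {p.unit_id for p in pems} if pems is not None else None
        units = [u for u in session.units if keep is None or u.unit_id in keep]
    rows = []
    for u in units:
        for variable in PAIRINGS:
            try:
                rec = unit_correlation(u, session, variable, config)
            except ValueError:
                continue
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


@dataclass
class ShuffleNull:
    variable: str
    n_iterations: int
    observed_count: int
    observed_mean_rho: float
    null_counts: np.ndarray
    null_mean_rhos: np.ndarray
    p_count: float  # empirical population p for the significant-unit count


def shuffle_null(
    session: Session,
    variable: str,
    config: AnalysisConfig = AnalysisConfig(),
    units: Optional[Sequence[Unit]] = None,
    n: Optional[int] = None,
    seed: int = 0,
) -> ShuffleNull:
    """Shuffle-null distribution of the significant-unit count.

    Per iteration the behavior vector is permuted independently for every
    unit and all Spearman tests recomputed; the population p-value is
    ``(1 + #{null count >= observed}) / (n + 1)``.
    """
    n = n if n is not None else config.n_shuffles
    if n < 100:
        warnings.warn(f"n={n} shuffle iterations gives a coarse null", stacklevel=2)
    if units is None:
        units = session.units
    series = []
    for u in units:
        rates, values = unit_series(u, session, variable, config)
        if rates.size >= config.min_trials and not (
            np.all(rates == rates[0]) or np.all(values == values[0])
        ):
            series.append((u, rates, values))
    if not series:
        raise ValueError("no units with computable correlations")

    alpha = config.corr_alpha
    obs_sig, obs_rhos = [], []
    for _, rates, values in series:
        rho, p = spearman(rates, values)
        obs_sig.append(p < alpha)
        if p < alpha:
            obs_rhos.append(rho)
    observed_count = int(np.sum(obs_sig))

    rng = np.random.default_rng([seed % (2**31), 13])
    null_counts = np.empty(n, dtype=int)
    null_mean_rhos = np.full(n, np.nan)
    for it in range(n):
        count = 0
        rhos = []
        for _, rates, values in series:
            rho, p = spearman(rates, rng.permutation(values))
            if np.isfinite(p) and p < alpha:
                count += 1
                rhos.append(rho)
        null_counts[it] = count
        if rhos:
            null_mean_rhos[it] = np.mean(rhos)
    return ShuffleNull(
        variable=variable,
        n_iterations=n,
        observed_count=observed_count,
        observed_mean_rho=float(np.mean(obs_rhos)) if obs_rhos else np.nan,
        null_counts=null_counts,
        null_mean_rhos=null_mean_rhos,
        p_count=float((1 + (null_counts >= observed_count).sum()) / (n + 1)),
    )


def overlap_counts(records: pd.DataFrame) -> dict:
    """Venn cells of significant units across the three variables, plus
    per-variable region contingency tables.

    Returns ``{"venn": {frozenset-> count}, "by_variable": {...},
    "tables": {variable: 2x2 region x (sig, nonsig) counts}}``.
    """
    variables = list(PAIRINGS)
    sig_sets = {
        v: set(records.loc[(records["variable"] == v) & records["significant"],
                           "unit_id"])
        for v in variables
    }
    all_units = sorted(set(records["unit_id"]))
    venn: dict = {}
    for mask in range(1, 8):
        members = [variables[i] for i in range(3) if mask >> i & 1]
        cell = set(all_units)
        for v in variables:
            cell &= sig_sets[v] if v in members else (set(all_units) - sig_sets[v])
        venn["&".join(members)] = len(cell)
    tables = {}
    for v in variables:
        t = []
        for region in ("DLS", "DMS"):
            ids = set(records.loc[(records["variable"] == v)
                                  & (records["region"] == region), "unit_id"])
            sig = len(ids & sig_sets[v])
            t.append([sig, len(ids) - sig])
        tables[v] = np.array(t)
    union = set().union(*sig_sets.values())
    return {
        "venn": venn,
        "by_variable": {v: len(sig_sets[v]) for v in variables},
        "union": len(union),
        "tables": tables,
    }
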