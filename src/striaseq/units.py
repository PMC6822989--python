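"""Waveform/rate screening of striatal units.

Putative fast-spiking interneurons (FSI) fire above 20 Hz with a narrow
spike-waveform half-valley width (< 0.15 ms); units with rates between 12.5
and 20 Hz — or fast-firing units with wide waveforms — have intermediate
characteristics and stay unclassified; everything else is a putative medium
spiny neuron (MSN). Tonically active neurons are not separated. Units whose
baseline rate falls below 0.5 Hz are excluded from all analyses.
"""

from __future__ import annotations

from typing import Iterable

from .config import AnalysisConfig
from .core_data import Session, Unit


def classify_unit(
    mean_rate: float,
    half_valley_width: float,
    config: AnalysisConfig = AnalysisConfig(),
) -> str:
    """Classify a unit as ``FSI``, ``unclassified`` or ``MSN``."""
    if mean_rate is None or half_valley_width is None:
        raise ValueError("mean_rate and half_valley_width are both required")
    if mean_rate > config.fsi_rate_hz:
        if half_valley_width < config.fsi_half_valley_ms:
            return "FSI"
        return "unclassified"  # fast but wide: intermediate characteristics
    if mean_rate >= config.unclassified_rate_lo_hz:
        return "unclassified"
    return "MSN"


def baseline_filter(unit: Unit, config: AnalysisConfig = AnalysisConfig()) -> bool:
    """True when the unit's baseline rate reaches 0.5 Hz (kept)."""
    if unit.baseline_mean is None:
        raise ValueError(
            f"unit {unit.unit_id}: baseline_mean not computed; run "
            "psth.baseline_stats first"
        )
    return unit.baseline_mean >= config.min_baseline_rate_hz


def screen_session(session: Session, config: AnalysisConfig = AnalysisConfig()) -> None:
    """Assign ``unit_class`` in place for every unit of a session."""
    for u in session.units:
        u.unit_class = classify_unit(u.mean_rate, u.half_valley_width, config)


def msns(units: Iterable[Unit]) -> list[Unit]:
    return [u for u in units if u.unit_class == "MSN"]
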