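"""Analysis configuration shared across pipeline stages.

All durations are seconds unless a field name says otherwise. The defaults
encode the standard analysis settings for discrete-trial fixed-ratio
sessions: 10 ms peri-event bins spanning +/-250 ms around each of the seven
sequence events (lever insertion, presses 1-5, reward port entry), a 5 s
baseline window anchored 20 s before the event inside the inter-trial
interval, and twelve 250 ms response windows tested against baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class AnalysisConfig:
    # peri-event binning: 51 bins of 10 ms with centers -250..+250 ms
    bin_width: float = 0.010
    event_window: float = 0.250
    n_bins_per_event: int = 51

    # baseline: 5 s window starting 20 s before the anchor event
    baseline_duration: float = 5.0
    baseline_offset: float = 20.0
    #: re-anchor the baseline at every event rather than once per trial
    baseline_per_event: bool = False

    # task-responsiveness: 12 windows (post-insertion, pre/post presses 1-5,
    # pre-port-entry), each tested at alpha against baseline
    trn_alpha: float = 0.01
    n_event_windows: int = 12
    #: Welch's t-test by default; set False for Student's equal-variance test
    welch: bool = True

    # unit screening thresholds (Hz, ms)
    fsi_rate_hz: float = 20.0
    fsi_half_valley_ms: float = 0.15
    unclassified_rate_lo_hz: float = 12.5
    min_baseline_rate_hz: float = 0.5

    # Fourier band cuts for Phasic/Non-phasic separation (Hz)
    low_cut: float = 1.0
    mid_cut: float = 4.0
    #: variance-stabilizing transform applied to the band powers before
    #: level-1 clustering: "sqrt" (default; the classical stabilizer for
    #: chi-squared-distributed power estimates), "log", or "none"
    power_transform: str = "sqrt"
    #: standardize band-power features column-wise before level-1 clustering
    standardize_features: bool = False
    #: decorrelate and rescale (PCA-whiten) the standardized band powers
    whiten_features: bool = False

    # clustering
    k_list: tuple[int, ...] = tuple(range(1, 11))
    n_perm: int = 1000
    k1_alpha: float = 0.05

    # decoding
    n_decode_reps: int = 50
    n_folds: int = 10
    ensemble_sizes: tuple[int, ...] = (60, 120, 200, 400, 600)
    n_pcs: int = 3

    # trial-by-trial correlation
    epoch_window: float = 0.500
    n_shuffles: int = 1000
    corr_alpha: float = 0.05
    min_trials: int = 10
    #: response rate denominator: lever availability (insertion->retraction);
    #: set True for the (n_presses-1)/sequence_duration alternative
    rate_per_sequence_duration: bool = False

    # behavior
    devaluation_threshold: float = 0.45

    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.event_window <= 0:
            raise ValueError("bin_width and event_window must be positive")
        if self.baseline_duration <= 0 or self.baseline_offset <= 0:
            raise ValueError("baseline windows must have positive duration")
        if not 0.0 < self.trn_alpha < 1.0:
            raise ValueError("trn_alpha must lie in (0, 1)")
        if self.low_cut >= self.mid_cut:
            raise ValueError("low_cut must be below mid_cut")

    @property
    def sampling_rate(self) -> float:
        """Effective sampling rate of the binned signal (Hz)."""
        return 1.0 / self.bin_width

    def replace(self, **kwargs) -> "AnalysisConfig":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kwargs)
        return AnalysisConfig(**vals)


#: the seven sequence events, in order
SEQUENCE_EVENTS = (
    "lever_insertion",
    "press_1",
    "press_2",
    "press_3",
    "press_4",
    "press_5",
    "reward_port_entry",
)

#: the twelve tested response windows as (event index, side) pairs;
#: side "post" is [0, +250 ms), side "pre" is [-250 ms, 0)
RESPONSE_WINDOWS = (
    (0, "post"),
    (1, "pre"), (1, "post"),
    (2, "pre"), (2, "post"),
    (3, "pre"), (3, "post"),
    (4, "pre"), (4, "post"),
    (5, "pre"), (5, "post"),
    (6, "pre"),
)
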