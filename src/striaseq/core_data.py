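"""Domain types and session bundle I/O.

A session bundle is a directory holding::

    events.csv          trial_index, event_type, time_s
    units.csv           unit_id, region, mean_rate_hz, half_valley_ms
    spikes/<unit>.csv   one spike timestamp (s) per line, header "time_s"
    session.json        stage, ratio, rat_id, session_id, provenance

All timestamps are seconds from session start. Event types are
``lever_insertion``, ``lever_press``, ``lever_retraction``, ``port_entry``
(the post-retraction reward port entry or a within-sequence entry) and
``iti_port_entry``. Windows throughout the package are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

REGIONS = ("DLS", "DMS")
STAGES = ("DT1", "DT5_early", "extended")
EVENT_TYPES = (
    "lever_insertion",
    "lever_press",
    "lever_retraction",
    "port_entry",
    "iti_port_entry",
)


class ValidationError(ValueError):
    """A session bundle violates one or more structural invariants."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class ParseError(ValueError):
    """A session bundle file is malformed."""


@dataclass
class Unit:
    """One recorded (or simulated) neuron."""

    unit_id: str
    region: str
    spikes: np.ndarray
    mean_rate: float
    half_valley_width: float
    rat_id: str = ""
    unit_class: str = "unclassified"  # MSN | FSI | unclassified
    baseline_mean: Optional[float] = None  # Hz, derived by psth.baseline_stats
    baseline_sd: Optional[float] = None
    archetype: Optional[str] = None  # synthetic ground truth, if any

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)

    def validate(self) -> list[str]:
        errs = []
        if self.region not in REGIONS:
            errs.append(f"unit {self.unit_id}: region {self.region!r} not in {REGIONS}")
        if self.spikes.ndim != 1:
            errs.append(f"unit {self.unit_id}: spikes must be 1-D")
        elif len(self.spikes) > 1 and not np.all(np.diff(self.spikes) > 0):
            errs.append(f"unit {self.unit_id}: spike times not strictly increasing")
        if self.mean_rate < 0:
            errs.append(f"unit {self.unit_id}: mean_rate {self.mean_rate} < 0")
        if self.half_valley_width <= 0:
            errs.append(
                f"unit {self.unit_id}: half_valley_width {self.half_valley_width} <= 0"
            )
        return errs


@dataclass
class Trial:
    """One discrete trial: lever insertion through reward retrieval."""

    lever_insertion: float
    press_times: list[float] = field(default_factory=list)
    lever_retraction: Optional[float] = None
    reward_port_entry: Optional[float] = None
    within_sequence_port_entries: list[float] = field(default_factory=list)
    omission: bool = False

    @property
    def n_presses(self) -> int:
        return len(self.press_times)

    @property
    def first_press(self) -> Optional[float]:
        return self.press_times[0] if self.press_times else None

    @property
    def last_press(self) -> Optional[float]:
        return self.press_times[-1] if self.press_times else None

    def validate(self, index: int, ratio: int) -> list[str]:
        errs = []
        p = np.asarray(self.press_times, dtype=float)
        if len(p) > 1 and not np.all(np.diff(p) > 0):
            errs.append(f"trial {index}: press times not strictly increasing")
        if len(p) and p[0] <= self.lever_insertion:
            errs.append(f"trial {index}: press before lever insertion")
        if self.lever_retraction is not None and len(p) and p[-1] > self.lever_retraction:
            errs.append(f"trial {index}: press after lever retraction")
        if not self.omission and len(p) != ratio:
            errs.append(
                f"trial {index}: rewarded trial has {len(p)} presses, expected {ratio}"
            )
        if self.omission and len(p) >= ratio:
            errs.append(f"trial {index}: omission flagged but ratio completed")
        return errs


@dataclass
class Session:
    """One behavioral session with its recorded unit set."""

    session_id: str
    stage: str  # DT1 | DT5_early | extended
    ratio: int  # 1 or 5
    trials: list[Trial]
    units: list[Unit]
    iti_port_entries: list[float] = field(default_factory=list)
    rat_id: str = ""
    stage_index: Optional[int] = None  # 1..3 for DT1, 1..10 for DT5_early
    provenance: dict = field(default_factory=dict)

    @property
    def rewarded_trials(self) -> list[Trial]:
        return [t for t in self.trials if not t.omission]

    def validate(self) -> None:
        errs: list[str] = []
        if self.stage not in STAGES:
            errs.append(f"stage {self.stage!r} not in {STAGES}")
        if self.ratio not in (1, 5):
            errs.append(f"ratio {self.ratio} not in (1, 5)")
        if self.stage == "DT1" and self.ratio != 1:
            errs.append("DT1 session must use ratio 1")
        if self.stage in ("DT5_early", "extended") and self.ratio != 5:
            errs.append(f"{self.stage} session must use ratio 5")
        if len(self.trials) > 30:
            errs.append(f"{len(self.trials)} trials exceeds the 30-trial session")
        starts = [t.lever_insertion for t in self.trials]
        if sorted(starts) != starts:
            errs.append("trials out of order")
        prev_end = -np.inf
        for i, t in enumerate(self.trials):
            errs.extend(t.validate(i, self.ratio))
            if t.lever_insertion < prev_end:
                errs.append(f"trial {i} overlaps previous trial")
            prev_end = max(
                [t.lever_insertion]
                + t.press_times
                + [x for x in (t.lever_retraction, t.reward_port_entry) if x is not None]
            )
        spans = [
            (t.lever_insertion, t.lever_retraction)
            for t in self.trials
            if t.lever_retraction is not None
        ]
        for pe in self.iti_port_entries:
            if any(a <= pe < b for a, b in spans):
                errs.append(f"ITI port entry at {pe:.3f}s falls inside a trial")
        for u in self.units:
            errs.extend(u.validate())
        if errs:
            raise ValidationError(errs)


# ---------------------------------------------------------------------------
# bundle I/O


def write_session(session: Session, path: str | Path) -> None:
    """Serialize a session bundle; timestamps kept to nanosecond precision."""
    path = Path(path)
    (path / "spikes").mkdir(parents=True, exist_ok=True)

    rows = []
    for i, t in enumerate(session.trials):
        rows.append((i, "lever_insertion", t.lever_insertion))
        rows.extend((i, "lever_press", p) for p in t.press_times)
        if t.lever_retraction is not None:
            rows.append((i, "lever_retraction", t.lever_retraction))
        if t.reward_port_entry is not None:
            rows.append((i, "port_entry", t.reward_port_entry))
        rows.extend((i, "port_entry", p) for p in t.within_sequence_port_entries)
    rows.extend((-1, "iti_port_entry", p) for p in session.iti_port_entries)
    events = pd.DataFrame(rows, columns=["trial_index", "event_type", "time_s"])
    events.to_csv(path / "events.csv", index=False, float_format="%.9f")

    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "region": [u.region for u in session.units],
            "mean_rate_hz": [u.mean_rate for u in session.units],
            "half_valley_ms": [u.half_valley_width for u in session.units],
            "unit_class": [u.unit_class for u in session.units],
            "archetype": [u.archetype or "" for u in session.units],
        }
    )
    units.to_csv(path / "units.csv", index=False, float_format="%.9f")
    for u in session.units:
        pd.DataFrame({"time_s": u.spikes}).to_csv(
            path / "spikes" / f"{u.unit_id}.csv", index=False, float_format="%.9f"
        )

    meta = {
        "session_id": session.session_id,
        "stage": session.stage,
        "stage_index": session.stage_index,
        "ratio": session.ratio,
        "rat_id": session.rat_id,
        "omissions": [i for i, t in enumerate(session.trials) if t.omission],
        "provenance": session.provenance,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))


def load_session(path: str | Path, validate: bool = True) -> Session:
    """Load and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    try:
        meta = json.loads((path / "session.json").read_text())
        events = pd.read_csv(path / "events.csv")
        units_df = pd.read_csv(path / "units.csv", keep_default_na=False)
    except (OSError, ValueError, KeyError) as e:
        raise ParseError(f"cannot read session bundle at {path}: {e}") from e
    missing = {"trial_index", "event_type", "time_s"} - set(events.columns)
    if missing:
        raise ParseError(f"events.csv missing columns {sorted(missing)}")
    bad = set(events["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ParseError(f"events.csv has unknown event types {sorted(bad)}")

    omissions = set(meta.get("omissions", []))
    trials = []
    for idx, grp in events[events["trial_index"] >= 0].groupby("trial_index"):
        by = {k: sorted(g["time_s"]) for k, g in grp.groupby("event_type")}
        ins = by.get("lever_insertion", [])
        if len(ins) != 1:
            raise ParseError(f"trial {idx}: expected one lever_insertion, got {len(ins)}")
        retraction = by.get("lever_retraction", [None])[-1]
        presses = by.get("lever_press", [])
        port = by.get("port_entry", [])
        reward_pe, within = None, []
        for p in port:
            if retraction is not None and p >= retraction and reward_pe is None:
                reward_pe = p
            else:
                within.append(p)
        trials.append(
            Trial(
                lever_insertion=ins[0],
                press_times=presses,
                lever_retraction=retraction,
                reward_port_entry=reward_pe,
                within_sequence_port_entries=within,
                omission=int(idx) in omissions,
            )
        )

    units = []
    for _, r in units_df.iterrows():
        spikes_file = path / "spikes" / f"{r['unit_id']}.csv"
        try:
            sp = pd.read_csv(spikes_file)["time_s"].to_numpy(dtype=float)
        except (OSError, ValueError, KeyError) as e:
            raise ParseError(f"cannot read spikes for unit {r['unit_id']}: {e}") from e
        units.append(
            Unit(
                unit_id=str(r["unit_id"]),
                region=str(r["region"]),
                spikes=sp,
                mean_rate=float(r["mean_rate_hz"]),
                half_valley_width=float(r["half_valley_ms"]),
                rat_id=str(meta.get("rat_id", "")),
                unit_class=str(r.get("unit_class", "unclassified") or "unclassified"),
                archetype=str(r.get("archetype", "")) or None,
            )
        )

    session = Session(
        session_id=str(meta.get("session_id", path.name)),
        stage=meta["stage"],
        ratio=int(meta["ratio"]),
        trials=trials,
        units=units,
        iti_port_entries=sorted(
            events.loc[events["event_type"] == "iti_port_entry", "time_s"]
        ),
        rat_id=str(meta.get("rat_id", "")),
        stage_index=meta.get("stage_index"),
        provenance=meta.get("provenance", {}),
    )
    if validate:
        session.validate()
    return session


def sessions_equal(a: Session, b: Session, tol: float = 1e-9) -> bool:
    """Field-by-field equality with a timestamp tolerance."""

    def close(x, y):
        if x is None or y is None:
            return x is None and y is None
        return abs(x - y) <= tol

    if (a.session_id, a.stage, a.ratio, a.rat_id) != (b.session_id, b.stage, b.ratio, b.rat_id):
        return False
    if len(a.trials) != len(b.trials) or len(a.units) != len(b.units):
        return False
    for ta, tb in zip(a.trials, b.trials):
        if ta.omission != tb.omission or len(ta.press_times) != len(tb.press_times):
            return False
        if not close(ta.lever_insertion, tb.lever_insertion):
            return False
        if not all(close(x, y) for x, y in zip(ta.press_times, tb.press_times)):
            return False
        if not (close(ta.lever_retraction, tb.lever_retraction)
                and close(ta.reward_port_entry, tb.reward_port_entry)):
            return False
    if len(a.iti_port_entries) != len(b.iti_port_entries):
        return False
    if not all(close(x, y) for x, y in zip(a.iti_port_entries, b.iti_port_entries)):
        return False
    for ua, ub in zip(a.units, b.units):
        if ua.unit_id != ub.unit_id or ua.region != ub.region:
            return False
        if len(ua.spikes) != len(ub.spikes):
            return False
        if len(ua.spikes) and np.max(np.abs(ua.spikes - ub.spikes)) > tol:
            return False
    return True
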