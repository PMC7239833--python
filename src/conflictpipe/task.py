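"""Deterministic model of the threat-of-punishment operant task.

The task: a rat receives a sucrose pellet every trial at a fixed interval.
On half of the trials pellet delivery coincides with a 12-s audiovisual
threat cue; entering the food port while the cue is on is punished with a
brief foot shock, whereas waiting out the cue allows free retrieval
("success").  On the other half ("no-stimulus" trials) the pellet can be
retrieved immediately.  This module turns session event streams into
per-trial outcomes and session-level statistics, including the shock
index, and implements the between-session foot-shock titration policy.

All times are seconds from session start; trial ``k`` spans
``[k * trial_duration, (k + 1) * trial_duration)``, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_KINDS",
    "TRIAL_TYPES",
    "OUTCOMES",
    "SessionConfig",
    "Event",
    "EventStream",
    "TrialSpec",
    "TrialRecord",
    "SessionSummary",
    "TitrationPolicy",
    "build_schedule",
    "build_trial_events",
    "classify_trial",
    "classify_session",
    "shock_index",
    "summarize",
    "titrate_intensity",
]

EVENT_KINDS = (
    "pellet_drop",
    "stimulus_on",
    "stimulus_off",
    "port_entry",
    "port_exit",
    "shock",
    "houselight_on",
    "houselight_off",
)

TRIAL_TYPES = ("stimulus", "no_stimulus")

#: success  - stimulus trial, first port entry at/after cue offset
#: shock    - stimulus trial, first port entry during the cue (punished)
#: omission - no port entry within the trial window (either trial type)
#: retrieved - no-stimulus trial with a port entry
OUTCOMES = ("success", "shock", "omission", "retrieved")

VARIANTS = ("standard", "houselight", "stimulus_only", "nostim_only")


@dataclass(frozen=True)
class SessionConfig:
    """Geometry and parameters of one task session.

    Defaults reproduce the published task: 60 trials of 40 s, half of them
    carrying a 12-s audiovisual cue, 0.3-s foot shock, initial intensity
    0.35 mA.  The ``houselight`` variant (used for photometry sessions)
    additionally signals each upcoming pellet drop with the house light,
    switched on ``houselight_lead`` s before and off ``houselight_tail`` s
    after the drop.
    """

    n_trials: int = 60
    trial_duration: float = 40.0
    stimulus_fraction: float = 0.5
    stimulus_duration: float = 12.0
    shock_duration: float = 0.3
    shock_intensity: float = 0.35
    variant: str = "standard"
    houselight_lead: float = 5.0
    houselight_tail: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.stimulus_fraction <= 1.0:
            raise ValueError("stimulus_fraction must lie in [0, 1]")
        if not 0.0 < self.stimulus_duration < self.trial_duration:
            raise ValueError("stimulus_duration must lie in (0, trial_duration)")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.shock_intensity <= 0:
            raise ValueError("shock_intensity must be positive")

    @property
    def session_duration(self) -> float:
        return self.n_trials * self.trial_duration


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    trial_index: int

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


class EventStream:
    """Timestamped behavioral/task events for one session.

    Thin wrapper over a DataFrame with columns ``time_s``, ``event``,
    ``trial_index``; times must be non-decreasing.
    """

    COLUMNS = ("time_s", "event", "trial_index")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"event frame missing columns {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        times = frame["time_s"].to_numpy(dtype=float)
        if len(times) and np.any(np.diff(times) < 0):
            raise ValueError("event times must be non-decreasing")
        bad = set(frame["event"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds {sorted(bad)}")
        self.frame = frame

    @classmethod
    def from_events(cls, events: Iterable[Event]) -> "EventStream":
        events = sorted(events, key=lambda e: e.time)
        return cls(
            pd.DataFrame(
                {
                    "time_s": [e.time for e in events],
                    "event": [e.kind for e in events],
                    "trial_index": [e.trial_index for e in events],
                }
            )
        )

    def __len__(self) -> int:
        return len(self.frame)

    def trial(self, trial_index: int) -> pd.DataFrame:
        return self.frame[self.frame["trial_index"] == trial_index]

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.frame[self.frame["event"] == kind]

    def trial_indices(self) -> list[int]:
        return sorted(self.frame["trial_index"].unique())


@dataclass(frozen=True)
class TrialSpec:
    """One row of the session schedule."""

    trial_index: int
    trial_type: str
    start_time: float


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    trial_type: str
    outcome: str
    latency: float | None  # first port entry relative to pellet drop
    shocked: bool

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "shock" and (self.trial_type != "stimulus" or not self.shocked):
            raise ValueError("shock outcome requires a shocked stimulus trial")
        if self.outcome == "omission" and self.latency is not None:
            raise ValueError("omission carries no latency")
        if self.outcome == "retrieved" and self.trial_type != "no_stimulus":
            raise ValueError("retrieved outcome only for no-stimulus trials")


@dataclass(frozen=True)
class SessionSummary:
    """Per-outcome counts and latency medians for one session.

    ``shock_index`` is the fraction of punished stimulus trials among the
    resolved (non-omitted) ones: ``100 * shock / (shock + success)``; it is
    ``nan`` when no stimulus trial was resolved.
    """

    n_success: int
    n_shock: int
    n_omission_stim: int
    n_retrieved: int
    n_omission_nostim: int
    shock_index: float
    latency_median_by_outcome: dict[str, float]

    @property
    def n_trials(self) -> int:
        return (
            self.n_success
            + self.n_shock
            + self.n_omission_stim
            + self.n_retrieved
            + self.n_omission_nostim
        )

    @property
    def n_stimulus_trials(self) -> int:
        return self.n_success + self.n_shock + self.n_omission_stim

    def to_dict(self) -> dict:
        return {
            "n_success": self.n_success,
            "n_shock": self.n_shock,
            "n_omission_stim": self.n_omission_stim,
            "n_retrieved": self.n_retrieved,
            "n_omission_nostim": self.n_omission_nostim,
            "shock_index": self.shock_index,
            "latency_median_by_outcome": dict(self.latency_median_by_outcome),
        }


def build_schedule(config: SessionConfig) -> list[TrialSpec]:
    """Construct the randomized trial order for one session.

    Exactly ``round(n_trials * stimulus_fraction)`` stimulus trials are
    interleaved with no-stimulus trials in a seeded random order
    (``config.rng_seed``).  The ``stimulus_only`` / ``nostim_only``
    variants emit a single trial type.
    """
    n = config.n_trials
    if config.variant == "stimulus_only":
        n_stim = n
    elif config.variant == "nostim_only":
        n_stim = 0
    else:
        n_stim = int(round(n * config.stimulus_fraction))
    types = np.array(["stimulus"] * n_stim + ["no_stimulus"] * (n - n_stim), dtype=object)
    rng = np.random.default_rng(config.rng_seed)
    types = types[rng.permutation(n)]
    return [
        TrialSpec(trial_index=k, trial_type=types[k], start_time=k * config.trial_duration)
        for k in range(n)
    ]


def build_trial_events(
    spec: TrialSpec,
    config: SessionConfig,
    entry_time: float | None,
) -> list[Event]:
    """Emit the task-side events of one trial given the first-entry time.

    ``entry_time`` is the first port entry relative to pellet drop (None
    for an omitted trial).  On a punished entry the stimulus terminates at
    the entry and a ``shock`` event is emitted immediately.
    """
    t0 = spec.start_time
    k = spec.trial_index
    events = [Event(t0, "pellet_drop", k)]
    if config.variant == "houselight":
        on = max(0.0, t0 - config.houselight_lead)
        events.append(Event(on, "houselight_on", k))
        events.append(Event(t0 + config.houselight_tail, "houselight_off", k))
    if spec.trial_type == "stimulus":
        events.append(Event(t0, "stimulus_on", k))
        if entry_time is not None and entry_time < config.stimulus_duration:
            # punished entry: cue terminates, shock delivered
            events.append(Event(t0 + entry_time, "stimulus_off", k))
            events.append(Event(t0 + entry_time, "shock", k))
        else:
            events.append(Event(t0 + config.stimulus_duration, "stimulus_off", k))
    if entry_time is not None:
        events.append(Event(t0 + entry_time, "port_entry", k))
    return events


def _first_entry_latency(
    trial_events: pd.DataFrame, spec: TrialSpec, config: SessionConfig
) -> float | None:
    t0 = spec.start_time
    t1 = t0 + config.trial_duration
    times = trial_events["time_s"].to_numpy(dtype=float)
    if len(times) and (times.min() < t0 or times.max() >= t1):
        raise ValueError(
            f"trial {spec.trial_index}: events outside window [{t0}, {t1})"
        )
    drops = trial_events[trial_events["event"] == "pellet_drop"]
    if len(drops) == 0:
        raise ValueError(f"trial {spec.trial_index}: missing pellet_drop event")
    t_drop = float(drops["time_s"].iloc[0])
    entries = trial_events[trial_events["event"] == "port_entry"]
    if len(entries) == 0:
        return None
    return float(entries["time_s"].iloc[0]) - t_drop


def classify_trial(
    events: EventStream | pd.DataFrame, spec: TrialSpec, config: SessionConfig
) -> TrialRecord:
    """Classify one trial from its event stream.

    Stimulus trial: first port entry before cue offset -> ``shock``;
    at/after cue offset -> ``success``; none -> ``omission``.  No-stimulus
    trial: any entry -> ``retrieved``; none -> ``omission``.  Latency is
    the first port entry relative to pellet drop; events after the first
    entry carry no task consequence.
    """
    frame = events.frame if isinstance(events, EventStream) else events
    trial_events = frame[frame["trial_index"] == spec.trial_index]
    if config.variant == "houselight":
        # the lead house-light event lives in the preceding trial window
        trial_events = trial_events[trial_events["event"] != "houselight_on"]
    latency = _first_entry_latency(trial_events, spec, config)
    if spec.trial_type == "stimulus":
        if latency is None:
            outcome, shocked = "omission", False
        elif latency < config.stimulus_duration:
            outcome, shocked = "shock", True
        else:
            outcome, shocked = "success", False
    else:
        if latency is None:
            outcome, shocked = "omission", False
        else:
            outcome, shocked = "retrieved", False
    return TrialRecord(
        trial_index=spec.trial_index,
        trial_type=spec.trial_type,
        outcome=outcome,
        latency=latency,
        shocked=shocked,
    )


def classify_session(
    events: EventStream, schedule: Sequence[TrialSpec], config: SessionConfig
) -> list[TrialRecord]:
    """Classify every trial of a session against its schedule."""
    return [classify_trial(events, spec, config) for spec in schedule]


def shock_index(n_shock: int, n_success: int) -> float:
    """``100 * shock / (shock + success)`` — failed inhibition among
    resolved stimulus trials, corrected for omissions."""
    if n_shock < 0 or n_success < 0:
        raise ValueError("counts must be non-negative")
    total = n_shock + n_success
    if total == 0:
        raise ZeroDivisionError("shock index undefined: no resolved stimulus trials")
    return 100.0 * n_shock / total


def summarize(records: Sequence[TrialRecord]) -> SessionSummary:
    """Tally per-outcome counts, latency medians and the shock index."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record list")
    indices = [r.trial_index for r in records]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate trial_index in records")
    n_success = sum(r.outcome == "success" for r in records)
    n_shock = sum(r.outcome == "shock" for r in records)
    n_retrieved = sum(r.outcome == "retrieved" for r in records)
    n_om_stim = sum(r.outcome == "omission" and r.trial_type == "stimulus" for r in records)
    n_om_nostim = sum(
        r.outcome == "omission" and r.trial_type == "no_stimulus" for r in records
    )
    medians: dict[str, float] = {}
    for outcome in OUTCOMES:
        lats = [r.latency for r in records if r.outcome == outcome and r.latency is not None]
        medians[outcome] = float(np.median(lats)) if lats else float("nan")
    si = (
        shock_index(n_shock, n_success)
        if n_shock + n_success > 0
        else float("nan")
    )
    return SessionSummary(
        n_success=n_success,
        n_shock=n_shock,
        n_omission_stim=n_om_stim,
        n_retrieved=n_retrieved,
        n_omission_nostim=n_om_nostim,
        shock_index=si,
        latency_median_by_outcome=medians,
    )


@dataclass(frozen=True)
class TitrationPolicy:
    """Between-session foot-shock adjustment rule.

    Intensity holds when at least ``hold_fraction`` of stimulus trials
    were successes (20/30 in the published protocol); it steps up when
    punished trials are the strict majority (shock too mild) and down
    when omitted trials are the strict majority (shock too intense).
    """

    step_up: float = 0.05
    step_down: float = 0.05
    hold_fraction: float = 2.0 / 3.0
    min_intensity: float = 0.05


def titrate_intensity(
    current: float, summary: SessionSummary, policy: TitrationPolicy | None = None
) -> float:
    """Apply the titration policy to one completed session."""
    if current <= 0:
        raise ValueError("current intensity must be positive")
    policy = policy or TitrationPolicy()
    n_stim = summary.n_stimulus_trials
    if n_stim == 0:
        return current
    # hold criterion is checked first
    if summary.n_success >= policy.hold_fraction * n_stim - 1e-12:
        return current
    if summary.n_shock > 0.5 * n_stim:
        return current + policy.step_up
    if summary.n_omission_stim > 0.5 * n_stim:
        return max(current - policy.step_down, policy.min_intensity)
    return current
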