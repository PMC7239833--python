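"""Synthetic data with ground truth for every analysis stage.

Three generators, one per data modality:

* :func:`simulate_agent_session` — a stochastic agent playing the operant
  task, emitting the session event stream plus the true per-trial
  outcomes and latencies;
* :func:`simulate_photometry` — a GCaMP6s-like fluorescence trace locked
  to a session's events under one of three hypothesised response
  patterns (value/reward-prediction-error coding, movement coding, or
  inhibition coding);
* :func:`render_fos_image` — a DAB-style micrograph of nucleus-sized
  spots on a slowly varying noisy background, with true coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .task import (
    Event,
    EventStream,
    SessionConfig,
    TrialSpec,
    build_schedule,
    build_trial_events,
)

__all__ = [
    "OscillationParams",
    "AgentParams",
    "SessionGroundTruth",
    "PhotometryModel",
    "PhotometryGroundTruth",
    "FosImageSpec",
    "FosGroundTruth",
    "simulate_agent_session",
    "simulate_photometry",
    "render_fos_image",
]

HYPOTHESES = ("value_rpe", "movement", "inhibition")


@dataclass(frozen=True)
class OscillationParams:
    """Attract-repel bout structure around pellet retrieval.

    Rats oscillate between approaching the visible pellet and retreating
    from the port, with the retreat faster than the approach.  The agent
    renders this as short port entry/exit bouts: each cycle spends
    ``period * dwell_fraction`` s in the port and an out-of-port interval
    proportional to ``1/approach_speed + 1/retreat_speed``.
    """

    period: float = 2.0
    approach_speed: float = 1.0
    retreat_speed: float = 3.0
    dwell_fraction: float = 0.2
    mean_cycles: float = 2.0

    def __post_init__(self) -> None:
        if self.retreat_speed <= self.approach_speed:
            raise ValueError("retreat must be faster than approach")
        if self.period <= 0:
            raise ValueError("period must be positive")


def _logistic_success(i50: float = 0.45, slope: float = 0.1, p_max: float = 0.95):
    def p(intensity: float) -> float:
        return p_max / (1.0 + math.exp(-(intensity - i50) / slope))

    return p


@dataclass(frozen=True)
class AgentParams:
    """Stochastic policy of a synthetic rat.

    ``p_success`` is the probability of waiting out the threat cue as a
    function of shock intensity (a constant or any non-decreasing
    callable); ``p_omit`` the probability of ignoring a trial entirely.
    Retrieval latencies are log-normal in seconds.
    """

    p_success: float | Callable[[float], float] = field(default_factory=_logistic_success)
    p_omit: float = 0.05
    latency_mu: float = 0.5   # log-seconds
    latency_sigma: float = 0.5
    oscillation: OscillationParams = field(default_factory=OscillationParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_omit <= 1.0:
            raise ValueError("p_omit must lie in [0, 1]")

    def p_success_at(self, intensity: float) -> float:
        p = self.p_success if not callable(self.p_success) else self.p_success(intensity)
        if not 0.0 <= p <= 1.0:
            raise ValueError("p_success must lie in [0, 1]")
        return float(p)


@dataclass
class SessionGroundTruth:
    """True per-trial outcomes and latencies behind a simulated session."""

    frame: pd.DataFrame  # trial_index, trial_type, outcome, latency

    def outcome(self, trial_index: int) -> str:
        row = self.frame.loc[self.frame["trial_index"] == trial_index]
        return str(row["outcome"].iloc[0])


def _draw_latency(rng: np.random.Generator, agent: AgentParams,
                  low: float, high: float) -> float:
    """Log-normal latency rejected into (low, high); falls back to the
    midpoint if the window is improbably narrow."""
    for _ in range(1000):
        lat = low + rng.lognormal(agent.latency_mu, agent.latency_sigma)
        if lat < high:
            return lat
    return 0.5 * (low + high)


def _oscillation_events(
    rng: np.random.Generator,
    osc: OscillationParams,
    trial_index: int,
    t_entry: float,
    t_end: float,
) -> list[Event]:
    """Attract-repel bouts starting at the classified first entry.

    The first port entry is the task-relevant one; subsequent exit/entry
    pairs portray the approach-avoidance oscillation and are ignored by
    the classifier.
    """
    events: list[Event] = []
    n_cycles = int(rng.poisson(osc.mean_cycles))
    dwell = osc.period * osc.dwell_fraction
    out = osc.period * 0.5 * (1.0 / osc.approach_speed + 1.0 / osc.retreat_speed)
    t = t_entry
    for _ in range(n_cycles):
        t_exit = t + dwell * (0.5 + rng.random())
        t_back = t_exit + out * (0.5 + rng.random())
        if t_back >= t_end - 1e-9:
            break
        events.append(Event(t_exit, "port_exit", trial_index))
        events.append(Event(t_back, "port_entry", trial_index))
        t = t_back
    return events


def simulate_agent_session(
    config: SessionConfig, agent: AgentParams, seed: int
) -> tuple[EventStream, SessionGroundTruth, list[TrialSpec]]:
    """Play one session; return its events, ground truth and schedule.

    Stimulus trials resolve to success with probability
    ``p_success(intensity)``, to omission with ``p_omit``, otherwise to a
    punished (shock) entry during the cue.  Success entries fall after
    cue offset; shock entries within the cue; no-stimulus retrievals
    shortly after the drop.
    """
    ps = agent.p_success_at(config.shock_intensity)
    if ps + agent.p_omit > 1.0 + 1e-12:
        raise ValueError("p_success + p_omit exceeds 1")
    rng = np.random.default_rng(seed)
    schedule = build_schedule(config)
    all_events: list[Event] = []
    rows = []
    for spec in schedule:
        t_end = spec.start_time + config.trial_duration
        if spec.trial_type == "stimulus":
            u = rng.random()
            if u < ps:
                outcome = "success"
                latency = _draw_latency(
                    rng, agent, config.stimulus_duration, config.trial_duration
                )
            elif u < ps + agent.p_omit:
                outcome, latency = "omission", None
            else:
                outcome = "shock"
                latency = _draw_latency(rng, agent, 0.0, config.stimulus_duration)
        else:
            if rng.random() < agent.p_omit:
                outcome, latency = "omission", None
            else:
                outcome = "retrieved"
                latency = _draw_latency(rng, agent, 0.0, config.trial_duration)
        all_events.extend(build_trial_events(spec, config, latency))
        if latency is not None:
            all_events.extend(
                _oscillation_events(
                    rng, agent.oscillation, spec.trial_index,
                    spec.start_time + latency, t_end,
                )
            )
        rows.append(
            {
                "trial_index": spec.trial_index,
                "trial_type": spec.trial_type,
                "outcome": outcome,
                "latency": latency if latency is not None else np.nan,
            }
        )
    stream = EventStream.from_events(all_events)
    truth = SessionGroundTruth(pd.DataFrame(rows))
    return stream, truth, schedule


# ---------------------------------------------------------------------------
# photometry


@dataclass(frozen=True)
class PhotometryModel:
    """Generative model of a single-channel GCaMP6s photometry trace.

    ``hypothesis`` selects where event-locked activity is placed:

    * ``value_rpe`` — activity ramps from the moment the pellet becomes
      safely available (drop on no-stimulus trials, cue offset on
      success trials) up to retrieval, plus a positive transient after a
      foot shock; no approach-locked activity on shock trials.
    * ``movement`` — a transient at every port entry regardless of trial
      type.
    * ``inhibition`` — sustained elevation while the animal withholds
      entry during the cue.

    The trace is ``baseline * exp(-t/bleach_tau) * (1 + s(t)) + noise``
    where ``s`` is the summed event-locked signal, built from a
    difference-of-exponentials kernel (``kernel_rise`` < ``kernel_decay``).
    """

    hypothesis: str = "value_rpe"
    kernel_rise: float = 0.2
    kernel_decay: float = 1.5
    event_amplitudes: dict = field(
        default_factory=lambda: {"approach": 0.05, "shock": 0.08,
                                 "movement": 0.05, "inhibition": 0.05}
    )
    baseline: float = 100.0
    bleach_tau: float = 1800.0
    noise_sd: float = 0.2
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.kernel_rise < self.kernel_decay:
            raise ValueError("need kernel_decay > kernel_rise > 0")
        if self.sampling_rate < 10.0:
            raise ValueError("sampling_rate must be at least 10 Hz")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.sampling_rate * self.kernel_rise < 2.0:
            raise ValueError("sampling_rate too low to resolve kernel_rise")


@dataclass
class PhotometryGroundTruth:
    """Noiseless fractional signal and the event-locked drive behind it."""

    signal: np.ndarray          # noiseless s(t), fractional units
    transients: pd.DataFrame    # time_s, kind, amplitude
    bleach: np.ndarray          # multiplicative bleaching baseline


def _kernel(model: PhotometryModel) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak."""
    dt = 1.0 / model.sampling_rate
    t = np.arange(0.0, model.kernel_decay * 8.0, dt)
    k = np.exp(-t / model.kernel_decay) - np.exp(-t / model.kernel_rise)
    return k / k.max()


def simulate_photometry(
    events: EventStream,
    model: PhotometryModel,
    seed: int,
    config: SessionConfig | None = None,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray, PhotometryGroundTruth]:
    """Synthesize a raw fluorescence trace locked to a session's events.

    Returns ``(time, F, ground_truth)``.  ``duration`` defaults to the
    session length implied by ``config`` (or the last event + 40 s).
    """
    config = config or SessionConfig()
    fs = model.sampling_rate
    dt = 1.0 / fs
    if duration is None:
        last = events.frame["time_s"].max() if len(events) else 0.0
        duration = max(config.session_duration, float(last) + config.trial_duration)
    n = int(round(duration * fs))
    t = np.arange(n) * dt
    kern = _kernel(model)
    kern_area = kern / kern.sum()

    impulse = np.zeros(n)   # delta drive, convolved with peak-1 kernel
    ramp = np.zeros(n)      # extended drive, convolved with area-1 kernel
    amps = model.event_amplitudes
    transients = []

    frame = events.frame

    def first_time(trial: pd.DataFrame, kind: str) -> float | None:
        sel = trial[trial["event"] == kind]
        return float(sel["time_s"].iloc[0]) if len(sel) else None

    for k in sorted(frame["trial_index"].unique()):
        trial = frame[frame["trial_index"] == k]
        t_drop = first_time(trial, "pellet_drop")
        t_on = first_time(trial, "stimulus_on")
        t_off = first_time(trial, "stimulus_off")
        t_entry = first_time(trial, "port_entry")
        t_shock = first_time(trial, "shock")
        if model.hypothesis == "value_rpe":
            anchor = None
            if t_entry is not None and t_shock is None:
                anchor = t_drop if t_on is None else t_off
            if anchor is not None and t_entry > anchor:
                i0, i1 = int(round(anchor * fs)), int(round(t_entry * fs))
                i1 = min(i1, n - 1)
                if i1 > i0:
                    ramp[i0 : i1 + 1] += amps["approach"] * np.linspace(0, 1, i1 - i0 + 1)
                    transients.append(
                        {"time_s": t_entry, "kind": "approach_ramp",
                         "amplitude": amps["approach"]}
                    )
            if t_shock is not None:
                i = int(round(t_shock * fs))
                if i < n:
                    impulse[i] += amps["shock"]
                    transients.append(
                        {"time_s": t_shock, "kind": "shock", "amplitude": amps["shock"]}
                    )
        elif model.hypothesis == "movement":
            for te in trial[trial["event"] == "port_entry"]["time_s"]:
                i = int(round(float(te) * fs))
                if i < n:
                    impulse[i] += amps["movement"]
                    transients.append(
                        {"time_s": float(te), "kind": "movement",
                         "amplitude": amps["movement"]}
                    )
        else:  # inhibition: sustained elevation while withholding entry
            if t_on is not None:
                hold_end = t_off if t_off is not None else t_on + config.stimulus_duration
                if t_entry is None or t_entry >= hold_end - 1e-9:
                    i0, i1 = int(round(t_on * fs)), min(int(round(hold_end * fs)), n - 1)
                    if i1 > i0:
                        ramp[i0:i1] += amps["inhibition"]
                        transients.append(
                            {"time_s": t_on, "kind": "inhibition_hold",
                             "amplitude": amps["inhibition"]}
                        )

    signal = np.convolve(impulse, kern)[:n] + np.convolve(ramp, kern_area)[:n]
    bleach = model.baseline * np.exp(-t / model.bleach_tau)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else 0.0
    F = bleach * (1.0 + signal) + noise
    truth = PhotometryGroundTruth(
        signal=signal,
        transients=pd.DataFrame(transients, columns=["time_s", "kind", "amplitude"]),
        bleach=bleach,
    )
    return t, F, truth


# ---------------------------------------------------------------------------
# histology


@dataclass(frozen=True)
class FosImageSpec:
    """Parameters of a synthetic DAB-style c-Fos micrograph.

    Spots are Gaussian-profile nuclei with full-width-half-maximum drawn
    from ``spot_diameter_range`` px, at least ``min_separation`` px
    apart, on a low-order polynomial background plus Gaussian noise.
    The default noise level keeps the band-passed peak SNR of the most
    attenuated (largest) nuclei above 5, about 10 for the median
    nucleus.  The generator writes
    bright spots on a dark background; pass ``polarity='dark_spots'`` for
    DAB-like dark nuclei on a light field.
    """

    size: tuple[int, int] = (256, 256)
    n_cells: int = 50
    spot_diameter_range: tuple[float, float] = (3.0, 6.0)
    spot_amplitude: float = 100.0
    background: float = 30.0
    noise_sd: float = 6.0
    min_separation: float = 8.0
    bit_depth: int = 16
    polarity: str = "bright_spots"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.spot_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("invalid spot_diameter_range")
        if self.polarity not in ("bright_spots", "dark_spots"):
            raise ValueError("polarity must be bright_spots or dark_spots")


@dataclass
class FosGroundTruth:
    """True sub-pixel nucleus centers (row, col) and diameters."""

    coordinates: np.ndarray  # (n, 2) float
    diameters: np.ndarray


def _place_spots(rng: np.random.Generator, spec: FosImageSpec) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation."""
    h, w = spec.size
    margin = spec.spot_diameter_range[1]
    pts: list[tuple[float, float]] = []
    tries = 0
    max_tries = 200 * max(spec.n_cells, 1)
    while len(pts) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} spots with "
                f"min_separation={spec.min_separation} in {spec.size}"
            )
        r = margin + rng.random() * (h - 2 * margin)
        c = margin + rng.random() * (w - 2 * margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= spec.min_separation**2 for pr, pc in pts):
            pts.append((r, c))
    return np.array(pts, dtype=float).reshape(-1, 2)


def render_fos_image(spec: FosImageSpec) -> tuple[np.ndarray, FosGroundTruth]:
    """Render one micrograph; returns ``(image, ground_truth)``.

    The image is an integer array at ``spec.bit_depth`` (uint8 or
    uint16); rendering is fully determined by ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.size
    centers = _place_spots(rng, spec)
    lo, hi = spec.spot_diameter_range
    diam = lo + rng.random(len(centers)) * (hi - lo)

    img = np.zeros((h, w), dtype=float)
    rr, cc = np.mgrid[0:h, 0:w]
    # slowly varying background: second-order polynomial in (r, c)
    if spec.background > 0:
        u, v = rr / h - 0.5, cc / w - 0.5
        coef = rng.normal(0.0, 1.0, 6)
        poly = (
            coef[0] + coef[1] * u + coef[2] * v
            + coef[3] * u * v + coef[4] * u**2 + coef[5] * v**2
        )
        poly = (poly - poly.min()) / max(np.ptp(poly), 1e-12)
        img += spec.background * poly

    fwhm_to_sigma = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for (r, c), d in zip(centers, diam):
        sigma = d * fwhm_to_sigma
        half = int(math.ceil(4 * sigma))
        r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
        sub_r, sub_c = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += spec.spot_amplitude * np.exp(
            -((sub_r - r) ** 2 + (sub_c - c) ** 2) / (2 * sigma**2)
        )

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, (h, w))

    max_val = 2**spec.bit_depth - 1
    if spec.polarity == "dark_spots":
        img = max_val * 0.9 - img
    img = np.clip(np.round(img), 0, max_val)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return img.astype(dtype), FosGroundTruth(coordinates=centers, diameters=diam)
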