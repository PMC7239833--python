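"""Fiber-photometry signal processing.

Pipeline: raw fluorescence -> dF/F against a sliding trimmed-mean
baseline -> per-trial peri-event segments -> time-warp of the
drop-to-retrieval span onto the group-average latency -> per-type
averages -> per-animal min-max normalization -> food-approach response.

dF/F follows the convention ``(F_x - F_0) / F_0`` where the baseline
``F_0`` at each time point is the mean of the central 50% of the ranked
samples in the 30 s strictly preceding that point (an interquartile
mean, robust to transients riding on the baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .task import EventStream, SessionConfig, TrialSpec, classify_trial

__all__ = [
    "RawFluorescenceTrace",
    "DffTrace",
    "TrialSegment",
    "AlignedTrialMatrix",
    "NormalizedMeans",
    "compute_dff",
    "extract_trial_segments",
    "timewarp_align",
    "average_by_type",
    "minmax_normalize",
    "approach_response",
]

#: analysis trial classes; stimulus trials split by whether the entry was
#: punished, omissions pooled across trial types (no retrieval anchor)
ALIGN_TYPES = ("no_stimulus", "stimulus_success", "stimulus_shock", "omission")


@dataclass
class RawFluorescenceTrace:
    """Uniformly sampled single-channel fluorescence."""

    time: np.ndarray
    F: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise ValueError("time and F must have the same length")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            nominal = 1.0 / self.sampling_rate
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise ValueError("sampling must be uniform within 1% jitter")

    def __len__(self) -> int:
        return len(self.F)


@dataclass
class DffTrace:
    """dF/F trace with its per-sample baseline.

    Samples whose baseline window precedes the recording start are
    flagged undefined: ``dff`` and ``f0`` are NaN there and ``defined``
    is False.  They are never silently zeroed.
    """

    time: np.ndarray
    dff: np.ndarray
    f0: np.ndarray
    sampling_rate: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.dff)


def _trimmed_mean_sliding(F: np.ndarray, w: int, middle_fraction: float,
                          chunk: int = 4096) -> np.ndarray:
    """Baseline at sample i = interquartile mean of ``F[i-w:i]``.

    Returns an array aligned with F; the first ``w`` samples are NaN.
    Windows are rank-partitioned in chunks to bound memory; only the
    two trim boundaries need to be in sorted position, so a partial
    partition replaces a full sort.
    """
    n = len(F)
    out = np.full(n, np.nan)
    if n <= w:
        return out
    k = int(math.floor(w * (1.0 - middle_fraction) / 2.0))
    windows = np.lib.stride_tricks.sliding_window_view(F[:-1], w)  # ends at i-1
    # windows[j] = F[j:j+w] -> baseline for sample j+w
    kth = (k, w - k - 1) if k > 0 else (w - 1,)
    m = windows.shape[0]
    for start in range(0, m, chunk):
        block = np.partition(windows[start : start + chunk], kth, axis=1)
        core = block[:, k : w - k]
        out[start + w : start + w + len(core)] = core.mean(axis=1)
    return out


def compute_dff(
    trace: RawFluorescenceTrace,
    window: float = 30.0,
    middle_fraction: float = 0.5,
    edge: Literal["undefined", "grow"] = "undefined",
) -> DffTrace:
    """Convert raw fluorescence to dF/F against a sliding trimmed mean.

    For each sample x, ``F_0`` is the mean of the samples in
    ``[t_x - window, t_x)`` whose ranks fall in the central
    ``middle_fraction`` (trimming ``floor(w*(1-middle_fraction)/2)``
    from each tail), and ``dff = (F_x - F_0)/F_0``.

    ``edge='undefined'`` flags the first ``window`` seconds as NaN;
    ``edge='grow'`` uses the available (shorter) preceding window there,
    leaving only the very first sample undefined.
    """
    if not 0.0 < middle_fraction <= 1.0:
        raise ValueError("middle_fraction must lie in (0, 1]")
    fs = trace.sampling_rate
    w = int(round(window * fs))
    if w < 2 or w >= len(trace):
        raise ValueError("window must be shorter than the trace and span >=2 samples")
    f0 = _trimmed_mean_sliding(trace.F, w, middle_fraction)
    if edge == "grow":
        for i in range(1, min(w, len(trace))):
            avail = trace.F[:i]
            k = int(math.floor(i * (1.0 - middle_fraction) / 2.0))
            core = np.sort(avail)[k : i - k]
            f0[i] = core.mean()
    defined = np.isfinite(f0)
    if np.any(f0[defined] <= 0):
        raise ValueError("baseline F_0 <= 0: dF/F undefined for this trace")
    dff = np.full_like(f0, np.nan)
    dff[defined] = (trace.F[defined] - f0[defined]) / f0[defined]
    return DffTrace(time=trace.time.copy(), dff=dff, f0=f0, sampling_rate=fs)


@dataclass
class TrialSegment:
    """Peri-event dF/F segment for one trial, anchored at pellet drop.

    ``anchors`` holds absolute session times for ``pellet_drop`` and,
    where present, ``stimulus_off`` and first ``port_entry``.
    """

    trial_index: int
    align_type: str
    time: np.ndarray  # relative to pellet drop
    dff: np.ndarray
    anchors: dict[str, float]
    sampling_rate: float

    @property
    def latency(self) -> float | None:
        if "port_entry" not in self.anchors:
            return None
        return self.anchors["port_entry"] - self.anchors["pellet_drop"]


def _align_type(record) -> str:
    if record.outcome == "retrieved":
        return "no_stimulus"
    if record.outcome == "success":
        return "stimulus_success"
    if record.outcome == "shock":
        return "stimulus_shock"
    return "omission"


def extract_trial_segments(
    dff: DffTrace,
    events: EventStream,
    schedule: Sequence[TrialSpec],
    config: SessionConfig,
    pre: float = 5.0,
    post: float = 35.0,
) -> list[TrialSegment]:
    """Cut one peri-drop segment per trial, ``[-pre, post)`` s around the
    pellet drop, carrying the anchor timestamps needed for warping."""
    fs = dff.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    t0 = dff.time[0]
    segments = []
    for spec in schedule:
        record = classify_trial(events, spec, config)
        trial = events.trial(spec.trial_index)
        t_drop = float(trial[trial["event"] == "pellet_drop"]["time_s"].iloc[0])
        i_drop = int(round((t_drop - t0) * fs))
        i0, i1 = i_drop - n_pre, i_drop + n_post
        if i0 < 0 or i1 > len(dff.dff):
            raise ValueError(
                f"trial {spec.trial_index}: window [{-pre}, {post}) s exceeds trace bounds"
            )
        anchors = {"pellet_drop": t_drop}
        offs = trial[trial["event"] == "stimulus_off"]
        if len(offs):
            anchors["stimulus_off"] = float(offs["time_s"].iloc[0])
        entries = trial[trial["event"] == "port_entry"]
        if len(entries):
            anchors["port_entry"] = float(entries["time_s"].iloc[0])
        segments.append(
            TrialSegment(
                trial_index=spec.trial_index,
                align_type=_align_type(record),
                time=dff.time[i0:i1] - t_drop,
                dff=dff.dff[i0:i1],
                anchors=anchors,
                sampling_rate=fs,
            )
        )
    return segments


@dataclass
class AlignedTrialMatrix:
    """Trials x warped-time matrix for one alignment class.

    Columns: ``n_pre`` unwarped pre-drop samples, then the drop-to-entry
    span resampled onto ``target_latency`` seconds, then unwarped
    post-entry samples.  ``anchors`` maps anchor names to the (shared)
    column index; for ``stimulus_off`` — which is recorded, not warped
    to — the column under the mean latency mapping is reported, and the
    per-trial columns are kept in ``row_anchors``.
    """

    align_type: str
    data: np.ndarray          # (n_trials, n_cols)
    time: np.ndarray          # warped time base, s relative to drop
    anchors: dict[str, int]
    row_anchors: list[dict[str, int]]
    target_latency: float
    sampling_rate: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _warp_one(
    seg: TrialSegment,
    n_pre: int,
    n_warp: int,
    n_post: int,
    target_latency: float,
    method: str,
) -> tuple[np.ndarray, dict[str, int]]:
    fs = seg.sampling_rate
    t_drop = 0.0
    lat = seg.latency
    if lat is None or lat <= 0:
        raise ValueError(f"trial {seg.trial_index}: missing or zero-length warp span")
    # pre flank: unwarped clock samples ending at the drop
    pre_times = (np.arange(-n_pre, 0)) / fs
    # warped span: n_warp samples spanning [0, lat] mapped onto [0, target]
    warp_times = t_drop + lat * np.arange(n_warp) / (n_warp - 1)
    # post flank: unwarped clock after the entry
    post_times = lat + np.arange(1, n_post + 1) / fs
    times = np.concatenate([pre_times, warp_times, post_times])
    if method == "nearest":
        idx = np.clip(np.round((times - seg.time[0]) * fs).astype(int), 0, len(seg.dff) - 1)
        row = seg.dff[idx]
    else:
        row = np.interp(times, seg.time, seg.dff)
    anchors = {"pellet_drop": n_pre, "port_entry": n_pre + n_warp - 1}
    if "stimulus_off" in seg.anchors:
        off = seg.anchors["stimulus_off"] - seg.anchors["pellet_drop"]
        frac = min(max(off / lat, 0.0), 1.0)
        anchors["stimulus_off"] = n_pre + int(round(frac * (n_warp - 1)))
    return row, anchors


def timewarp_align(
    segments: Sequence[TrialSegment],
    target_latency: float | None = None,
    pre: float = 5.0,
    post_entry: float = 5.0,
    method: Literal["linear", "nearest"] = "linear",
) -> AlignedTrialMatrix:
    """Warp a set of same-class segments onto a common latency.

    The drop-to-entry sub-segment of every trial is resampled (linear
    interpolation by default) onto ``target_latency`` seconds — the mean
    retrieval latency of the contributing trials unless overridden — so
    rows share one time base and anchor columns.  Omission segments have
    no retrieval anchor and are stacked unwarped over the fixed trial
    window instead.
    """
    if not segments:
        raise ValueError("no segments to align")
    align_type = segments[0].align_type
    if any(s.align_type != align_type for s in segments):
        raise ValueError("segments must share one alignment class")
    fs = segments[0].sampling_rate

    if align_type == "omission":
        data = np.vstack([s.dff for s in segments])
        time = segments[0].time.copy()
        anchors = {"pellet_drop": int(round(-time[0] * fs))}
        return AlignedTrialMatrix(
            align_type=align_type, data=data, time=time, anchors=anchors,
            row_anchors=[dict(anchors) for _ in segments],
            target_latency=float("nan"), sampling_rate=fs,
        )

    lats = [s.latency for s in segments]
    if any(l is None or l <= 0 for l in lats):
        raise ValueError("warped alignment requires drop and entry anchors")
    if target_latency is None:
        target_latency = float(np.mean(lats))
    if target_latency <= 0:
        raise ValueError("target_latency must be positive")

    n_pre = int(round(pre * fs))
    n_warp = int(round(target_latency * fs)) + 1
    n_post = int(round(post_entry * fs))
    rows, row_anchors = [], []
    for seg in segments:
        row, anch = _warp_one(seg, n_pre, n_warp, n_post, target_latency, method)
        rows.append(row)
        row_anchors.append(anch)
    data = np.vstack(rows)
    time = np.concatenate(
        [
            np.arange(-n_pre, 0) / fs,
            target_latency * np.arange(n_warp) / (n_warp - 1),
            target_latency + np.arange(1, n_post + 1) / fs,
        ]
    )
    anchors = {"pellet_drop": n_pre, "port_entry": n_pre + n_warp - 1}
    offs = [a["stimulus_off"] for a in row_anchors if "stimulus_off" in a]
    if offs:
        anchors["stimulus_off"] = int(round(float(np.mean(offs))))
    return AlignedTrialMatrix(
        align_type=align_type, data=data, time=time, anchors=anchors,
        row_anchors=row_anchors, target_latency=float(target_latency),
        sampling_rate=fs,
    )


def average_by_type(
    matrices: dict[str, AlignedTrialMatrix]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and SEM across trials, per alignment class."""
    out = {}
    for name, mat in matrices.items():
        if mat.n_trials == 0:
            raise ValueError(f"empty alignment class {name!r}")
        mean = np.nanmean(mat.data, axis=0)
        if mat.n_trials > 1:
            sem = np.nanstd(mat.data, axis=0, ddof=1) / math.sqrt(mat.n_trials)
        else:
            sem = np.zeros_like(mean)
        out[name] = (mean, sem)
    return out


@dataclass
class NormalizedMeans:
    """Per-animal trial-type means mapped onto [0, 1].

    ``F_x,norm = (F_x - F_min)/(F_max - F_min)`` with the extrema taken
    over all four trial-type means of that animal, so the global minimum
    across types is exactly 0 and the global maximum exactly 1.
    """

    means: dict[str, np.ndarray]
    f_min: float
    f_max: float


def minmax_normalize(type_means: dict[str, np.ndarray]) -> NormalizedMeans:
    """Normalize an animal's trial-type mean traces to the 0-1 range."""
    if not type_means:
        raise ValueError("no trial-type means supplied")
    allvals = np.concatenate([np.asarray(v, dtype=float).ravel() for v in type_means.values()])
    allvals = allvals[np.isfinite(allvals)]
    f_min, f_max = float(allvals.min()), float(allvals.max())
    if f_max <= f_min:
        raise ValueError("flat signal: F_max equals F_min")
    scaled = {k: (np.asarray(v, dtype=float) - f_min) / (f_max - f_min)
              for k, v in type_means.items()}
    return NormalizedMeans(means=scaled, f_min=f_min, f_max=f_max)


def approach_response(
    matrix: AlignedTrialMatrix,
    baseline_duration: float | None = None,
) -> float:
    """Mean dF/F during food approach, baseline-subtracted.

    The approach span runs from the moment the pellet became safely
    available — the drop for no-stimulus trials, cue offset for stimulus
    trials (per-row anchor) — to the retrieval entry; the baseline is
    the window of equal clock duration immediately before the drop.
    Returns the across-trial mean of the per-trial difference.
    """
    if matrix.align_type == "omission":
        raise ValueError("approach response undefined for omission trials")
    vals = []
    for row, anch in zip(matrix.data, matrix.row_anchors):
        end = anch["port_entry"]
        start = anch.get("stimulus_off", anch["pellet_drop"])
        if start >= end:
            # punished entries terminate the cue at the entry itself;
            # the approach then spans drop -> entry
            start = anch["pellet_drop"]
        if end <= start:
            continue
        approach = np.nanmean(row[start : end + 1])
        n_base = end - start + 1
        if baseline_duration is not None:
            n_base = int(round(baseline_duration * matrix.sampling_rate))
        b1 = anch["pellet_drop"]
        b0 = max(0, b1 - n_base)
        if b1 <= b0:
            raise ValueError("baseline span outside matrix")
        base = np.nanmean(row[b0:b1])
        vals.append(approach - base)
    if not vals:
        raise ValueError("no trials with a valid approach span")
    return float(np.mean(vals))
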