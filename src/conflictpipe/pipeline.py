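"""End-to-end demo pipeline: simulate a cohort, run every analysis stage.

``PipelineConfig`` gathers all stage parameters in one YAML-serializable
tree; :func:`run_demo` simulates behavioral sessions, photometry traces
and histology images for a synthetic cohort, runs the session
statistics, the dF/F + time-warp analysis, the nucleus counting and the
statistical battery, and writes every table plus a manifest of outputs,
seeds and per-stage timing.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .fos import BandPassSpec, GrayImage, count_in_roi, detect_nuclei, group_contrast
from .photometry import (
    RawFluorescenceTrace,
    approach_response,
    average_by_type,
    compute_dff,
    extract_trial_segments,
    minmax_normalize,
    timewarp_align,
)
from .stats import pearson_r, rm_anova_1way
from .synth import (
    AgentParams,
    FosImageSpec,
    PhotometryModel,
    render_fos_image,
    simulate_agent_session,
)
from .task import SessionConfig, classify_session, summarize

__all__ = ["PipelineConfig", "run_demo"]


@dataclass
class PipelineConfig:
    """All knobs of the demo cohort in one serializable object.

    ``agent_p_success``/``agent_p_omit`` parameterize the synthetic rats
    (intensity-independent success probability keeps the config flat and
    lossless on disk); analysis parameters carry the published defaults
    (30-s baseline window with the central 50%, 3-6 px band-pass,
    maxima tolerance 145).
    """

    n_animals: int = 6
    seed: int = 0
    session: SessionConfig = field(default_factory=lambda: SessionConfig(variant="houselight"))
    agent_p_success: float = 0.7
    agent_p_omit: float = 0.05
    photometry_hypothesis: str = "value_rpe"
    sampling_rate: float = 100.0
    dff_window: float = 30.0
    dff_middle_fraction: float = 0.5
    segment_pre: float = 5.0
    segment_post: float = 35.0
    fos_n_animals_per_group: int = 9
    fos_regions: tuple[str, ...] = ("VS_core", "VS_shell_medial", "VS_shell_lateral")
    fos_cells_baseline: int = 40
    fos_cells_stimulus_boost: int = 20
    bandpass_small: float = 3.0
    bandpass_large: float = 6.0
    maxima_tolerance: float = 145.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"] = dataclasses.asdict(self.session)
        d["fos_regions"] = list(self.fos_regions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "session" in d:
            d["session"] = SessionConfig(**d["session"])
        if "fos_regions" in d:
            d["fos_regions"] = tuple(d["fos_regions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        cio.dump_yaml(self.to_dict(), path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(cio.load_yaml(path))


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            if exc[0] is None:
                manifest["stages"].append(
                    {"stage": name, "elapsed_s": round(time.perf_counter() - self.t0, 3)}
                )
            else:
                manifest["failed_stage"] = name
            return False

    return _Timer()


def run_demo(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic-cohort demo; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": []}
    root_rng = np.random.default_rng(config.seed)
    agent = AgentParams(p_success=config.agent_p_success, p_omit=config.agent_p_omit)

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.6g")
        manifest["files"].append(name)

    # --- behavior ---------------------------------------------------------
    with _stage(manifest, "behavior"):
        rows, sessions = [], []
        for animal in range(config.n_animals):
            seed = int(root_rng.integers(2**31 - 1))
            sess_cfg = dataclasses.replace(config.session, rng_seed=seed)
            events, truth, schedule = simulate_agent_session(sess_cfg, agent, seed)
            records = classify_session(events, schedule, sess_cfg)
            summary = summarize(records)
            sessions.append((animal, events, schedule, sess_cfg, summary))
            rows.append({"animal": animal, "seed": seed, **{
                k: v for k, v in summary.to_dict().items()
                if k != "latency_median_by_outcome"
            }})
        emit(pd.DataFrame(rows), "session_summaries.csv")

    # --- photometry -------------------------------------------------------
    with _stage(manifest, "photometry"):
        from .synth import simulate_photometry

        model = PhotometryModel(hypothesis=config.photometry_hypothesis,
                                sampling_rate=config.sampling_rate)
        resp_rows, norm_rows = [], []
        warm_up = config.dff_window + config.segment_pre
        for animal, events, schedule, sess_cfg, _summary in sessions:
            seed = int(root_rng.integers(2**31 - 1))
            t, F, _gt = simulate_photometry(events, model, seed, config=sess_cfg)
            dff = compute_dff(
                RawFluorescenceTrace(t, F, model.sampling_rate),
                window=config.dff_window,
                middle_fraction=config.dff_middle_fraction,
            )
            usable = [s for s in schedule if s.start_time >= warm_up]
            segments = extract_trial_segments(
                dff, events, usable, sess_cfg,
                pre=config.segment_pre, post=config.segment_post,
            )
            by_type: dict[str, list] = {}
            for seg in segments:
                by_type.setdefault(seg.align_type, []).append(seg)
            matrices = {
                name: timewarp_align(segs)
                for name, segs in by_type.items()
                if name != "omission" and len(segs) >= 2
            }
            means = {k: v[0] for k, v in average_by_type(matrices).items()}
            if len(means) >= 2:
                norm = minmax_normalize(means)
                for k, v in norm.means.items():
                    norm_rows.append({"animal": animal, "trial_type": k,
                                      "norm_min": float(np.nanmin(v)),
                                      "norm_max": float(np.nanmax(v))})
            for name, mat in matrices.items():
                resp_rows.append({
                    "animal": animal, "trial_type": name,
                    "n_trials": mat.n_trials,
                    "approach_response": approach_response(mat),
                })
        resp = pd.DataFrame(resp_rows)
        emit(resp, "approach_responses.csv")
        emit(pd.DataFrame(norm_rows), "normalized_range.csv")

    # --- photometry statistics -------------------------------------------
    with _stage(manifest, "photometry_stats"):
        wide = resp.pivot_table(index="animal", columns="trial_type",
                                values="approach_response")
        stat_rows = []
        if wide.shape[1] >= 2 and not wide.isna().any().any():
            results = rm_anova_1way(
                resp.rename(columns={"animal": "subject", "trial_type": "level",
                                     "approach_response": "response"}),
                posthoc=True,
            )
            for r in results:
                stat_rows.append({"effect": r.effect, "statistic": r.statistic,
                                  "df1": r.df[0], "df2": r.df[-1],
                                  "p": r.p_value, "p_bonferroni": r.adjusted_p})
        emit(pd.DataFrame(stat_rows), "photometry_anova.csv")

    # --- histology --------------------------------------------------------
    with _stage(manifest, "fos"):
        bp = BandPassSpec(config.bandpass_small, config.bandpass_large)
        dens_rows = []
        for group in ("no_stimulus", "stimulus"):
            boost = config.fos_cells_stimulus_boost if group == "stimulus" else 0
            for animal in range(config.fos_n_animals_per_group):
                n_shocks = int(root_rng.integers(0, 10)) if group == "stimulus" else 0
                for region in config.fos_regions:
                    seed = int(root_rng.integers(2**31 - 1))
                    n_cells = config.fos_cells_baseline + boost + int(root_rng.integers(-5, 6))
                    spec = FosImageSpec(n_cells=max(n_cells, 1), rng_seed=seed,
                                        polarity="dark_spots")
                    img, _truth = render_fos_image(spec)
                    gray = GrayImage(img.astype(float), bit_depth=spec.bit_depth,
                                     polarity="dark_spots")
                    spots = detect_nuclei(gray, bp, config.maxima_tolerance)
                    mask = np.ones(spec.size, dtype=bool)
                    rec = count_in_roi(spots, mask, roi_name=region)
                    dens_rows.append({"group": group, "animal": animal,
                                      "region": region, "n_shocks": n_shocks,
                                      "count": rec.count, "area_px2": rec.area_px2,
                                      "density": rec.density})
        dens = pd.DataFrame(dens_rows)
        emit(dens, "fos_densities.csv")

    # --- histology statistics --------------------------------------------
    with _stage(manifest, "fos_stats"):
        results = group_contrast(dens)
        emit(pd.DataFrame(
            [{"effect": r.effect, "F": r.statistic, "df1": r.df[0],
              "df2": r.df[1], "p": r.p_value} for r in results]
        ), "fos_anova.csv")
        stim = dens[dens["group"] == "stimulus"].groupby("animal").agg(
            density=("density", "mean"), n_shocks=("n_shocks", "first")
        )
        corr = pearson_r(stim["density"], stim["n_shocks"])
        emit(pd.DataFrame([{"effect": "density_vs_shocks", "r": corr.statistic,
                            "df": corr.df[0], "p": corr.p_value}]),
             "fos_shock_correlation.csv")

    manifest["config"] = config.to_dict()
    manifest["files"].append("manifest.json")
    cio.write_json(manifest, outdir / "manifest.json")
    return manifest
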