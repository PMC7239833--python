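"""Semi-automated c-Fos nucleus counting.

The routine mirrors a classic brightfield workflow: Fourier-domain
band-pass keeping structures the size of c-Fos-expressing nuclei
(3-6 px by default), then prominence-based local-maxima detection
(noise tolerance 145 on the 8-bit scale), then per-ROI density
(count / area).

``find_maxima`` follows the flood/prominence semantics of the familiar
"find maxima" tool: a candidate peak is a separate maximum iff it
cannot reach a strictly higher pixel along any path on which intensity
stays above ``peak - tolerance``; the globally highest peak is always
reported, plateaus yield one maximum at their centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrayImage",
    "BandPassSpec",
    "SpotSet",
    "DensityRecord",
    "bandpass_fft",
    "find_maxima",
    "rescale_to_8bit",
    "detect_nuclei",
    "count_in_roi",
    "group_contrast",
]


@dataclass
class GrayImage:
    """Single-channel image with polarity metadata.

    ``polarity='dark_spots'`` marks DAB-style dark nuclei on a light
    background; detection-side code inverts such images first so that
    maxima are bright.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size: float | None = None  # microns per pixel
    polarity: str = "bright_spots"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.polarity not in ("bright_spots", "dark_spots"):
            raise ValueError("polarity must be bright_spots or dark_spots")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BandPassSpec:
    """Pass band in structure-size units (pixels)."""

    small_structure: float = 3.0
    large_structure: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.small_structure < self.large_structure:
            raise ValueError("need 0 < small_structure < large_structure")


def bandpass_transfer(shape: tuple[int, int], spec: BandPassSpec,
                      profile: str = "gaussian") -> np.ndarray:
    """Frequency-domain transfer function of the band-pass.

    Gaussian-edged annulus with half-gain cutoffs at spatial periods
    equal to the structure sizes:
    ``H(f) = exp(-ln2 (f*small)^2) * (1 - exp(-ln2 (f*large)^2))``,
    so H(0) = 0 (the output is zero-mean).  ``profile='tophat'`` gives a
    hard annulus between the two cutoff frequencies instead.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    if profile == "gaussian":
        ln2 = math.log(2.0)
        low = np.exp(-ln2 * (f * spec.small_structure) ** 2)
        high = 1.0 - np.exp(-ln2 * (f * spec.large_structure) ** 2)
        return low * high
    if profile == "tophat":
        return ((f >= 1.0 / spec.large_structure) & (f <= 1.0 / spec.small_structure)).astype(float)
    raise ValueError("profile must be gaussian or tophat")


def bandpass_fft(image: GrayImage, spec: BandPassSpec | None = None,
                 profile: str = "gaussian") -> GrayImage:
    """Band-pass an image in the frequency domain.

    Dark-spot images are inverted first so nuclei come out as positive
    peaks; the output is zero-mean with ``polarity='bright_spots'``.
    """
    spec = spec or BandPassSpec()
    h, w = image.shape
    if min(h, w) < 2 * spec.large_structure:
        raise ValueError("image smaller than twice the large structure size")
    x = image.pixels
    if image.polarity == "dark_spots":
        x = -x
    H = bandpass_transfer((h, w), spec, profile)
    out = np.real(np.fft.ifft2(np.fft.fft2(x) * H))
    return GrayImage(pixels=out, bit_depth=image.bit_depth,
                     pixel_size=image.pixel_size, polarity="bright_spots")


@dataclass
class SpotSet:
    """Detected maxima: sub-pixel (row, col) coordinates and peak values."""

    coordinates: np.ndarray  # (n, 2) float
    peak_values: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        self.peak_values = np.asarray(self.peak_values, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.coordinates)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_maxima(filtered: GrayImage | np.ndarray, tolerance: float = 145.0) -> SpotSet:
    """Prominence-thresholded local maxima (8-connectivity).

    Implemented as a single descending-intensity union-find sweep: a
    region dies when it merges into higher ground, and is reported as a
    maximum iff its peak stands at least ``tolerance`` above the merge
    level.  Equal-height peaks whose connecting saddle is within
    tolerance merge into one maximum at the centroid of their peak
    pixels; the global maximum is always reported.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    img = filtered.pixels if isinstance(filtered, GrayImage) else np.asarray(filtered, dtype=float)
    h, w = img.shape
    n = h * w
    flat = img.ravel()
    order = np.lexsort((np.arange(n), -flat))  # descending value, stable

    parent = np.full(n, -1, dtype=np.int64)  # -1: unprocessed
    peak_val: dict[int, float] = {}
    peak_pixels: dict[int, list[int]] = {}

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    accepted_coords: list[tuple[float, float]] = []
    accepted_vals: list[float] = []

    def centroid(pixels: list[int]) -> tuple[float, float]:
        rr = [p // w for p in pixels]
        cc = [p % w for p in pixels]
        return float(np.mean(rr)), float(np.mean(cc))

    for p in order:
        val = flat[p]
        r, c = divmod(int(p), w)
        roots = []
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                q = rr * w + cc
                if parent[q] != -1:
                    root = find(q)
                    if root not in roots:
                        roots.append(root)
        if not roots:
            parent[p] = p
            peak_val[p] = float(val)
            peak_pixels[p] = [int(p)]
            continue
        # winner: highest peak; ties go to the earliest-created region
        winner = max(roots, key=lambda rt: (peak_val[rt], -rt))
        parent[p] = winner
        if val == peak_val[winner]:
            peak_pixels[winner].append(int(p))  # plateau extension
        for rt in roots:
            if rt == winner:
                continue
            prominence = peak_val[rt] - float(val)
            if peak_val[rt] == peak_val[winner] and prominence < tolerance:
                # equal peaks within tolerance: one merged maximum
                peak_pixels[winner].extend(peak_pixels[rt])
            elif prominence >= tolerance:
                accepted_coords.append(centroid(peak_pixels[rt]))
                accepted_vals.append(peak_val[rt])
            parent[rt] = winner
            del peak_val[rt], peak_pixels[rt]

    # the surviving region holds the global maximum
    for rt, v in peak_val.items():
        accepted_coords.append(centroid(peak_pixels[rt]))
        accepted_vals.append(v)

    if not accepted_coords:
        return SpotSet(np.empty((0, 2)), np.empty(0))
    order_out = np.argsort(-np.asarray(accepted_vals), kind="stable")
    coords = np.asarray(accepted_coords, dtype=float)[order_out]
    vals = np.asarray(accepted_vals, dtype=float)[order_out]
    return SpotSet(coords, vals)


def rescale_to_8bit(image: GrayImage, saturation: float = 0.35) -> GrayImage:
    """Saturated autoscale onto [0, 255].

    Maps the ``[saturation/2, 100 - saturation/2]`` intensity
    percentiles onto the 8-bit range and clips the tails — the familiar
    display-oriented contrast stretch that frequency-domain band-pass
    tools apply after filtering.  ``saturation=0`` gives a plain min-max
    mapping.
    """
    x = image.pixels
    if saturation > 0:
        lo, hi = (float(v) for v in np.percentile(x, [saturation / 2.0,
                                                      100.0 - saturation / 2.0]))
    else:
        lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        scaled = np.zeros_like(x)
    else:
        scaled = np.clip((x - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return GrayImage(pixels=scaled, bit_depth=8, pixel_size=image.pixel_size,
                     polarity=image.polarity)


def detect_nuclei(
    image: GrayImage,
    spec: BandPassSpec | None = None,
    tolerance: float = 145.0,
    profile: str = "gaussian",
) -> SpotSet:
    """Full detection pipeline: band-pass, 8-bit rescale, find maxima.

    ``tolerance`` is on the 8-bit intensity scale; band-passed images are
    rescaled onto [0, 255] before detection regardless of input depth.
    """
    filtered = bandpass_fft(image, spec, profile)
    return find_maxima(rescale_to_8bit(filtered), tolerance)


@dataclass
class DensityRecord:
    """Spot count, ROI area and their ratio for one region."""

    roi_name: str
    count: int
    area_px2: float
    density: float          # per px^2
    area_mm2: float | None = None
    density_mm2: float | None = None


def count_in_roi(
    spots: SpotSet,
    mask: np.ndarray,
    roi_name: str = "roi",
    pixel_size: float | None = None,
) -> DensityRecord:
    """Count detected spots inside a binary ROI mask and compute density.

    ``pixel_size`` (microns/px), when given, also yields area and
    density in mm^2 units.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty ROI mask")
    count = 0
    h, w = mask.shape
    for r, c in spots.coordinates:
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < h and 0 <= ci < w and mask[ri, ci]:
            count += 1
    rec = DensityRecord(roi_name=roi_name, count=count, area_px2=area,
                        density=count / area)
    if pixel_size is not None:
        area_mm2 = area * (pixel_size / 1000.0) ** 2
        rec.area_mm2 = area_mm2
        rec.density_mm2 = count / area_mm2
    return rec


def group_contrast(records: pd.DataFrame):
    """Two-way ANOVA (group x region, between subjects) on ROI densities.

    ``records`` needs columns ``group``, ``region``, ``density`` with a
    balanced design and at least two observations per cell.  Returns the
    stats-module result list (two main effects and the interaction).
    """
    from .stats import anova_2way

    required = {"group", "region", "density"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    return anova_2way(records, factor_a="group", factor_b="region",
                      response="density")
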