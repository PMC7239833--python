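"""Band-pass, maxima detection, ROI density, group contrast."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conflictpipe.fos import (
    BandPassSpec,
    GrayImage,
    SpotSet,
    bandpass_fft,
    bandpass_transfer,
    count_in_roi,
    detect_nuclei,
    find_maxima,
    group_contrast,
    rescale_to_8bit,
)
from conflictpipe.synth import FosImageSpec, render_fos_image


# --------------------------------------------------------------------------
# independent flood oracle for find_maxima

def flood_oracle(img: np.ndarray, tol: float) -> set[tuple[float, float]]:
    """Exhaustive prominence oracle.

    A candidate local maximum is rejected iff a breadth-first flood over
    pixels strictly above (peak - tol) reaches a strictly higher pixel.
    Equal-height accepted candidates joined by such a flood merge into
    one maximum at the centroid of their peak pixels; plateau candidates
    are connected equal-value components without a higher neighbor.
    """
    h, w = img.shape
    nb = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def neighbors(r, c):
        for dr, dc in nb:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    # plateau-aware candidates: connected equal-value components
    seen = np.zeros((h, w), dtype=bool)
    candidates = []  # (value, [pixels])
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            v = img[r, c]
            comp, stack = [], [(r, c)]
            seen[r, c] = True
            is_max = True
            while stack:
                rr, cc = stack.pop()
                comp.append((rr, cc))
                for r2, c2 in neighbors(rr, cc):
                    if img[r2, c2] == v and not seen[r2, c2]:
                        seen[r2, c2] = True
                        stack.append((r2, c2))
                    elif img[r2, c2] > v:
                        is_max = False
            if is_max:
                candidates.append((v, comp))

    accepted = []
    regions = []
    for v, comp in candidates:
        flooded = set(comp)
        stack = list(comp)
        higher = False
        while stack:
            rr, cc = stack.pop()
            for r2, c2 in neighbors(rr, cc):
                if (r2, c2) in flooded:
                    continue
                if img[r2, c2] > v:
                    higher = True
                if img[r2, c2] > v - tol:
                    flooded.add((r2, c2))
                    stack.append((r2, c2))
        if not higher:
            accepted.append((v, comp))
            regions.append(flooded)

    # merge equal-height accepted candidates whose floods touch
    merged: list[tuple[float, float]] = []
    used = [False] * len(accepted)
    for i, (v, comp) in enumerate(accepted):
        if used[i]:
            continue
        group = list(comp)
        used[i] = True
        for j in range(i + 1, len(accepted)):
            if used[j]:
                continue
            vj, compj = accepted[j]
            if vj == v and any(p in regions[i] for p in compj):
                group.extend(compj)
                used[j] = True
        rr = sum(p[0] for p in group) / len(group)
        cc = sum(p[1] for p in group) / len(group)
        merged.append((rr, cc))
    return set(merged)


def gaussian_spot(shape, r0, c0, amp, fwhm=4.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    return amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


class TestBandPass:
    def test_uniform_image_maps_to_zero(self):
        out = bandpass_fft(GrayImage(np.full((64, 64), 9.0)))
        assert np.abs(out.pixels).max() < 1e-10

    def test_sinusoid_gains_in_and_out_of_band(self):
        # integer cycle counts avoid spectral leakage in the gain estimate
        x = np.arange(128)
        in_band = np.sin(2 * np.pi * x / 4.0)[None, :].repeat(128, axis=0)
        x2 = np.arange(200)
        out_band = np.sin(2 * np.pi * x2 / 50.0)[None, :].repeat(200, axis=0)
        g_in = np.ptp(bandpass_fft(GrayImage(in_band)).pixels) / np.ptp(in_band)
        g_out = np.ptp(bandpass_fft(GrayImage(out_band)).pixels) / np.ptp(out_band)
        assert g_in > 0.5
        assert g_out < 0.05

    def test_matches_spatial_convolution_oracle(self, rng):
        """Frequency filtering equals direct circular convolution with
        the inverse-transformed kernel (convolution theorem)."""
        img = rng.random((64, 64))
        spec = BandPassSpec()
        out = bandpass_fft(GrayImage(img), spec).pixels
        kernel = np.real(np.fft.ifft2(bandpass_transfer((64, 64), spec)))
        direct = np.zeros_like(img)
        for k in range(64):
            for l in range(64):
                if abs(kernel[k, l]) > 0:
                    direct += kernel[k, l] * np.roll(np.roll(img, k, axis=0), l, axis=1)
        assert np.max(np.abs(out - direct)) < 1e-6

    def test_dark_polarity_inverted_before_filtering(self):
        img = 200.0 - gaussian_spot((64, 64), 32, 32, 100.0)
        dark = bandpass_fft(GrayImage(img, polarity="dark_spots"))
        bright = bandpass_fft(GrayImage(200.0 - img, polarity="bright_spots"))
        assert np.allclose(dark.pixels, bright.pixels, atol=1e-9)
        assert dark.pixels[32, 32] == dark.pixels.max()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandPassSpec(small_structure=6.0, large_structure=3.0)
        with pytest.raises(ValueError):
            bandpass_fft(GrayImage(np.zeros((8, 8))), BandPassSpec(3, 6))


class TestFindMaxima:
    def test_single_spot_above_tolerance(self):
        img = gaussian_spot((64, 64), 30, 40, 300.0)
        spots = find_maxima(img, 145.0)
        assert len(spots) == 1
        assert spots.coordinates[0] == pytest.approx([30, 40])

    def test_global_highest_rule(self):
        lone = gaussian_spot((64, 64), 30, 40, 100.0)
        assert len(find_maxima(lone, 145.0)) == 1  # global max always reported
        both = lone + gaussian_spot((64, 64), 10, 10, 400.0)
        spots = find_maxima(both, 145.0)
        assert len(spots) == 1
        assert spots.coordinates[0] == pytest.approx([10, 10])

    def test_valley_separates_saddle_merges(self):
        a = gaussian_spot((64, 64), 20, 20, 300.0, fwhm=3.0)
        b = gaussian_spot((64, 64), 20, 44, 300.0, fwhm=3.0)
        assert len(find_maxima(a + b, 145.0)) == 2  # valley at ~0
        ridge = np.zeros((64, 64))
        ridge[20, 20:45] = 250.0
        ridge[20, 20] = 300.0
        ridge[20, 44] = 300.0
        assert len(find_maxima(ridge, 145.0)) == 1  # saddle drop 50 < 145
        assert len(find_maxima(ridge, 40.0)) == 2

    def test_plateau_reported_once_at_centroid(self):
        img = np.zeros((32, 32))
        img[10:13, 10:14] = 200.0
        spots = find_maxima(img, 50.0)
        assert len(spots) == 1
        assert spots.coordinates[0] == pytest.approx([11.0, 11.5])

    def test_matches_flood_oracle_on_random_images(self, rng):
        """200 random 32x32 images: exact coordinate agreement with the
        exhaustive flood oracle."""
        for i in range(200):
            img = rng.random((32, 32)) * 300.0
            tol = float(rng.uniform(20.0, 200.0))
            got = {tuple(c) for c in find_maxima(img, tol).coordinates}
            expected = flood_oracle(img, tol)
            assert got == expected, f"mismatch on image {i} (tol={tol})"

    def test_monotone_in_tolerance(self, rng):
        img = rng.random((48, 48)) * 255.0
        counts = [len(find_maxima(img, tol)) for tol in (10, 40, 80, 120, 160)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_equivariance(self, rng):
        img = np.zeros((64, 64))
        for r, c in [(15, 20), (40, 45), (25, 50)]:
            img += gaussian_spot((64, 64), r, c, 300.0, fwhm=4.0)
        base = find_maxima(img, 145.0)
        shifted = find_maxima(np.roll(np.roll(img, 5, axis=0), -3, axis=1), 145.0)
        expect = sorted((r + 5, c - 3) for r, c in base.coordinates)
        got = sorted(map(tuple, shifted.coordinates))
        assert np.allclose(got, expect)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            find_maxima(np.zeros((8, 8)), -1.0)


class TestCountRecovery:
    @pytest.mark.parametrize("n_cells,size", [(20, (256, 256)), (50, (256, 256)),
                                              (100, (360, 360))])
    def test_detected_count_and_f1_on_synthetic_images(self, n_cells, size):
        """End-to-end recovery: count within 5%, centroid-matched F1 >= 0.95.

        Field size grows with the cell count so density stays in the
        range typical of a c-Fos-positive striatal section.
        """
        spec = FosImageSpec(n_cells=n_cells, size=size, rng_seed=100 + n_cells,
                            polarity="dark_spots")
        img, truth = render_fos_image(spec)
        gray = GrayImage(img.astype(float), bit_depth=16, polarity="dark_spots")
        spots = detect_nuclei(gray)
        assert abs(len(spots) - n_cells) <= 0.05 * n_cells
        tree = cKDTree(truth.coordinates)
        d, idx = tree.query(spots.coordinates)
        tp = len(set(idx[d <= 3.0]))
        precision = tp / len(spots)
        recall = tp / n_cells
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95


class TestRoiDensity:
    def _spots(self, coords):
        return SpotSet(np.array(coords, dtype=float), np.ones(len(coords)))

    def test_density_is_count_over_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True  # 100 px^2
        spots = self._spots([(i, i) for i in range(10)])
        rec = count_in_roi(spots, mask)
        assert rec.count == 10
        assert rec.area_px2 == 100
        assert rec.density == pytest.approx(0.1)

    def test_mask_excluding_all_spots(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[15:, 15:] = True
        rec = count_in_roi(self._spots([(0, 0), (1, 1)]), mask)
        assert rec.count == 0 and rec.density == 0.0

    def test_matches_membership_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((30, 30)) > 0.5
            if not mask.any():
                continue
            coords = rng.uniform(0, 29, size=(40, 2))
            rec = count_in_roi(self._spots(coords), mask)
            expected = sum(
                mask[int(round(r)), int(round(c))] for r, c in coords
            )
            assert rec.count == expected

    def test_density_additive_over_disjoint_rois(self, rng):
        mask_a = np.zeros((30, 30), dtype=bool)
        mask_b = np.zeros((30, 30), dtype=bool)
        mask_a[:15] = True
        mask_b[15:] = True
        coords = rng.uniform(0, 29, size=(25, 2))
        spots = self._spots(coords)
        ca = count_in_roi(spots, mask_a).count
        cb = count_in_roi(spots, mask_b).count
        cu = count_in_roi(spots, mask_a | mask_b).count
        assert ca + cb == cu

    def test_pixel_size_converts_to_mm2(self):
        mask = np.ones((10, 10), dtype=bool)
        rec = count_in_roi(self._spots([(5, 5)]), mask, pixel_size=2.0)
        assert rec.area_mm2 == pytest.approx(100 * (2.0 / 1000) ** 2)
        assert rec.density_mm2 == pytest.approx(1 / rec.area_mm2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            count_in_roi(self._spots([(1, 1)]), np.zeros((5, 5), dtype=bool))


class TestGroupContrast:
    def _table(self, rng, offset=0.0, n=8, sd=1.0):
        import pandas as pd

        rows = []
        for group in ("stimulus", "no_stimulus"):
            for region in ("core", "shell_med", "shell_lat"):
                for i in range(n):
                    d = 10.0 + (offset if group == "stimulus" else 0.0)
                    rows.append({"group": group, "region": region,
                                 "density": d + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_identical_densities_give_null_result(self):
        import pandas as pd

        rows = [
            {"group": g, "region": r, "density": 5.0}
            for g in ("a", "b") for r in ("x", "y") for _ in range(3)
        ]
        results = group_contrast(pd.DataFrame(rows))
        for res in results:
            assert res.statistic == pytest.approx(0.0)
            assert res.p_value == pytest.approx(1.0)

    def test_group_offset_detected_without_interaction(self, rng):
        results = group_contrast(self._table(rng, offset=3.0, sd=1.0))
        by_effect = {r.effect: r for r in results}
        assert by_effect["group"].p_value < 0.001
        assert by_effect["group x region"].p_value > 0.05

    def test_null_rejection_rate_near_alpha(self, rng):
        """Permuted (null) group labels reject at ~5%."""
        hits = 0
        reps = 400
        for _ in range(reps):
            results = group_contrast(self._table(rng, offset=0.0, n=4))
            by_effect = {r.effect: r for r in results}
            hits += by_effect["group"].p_value < 0.05
        rate = hits / reps
        assert 0.02 < rate < 0.08
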