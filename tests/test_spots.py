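"""Spot detection, photometry and aggregate filtering on rendered frames."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nanochrome.simulate import (
    BandResponseTable,
    ImagingConfig,
    PopulationConfig,
    generate_dataset,
    render_frames,
    sample_particles,
)
from nanochrome.spots import (
    DetectionParams,
    analyze_dataset,
    analyze_frame,
    detect_spots,
    filter_spots,
    match_spots,
    max_area_from_table,
    measure_spot,
)

PARAMS = DetectionParams()


def _noiseless_img(**kw):
    return ImagingConfig(shot_noise=False, read_noise_sd=0.0, **kw)


class TestDetectSpots:
    def test_constant_frame_has_no_peaks(self):
        assert detect_spots(np.full((64, 64), 7.0), PARAMS) == []

    def test_single_noiseless_spot_located_within_one_pixel(self):
        pop = PopulationConfig(sd_diameter=0.0, shell_sd=0.0, aggregate_fraction=0.0)
        particles = sample_particles(1, pop, seed=1)
        r, g, truth = render_frames(
            particles, pop, _noiseless_img(spots_per_frame=1), seed=2
        )
        peaks = detect_spots(r[0].astype(float) + g[0].astype(float), PARAMS)
        assert len(peaks) == 1
        row, col = truth[["row", "col"]].iloc[0]
        assert abs(peaks[0][0] - row) <= 1.0 and abs(peaks[0][1] - col) <= 1.0

    def test_two_well_separated_spots_both_found(self):
        pop = PopulationConfig(sd_diameter=0.0, shell_sd=0.0, aggregate_fraction=0.0)
        particles = sample_particles(2, pop, seed=3)
        img = _noiseless_img(spots_per_frame=2)
        r, g, truth = render_frames(particles, pop, img, seed=4)
        sep = np.hypot(
            np.diff(truth["row"].to_numpy())[0], np.diff(truth["col"].to_numpy())[0]
        )
        assert sep >= 5 * img.psf_sigma
        peaks = detect_spots(r[0].astype(float) + g[0].astype(float), PARAMS)
        assert len(peaks) == 2

    def test_nonfinite_frame_rejected(self):
        frame = np.zeros((32, 32))
        frame[3, 3] = np.nan
        with pytest.raises(ValueError):
            detect_spots(frame, PARAMS)


class TestMeasureSpot:
    def test_noiseless_photometry_recovers_commanded_integral(self):
        """r_scat on a clean background matches the commanded photon
        integral to < 0.5% (aperture + pixelation losses)."""
        pop = PopulationConfig(sd_diameter=0.0, shell_sd=0.0, aggregate_fraction=0.0)
        img = _noiseless_img(spots_per_frame=1)
        particles = sample_particles(1, pop, seed=5)
        r, g, truth = render_frames(particles, pop, img, seed=6)
        spots = analyze_frame(r[0], g[0], PARAMS)
        assert len(spots) == 1
        commanded = truth["r_photons"].iloc[0] * img.adu_per_photon
        assert spots[0].r_scat == pytest.approx(commanded, rel=0.01)
        # aperture misses a slight, equal fraction in both channels
        assert spots[0].r_scat < commanded

    def test_identical_channels_give_zero_gamma(self):
        rng = np.random.default_rng(0)
        frame = np.full((64, 64), 50.0)
        yy, xx = np.mgrid[:64, :64]
        frame += 4000 * np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.2**2)))
        spots = analyze_frame(frame, frame.copy(), PARAMS)
        assert len(spots) == 1
        assert spots[0].gamma == pytest.approx(0.0, abs=1e-12)

    def test_corner_peak_flagged_edge(self):
        frame = np.zeros((64, 64))
        frame[1, 1] = 1000.0
        spot = measure_spot(frame, frame, (1.0, 1.0, 1000.0), PARAMS)
        assert spot.excluded and spot.reason == "edge"

    def test_gamma_reflects_channel_asymmetry(self):
        yy, xx = np.mgrid[:64, :64]
        blob = np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.2**2)))
        r = 30.0 + 3000 * blob
        g = 30.0 + 1000 * blob
        spots = analyze_frame(r, g, PARAMS)
        assert spots[0].gamma == pytest.approx(0.5, abs=0.02)


class TestFilterSpots:
    def test_all_kept_when_under_threshold(self):
        spots = analyze_frame(*self._single_frame(), PARAMS)
        from dataclasses import replace

        kept = filter_spots(spots, replace(PARAMS, max_area=10_000))
        assert len(kept) == len(spots)

    def test_zero_max_area_excludes_everything(self):
        spots = analyze_frame(*self._single_frame(), PARAMS)
        from dataclasses import replace

        kept = filter_spots(spots, replace(PARAMS, max_area=0))
        assert kept == []
        assert all(s.reason == "oversize" for s in spots if s.excluded)

    @staticmethod
    def _single_frame():
        pop = PopulationConfig(sd_diameter=0.0, shell_sd=0.0, aggregate_fraction=0.0)
        particles = sample_particles(1, pop, seed=7)
        r, g, _ = render_frames(particles, pop, _noiseless_img(spots_per_frame=1), seed=8)
        return r[0], g[0]

    def test_doublet_aggregate_excluded_by_calibrated_threshold(self):
        """A doublet's footprint exceeds the 99.5th percentile of
        single-particle areas, so the calibrated area filter removes it."""
        pop = PopulationConfig(sd_diameter=0.0, shell_sd=0.0, aggregate_fraction=0.0)
        img = _noiseless_img(spots_per_frame=40)
        particles = sample_particles(40, pop, seed=9)
        particles.loc[0, "is_aggregate"] = True
        particles.loc[0, "diameter2"] = 80.0
        r, g, truth = render_frames(particles, pop, img, seed=10)
        table, _ = analyze_dataset(r, g)
        truth_frame = truth.rename(columns={"frame": "frame"})
        max_area = max_area_from_table(table, truth_frame)
        match = match_spots(table, truth_frame)
        agg_rows = truth_frame.index[truth_frame["is_aggregate"]]
        agg_detections = table.loc[match.isin(agg_rows)]
        assert len(agg_detections) >= 1
        assert (agg_detections["area_px"] > max_area).all()


class TestAnalyzeDataset:
    def test_empty_stack_gives_empty_table(self):
        table, summary = analyze_dataset(
            np.zeros((0, 64, 64), dtype=np.uint16), np.zeros((0, 64, 64), dtype=np.uint16)
        )
        assert table.empty
        assert summary["detected"] == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            analyze_dataset(np.zeros((1, 64, 64)), np.zeros((1, 32, 32)))

    def test_deterministic_on_identical_input(self, nc_dataset):
        t1, s1 = analyze_dataset(nc_dataset.r_stack[:2], nc_dataset.g_stack[:2])
        t2, s2 = analyze_dataset(nc_dataset.r_stack[:2], nc_dataset.g_stack[:2])
        pd.testing.assert_frame_equal(t1, t2)
        assert s1 == s2

    def test_counts_conserved(self, nc_dataset):
        from dataclasses import replace

        table, summary = analyze_dataset(
            nc_dataset.r_stack, nc_dataset.g_stack, replace(PARAMS, max_area=100.0)
        )
        assert summary["detected"] == summary["kept"] + sum(summary["excluded"].values())
        assert not (table["excluded"] & (table["reason"] == "")).any()

    def test_recall_and_false_positives_on_noiseless_frames(self, noiseless_dataset):
        """On noiseless frames at default density, >= 95% of non-aggregate
        truth spots are recovered within 1 px and <= 1% of detections are
        spurious."""
        ds = noiseless_dataset
        table, _ = analyze_dataset(ds.r_stack, ds.g_stack)
        det = table.loc[~table["excluded"]]
        match = match_spots(det, ds.ground_truth, radius=1.0)
        singles = ds.ground_truth.loc[~ds.ground_truth["is_aggregate"]]
        recovered = match[match >= 0].unique()
        recall = np.isin(singles.index.to_numpy(), recovered).mean()
        assert recall >= 0.95
        loose = match_spots(det, ds.ground_truth, radius=3.0)
        fpr = (loose < 0).mean()
        assert fpr <= 0.01

    def test_measured_gamma_tracks_truth_in_size_dependent_mode(self):
        """With per-diameter Mie contrast enabled, measured gamma rank-
        correlates with ground truth (rho >= 0.8) at the default photon
        budget."""
        pop = PopulationConfig(size_dependent_contrast=True, aggregate_fraction=0.0)
        table = BandResponseTable(pop)
        ds = generate_dataset(0.0, n_spots=400, pop=pop, seed=21, table=table)
        spot_table, _ = analyze_dataset(ds.r_stack, ds.g_stack)
        det = spot_table.loc[~spot_table["excluded"]].copy()
        match = match_spots(det, ds.ground_truth)
        det["gamma_true"] = match.map(
            lambda i: ds.ground_truth["gamma_true"].get(i, np.nan)
        )
        det = det.dropna(subset=["gamma_true", "gamma"])
        rho = spearmanr(det["gamma"], det["gamma_true"]).statistic
        assert rho >= 0.8

    def test_default_density_recall_with_noise(self, nc_dataset):
        table, _ = analyze_dataset(nc_dataset.r_stack, nc_dataset.g_stack)
        det = table.loc[~table["excluded"]]
        match = match_spots(det, nc_dataset.ground_truth, radius=1.0)
        singles = nc_dataset.ground_truth.loc[~nc_dataset.ground_truth["is_aggregate"]]
        recovered = match[match >= 0].unique()
        recall = np.isin(singles.index.to_numpy(), recovered).mean()
        assert recall >= 0.95
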