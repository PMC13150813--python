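"""Cosine scoring, ROI construction, SNR exclusion and report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabosim import (
    EmptyReportError,
    Peak,
    PeakList,
    RegionOfInterest,
    SimilarityReport,
    UndefinedScoreError,
    UndefinedSNRError,
    ValidationError,
    cosine_score,
    overall_score,
    regions_of_interest,
    render,
    snr,
)


class TestCosine:
    def test_self_is_one_and_inverted_is_minus_one(self, doublet_grid):
        y = doublet_grid.intensities
        assert cosine_score(y, y) == pytest.approx(1.0, abs=1e-12)
        assert cosine_score(y, -y) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_vector_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            cosine_score(np.zeros(8), np.ones(8))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cosine_score(np.ones(4), np.ones(5))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        c=st.floats(1e-6, 1e6, allow_nan=False),
    )
    def test_scale_invariance_and_symmetry(self, seed, c):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=64)
        b = rng.normal(size=64)
        assert cosine_score(a, c * b) == pytest.approx(
            cosine_score(a, b), abs=1e-12
        )
        assert cosine_score(a, b) == cosine_score(b, a)

    @pytest.mark.parametrize("r", [1.5, 2.0, 2.5, 4.0])
    def test_width_ratio_law(self, r):
        """Co-centered Lorentzians of width ratio r score 2 sqrt(r)/(1+r)
        on a grid spanning >= 500 widths; 0.90 (two decimals) at r = 2.5."""
        w = 1.0  # Hz at 600 MHz
        span = 550 * r * w / 600.0
        args = (600.0, 5.0 + span / 2, 5.0 - span / 2, 1 << 16)
        a = render(PeakList([Peak(5.0, 1.0, w)]), *args).intensities
        b = render(PeakList([Peak(5.0, 1.0, r * w)]), *args).intensities
        expected = 2 * np.sqrt(r) / (1 + r)
        score = cosine_score(a, b)
        assert score == pytest.approx(expected, abs=0.005)
        if r == 2.5:
            assert round(score, 2) == 0.90


class TestRegionsOfInterest:
    def test_single_peak_margin_definition(self):
        pl = PeakList([Peak(3.0, 1.0, 1.0, multiplet_id="M1")])
        (roi,) = regions_of_interest(pl, 600.0, margin_factor=10.0)
        assert roi.ppm_high == pytest.approx(3.0 + 10.0 / 600.0)
        assert roi.ppm_low == pytest.approx(3.0 - 10.0 / 600.0)

    def test_distant_multiplets_stay_disjoint(self, doublet_peaks):
        rois = regions_of_interest(doublet_peaks, 600.0)
        assert len(rois) == 2
        assert rois[0].ppm_low > rois[1].ppm_high  # descending, disjoint

    def test_overlapping_margins_merge_to_interval_union(self):
        pl = PeakList(
            [
                Peak(3.00, 1.0, 6.0, multiplet_id="A"),
                Peak(3.05, 1.0, 6.0, multiplet_id="B"),
            ]
        )
        rois = regions_of_interest(pl, 600.0, margin_factor=10.0)
        assert len(rois) == 1
        # brute-force union of the two margined intervals
        m = 10.0 * 6.0 / 600.0
        assert rois[0].ppm_high == pytest.approx(3.05 + m)
        assert rois[0].ppm_low == pytest.approx(3.00 - m)

    def test_empty_peaklist_rejected(self):
        with pytest.raises(ValidationError):
            regions_of_interest(PeakList([]), 600.0)


class TestSNR:
    def test_noiseless_grid_has_undefined_snr(self, doublet_grid):
        # constant (zero-signal) noise region: deviation 0, SNR undefined
        flat = doublet_grid.with_intensities(
            np.zeros(doublet_grid.n_points)
        )
        with pytest.raises(UndefinedSNRError):
            snr(flat, RegionOfInterest(2.1, 1.9), RegionOfInterest(5.0, 4.0))

    def test_constructed_snr_near_hundred(self, doublet_grid):
        rng = np.random.default_rng(42)
        noisy = doublet_grid.with_intensities(
            doublet_grid.intensities * 100.0 + rng.normal(size=doublet_grid.n_points)
        )
        value = snr(noisy, RegionOfInterest(2.1, 1.9), RegionOfInterest(5.0, 4.0))
        assert value == pytest.approx(100.0, rel=0.1)

    def test_peak_free_roi_has_small_snr(self, doublet_grid):
        rng = np.random.default_rng(43)
        noisy = doublet_grid.with_intensities(
            doublet_grid.intensities + rng.normal(size=doublet_grid.n_points)
        )
        value = snr(noisy, RegionOfInterest(4.6, 4.4), RegionOfInterest(5.5, 4.8))
        assert value < 6.0

    def test_tiny_noise_interval_rejected(self, doublet_grid):
        with pytest.raises(ValidationError):
            snr(
                doublet_grid,
                RegionOfInterest(2.1, 1.9),
                RegionOfInterest(4.001, 4.0),
            )


class TestOverallScore:
    def test_identical_grids_score_one_and_pass(
        self, doublet_peaks, doublet_grid
    ):
        rois = regions_of_interest(doublet_peaks, 600.0)
        report = overall_score(doublet_grid, doublet_grid, rois)
        assert report.overall == pytest.approx(1.0, abs=1e-12)
        assert report.passed
        assert report.excluded_rois == []

    def test_overall_is_unweighted_mean_of_roi_scores(
        self, doublet_peaks, doublet_grid
    ):
        rng = np.random.default_rng(11)
        exp = doublet_grid.with_intensities(
            doublet_grid.intensities
            + rng.normal(0, 0.2, doublet_grid.n_points)
        )
        rois = regions_of_interest(doublet_peaks, 600.0)
        report = overall_score(doublet_grid, exp, rois, snr_min=0.0)
        assert report.overall == pytest.approx(
            np.mean(report.roi_scores), abs=1e-15
        )

    def test_displaced_multiplet_drags_overall_down(self, doublet_peaks):
        """Shifting one multiplet by many widths inside its ROI sends that
        ROI's score toward 0 and the mean toward 0.5."""
        sim = render(doublet_peaks, 600.0, 9.0, 0.0, 8192)
        moved = PeakList(
            [
                doublet_peaks.peaks[0],
                doublet_peaks.peaks[1],
                Peak(7.02, 2.0, 1.5, multiplet_id="M2"),  # 8 widths off
            ]
        )
        exp = render(moved, 600.0, 9.0, 0.0, 8192)
        rois = regions_of_interest(doublet_peaks, 600.0)
        report = overall_score(sim, exp, rois, snr_min=0.0)
        assert min(report.roi_scores) < 0.15
        assert 0.4 < report.overall < 0.65
        assert not report.passed

    def test_low_snr_roi_excluded_from_mean(self, doublet_peaks):
        sim = render(doublet_peaks, 600.0, 9.0, 0.0, 8192)
        weak = PeakList(
            [
                Peak(2.006, 1.0, 1.5, multiplet_id="M1"),
                Peak(1.994, 1.0, 1.5, multiplet_id="M1"),
                Peak(7.0, 0.002, 1.5, multiplet_id="M2"),  # below 10x noise
            ]
        )
        rng = np.random.default_rng(7)
        exp = render(weak, 600.0, 9.0, 0.0, 8192)
        exp = exp.with_intensities(
            exp.intensities + rng.normal(0, 1e-3, exp.n_points)
        )
        rois = regions_of_interest(doublet_peaks, 600.0)
        report = overall_score(
            sim, exp, rois, noise_interval=RegionOfInterest(5.5, 4.5)
        )
        assert len(report.excluded_rois) == 1
        assert len(report.roi_scores) == 1

    def test_all_rois_excluded_raises(self, doublet_peaks):
        sim = render(doublet_peaks, 600.0, 9.0, 0.0, 8192)
        rng = np.random.default_rng(8)
        exp = sim.with_intensities(rng.normal(0, 1e-3, sim.n_points))
        with pytest.raises(EmptyReportError):
            overall_score(
                sim,
                exp,
                regions_of_interest(doublet_peaks, 600.0),
                noise_interval=RegionOfInterest(5.5, 4.5),
            )

    def test_intensity_outside_rois_does_not_change_report(
        self, doublet_peaks
    ):
        sim = render(doublet_peaks, 600.0, 9.0, 0.0, 8192)
        rng = np.random.default_rng(9)
        exp = sim.with_intensities(
            sim.intensities + rng.normal(0, 0.01, sim.n_points)
        )
        rois = regions_of_interest(doublet_peaks, 600.0)
        noise = RegionOfInterest(5.5, 4.5)
        before = overall_score(sim, exp, rois, noise_interval=noise)
        # contaminate a region outside every ROI and the noise interval
        contaminated = exp.intensities.copy()
        idx = exp.slice_indices(8.6, 8.2)
        contaminated[idx] += 50.0
        after = overall_score(
            sim, exp.with_intensities(contaminated), rois, noise_interval=noise
        )
        assert after.roi_scores == before.roi_scores
        assert after.overall == before.overall


class TestReport:
    def test_text_round_trip(self, doublet_peaks, doublet_grid):
        rois = regions_of_interest(doublet_peaks, 600.0)
        report = overall_score(doublet_grid, doublet_grid, rois)
        back = SimilarityReport.from_text(report.to_text())
        assert back.overall == report.overall
        assert back.threshold == report.threshold
        assert back.passed == report.passed
        assert len(back.rois) == len(report.rois)
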