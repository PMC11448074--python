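"""Preprocessing chain: transforms, SNIP, TIC, detection, binning, matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sakeityper import (
    CohortDesign,
    NoiseParams,
    PeakTemplate,
    PipelineOrderError,
    Spectrum,
    StrainProfile,
    bin_peaks,
    build_feature_matrix,
    detect_peaks,
    estimate_noise,
    preprocess_spectrum,
    snip_baseline,
    sqrt_transform,
    subtract_baseline,
    synthesize_spectrum,
    tic_normalize,
)
from sakeityper.spectrum import PeakList


def spec(intensity, state=("raw",), mz=None, sid="s"):
    intensity = np.asarray(intensity, float)
    if mz is None:
        mz = 2000.0 + np.arange(intensity.size, dtype=float)
    return Spectrum(mz=mz, intensity=intensity, state=tuple(state), spectrum_id=sid)


class TestSqrtTransform:
    def test_elementwise_values(self):
        out = sqrt_transform(spec([0, 1, 4, 9]))
        np.testing.assert_array_equal(out.intensity, [0, 1, 2, 3])
        assert out.state == ("raw", "sqrt")

    def test_all_zero_stays_zero(self):
        np.testing.assert_array_equal(sqrt_transform(spec([0, 0, 0])).intensity, 0)

    def test_random_vector_matches_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 100, 512)
        np.testing.assert_allclose(sqrt_transform(spec(y)).intensity, np.sqrt(y))

    def test_refuses_out_of_order(self):
        s = sqrt_transform(spec([1, 2, 3]))
        with pytest.raises(PipelineOrderError):
            sqrt_transform(s)


class TestSnipBaseline:
    def test_constant_spectrum_is_its_own_baseline(self):
        y = np.full(200, 3.5)
        np.testing.assert_array_equal(snip_baseline(spec(y), 20), y)

    def test_linear_ramp_is_preserved(self):
        y = np.linspace(1.0, 9.0, 300)
        np.testing.assert_allclose(snip_baseline(spec(y), 30), y)

    def test_baseline_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 10, 1000)
        assert np.all(snip_baseline(spec(y), 50) <= y + 1e-15)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 10, 1000) + np.linspace(5, 0, 1000)
        b1 = snip_baseline(spec(y), 40)
        b2 = snip_baseline(b1, 40)
        np.testing.assert_allclose(b2, b1, atol=1e-12)

    def test_recovers_synthetic_baseline_off_peak(self):
        # exponential baseline + one narrow Gaussian: off-peak error < 2% of A
        mz = 2000.0 + np.arange(6000, dtype=float)
        amplitude = 20.0
        true_baseline = amplitude * np.exp(-(mz - 2000.0) / 4500.0)
        peak = 50.0 * np.exp(-0.5 * ((mz - 5000.0) / 4.0) ** 2)
        est = snip_baseline(spec(true_baseline + peak, mz=mz), 100)
        off_peak = np.abs(mz - 5000.0) > 150
        assert np.max(np.abs(est - true_baseline)[off_peak]) < 0.02 * amplitude

    def test_oversized_iterations_clamped(self, caplog):
        y = np.arange(10.0)
        with caplog.at_level("WARNING", logger="sakeityper.preprocess"):
            out = snip_baseline(spec(y), 500)
        assert out.shape == y.shape
        assert any("clamped" in r.message for r in caplog.records)


class TestSubtractBaseline:
    def test_zero_baseline_is_identity(self):
        s = sqrt_transform(spec([1, 4, 9, 16]))
        out = subtract_baseline(s, np.zeros(4))
        np.testing.assert_array_equal(out.intensity, s.intensity)
        assert out.current_state == "baseline_subtracted"

    def test_pure_baseline_subtracts_to_zero(self):
        y = np.linspace(10, 1, 500) ** 2
        s = sqrt_transform(spec(y))
        out = subtract_baseline(s, snip_baseline(s, 50))
        assert np.max(out.intensity) < 1e-9

    def test_planted_peak_height_recovered_within_5pct(self):
        mz = 2000.0 + np.arange(4000, dtype=float)
        baseline = np.linspace(8, 2, 4000)
        peak = 6.0 * np.exp(-0.5 * ((mz - 4000.0) / 4.0) ** 2)
        s = spec(baseline + peak, state=("raw", "sqrt"), mz=mz)
        out = subtract_baseline(s, snip_baseline(s, 100))
        assert abs(out.intensity.max() - 6.0) / 6.0 < 0.05

    def test_length_mismatch_rejected(self):
        s = sqrt_transform(spec([1, 2, 3]))
        with pytest.raises(ValueError, match="length"):
            subtract_baseline(s, np.zeros(5))


class TestTicNormalize:
    def _prep(self, y):
        s = sqrt_transform(spec(y))
        return subtract_baseline(s, np.zeros(len(y)))

    def test_sum_is_one(self):
        out = tic_normalize(self._prep([1.0, 2.0, 3.0, 4.0]))
        assert out.intensity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        y = np.random.default_rng(3).uniform(0.1, 5, 100)
        a = tic_normalize(self._prep(y))
        b = tic_normalize(self._prep(7.0 * y))
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_already_normalized_unchanged(self):
        y = np.array([0.25, 0.25, 0.5])
        out = tic_normalize(self._prep(y * y))  # sqrt undoes the square
        np.testing.assert_allclose(out.intensity, y / y.sum())

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            tic_normalize(self._prep([0.0, 0.0, 0.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_property_sum_one_for_random_spectra(self, seed):
        y = np.random.default_rng(seed).uniform(0, 10, 64) + 1e-6
        out = tic_normalize(self._prep(y))
        assert out.intensity.sum() == pytest.approx(1.0, abs=1e-9)


class TestEstimateNoise:
    def test_constant_spectrum_zero_noise(self):
        assert estimate_noise(np.full(100, 2.0)) == 0.0

    def test_gaussian_noise_sd_recovered(self):
        y = np.random.default_rng(4).normal(0, 1.7, 5000)
        assert estimate_noise(y) == pytest.approx(1.7, rel=0.10)

    def test_robust_to_sparse_peaks(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1.0, 5000)
        y[::250] += 50.0  # 20 large peaks
        assert estimate_noise(y) == pytest.approx(1.0, rel=0.15)


class TestDetectPeaks:
    def _processed(self, y, mz=None):
        return spec(y, state=("raw", "sqrt", "baseline_subtracted", "tic_normalized"),
                    mz=mz)

    def test_flat_spectrum_yields_no_peaks(self):
        pl = detect_peaks(self._processed(np.full(500, 0.002)))
        assert len(pl) == 0

    def test_single_planted_peak_found_at_center(self):
        design = CohortDesign()
        tpl = PeakTemplate(7000.0, {"sakei": 1.0}, 60.0, intensity_cv=0.0)
        profile = StrainProfile("sakei_001", "sakei", (tpl,))
        ls = synthesize_spectrum(
            profile, design, NoiseParams(mz_jitter_sd=0.0), "on_plate", seed=8
        )
        pl = detect_peaks(preprocess_spectrum(ls.spectrum))
        strong = pl.mz[pl.snr >= 5]
        assert len(strong) == 1
        assert abs(strong[0] - 7000.0) <= 2 * design.grid_step

    def test_all_retained_peaks_meet_snr_threshold(self):
        rng = np.random.default_rng(9)
        y = np.abs(rng.normal(0, 1e-4, 3000))
        y[500] = 0.01
        pl = detect_peaks(self._processed(y), snr_threshold=3.0)
        assert np.all(pl.snr >= 3.0)

    def test_requires_fully_preprocessed_spectrum(self):
        with pytest.raises(PipelineOrderError):
            detect_peaks(spec([1, 2, 3]))


class TestBinPeaks:
    def _pl(self, mzs, sid):
        mzs = np.asarray(mzs, float)
        return PeakList(mz=mzs, intensity=np.ones_like(mzs),
                        snr=np.full_like(mzs, 10.0), source_spectrum_id=sid)

    def test_nearby_peaks_merge_into_one_bin(self):
        # 9653 vs 9662: relative gap ~0.00093 < 0.002
        binned, refs = bin_peaks([self._pl([9653.0], "a"), self._pl([9662.0], "b")])
        assert refs.size == 1
        assert refs[0] == pytest.approx(9657.5)
        assert binned[0].mz[0] == binned[1].mz[0] == pytest.approx(9657.5)

    def test_distant_peaks_stay_separate(self):
        _, refs = bin_peaks([self._pl([4000.0], "a"), self._pl([4100.0], "b")])
        assert refs.size == 2

    def test_single_spectrum_bins_are_its_peaks(self):
        pl = self._pl([3000.0, 5000.0, 9000.0], "a")
        binned, refs = bin_peaks([pl])
        np.testing.assert_allclose(refs, pl.mz)
        np.testing.assert_allclose(binned[0].mz, pl.mz)

    def test_order_independence(self):
        lists = [self._pl([3000.0, 5002.0], "a"), self._pl([5000.0, 9000.0], "b"),
                 self._pl([2999.0], "c")]
        _, refs_fwd = bin_peaks(lists)
        _, refs_rev = bin_peaks(lists[::-1])
        np.testing.assert_allclose(refs_fwd, refs_rev)

    def test_members_within_tolerance_of_reference(self, small_features):
        _, _, peaklists, _ = small_features
        binned, refs = bin_peaks(peaklists)
        for raw, b in zip(peaklists, binned):
            if len(raw) == 0:
                continue
            # each binned m/z is a reference, and the raw peak it came from
            # deviates by at most the tolerance
            for raw_mz in raw.mz:
                ref = refs[np.argmin(np.abs(refs - raw_mz))]
                assert abs(raw_mz - ref) <= 0.002 * ref


class TestFeatureMatrix:
    def _spectra_pair(self):
        mz = 2000.0 + np.arange(100, dtype=float)
        y1 = np.zeros(100); y1[[20, 60]] = [0.4, 0.6]
        y2 = np.zeros(100); y2[20] = 1.0
        st4 = ("raw", "sqrt", "baseline_subtracted", "tic_normalized")
        s1 = spec(y1, state=st4, mz=mz, sid="s1")
        s2 = spec(y2, state=st4, mz=mz, sid="s2")
        pl1 = PeakList([2020.0, 2060.0], [0.4, 0.6], [9, 9], "s1")
        pl2 = PeakList([2020.0], [1.0], [9], "s2")
        return [s1, s2], [pl1, pl2]

    def test_full_detection_gives_apex_intensities(self):
        spectra, pls = self._spectra_pair()
        binned, refs = bin_peaks(pls)
        fm = build_feature_matrix(binned, spectra, refs, fill="zero")
        assert fm.intensities.loc["s1", 2020.0] == pytest.approx(0.4)
        assert fm.intensities.loc["s2", 2020.0] == pytest.approx(1.0)

    def test_zero_fill_for_missing_bin(self):
        spectra, pls = self._spectra_pair()
        binned, refs = bin_peaks(pls)
        fm = build_feature_matrix(binned, spectra, refs, fill="zero")
        assert fm.intensities.loc["s2", 2060.0] == 0.0
        assert not fm.detected.loc["s2", 2060.0]

    def test_interpolation_fill_matches_midpoint(self):
        mz = np.array([2000.0, 2001.0])
        st4 = ("raw", "sqrt", "baseline_subtracted", "tic_normalized")
        s = spec([0.2, 0.8], state=st4, mz=mz, sid="s1")
        empty = PeakList([], [], [], "s1")
        fm = build_feature_matrix([empty], [s], np.array([2000.5]), fill="interpolate")
        assert fm.intensities.iloc[0, 0] == pytest.approx(0.5)

    def test_out_of_range_bin_zero_filled_with_warning(self):
        spectra, pls = self._spectra_pair()
        refs = np.array([1500.0])
        empties = [PeakList([], [], [], "s1"), PeakList([], [], [], "s2")]
        with pytest.warns(UserWarning, match="outside the mass range"):
            fm = build_feature_matrix(empties, spectra, refs, fill="interpolate")
        assert (fm.intensities[1500.0] == 0).all()

    def test_matrix_shape_matches_cohort(self, small_features):
        features, processed, _, manifest = small_features
        assert features.intensities.shape[0] == len(manifest)
        assert features.intensities.shape[1] == features.bin_mz.size
        assert not features.intensities.isna().any().any()


class TestEndToEndRecovery:
    def test_planted_bins_recovered_and_few_spurious(self, small_features):
        from sakeityper import default_templates

        features, _, _, _ = small_features
        refs = features.bin_mz
        centers = np.array([t.mz_center for t in default_templates()])
        # class-marker templates present as matrix columns
        matched = [
            np.any(np.abs(refs - c) <= 0.002 * c + 3.0) for c in centers
        ]
        assert np.mean(matched) >= 0.95
        # spurious columns: no planted template nearby
        spurious = [
            not np.any(np.abs(centers - r) <= 0.002 * r + 3.0) for r in refs
        ]
        assert np.mean(spurious) < 0.10
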