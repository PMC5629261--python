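"""mScore scoring: m/z score, scaling factor, intensity score, combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micquant import (
    CentroidedSpectrum,
    MoleculeSpec,
    ScoringParams,
    build_library,
    combine,
    compute_sigma,
    find_peak_candidates,
    match_pattern,
    score_intensity,
    score_mz,
)
from micquant.scoring import PeakMatch

from conftest import spectrum_from_pattern


def make_peak(ppm_error=0.0, r=1.0, measured=1.0, theoretical=None, k=0):
    return PeakMatch(peak_index=k, mz_theoretical=500.0, rel_intensity=r,
                     mz_measured=500.0, intensity_measured=measured,
                     ppm_error=ppm_error, intensity_theoretical=theoretical)


@pytest.fixture(scope="module")
def adenosine_pattern():
    mol = MoleculeSpec.from_identity("C10O4N5H13")
    return build_library([mol], charges=[1], percentiles=[0])[("C10H13N5O4", 1, 0.0)]


class TestMzScore:
    def test_half_alpha_error_scores_one_half(self, params):
        """2.5 ppm error at alpha = 5 ppm gives exactly 0.5."""
        assert score_mz([make_peak(ppm_error=2.5)], params) == 0.5

    def test_zero_error_scores_one(self, params):
        peaks = [make_peak(0.0, r) for r in (1.0, 0.5, 0.1)]
        assert score_mz(peaks, params) == 1.0

    def test_weighted_sum_arithmetic(self, params):
        # s = (1.0, 0.4), r = (1.0, 0.5): (1.0 + 0.4*0.5)/1.5 = 0.8
        peaks = [make_peak(0.0, 1.0), make_peak(3.0, 0.5)]
        assert score_mz(peaks, params) == pytest.approx(0.8)

    def test_empty_peak_list_is_no_match(self, params):
        assert score_mz([], params) is None


class TestSigma:
    def test_uniform_scale_recovered(self):
        peaks = [make_peak(r=r, measured=2.0 * r) for r in (1.0, 0.3, 0.05)]
        assert compute_sigma(peaks) == pytest.approx(2.0)

    def test_identity_scale(self):
        peaks = [make_peak(r=r, measured=r) for r in (1.0, 0.3)]
        assert compute_sigma(peaks) == pytest.approx(1.0)

    def test_weighted_ratio_arithmetic(self):
        # r=(1, 0.5), theoretical=(100, 50), measured=(300, 100):
        # (300*1 + 100*0.5) / (100*1 + 50*0.5) = 350/125 = 2.8
        peaks = [make_peak(r=1.0, measured=300.0, theoretical=100.0),
                 make_peak(r=0.5, measured=100.0, theoretical=50.0, k=1)]
        assert compute_sigma(peaks) == pytest.approx(2.8)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            compute_sigma([make_peak(r=0.0, measured=10.0)])


class TestIntensityScore:
    def test_exact_sigma_scaled_intensities_score_one(self, params):
        peaks = [make_peak(r=r, measured=7.0 * r) for r in (1.0, 0.4)]
        assert score_intensity(peaks, 7.0, params) == 1.0

    def test_ten_percent_error_on_top_peak(self, params):
        # r = 1: denominator is epsilon = 0.2, so 10% error scores 0.5
        peaks = [make_peak(r=1.0, measured=1.1)]
        assert score_intensity(peaks, 1.0, params) == pytest.approx(0.5)

    def test_low_abundance_peaks_are_penalized_less(self, params):
        # same 10% relative error at r = 0.5: denominator 0.7, s ~ 0.857
        peaks = [make_peak(r=0.5, measured=0.55)]
        assert score_intensity(peaks, 1.0, params) == pytest.approx(1 - 0.1 / 0.7)


class TestCombine:
    def test_perfect_scores_combine_to_one(self, params):
        assert combine(1.0, 1.0, params) == 1.0

    def test_default_weighting(self, params):
        assert combine(0.5, 1.0, params) == pytest.approx(0.8)

    def test_degenerate_weight_returns_mz_score(self):
        p = ScoringParams(xi=1.0)
        assert combine(0.37, 0.99, p) == pytest.approx(0.37)


class TestCandidateSearch:
    def _spectrum(self, mzs, intensities=None):
        mzs = np.asarray(mzs, dtype=float)
        if intensities is None:
            intensities = np.ones_like(mzs)
        return CentroidedSpectrum(1, 10.0, mzs, np.asarray(intensities, float))

    def test_boundary_ppm_error_is_accepted(self, params, adenosine_pattern):
        pat = adenosine_pattern
        spectrum = spectrum_from_pattern(pat, ppm_shift=5.0)
        peaks = find_peak_candidates(pat, spectrum, params)
        assert len(peaks) == len(pat)
        assert all(p.ppm_error == pytest.approx(5.0, abs=1e-9) for p in peaks)

    def test_beyond_alpha_is_rejected(self, params, adenosine_pattern):
        spectrum = spectrum_from_pattern(adenosine_pattern, ppm_shift=5.5)
        assert find_peak_candidates(adenosine_pattern, spectrum, params) == []

    def test_nearest_ppm_wins(self, params, adenosine_pattern):
        pat = adenosine_pattern
        mz0 = pat.mzs[0]
        spectrum = self._spectrum([mz0 * (1 - 3e-6), mz0 * (1 + 2e-6)], [5.0, 1.0])
        peaks = find_peak_candidates(pat, spectrum, params)
        assert peaks[0].mz_measured == pytest.approx(mz0 * (1 + 2e-6))

    def test_machine_offset_is_subtracted(self, adenosine_pattern):
        pat = adenosine_pattern
        params = ScoringParams(machine_offset_ppm=2.0)
        spectrum = spectrum_from_pattern(pat, ppm_shift=6.0)
        peaks = find_peak_candidates(pat, spectrum, params)
        assert len(peaks) == len(pat)
        assert all(p.ppm_error == pytest.approx(4.0, abs=1e-9) for p in peaks)


class TestMatchPattern:
    def test_scaled_pattern_is_a_perfect_match(self, params, adenosine_pattern):
        spectrum = spectrum_from_pattern(adenosine_pattern, scale=1000.0)
        m = match_pattern(adenosine_pattern, spectrum, params)
        assert m.mscore == pytest.approx(1.0, abs=1e-12)
        assert m.sigma == pytest.approx(1000.0)

    def test_uniform_ppm_shift_composes_both_scores(self, params, adenosine_pattern):
        spectrum = spectrum_from_pattern(adenosine_pattern, ppm_shift=2.5)
        m = match_pattern(adenosine_pattern, spectrum, params)
        assert m.score_mz == pytest.approx(0.5, abs=1e-9)
        assert m.score_intensity == pytest.approx(1.0)
        assert m.mscore == pytest.approx(0.4 * 0.5 + 0.6 * 1.0, abs=1e-9)

    def test_missing_required_peak_rejects_the_match(self, params, adenosine_pattern):
        top = int(np.argmax(adenosine_pattern.rel_intensities))
        spectrum = spectrum_from_pattern(adenosine_pattern, drop=(top,))
        assert match_pattern(adenosine_pattern, spectrum, params) is None

    def test_min_matched_fraction_relaxes_the_policy(self, adenosine_pattern):
        relaxed = ScoringParams(min_matched_fraction=0.5)
        last = len(adenosine_pattern) - 1
        spectrum = spectrum_from_pattern(adenosine_pattern, drop=(last,))
        m = match_pattern(adenosine_pattern, spectrum, relaxed)
        assert m is not None
        assert len(m.peaks) == len(adenosine_pattern) - 1


@pytest.mark.parametrize("shift", [0.0, 1.25, 2.5, 3.75, 5.0])
def test_mz_score_decays_linearly_with_uniform_shift(shift, params, adenosine_pattern):
    """A uniform shift d in [0, alpha] gives S^mz = 1 - d/alpha exactly."""
    spectrum = spectrum_from_pattern(adenosine_pattern, ppm_shift=shift)
    m = match_pattern(adenosine_pattern, spectrum, params)
    assert m.score_mz == pytest.approx(1.0 - shift / 5.0, abs=1e-9)


@given(st.floats(0.1, 1e7), st.floats(-4.9, 4.9), st.floats(0.5, 3.0))
@settings(max_examples=30)
def test_sigma_linearity_and_score_invariance(scale, shift, sigma0):
    """Scaling intensities by c multiplies sigma by c, leaving scores fixed."""
    mol = MoleculeSpec.from_identity("GASPVTK")
    pattern = build_library([mol], charges=[2], percentiles=[0])[
        (mol.formula.to_string(), 2, 0.0)]
    params = ScoringParams()
    base = spectrum_from_pattern(pattern, scale=sigma0, ppm_shift=shift)
    scaled = CentroidedSpectrum(1, 10.0, base.mzs, base.intensities * scale)
    m1 = match_pattern(pattern, base, params)
    m2 = match_pattern(pattern, scaled, params)
    assert m2.sigma == pytest.approx(m1.sigma * scale, rel=1e-9)
    assert m2.score_mz == pytest.approx(m1.score_mz, abs=1e-9)
    assert m2.score_intensity == pytest.approx(m1.score_intensity, abs=1e-6)


@given(st.lists(st.tuples(st.floats(0, 10), st.floats(0.01, 1.0),
                          st.floats(0.01, 100)), min_size=1, max_size=6))
@settings(max_examples=50)
def test_scores_always_clamped_to_unit_interval(raw):
    """No per-peak or total score leaves [0, 1], whatever the errors."""
    params = ScoringParams()
    peaks = [make_peak(ppm_error=min(ppm, 5.0), r=r, measured=meas, k=i)
             for i, (ppm, r, meas) in enumerate(raw)]
    s_mz = score_mz(peaks, params)
    assert 0.0 <= s_mz <= 1.0
    sigma = compute_sigma(peaks)
    s_int = score_intensity(peaks, sigma, params)
    assert 0.0 <= s_int <= 1.0
    assert 0.0 <= combine(s_mz, s_int, params) <= 1.0


def test_weights_in_both_totals_are_identical(params, adenosine_pattern):
    """The r_k weight sums of the m/z and intensity totals coincide."""
    spectrum = spectrum_from_pattern(adenosine_pattern, scale=10.0)
    peaks = find_peak_candidates(adenosine_pattern, spectrum, params)
    weights = [p.rel_intensity for p in peaks]
    assert weights == list(adenosine_pattern.rel_intensities)
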