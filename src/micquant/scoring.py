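"""Matching and mScore similarity scoring of patterns against spectra.

A theoretical pattern is compared with a centroided MS¹ spectrum peak by
peak.  Two Gower-style similarity scores are computed independently and then
combined:

* the m/z score — per peak, s^mz = 1 − δ^mz/α, where δ^mz is the ppm error
  (after machine-offset correction) and α the ppm range over which the score
  falls linearly from 1 to 0 (instrument precision, default 5 ppm);
* the intensity score — a scaling factor σ (the molecule's abundance on the
  spectrum's intensity scale) is fitted as the ratio of r_k-weighted
  measured to theoretical intensities; per peak the relative intensity error
  δ^int is scored as s^int = 1 − δ^int/(1 − r_k + ε), so low-abundance peaks,
  which are measured less precisely, are penalized more leniently (ε is the
  relative error allowed on the most intense peak, default 0.2).

Both totals are r_k-weighted means over the matched peaks; the final
mScore = ξ·S^mz + (1 − ξ)·S^intensity with ξ (default 0.4) the m/z-score
weight, adjustable to the accuracy profile of the instrument.  Per-peak
scores are clamped to [0, 1], so the mScore lies in [0, 1], with 1 a
perfect match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .isotope_pattern import DEFAULT_MATCHING_THRESHOLD, IsotopePattern

__all__ = [
    "ScoringParams",
    "CentroidedSpectrum",
    "PeakMatch",
    "PatternMatch",
    "find_peak_candidates",
    "score_mz",
    "compute_sigma",
    "score_intensity",
    "combine",
    "match_pattern",
]


@dataclass(frozen=True)
class ScoringParams:
    """Tunable matching/scoring parameters.

    Attribute names mirror the conventional parameter names: ``alpha_ppm``
    (REL_MZ_RANGE), ``epsilon`` (REL_I_RANGE), ``xi`` (MZ_SCORE_PERCENTILE).
    ``alpha_intensity`` normalizes the relative intensity error; the default
    1 makes δ^int a plain relative error (the dimensionally coherent
    reading), while setting it to ``alpha_ppm`` reproduces the literal
    equation form.  ``min_matched_fraction = 1.0`` requires every pattern
    peak above the matching threshold to find a measured partner (the
    conservative policy); lower it to allow partial-pattern matches.
    """

    alpha_ppm: float = 5.0
    epsilon: float = 0.2
    xi: float = 0.4
    matching_threshold: float = DEFAULT_MATCHING_THRESHOLD
    machine_offset_ppm: float = 0.0
    alpha_intensity: float = 1.0
    min_matched_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_ppm <= 0 or self.epsilon <= 0:
            raise ValueError("alpha_ppm and epsilon must be positive")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must be in [0, 1]")
        if not 0.0 < self.matching_threshold < 1.0:
            raise ValueError("matching threshold must be in (0, 1)")


@dataclass(frozen=True)
class CentroidedSpectrum:
    """One centroided spectrum: sorted (m/z, intensity) peak apexes."""

    spectrum_id: int
    retention_time: float  # minutes
    mzs: np.ndarray
    intensities: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "mzs", np.asarray(self.mzs, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if len(self.mzs) != len(self.intensities):
            raise ValueError("m/z and intensity arrays differ in length")
        if len(self.mzs) > 1 and not np.all(np.diff(self.mzs) > 0):
            raise ValueError("spectrum m/z values must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity")

    def __len__(self) -> int:
        return len(self.mzs)


@dataclass(frozen=True)
class PeakMatch:
    """One theoretical peak paired with one measured peak.

    ``intensity_theoretical`` (I_jk) may be on any scale; ``rel_intensity``
    (r_k) is I_jk relative to the pattern's most intense peak.  Patterns
    built in-package store theoretical intensities already normalized to
    max = 1, so I_jk = r_k and σ comes out in max-peak-equivalent ion
    counts.
    """

    peak_index: int        # k, index into the pattern
    mz_theoretical: float  # m/z_jk
    rel_intensity: float   # r_k
    mz_measured: float     # m/z_ik (raw, uncorrected)
    intensity_measured: float  # intensity_ik
    ppm_error: float       # δ^mz_ijk, |ppm| after machine-offset correction
    intensity_theoretical: float | None = None  # I_jk; defaults to r_k

    @property
    def theoretical(self) -> float:
        return self.rel_intensity if self.intensity_theoretical is None \
            else self.intensity_theoretical


@dataclass(frozen=True)
class PatternMatch:
    """A scored comparison of one pattern with one spectrum."""

    pattern_key: tuple[str, int, float]  # (formula, charge, label percentile)
    spectrum_id: int
    retention_time: float
    sigma: float
    score_mz: float
    score_intensity: float
    mscore: float
    peaks: tuple[PeakMatch, ...] = field(repr=False, default=())

    @property
    def formula(self) -> str:
        return self.pattern_key[0]

    @property
    def charge(self) -> int:
        return self.pattern_key[1]

    @property
    def label_percentile(self) -> float:
        return self.pattern_key[2]

    @property
    def abundance(self) -> float:
        """σ is the abundance on the scale of the pattern's max peak."""
        return self.sigma


def find_peak_candidates(
    pattern: IsotopePattern,
    spectrum: CentroidedSpectrum,
    params: ScoringParams,
) -> list[PeakMatch]:
    """Pair each pattern peak with its best measured peak within α ppm.

    The ppm error is computed after subtracting the signed machine offset
    from the raw error; the tolerance interval is closed (|δ| = α is
    accepted).  Ties on |δ| break toward the higher-intensity measured peak
    so output is deterministic.  Pattern peaks without a partner are simply
    absent from the result.
    """
    matches: list[PeakMatch] = []
    mzs = spectrum.mzs
    if len(mzs) == 0:
        return matches
    for k, (mz_t, r_k) in enumerate(zip(pattern.mzs, pattern.rel_intensities)):
        tol = mz_t * params.alpha_ppm * 1e-6 * 2  # coarse window; exact test below
        lo = np.searchsorted(mzs, mz_t - tol - abs(params.machine_offset_ppm) * mz_t * 1e-6)
        hi = np.searchsorted(mzs, mz_t + tol + abs(params.machine_offset_ppm) * mz_t * 1e-6)
        best: tuple[float, float, float] | None = None  # (|ppm|, -intensity, mz)
        for i in range(lo, hi):
            raw_ppm = (mzs[i] - mz_t) / mz_t * 1e6
            delta = abs(raw_ppm - params.machine_offset_ppm)
            # closed interval; 1e-9 ppm slack keeps the boundary robust to
            # floating-point rounding of the ppm computation itself
            if delta - params.alpha_ppm > 1e-9:
                continue
            cand = (delta, -spectrum.intensities[i], mzs[i])
            if best is None or cand < best:
                best = cand
                best_i = i
        if best is not None:
            matches.append(PeakMatch(
                peak_index=k, mz_theoretical=mz_t, rel_intensity=r_k,
                mz_measured=float(mzs[best_i]),
                intensity_measured=float(spectrum.intensities[best_i]),
                ppm_error=best[0],
            ))
    return matches


def score_mz(peaks: Sequence[PeakMatch], params: ScoringParams) -> float | None:
    """r_k-weighted mean of the per-peak m/z similarities.

    Per peak, s^mz = 1 − δ^mz/α clamped to [0, 1].  Returns ``None`` (the
    no-match sentinel) for an empty peak list.
    """
    if not peaks:
        return None
    num = den = 0.0
    for p in peaks:
        s = max(0.0, min(1.0, 1.0 - p.ppm_error / params.alpha_ppm))
        num += s * p.rel_intensity
        den += p.rel_intensity
    return num / den


def compute_sigma(peaks: Sequence[PeakMatch]) -> float:
    """Scaling factor σ: weighted measured over weighted theoretical intensity.

    σ equals the abundance of the measured molecule on the scale where the
    pattern's most intense peak has theoretical intensity 1.
    """
    num = sum(p.intensity_measured * p.rel_intensity for p in peaks)
    den = sum(p.theoretical * p.rel_intensity for p in peaks)
    if den == 0.0:
        raise ValueError("cannot compute sigma: zero weighted theoretical intensity")
    return num / den


def score_intensity(peaks: Sequence[PeakMatch], sigma: float,
                    params: ScoringParams) -> float | None:
    """r_k-weighted mean of the per-peak intensity similarities.

    δ^int_k = |I_ik − σ·I_jk| / (α_int·σ·I_jk): the relative error of the
    measured intensity against the σ-scaled theoretical one.  Normalizing
    by σ·I_jk (not I_jk alone) keeps the score invariant under rescaling
    the spectrum's intensity axis — the same match must score identically
    whatever the detector's count scale.  s^int_k = 1 − δ^int_k/(1 − r_k + ε),
    clamped to [0, 1].
    """
    if not peaks:
        return None
    num = den = 0.0
    for p in peaks:
        if p.theoretical == 0.0 or sigma == 0.0:
            continue  # theoretical intensity 0 carries no information
        delta = abs(p.intensity_measured - sigma * p.theoretical) / (
            params.alpha_intensity * sigma * p.theoretical)
        s = max(0.0, min(1.0, 1.0 - delta / (1.0 - p.rel_intensity + params.epsilon)))
        num += s * p.rel_intensity
        den += p.rel_intensity
    if den == 0.0:
        return None
    return num / den


def combine(score_mz_total: float, score_intensity_total: float,
            params: ScoringParams) -> float:
    """mScore = ξ·S^mz + (1 − ξ)·S^intensity."""
    return params.xi * score_mz_total + (1.0 - params.xi) * score_intensity_total


def match_pattern(
    pattern: IsotopePattern,
    spectrum: CentroidedSpectrum,
    params: ScoringParams | None = None,
) -> PatternMatch | None:
    """Full matching pipeline for one (pattern, spectrum) pair.

    Returns ``None`` when the matched fraction of required pattern peaks
    (those with r_k above the matching threshold — i.e. all retained peaks)
    falls below ``params.min_matched_fraction``; with the default 1.0 a
    single missing isotope peak rejects the match.
    """
    params = params or ScoringParams()
    required = sum(1 for r in pattern.rel_intensities if r >= params.matching_threshold)
    peaks = find_peak_candidates(pattern, spectrum, params)
    matched_required = sum(
        1 for p in peaks if p.rel_intensity >= params.matching_threshold)
    if required == 0 or matched_required < params.min_matched_fraction * required:
        return None
    sigma = compute_sigma(peaks)
    s_mz = score_mz(peaks, params)
    s_int = score_intensity(peaks, sigma, params)
    if s_mz is None or s_int is None:
        return None
    return PatternMatch(
        pattern_key=pattern.key,
        spectrum_id=spectrum.spectrum_id,
        retention_time=spectrum.retention_time,
        sigma=sigma,
        score_mz=s_mz,
        score_intensity=s_int,
        mscore=combine(s_mz, s_int, params),
        peaks=tuple(peaks),
    )
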