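"""Quantifiability screening of library peptides from MRM chromatograms.

A peptide enters the quantifiable library when (1) the best-transition
signal-to-noise ratio exceeds the SNR threshold (default 3; SNR > 10
marks high confidence), (2) the retention times of the synthetic
standard, the endogenous peptide and the standard spiked into the sample
agree within tolerance, and (3) the relative abundances of the top three
product ions match between standard and sample (cosine similarity).

SNR is defined as apex height above a robust baseline divided by the
robust (MAD-based) baseline noise SD; the reference data system reported
peaks without defining SNR numerically, so the definition here is the
package's own and is fully config-exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .synthetic import Chromatogram


@dataclass(frozen=True)
class ScreeningConfig:
    snr_threshold: float = 3.0
    snr_high: float = 10.0
    rt_tolerance_min: float = 0.2
    ratio_threshold: float = 0.95
    baseline_exclusion_halfwidth: float = 0.5  # minutes around the apex
    smooth_window: int = 5  # moving-average points before apex picking

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise InputError("snr_threshold must be > 0")
        if self.rt_tolerance_min <= 0:
            raise InputError("rt_tolerance_min must be > 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise InputError("smooth_window must be a positive odd integer")


@dataclass
class PeakCall:
    """A detected chromatographic peak for one transition."""

    transition_id: str
    rt_min: float
    height: float
    area: float
    noise_sd: float
    snr: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class QuantifiabilityCall:
    """Per-peptide screening outcome with machine-readable failure reasons."""

    peptide_id: str
    snr: float
    rt_delta_min: float
    ratio_similarity: float
    quantifiable: bool
    high_confidence: bool
    reasons: list[str] = field(default_factory=list)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def detect_peak(
    trace: np.ndarray,
    time_min: np.ndarray,
    cfg: ScreeningConfig = ScreeningConfig(),
    transition_id: str = "t1",
) -> PeakCall:
    """Detect the dominant peak in one transition trace.

    Apex = maximum of the moving-average-smoothed trace. Baseline and
    noise are estimated from samples further than the exclusion
    halfwidth from the apex (median, and 1.4826*MAD). Area is the
    trapezoidal integral of the baseline-subtracted raw trace over
    apex +/- 3 sigma (sigma from the full width at half maximum),
    floored at 0. A flat trace yields noise_sd 0 and an infinite SNR
    sentinel with a warning, never a crash.
    """
    trace = np.asarray(trace, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    if trace.size < 10:
        raise InputError("trace must contain at least 10 samples")
    if trace.size != time_min.size:
        raise InputError("trace and time axis lengths differ")
    if not np.isfinite(trace).all():
        raise InputError("trace contains non-finite intensities")

    warnings: list[str] = []
    smoothed = _moving_average(trace, cfg.smooth_window)
    apex = int(np.argmax(smoothed))
    rt = float(time_min[apex])

    outside = np.abs(time_min - rt) > cfg.baseline_exclusion_halfwidth
    if outside.sum() < 10:
        outside = np.ones_like(outside, dtype=bool)
        warnings.append("baseline_window_fallback")
    baseline = float(np.median(trace[outside]))
    mad = float(np.median(np.abs(trace[outside] - baseline)))
    noise_sd = 1.4826 * mad
    height = float(smoothed[apex] - baseline)

    if noise_sd == 0:
        snr = math.inf if height > 0 else 0.0
        warnings.append("zero_noise")
    else:
        snr = height / noise_sd

    # peak width from half-maximum crossings of the smoothed trace
    half = baseline + height / 2.0
    above = smoothed >= half
    left = apex
    while left > 0 and above[left - 1]:
        left -= 1
    right = apex
    while right < trace.size - 1 and above[right + 1]:
        right += 1
    fwhm = max(float(time_min[right] - time_min[left]), 1e-9)
    sigma_fit = fwhm / 2.3548200450309493
    window = np.abs(time_min - rt) <= 3 * sigma_fit
    area = float(
        np.trapezoid(np.clip(trace[window] - baseline, 0, None), time_min[window])
    )
    return PeakCall(
        transition_id=transition_id, rt_min=rt, height=max(height, 0.0),
        area=max(area, 0.0), noise_sd=noise_sd, snr=max(snr, 0.0),
        warnings=warnings,
    )


def detect_peaks(
    chrom: Chromatogram, cfg: ScreeningConfig = ScreeningConfig()
) -> list[PeakCall]:
    """Run peak detection on every transition of one chromatogram."""
    return [
        detect_peak(chrom.intensities[i], chrom.time_min, cfg, tid)
        for i, tid in enumerate(chrom.transitions)
    ]


def match_retention_time(
    standard: PeakCall | None,
    endogenous: PeakCall | None,
    spiked: PeakCall | None,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> tuple[float, bool, str | None]:
    """Compare the RTs of standard, endogenous and spiked-in peaks.

    Passes when the maximum pairwise RT difference is within tolerance
    (inclusive at the boundary). A missing peak fails with a reason code.
    """
    peaks = {"standard": standard, "endogenous": endogenous, "spiked": spiked}
    missing = [name for name, p in peaks.items() if p is None]
    if missing:
        return math.nan, False, f"missing_peak:{','.join(missing)}"
    rts = [p.rt_min for p in peaks.values()]
    delta = max(rts) - min(rts)
    # inclusive boundary, robust to float roundoff in the subtraction
    return delta, delta <= cfg.rt_tolerance_min * (1 + 1e-9), None


def compare_transition_ratios(
    standard_areas, sample_areas
) -> float:
    """Cosine similarity of the top-3 relative product-ion abundances."""
    a = np.asarray(standard_areas, dtype=float)
    b = np.asarray(sample_areas, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise InputError("expected exactly three areas per side")
    if (a < 0).any() or (b < 0).any():
        raise InputError("areas must be nonnegative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def call_quantifiable(
    peptide_id: str,
    sample_peaks: list[PeakCall],
    standard_peaks: list[PeakCall],
    spiked_peaks: list[PeakCall] | None = None,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> QuantifiabilityCall:
    """Combine SNR, RT agreement and ratio similarity into one call.

    The peptide's SNR is that of its best sample transition; the top-3
    area vectors define the ratio comparison. The spiked condition
    defaults to the standard when not measured separately.
    """
    if len(sample_peaks) != 3 or len(standard_peaks) != 3:
        raise InputError("expected three transitions per condition")
    reasons: list[str] = []
    best_sample = max(sample_peaks, key=lambda p: p.snr)
    best_standard = max(standard_peaks, key=lambda p: p.snr)
    snr = best_sample.snr
    if not snr > cfg.snr_threshold:
        reasons.append("low_snr")

    spiked_best = (
        max(spiked_peaks, key=lambda p: p.snr) if spiked_peaks else best_standard
    )
    rt_delta, rt_ok, rt_reason = match_retention_time(
        best_standard, best_sample, spiked_best, cfg
    )
    if not rt_ok:
        reasons.append(rt_reason or "rt_mismatch")

    similarity = compare_transition_ratios(
        [p.area for p in standard_peaks], [p.area for p in sample_peaks]
    )
    if similarity < cfg.ratio_threshold:
        reasons.append("ratio_mismatch")

    return QuantifiabilityCall(
        peptide_id=peptide_id,
        snr=snr,
        rt_delta_min=rt_delta,
        ratio_similarity=similarity,
        quantifiable=not reasons,
        high_confidence=snr > cfg.snr_high,
        reasons=reasons,
    )


def screen_peptide(
    peptide_id: str,
    sample_chrom: Chromatogram,
    standard_chrom: Chromatogram,
    spiked_chrom: Chromatogram | None = None,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> QuantifiabilityCall:
    """Full screening of one peptide from its three chromatogram conditions."""
    sample_peaks = detect_peaks(sample_chrom, cfg)
    standard_peaks = detect_peaks(standard_chrom, cfg)
    spiked_peaks = detect_peaks(spiked_chrom, cfg) if spiked_chrom else None
    return call_quantifiable(
        peptide_id, sample_peaks, standard_peaks, spiked_peaks, cfg
    )
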