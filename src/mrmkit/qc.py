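"""Analytical performance evaluation of candidate marker assays.

Linearity (six-point calibration, R^2 and back-calculated accuracy with
the >= 5-of-6 within +/-20% rule), intra/inter-day precision over
five-replicate series, seven-day storage stability, internal-standard
ratio quantification, and the AND-gate that admits a marker only when
every component test passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class QcConfig:
    accuracy_tolerance_pct: float = 20.0  # back-calc accuracy, % of nominal
    max_accuracy_failures: int = 1        # "at least 5 of 6 points"
    cv_threshold_pct: float = 20.0        # intra/inter-day precision gate
    stability_tolerance_pct: float = 20.0  # recovery within 100 +/- tol
    weighted_1_over_x: bool = False


@dataclass
class CalibrationResult:
    peptide_id: str
    slope: float
    intercept: float
    r_squared: float
    per_point_accuracy: np.ndarray  # % of nominal, one per point
    accuracy_pass: bool
    n_points: int


@dataclass
class PrecisionResult:
    peptide_id: str
    level: float
    intra_day_cv: float  # %, worst day
    inter_day_cv: float  # %, CV of daily means
    n_replicates: int
    passed: bool


@dataclass
class StabilityResult:
    peptide_id: str
    condition: str  # deep_freeze | fridge_4C
    day0_value: float
    day7_value: float
    recovery_pct: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def fit_linearity(
    points, peptide_id: str = "pep", cfg: QcConfig = QcConfig()
) -> CalibrationResult:
    """Least-squares calibration line with back-calculated accuracy.

    ``points`` is an iterable of (nominal_conc, response) pairs or a
    DataFrame with columns nominal_conc / measured_response. Accuracy
    per point = back-calculated concentration / nominal * 100; the
    calibration passes when at most ``max_accuracy_failures`` points
    fall outside 100 +/- tolerance.
    """
    if hasattr(points, "columns"):
        conc = np.asarray(points["nominal_conc"], dtype=float)
        resp = np.asarray(points["measured_response"], dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        conc, resp = arr[:, 0], arr[:, 1]
    if conc.size < 6:
        raise InputError("calibration requires at least 6 points")
    if np.unique(conc).size < 2:
        raise InputError("concentrations have zero variance")
    if cfg.weighted_1_over_x:
        w = 1.0 / conc
        W = np.diag(w)
        X = np.column_stack([conc, np.ones_like(conc)])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ resp)
        slope, intercept = float(beta[0]), float(beta[1])
        fitted = slope * conc + intercept
        ss_res = float(np.sum(w * (resp - fitted) ** 2))
        ss_tot = float(np.sum(w * (resp - np.average(resp, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(conc, resp)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    if slope == 0:
        raise InputError("degenerate calibration: zero slope")
    back_calc = (resp - intercept) / slope
    accuracy = back_calc / conc * 100.0
    n_fail = int(np.sum(np.abs(accuracy - 100.0) > cfg.accuracy_tolerance_pct))
    return CalibrationResult(
        peptide_id=peptide_id, slope=slope, intercept=intercept, r_squared=r2,
        per_point_accuracy=accuracy,
        accuracy_pass=n_fail <= cfg.max_accuracy_failures,
        n_points=int(conc.size),
    )


def assess_precision(
    replicates_per_day: dict,
    level: float = float("nan"),
    peptide_id: str = "pep",
    cfg: QcConfig = QcConfig(),
) -> PrecisionResult:
    """Intra-day (worst day) and inter-day CV from replicate series.

    ``replicates_per_day`` maps day -> array of replicate measurements
    (five per day in the standard design). Inter-day CV is the CV of
    the daily means; both must stay at or below the CV threshold.
    """
    if not replicates_per_day:
        raise InputError("no replicate data supplied")
    intra = []
    day_means = []
    n_rep = None
    for day, vals in sorted(replicates_per_day.items()):
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise InputError(f"day {day}: need >= 2 replicates")
        n_rep = v.size if n_rep is None else min(n_rep, v.size)
        m = float(v.mean())
        if m <= 0:
            return PrecisionResult(
                peptide_id, level, float("inf"), float("inf"), v.size, False
            )
        intra.append(float(v.std(ddof=1)) / m * 100.0)
        day_means.append(m)
    intra_cv = max(intra)
    if len(day_means) >= 2:
        dm = np.asarray(day_means)
        inter_cv = float(dm.std(ddof=1) / dm.mean() * 100.0)
    else:
        inter_cv = 0.0
    passed = intra_cv <= cfg.cv_threshold_pct and inter_cv <= cfg.cv_threshold_pct
    return PrecisionResult(
        peptide_id=peptide_id, level=level, intra_day_cv=intra_cv,
        inter_day_cv=inter_cv, n_replicates=int(n_rep or 0), passed=passed,
    )


def assess_stability(
    day0: float,
    day7: float,
    condition: str = "deep_freeze",
    peptide_id: str = "pep",
    cfg: QcConfig = QcConfig(),
) -> StabilityResult:
    """Seven-day storage recovery; passes within 100 +/- tolerance %."""
    if condition not in ("deep_freeze", "fridge_4C"):
        raise InputError(f"unknown storage condition {condition!r}")
    if day0 <= 0:
        return StabilityResult(
            peptide_id, condition, day0, day7, float("nan"), False,
            reasons=["nonpositive_day0"],
        )
    recovery = day7 / day0 * 100.0
    passed = abs(recovery - 100.0) <= cfg.stability_tolerance_pct
    reasons = [] if passed else ["recovery_out_of_range"]
    return StabilityResult(
        peptide_id, condition, day0, day7, recovery, passed, reasons
    )


def quantify_with_is(
    analyte_area: float, is_area: float, is_amount: float
) -> float:
    """Concentration from the analyte/internal-standard area ratio.

    concentration = (analyte_area / is_area) * is_amount, in the units
    of ``is_amount`` (the known spiked quantity of the heavy-labeled
    internal standard).
    """
    if is_area <= 0:
        raise InputError("internal standard area must be > 0")
    if analyte_area < 0:
        raise InputError("analyte area must be >= 0")
    return analyte_area / is_area * is_amount


@dataclass
class QcGateEntry:
    peptide_id: str
    validated: bool
    failed_tests: list[str] = field(default_factory=list)


def qc_gate(
    candidate_ids,
    calibration: dict[str, CalibrationResult],
    precision: dict[str, PrecisionResult],
    stability: dict[str, list[StabilityResult]],
) -> list[QcGateEntry]:
    """AND-gate over all analytical tests per candidate marker.

    A marker is validated only when its calibration accuracy, precision
    and every stability condition pass; missing component results reject
    the marker with reason ``incomplete_qc``.
    """
    out = []
    for pid in candidate_ids:
        failed: list[str] = []
        cal = calibration.get(pid)
        prec = precision.get(pid)
        stab = stability.get(pid)
        if cal is None or prec is None or not stab:
            failed.append("incomplete_qc")
        else:
            if not cal.accuracy_pass:
                failed.append("linearity_accuracy")
            if not prec.passed:
                failed.append("precision")
            if not all(s.passed for s in stab):
                failed.append("stability")
        out.append(QcGateEntry(peptide_id=pid, validated=not failed,
                               failed_tests=failed))
    return out
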