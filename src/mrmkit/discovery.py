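"""Two-stage biomarker discovery and validation cascade.

Stage 1 (discovery cohort): peptides passing a two-sided fold-change
filter (case/control mean ratio >= fc_threshold or <= 1/fc_threshold,
inclusive) AND a two-sided Wilcoxon rank-sum test at raw p < alpha.
Stage 2 (validation cohort): stage-1 survivors must reproduce the
fold-change criterion in the same direction. No multiple-testing
correction is applied by default (a Benjamini-Hochberg option exists),
matching common practice for small targeted panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .synthetic import QuantMatrix


@dataclass(frozen=True)
class DiscoveryConfig:
    fc_threshold: float = 1.2
    alpha: float = 0.05
    center: str = "mean"  # or "median"
    use_bh_correction: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise InputError("fc_threshold must be >= 1")
        if not (0 < self.alpha < 1):
            raise InputError("alpha must be in (0, 1)")
        if self.center not in ("mean", "median"):
            raise InputError("center must be 'mean' or 'median'")


@dataclass
class MarkerResult:
    peptide_id: str
    fold_change: float
    log2_fc: float
    p_value: float
    passed_discovery: bool
    passed_validation: bool
    validation_fc: float = float("nan")
    reasons: list[str] = field(default_factory=list)


def aggregate_replicates(matrix: QuantMatrix) -> QuantMatrix:
    """Collapse technical replicates to their per-peptide mean.

    Output has one row per biological sample (the ``replicate_of``
    parent). Missing replicate values are ignored (the surviving value
    is used); a replicate referencing an unknown parent is an error.
    """
    meta = matrix.sample_meta
    if "replicate_of" not in meta.columns:
        raise InputError("sample_meta lacks a replicate_of column")
    parents = meta["replicate_of"]
    if parents.isna().any():
        raise InputError("replicate_of contains missing parent references")
    values = matrix.values.groupby(parents).mean()
    new_meta = (
        meta.groupby(parents)
        .agg(group=("group", "first"), batch=("batch", "first"))
        .assign(replicate_of=lambda d: d.index)
    )
    values.index.name = "sample_id"
    new_meta.index.name = "sample_id"
    return QuantMatrix(values=values, sample_meta=new_meta.loc[values.index])


def fold_change(
    case_values, control_values, center: str = "mean"
) -> tuple[float, float]:
    """Case/control abundance ratio on the linear scale, plus log2."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case, control = case[~np.isnan(case)], control[~np.isnan(control)]
    if case.size < 3 or control.size < 3:
        raise InputError("need at least 3 values per group")
    agg = np.mean if center == "mean" else np.median
    denom = float(agg(control))
    if denom <= 0:
        raise InputError("control center must be positive")
    fc = float(agg(case)) / denom
    return fc, float(np.log2(fc)) if fc > 0 else float("-inf")


def rank_sum_test(case_values, control_values) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when both groups have <= 8 observations and
    no ties; otherwise the normal approximation with tie and continuity
    corrections. Identical constant groups return p = 1.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 3 or control.size < 3:
        raise InputError("need at least 3 values per group")
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if case.size <= 8 and control.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        case, control, alternative="two-sided", method=method,
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def passes_fold_change(fc: float, threshold: float) -> bool:
    """Two-sided, inclusive fold-change rule: fc >= t or fc <= 1/t."""
    return fc >= threshold or fc <= 1.0 / threshold


def run_cascade(
    discovery_matrix: QuantMatrix,
    validation_matrix: QuantMatrix,
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> list[MarkerResult]:
    """Run the discovery -> validation filter cascade over all peptides.

    Matrices must already be aggregated to biological samples (use
    :func:`aggregate_replicates` first if they carry technical
    replicates). Validation requires the fold change to clear the
    threshold in the same direction as discovery; a peptide absent from
    the validation matrix fails with reason ``not_measured``.
    """
    results: list[MarkerResult] = []
    disc_groups = discovery_matrix.sample_meta["group"]
    case_rows = disc_groups == "case"
    control_rows = disc_groups == "control"
    val_groups = validation_matrix.sample_meta["group"]

    p_values: dict[str, float] = {}
    fcs: dict[str, tuple[float, float]] = {}
    for pid in discovery_matrix.peptide_ids:
        col = discovery_matrix.values[pid]
        try:
            fcs[pid] = fold_change(
                col[case_rows], col[control_rows], cfg.center
            )
            p_values[pid] = rank_sum_test(col[case_rows], col[control_rows])
        except InputError:
            fcs[pid] = (float("nan"), float("nan"))
            p_values[pid] = float("nan")

    if cfg.use_bh_correction:
        pids = [p for p in p_values if np.isfinite(p_values[p])]
        raw = np.array([p_values[p] for p in pids])
        adj = stats.false_discovery_control(raw, method="bh")
        for pid, q in zip(pids, adj):
            p_values[pid] = float(q)

    for pid in discovery_matrix.peptide_ids:
        fc, log2fc = fcs[pid]
        p = p_values[pid]
        reasons: list[str] = []
        if not np.isfinite(fc):
            reasons.append("discovery_not_evaluable")
            passed_disc = False
        else:
            fc_ok = passes_fold_change(fc, cfg.fc_threshold)
            p_ok = np.isfinite(p) and p < cfg.alpha
            if not fc_ok:
                reasons.append("fc_below_threshold")
            if not p_ok:
                reasons.append("p_above_alpha")
            passed_disc = fc_ok and p_ok

        passed_val = False
        val_fc = float("nan")
        if passed_disc:
            if pid not in validation_matrix.values.columns:
                reasons.append("not_measured")
            else:
                col = validation_matrix.values[pid]
                try:
                    val_fc, _ = fold_change(
                        col[val_groups == "case"],
                        col[val_groups == "control"],
                        cfg.center,
                    )
                except InputError:
                    reasons.append("validation_not_evaluable")
                else:
                    same_direction = (fc >= 1) == (val_fc >= 1)
                    if passes_fold_change(val_fc, cfg.fc_threshold) and same_direction:
                        passed_val = True
                    else:
                        reasons.append("validation_fc_failed")
        results.append(
            MarkerResult(
                peptide_id=pid, fold_change=fc, log2_fc=log2fc, p_value=p,
                passed_discovery=passed_disc, passed_validation=passed_val,
                validation_fc=val_fc, reasons=reasons,
            )
        )
    return results


def zscore_heatmap_table(
    matrix: QuantMatrix, markers: list[MarkerResult]
) -> pd.DataFrame:
    """Plot-ready long table of per-sample z-scores for selected markers.

    z = (value - peptide mean) / peptide SD across all samples; a
    zero-SD peptide gets z = 0 everywhere. Columns: sample_id, group,
    peptide_id, zscore, fold_change.
    """
    if not markers:
        raise InputError("markers must be non-empty")
    rows = []
    for m in markers:
        col = matrix.values[m.peptide_id].astype(float)
        sd = float(col.std(ddof=1))
        mean = float(col.mean())
        z = (col - mean) / sd if sd > 0 else col * 0.0
        for sid, zi in z.items():
            rows.append(
                {
                    "sample_id": sid,
                    "group": matrix.sample_meta.loc[sid, "group"],
                    "peptide_id": m.peptide_id,
                    "zscore": float(zi),
                    "fold_change": m.fold_change,
                }
            )
    return pd.DataFrame(rows)
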