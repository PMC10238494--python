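"""End-to-end pipeline: library -> screening -> discovery -> QC -> model.

Chains every stage on synthetic inputs with a single global seed, writes
each stage's outputs (FASTA proteome, transition list CSV, screening
calls, marker table, QC report, hold-out metrics table) into one
directory, logs the candidate funnel (counts in -> out per stage), and
is byte-deterministic per (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .candidates import build_library, compute_mz
from .classify import evaluate_panel
from .discovery import aggregate_replicates, run_cascade, zscore_heatmap_table
from .qc import assess_precision, assess_stability, fit_linearity, qc_gate
from .screening import screen_peptide
from .synthetic import (
    ChromatogramSimSpec,
    CohortSimSpec,
    SyntheticProteomeSpec,
    generate_calibration_series,
    generate_cohort,
    generate_precision_series,
    generate_proteome,
    simulate_chromatogram,
)

logger = logging.getLogger("mrmkit")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _log_funnel(stage: str, n_in: int, n_out: int, seed: int) -> None:
    logger.info("stage=%s in=%d out=%d seed=%d", stage, n_in, n_out, seed)


def run_pipeline(cfg: mio.PipelineConfig, out_dir) -> dict:
    """Run every stage and write its outputs under ``out_dir``.

    Returns a summary dict with the funnel counts and key tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = _child_seeds(cfg.seed, 8)
    try:
        mio.dump_config(cfg, out / "config.resolved.yaml")

        # 1. synthetic proteome
        proteome = generate_proteome(
            SyntheticProteomeSpec(n_proteins=cfg.n_proteins, seed=seeds[0])
        )
        mio.write_fasta(proteome, out / "proteome.fasta")
        _log_funnel("proteome", cfg.n_proteins, len(proteome), seeds[0])

        # 2. surrogate-peptide library + transitions
        sel_cfg = dataclasses.replace(cfg.selection, seed=seeds[1])
        selected, empty = build_library(proteome, sel_cfg)
        transitions = []
        for pep in selected:
            for state in ("light", "heavy"):
                try:
                    transitions.append(
                        (pep.protein_id, compute_mz(pep.sequence, 2, state))
                    )
                except Exception:  # peptide not labelable (no C-term K/R)
                    continue
        mio.write_transition_list(transitions, out / "transitions.csv")
        _log_funnel("library", len(proteome), len(selected), seeds[1])
        if empty:
            logger.info("proteins_without_candidates=%d", len(empty))

        # 3. quantifiability screening on simulated chromatograms
        rng = np.random.default_rng(seeds[2])
        calls = []
        snr_levels = np.array([0.5, 2.0, 5.0, 20.0, 100.0])
        for i, pep in enumerate(selected):
            true_snr = float(rng.choice(snr_levels))
            noise_sd = 10.0
            height = true_snr * noise_sd / 0.5  # best transition carries 0.5
            rt = float(rng.uniform(1.0, 9.0))
            base = dict(peak_rt=rt, noise_sd=noise_sd)
            sample = simulate_chromatogram(
                ChromatogramSimSpec(
                    peak_height=height, seed=int(rng.integers(2**31)), **base
                ),
                pep.sequence,
            )
            standard = simulate_chromatogram(
                ChromatogramSimSpec(
                    peak_height=100 * noise_sd,
                    seed=int(rng.integers(2**31)), **base,
                ),
                pep.sequence,
            )
            spiked = simulate_chromatogram(
                ChromatogramSimSpec(
                    peak_height=height + 50 * noise_sd,
                    seed=int(rng.integers(2**31)), **base,
                ),
                pep.sequence,
            )
            call = screen_peptide(
                pep.sequence, sample, standard, spiked, cfg.screening
            )
            calls.append(
                {
                    "peptide": pep.sequence,
                    "protein_id": pep.protein_id,
                    "true_snr": true_snr,
                    "snr": call.snr,
                    "rt_delta_min": call.rt_delta_min,
                    "ratio_similarity": call.ratio_similarity,
                    "quantifiable": call.quantifiable,
                    "high_confidence": call.high_confidence,
                    "reasons": ";".join(call.reasons),
                }
            )
        calls_df = pd.DataFrame(calls)
        calls_df.to_csv(out / "screening_calls.csv", index=False,
                        float_format="%.6g")
        quantifiable = calls_df[calls_df["quantifiable"]]
        _log_funnel("screening", len(selected), len(quantifiable), seeds[2])

        # 4. two-stage biomarker discovery on synthetic cohorts
        n_pep = min(cfg.n_cohort_peptides, max(len(quantifiable), 10))
        disc_matrix, truth = generate_cohort(
            CohortSimSpec(
                n_cases=cfg.cohorts.discovery_cases,
                n_controls=cfg.cohorts.discovery_controls,
                n_peptides=n_pep,
                n_differential=min(cfg.n_differential, n_pep),
                planted_fc=cfg.planted_fc,
                cv_biological=cfg.cv_biological,
                cv_technical=cfg.cv_technical,
                seed=seeds[3],
            )
        )
        planted = tuple(sorted(truth.differential_peptide_ids))
        val_matrix, _ = generate_cohort(
            CohortSimSpec(
                n_cases=cfg.cohorts.validation_cases,
                n_controls=cfg.cohorts.validation_controls,
                n_peptides=n_pep,
                n_differential=len(planted),
                planted_fc=cfg.planted_fc,
                cv_biological=cfg.cv_biological,
                cv_technical=cfg.cv_technical,
                differential_ids=planted,
                seed=seeds[4],
            )
        )
        disc_agg = aggregate_replicates(disc_matrix)
        val_agg = aggregate_replicates(val_matrix)
        mio.write_quant_matrix(
            disc_matrix, out / "discovery_matrix.tsv", out / "discovery_meta.tsv"
        )
        markers = run_cascade(disc_agg, val_agg, cfg.discovery)
        marker_df = pd.DataFrame(
            [
                {
                    "peptide_id": m.peptide_id,
                    "fold_change": m.fold_change,
                    "log2_fc": m.log2_fc,
                    "p_value": m.p_value,
                    "validation_fc": m.validation_fc,
                    "passed_discovery": m.passed_discovery,
                    "passed_validation": m.passed_validation,
                    "is_planted": m.peptide_id in truth.differential_peptide_ids,
                }
                for m in markers
            ]
        )
        marker_df.to_csv(out / "markers.csv", index=False, float_format="%.6g")
        survivors = [m for m in markers if m.passed_validation]
        _log_funnel(
            "discovery", n_pep, sum(m.passed_discovery for m in markers), seeds[3]
        )
        _log_funnel(
            "validation",
            sum(m.passed_discovery for m in markers),
            len(survivors),
            seeds[4],
        )
        if survivors:
            zscore_heatmap_table(disc_agg, survivors).to_csv(
                out / "heatmap_table.csv", index=False, float_format="%.6g"
            )

        # 5. analytical QC on the surviving markers
        qc_rng = np.random.default_rng(seeds[5])
        calibration, precision, stability = {}, {}, {}
        for m in survivors:
            pid = m.peptide_id
            cal = generate_calibration_series(
                6, slope=2.0, intercept=5.0, error_cv=0.05,
                seed=int(qc_rng.integers(2**31)),
            )
            calibration[pid] = fit_linearity(cal, pid, cfg.qc)
            series = generate_precision_series(
                true_value=100.0, n_days=3, cv_within_day=0.05,
                cv_between_day=0.05, seed=int(qc_rng.integers(2**31)),
            )
            precision[pid] = assess_precision(series, 100.0, pid, cfg.qc)
            recov = {
                "deep_freeze": float(qc_rng.normal(1.0, 0.05)),
                "fridge_4C": float(qc_rng.normal(0.95, 0.05)),
            }
            stability[pid] = [
                assess_stability(100.0, 100.0 * r, cond, pid, cfg.qc)
                for cond, r in recov.items()
            ]
        gate = qc_gate([m.peptide_id for m in survivors],
                       calibration, precision, stability)
        qc_df = pd.DataFrame(
            [
                {
                    "peptide_id": g.peptide_id,
                    "validated": g.validated,
                    "failed_tests": ";".join(g.failed_tests),
                    "r_squared": calibration[g.peptide_id].r_squared,
                    "intra_day_cv": precision[g.peptide_id].intra_day_cv,
                    "inter_day_cv": precision[g.peptide_id].inter_day_cv,
                }
                for g in gate
            ]
        )
        qc_df.to_csv(out / "qc_report.csv", index=False, float_format="%.6g")
        validated = [g.peptide_id for g in gate if g.validated]
        _log_funnel("qc", len(survivors), len(validated), seeds[5])

        # 6. hold-out classifier evaluation on a fresh cohort
        metrics = pd.DataFrame()
        if validated:
            eval_matrix, _ = generate_cohort(
                CohortSimSpec(
                    n_cases=100, n_controls=100, n_peptides=n_pep,
                    n_differential=len(planted),
                    planted_fc=cfg.planted_fc,
                    cv_biological=cfg.cv_biological,
                    cv_technical=cfg.cv_technical,
                    differential_ids=planted, seed=seeds[6],
                )
            )
            panel = [p for p in validated if p in eval_matrix.values.columns]
            if panel:
                _, metrics = evaluate_panel(eval_matrix, panel, cfg.evaluation)
                metrics.to_csv(out / "holdout_metrics.csv", index=False,
                               float_format="%.6g")
                _log_funnel("evaluation", len(panel), len(metrics) - 1, seeds[6])

        return {
            "n_proteins": len(proteome),
            "n_selected": len(selected),
            "n_quantifiable": int(len(quantifiable)),
            "n_discovery": int(sum(m.passed_discovery for m in markers)),
            "n_validated_markers": len(survivors),
            "n_qc_validated": len(validated),
            "markers": marker_df,
            "metrics": metrics,
            "ground_truth": truth,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
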