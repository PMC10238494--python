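"""Replicate aggregation, fold change, rank-sum test, and the filter cascade."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmkit.discovery import (
    DiscoveryConfig,
    aggregate_replicates,
    fold_change,
    passes_fold_change,
    rank_sum_test,
    run_cascade,
    zscore_heatmap_table,
)
from mrmkit.errors import InputError
from mrmkit.synthetic import CohortSimSpec, QuantMatrix, generate_cohort


def exact_ranksum_oracle(a, b) -> float:
    """Exhaustive-enumeration two-sided rank-sum p-value (no ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    u_obs = sum((x > y) for x in a for y in b)
    us = []
    for comb in combinations(range(pooled.size), n1):
        ga = pooled[list(comb)]
        gb = np.delete(pooled, list(comb))
        us.append(sum((x > y) for x in ga for y in gb))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def _matrix(values: dict, groups: list, replicate_of=None) -> QuantMatrix:
    df = pd.DataFrame(values)
    df.index = [f"s{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {
            "group": groups,
            "replicate_of": replicate_of or list(df.index),
            "batch": 1,
        },
        index=df.index,
    )
    return QuantMatrix(values=df, sample_meta=meta)


class TestAggregate:
    def test_replicate_mean(self):
        m = _matrix(
            {"p1": [100.0, 120.0, 50.0, 70.0]},
            ["case", "case", "control", "control"],
            replicate_of=["b1", "b1", "b2", "b2"],
        )
        agg = aggregate_replicates(m)
        assert agg.values.loc["b1", "p1"] == 110.0
        assert agg.values.loc["b2", "p1"] == 60.0
        assert list(agg.sample_meta["group"]) == ["case", "control"]

    def test_no_replicates_is_identity(self):
        m = _matrix({"p1": [1.0, 2.0]}, ["case", "control"])
        agg = aggregate_replicates(m)
        assert np.allclose(agg.values.to_numpy(), m.values.to_numpy())

    def test_missing_value_uses_survivor(self):
        m = _matrix(
            {"p1": [100.0, np.nan]}, ["case", "case"], replicate_of=["b1", "b1"]
        )
        agg = aggregate_replicates(m)
        assert agg.values.loc["b1", "p1"] == 100.0


class TestFoldChange:
    def test_known_ratio(self):
        fc, log2fc = fold_change([12, 12, 12], [10, 10, 10])
        assert fc == pytest.approx(1.2)
        assert log2fc == pytest.approx(np.log2(1.2))
        assert passes_fold_change(fc, 1.2)  # inclusive at threshold

    def test_two_sided_symmetry(self):
        fc_up, _ = fold_change([12, 12, 12], [10, 10, 10])
        fc_dn, _ = fold_change([10, 10, 10], [12, 12, 12])
        assert fc_dn == pytest.approx(1 / fc_up)
        assert passes_fold_change(fc_dn, 1.2)

    def test_equal_means_fail(self):
        fc, _ = fold_change([5, 5, 5], [5, 5, 5])
        assert fc == 1.0 and not passes_fold_change(fc, 1.2)

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            fold_change([1, 2], [1, 2, 3])


class TestRankSum:
    def test_separated_groups_exact(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_values(self):
        assert rank_sum_test([5, 5, 5], [5, 5, 5]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 7, size=2)
            a = rng.normal(size=int(n1))
            b = rng.normal(size=int(n2))
            assert rank_sum_test(a, b) == pytest.approx(
                exact_ranksum_oracle(a, b), abs=1e-12
            )

    def test_approximation_close_to_exact(self, rng):
        # continuity-corrected normal approximation tracks the exact
        # null distribution closely at n=8/8 (worst case slightly above
        # 0.01, typical error well below)
        diffs = []
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8)
            exact = rank_sum_test(a, b)
            approx = float(
                stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
            )
            diffs.append(abs(exact - approx))
        assert np.mean(diffs) <= 0.01
        assert max(diffs) <= 0.03

    def test_null_p_values_uniform(self, rng):
        ps = [
            rank_sum_test(rng.normal(size=20), rng.normal(size=20))
            for _ in range(1000)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_label_swap_leaves_p_unchanged(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=12)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a), abs=1e-12)


class TestCascade:
    def _cohorts(self, seed=0, planted_fc=1.5, flip_validation=False):
        disc, truth = generate_cohort(
            CohortSimSpec(
                n_cases=30, n_controls=30, n_peptides=40, n_differential=5,
                planted_fc=planted_fc, cv_biological=0.15, cv_technical=0,
                n_tech_reps=1, seed=seed,
            )
        )
        planted = tuple(sorted(truth.differential_peptide_ids))
        val, _ = generate_cohort(
            CohortSimSpec(
                n_cases=30, n_controls=30, n_peptides=40,
                n_differential=len(planted),
                planted_fc=(1 / planted_fc if flip_validation else planted_fc),
                cv_biological=0.15, cv_technical=0, n_tech_reps=1,
                differential_ids=planted, seed=seed + 1,
            )
        )
        return disc, val, truth

    def test_planted_markers_survive(self):
        disc, val, truth = self._cohorts(seed=42)
        results = run_cascade(disc, val)
        survivors = {m.peptide_id for m in results if m.passed_validation}
        assert truth.differential_peptide_ids <= survivors

    def test_flipped_direction_fails_validation(self):
        disc, val, truth = self._cohorts(seed=7, flip_validation=True)
        results = run_cascade(disc, val)
        for m in results:
            if m.peptide_id in truth.differential_peptide_ids:
                assert not m.passed_validation

    def test_missing_peptide_not_measured(self):
        disc, val, truth = self._cohorts(seed=3)
        pid = sorted(truth.differential_peptide_ids)[0]
        val_short = QuantMatrix(
            values=val.values.drop(columns=[pid]), sample_meta=val.sample_meta
        )
        res = {m.peptide_id: m for m in run_cascade(disc, val_short)}
        assert not res[pid].passed_validation
        assert "not_measured" in res[pid].reasons

    def test_raising_threshold_never_adds_survivors(self):
        disc, val, _ = self._cohorts(seed=5)
        counts = []
        for thr in (1.0, 1.2, 1.5, 2.0):
            res = run_cascade(disc, val, DiscoveryConfig(fc_threshold=thr))
            counts.append(sum(m.passed_discovery for m in res))
        assert counts == sorted(counts, reverse=True)

    def test_case_control_swap_symmetry(self):
        disc, val, _ = self._cohorts(seed=9)
        swapped_meta = disc.sample_meta.copy()
        swapped_meta["group"] = swapped_meta["group"].map(
            {"case": "control", "control": "case"}
        )
        swapped = QuantMatrix(values=disc.values, sample_meta=swapped_meta)
        res = {m.peptide_id: m for m in run_cascade(disc, val)}
        res_sw = {m.peptide_id: m for m in run_cascade(swapped, val)}
        for pid in res:
            assert res_sw[pid].fold_change == pytest.approx(
                1 / res[pid].fold_change, rel=1e-9
            )
            assert res_sw[pid].p_value == pytest.approx(
                res[pid].p_value, abs=1e-9
            )


class TestZscores:
    def test_rows_are_standardized(self):
        disc, val, truth = TestCascade()._cohorts(seed=2)
        res = run_cascade(disc, val)
        markers = [m for m in res if m.passed_validation]
        table = zscore_heatmap_table(disc, markers)
        for pid, grp in table.groupby("peptide_id"):
            assert grp["zscore"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["zscore"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_peptide_gets_zero(self):
        m = _matrix({"p1": [5.0, 5.0, 5.0, 5.0]},
                    ["case", "case", "control", "control"])
        from mrmkit.discovery import MarkerResult

        mk = MarkerResult("p1", 1.0, 0.0, 1.0, False, False)
        table = zscore_heatmap_table(m, [mk])
        assert (table["zscore"] == 0).all()

    def test_empty_markers_rejected(self):
        m = _matrix({"p1": [1.0, 2.0]}, ["case", "control"])
        with pytest.raises(InputError):
            zscore_heatmap_table(m, [])
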