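import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroprog.errors import EvaluationError
from neuroprog.evaluation import (
    ModelSpec, auc, bootstrap_ci, make_balanced_split, make_stratified_folds,
    mann_whitney_u, r_squared, run_comparison,
)
from neuroprog.outcomes import outcome_table
from neuroprog.synthetic_cohort import GeneratorConfig, generate_cohort


def _brute_force_auc(scores, labels):
    """Pairwise concordance oracle: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _enumerate_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all labelings (no ties)."""
    pooled = sorted(a + b)
    n1 = len(a)
    u_obs = sum(sum(x > y for y in b) for x in a)
    mean_u = n1 * len(b) / 2.0
    count = total = 0
    for combo in itertools.combinations(pooled, n1):
        rest = list(pooled)
        for x in combo:
            rest.remove(x)
        u = sum(sum(x > y for y in rest) for x in combo)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u):
            count += 1
    return count / total


class TestBalancedSplit:
    def test_default_cohort_split_sizes(self, full_cohort_records):
        split = make_balanced_split(full_cohort_records, seed=0)
        assert len(split.test_ids) == 65
        assert len(split.development_ids) == 267
        assert set(split.test_ids).isdisjoint(split.development_ids)
        assert all(p >= 0.05 for p in split.balance_pvalues.values())
        by_id = {r.subject_id: r for r in full_cohort_records}
        assert sum(by_id[s].group == "early-AD" for s in split.test_ids) == 21
        assert sum(by_id[s].group == "early-AD" for s in split.development_ids) == 88

    def test_clone_cohort_passes_first_draw(self, full_cohort_records):
        template = full_cohort_records[0]
        ad = full_cohort_records[-1]
        clones = ([dataclasses.replace(template, subject_id=f"c{i}") for i in range(40)]
                  + [dataclasses.replace(ad, subject_id=f"d{i}") for i in range(20)])
        split = make_balanced_split(clones, seed=3)
        assert split.attempts == 1
        assert all(p == pytest.approx(1.0) for p in split.balance_pvalues.values())

    def test_impossible_constraint_terminates(self, full_cohort_records):
        with pytest.raises(EvaluationError, match="attempts"):
            make_balanced_split(full_cohort_records, alpha=1.0, max_attempts=5)

    def test_single_group_cohort_rejected(self, full_cohort_records):
        only = [r for r in full_cohort_records if r.group == "non-AD"]
        with pytest.raises(EvaluationError):
            make_balanced_split(only)


class TestStratifiedFolds:
    def test_minority_counts_differ_by_at_most_one(self):
        # 267 development subjects with 88 early-AD: 8 or 9 per fold
        labels = np.r_[np.ones(88), np.zeros(179)].astype(int)
        ids = [f"s{i}" for i in range(267)]
        folds = make_stratified_folds(ids, labels, k=10, seed=0)
        per_fold = [sum(labels[int(s[1:])] for s in folds.held_out_ids(f))
                    for f in range(1, 11)]
        assert set(per_fold) <= {8, 9}
        sizes = [len(folds.held_out_ids(f)) for f in range(1, 11)]
        assert max(sizes) - min(sizes) <= 1

    def test_leave_one_out_supported(self):
        ids = [f"s{i}" for i in range(6)]
        folds = make_stratified_folds(ids, [0, 1, 0, 1, 0, 1], k=6, seed=0)
        assert sorted(folds.fold_of.values()) == [1, 2, 3, 4, 5, 6]

    def test_deterministic_given_seed(self):
        labels = np.r_[np.ones(20), np.zeros(40)].astype(int)
        ids = [f"s{i}" for i in range(60)]
        a = make_stratified_folds(ids, labels, k=10, seed=5)
        b = make_stratified_folds(ids, labels, k=10, seed=5)
        assert a.fold_of == b.fold_of
        c = make_stratified_folds(ids, labels, k=10, seed=6)
        assert a.fold_of != c.fold_of

    def test_k_beyond_minority_rejected(self):
        with pytest.raises(EvaluationError):
            make_stratified_folds(["a", "b", "c", "d"], [0, 0, 0, 1], k=2)


class TestMetrics:
    def test_auc_known_values(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
        # 3 wins + 1 half-tie over 4 pairs
        assert auc([0.9, 0.5, 0.5, 0.2], [1, 1, 0, 0]) == 0.875
        with pytest.raises(EvaluationError):
            auc([0.5, 0.6], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_u_statistic_identity(self, seed):
        """AUC == U/(n1*n2), U taken from the Mann-Whitney implementation on
        positive-class vs negative-class scores."""
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 12, 2)
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        scores = np.round(rng.normal(size=n1 + n0), 1)  # force some ties
        u, _ = mann_whitney_u(scores[:n1], scores[n1:])
        assert auc(scores, labels) == pytest.approx(u / (n1 * n0))
        assert auc(scores, labels) == pytest.approx(_brute_force_auc(scores, labels))

    def test_r_squared(self):
        y = np.array([1.0, 2.0, 4.0, 7.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(np.full(4, y.mean()), y) == 0.0
        assert r_squared(-y, y) < 0  # held-out R^2 may be negative
        with pytest.raises(EvaluationError):
            r_squared([1.0, 2.0], [3.0, 3.0])


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(_enumerate_mw_p([1, 2, 3], [4, 5, 6]))

    def test_all_ties_symmetric(self):
        u, p = mann_whitney_u([5.0] * 4, [5.0] * 6)
        assert u == 12.0  # n1*n2/2
        assert p == 1.0

    def test_swap_antisymmetry(self):
        a, b = [1.2, 3.4, 2.2, 8.0], [0.5, 2.5, 9.1]
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert u_ab + u_ba == len(a) * len(b)
        assert p_ab == pytest.approx(p_ba)

    def test_exact_close_to_normal_approximation_at_n10(self):
        """Regime check for the method switch at n1=n2=10 on un-tied data."""
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=10), rng.normal(0.5, 1, size=10)
            _, p_exact = mann_whitney_u(a, b)
            p_norm = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.05

    def test_empty_sample_error(self):
        with pytest.raises(EvaluationError):
            mann_whitney_u([], [1.0])


class TestBootstrap:
    def test_degenerate_metric_zero_width(self):
        # perfectly separated scores: AUC is 1 under any stratified resample
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [1, 1, 0, 0]
        assert bootstrap_ci(scores, labels, "auc", B=200, seed=0) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_interval_contains_point_estimate(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(30), np.zeros(30)]
        scores = rng.normal(labels, 1.0)
        lo, hi = bootstrap_ci(scores, labels, "auc", B=500, seed=seed)
        assert lo <= auc(scores, labels) <= hi


class _ConstantSpec(ModelSpec):
    """Deterministic spec scoring subjects by a fixed feature; records the
    subject ids seen during fitting (for the leakage instrumentation test)."""

    def __init__(self, name, jitter=0.0):
        self.name = name
        self.jitter = jitter
        self.seen_ids: set[str] = set()

    def fit(self, records, outcome, seed):
        self.seen_ids.update(r.subject_id for r in records)
        return seed

    def predict(self, fitted, records):
        rng = np.random.default_rng(fitted)
        base = np.array([-r.hippocampal_volume for r in records], dtype=float)
        return base + self.jitter * rng.normal(size=len(records))


class _FailingSpec(ModelSpec):
    name = "broken"

    def fit(self, records, outcome, seed):
        raise RuntimeError("cannot fit")

    def predict(self, fitted, records):
        raise AssertionError("unreachable")


@pytest.fixture(scope="module")
def comparison_setup(full_cohort_records):
    outc = outcome_table(full_cohort_records)
    split = make_balanced_split(full_cohort_records, seed=1)
    labels = outc.loc[split.development_ids, "progressed_4y"].astype(int)
    folds = make_stratified_folds(split.development_ids, labels.to_numpy(),
                                  k=10, seed=1)
    return full_cohort_records, outc, split, folds


class TestRunComparison:
    def test_identical_specs_all_ties(self, comparison_setup):
        records, outc, split, folds = comparison_setup
        specs = [_ConstantSpec("a"), _ConstantSpec("b")]
        rep = run_comparison(records, outc["progressed_4y"].astype(float), specs,
                             "progression", split, folds, B=50, seed=0)
        row = rep.pairwise.iloc[0]
        assert row["U"] == 50.0  # 10 vs 10, all tied
        assert row["p"] == 1.0
        assert not row["significant"]

    def test_report_structure(self, comparison_setup):
        records, outc, split, folds = comparison_setup
        specs = [_ConstantSpec("a", jitter=5.0), _ConstantSpec("b", jitter=500.0)]
        rep = run_comparison(records, outc["progressed_4y"].astype(float), specs,
                             "progression", split, folds, B=50, seed=0)
        assert rep.fold_metrics.shape == (2, 10)
        for name in ("a", "b"):
            s = rep.summary.loc[name]
            assert s["ci_lower"] <= s["mean"] <= s["ci_upper"]

    def test_failing_model_marked_not_fatal(self, comparison_setup):
        records, outc, split, folds = comparison_setup
        specs = [_ConstantSpec("a"), _ConstantSpec("b"), _FailingSpec()]
        rep = run_comparison(records, outc["progressed_4y"].astype(float), specs,
                             "progression", split, folds, B=50, seed=0)
        assert rep.summary.loc["broken", "failed"].startswith("RuntimeError")
        assert np.isnan(rep.summary.loc["broken", "mean"])
        assert len(rep.pairwise) == 1  # only the surviving pair

    def test_fitting_never_sees_test_subjects(self, comparison_setup):
        records, outc, split, folds = comparison_setup
        spec_a, spec_b = _ConstantSpec("a"), _ConstantSpec("b")
        run_comparison(records, outc["progressed_4y"].astype(float),
                       [spec_a, spec_b], "progression", split, folds, B=10, seed=0)
        assert spec_a.seen_ids.isdisjoint(split.test_ids)
        assert spec_b.seen_ids.isdisjoint(split.test_ids)

    def test_continuous_task_uses_r_squared(self, comparison_setup):
        records, outc, split, folds = comparison_setup
        specs = [_ConstantSpec("a"), _ConstantSpec("b", jitter=1.0)]
        rep = run_comparison(records, outc["mmse_slope"], specs, "slope",
                             split, folds, B=50, seed=0)
        assert rep.fold_metrics.shape == (2, 10)
        assert np.isfinite(rep.summary["mean"]).all()
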