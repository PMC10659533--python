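"""Evaluation protocol: balance-tested 80/20 split, stratified 10-fold CV,
per-fold test metrics, fold-wise Mann-Whitney model comparison, and
bootstrap confidence intervals.

The development/test split is drawn repeatedly (stratified by outcome
group) until no balance test rejects at the configured alpha: Fisher's
exact test for sex, SCD/MCI diagnosis and APOE e4 carriership, Welch's
t-test for age and education.  Each model is then fitted once per
cross-validation fold (on the fold's training portion only) and scored on
the untouched test set; the ten fold scores feed pairwise Mann-Whitney
U-tests, and bootstrapping the test subjects yields 95% percentile
intervals of the fold-mean metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import EvaluationError
from .synthetic_cohort import SubjectRecord

__all__ = [
    "CohortSplit",
    "FoldAssignment",
    "EvaluationReport",
    "make_balanced_split",
    "make_stratified_folds",
    "auc",
    "r_squared",
    "mann_whitney_u",
    "bootstrap_ci",
    "run_comparison",
]


# ---------------------------------------------------------------------------
# Split and folds
# ---------------------------------------------------------------------------

@dataclass
class CohortSplit:
    development_ids: list[str]
    test_ids: list[str]
    balance_pvalues: dict[str, float]
    seed: int
    attempts: int


@dataclass
class FoldAssignment:
    """1-based fold index per development subject."""

    fold_of: dict[str, int]
    k: int

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f != fold]

    def held_out_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]


def _balance_pvalues(dev: list[SubjectRecord], test: list[SubjectRecord]) -> dict[str, float]:
    def fisher(attr: Callable[[SubjectRecord], bool]) -> float:
        table = [[sum(attr(r) for r in grp), sum(not attr(r) for r in grp)]
                 for grp in (dev, test)]
        return float(sps.fisher_exact(table)[1])

    def welch(attr: Callable[[SubjectRecord], float]) -> float:
        a = np.array([attr(r) for r in dev], dtype=float)
        b = np.array([attr(r) for r in test], dtype=float)
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):  # both samples constant: identical means pass trivially
            return 1.0 if np.mean(a) == np.mean(b) else 0.0
        return p

    return {
        "diagnosis": fisher(lambda r: r.diagnosis == "MCI"),
        "sex": fisher(lambda r: r.sex == "F"),
        "apoe_e4": fisher(lambda r: r.apoe_e4_count > 0),
        "age": welch(lambda r: r.age),
        "education": welch(lambda r: r.education),
    }


def make_balanced_split(
    cohort: Sequence[SubjectRecord],
    test_frac: float = 0.2,
    alpha: float = 0.05,
    max_attempts: int = 10_000,
    seed: int = 0,
) -> CohortSplit:
    """Stratified random 80/20 split, redrawn until all balance tests pass.

    The test set takes ``floor(test_frac * n)`` subjects from each outcome
    group (so 332 subjects at ``test_frac=0.2`` give a 65/267 split:
    44 + 21 vs 179 + 88).
    """
    records = list(cohort)
    groups = {r.group for r in records}
    if len(groups) < 2:
        raise EvaluationError("cohort must contain both outcome groups")
    rng = np.random.default_rng(seed)
    by_group = {g: [r for r in records if r.group == g] for g in groups}

    last_failing: list[str] = []
    for attempt in range(1, max_attempts + 1):
        test: list[SubjectRecord] = []
        for g, members in sorted(by_group.items()):
            n_test = int(np.floor(test_frac * len(members)))
            idx = rng.choice(len(members), size=n_test, replace=False)
            test.extend(members[i] for i in idx)
        test_ids = {r.subject_id for r in test}
        dev = [r for r in records if r.subject_id not in test_ids]
        pvals = _balance_pvalues(dev, test)
        if all(p >= alpha for p in pvals.values()):
            return CohortSplit(
                development_ids=[r.subject_id for r in dev],
                test_ids=[r.subject_id for r in test],
                balance_pvalues=pvals, seed=seed, attempts=attempt,
            )
        last_failing = [k for k, p in pvals.items() if p < alpha]
    raise EvaluationError(
        f"no balanced split found in {max_attempts} attempts; "
        f"variables failing on the last attempt: {last_failing}"
    )


def make_stratified_folds(
    dev_ids: Sequence[str], labels: Sequence[int], k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Class-stratified k-fold partition, random apart from stratification.

    Per-fold class counts differ by at most one.  ``k == n`` degenerates to
    leave-one-out.
    """
    dev_ids = list(dev_ids)
    y = np.asarray(labels).astype(int)
    if len(dev_ids) != y.size:
        raise EvaluationError("labels length does not match dev_ids")
    if k == len(dev_ids):  # leave-one-out: stratification is vacuous
        return FoldAssignment({s: i + 1 for i, s in enumerate(dev_ids)}, k)
    minority = int(np.bincount(y).min())
    if k > minority:
        raise EvaluationError(
            f"k={k} exceeds the minority-class count ({minority})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, held) in enumerate(skf.split(np.zeros(y.size), y), start=1):
        for i in held:
            fold_of[dev_ids[i]] = fold
    return FoldAssignment(fold_of, k)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Area under the ROC curve (ties credited half)."""
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise EvaluationError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def r_squared(predicted, observed) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    yo = np.asarray(observed, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if yo.size < 2 or np.var(yo) == 0:
        raise EvaluationError("R^2 requires >= 2 observations with nonzero variance")
    return float(r2_score(yo, yp))


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-sided p-value.

    Exact enumeration when both samples have n <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _auc_rows(pos_scores: np.ndarray, neg_scores: np.ndarray) -> np.ndarray:
    """Row-wise AUC via midranks: U / (n1*n2) for each (B, .) score pair."""
    n1, n0 = pos_scores.shape[1], neg_scores.shape[1]
    combined = np.concatenate([pos_scores, neg_scores], axis=1)
    ranks = sps.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_ci(
    scores, labels_or_values, metric: str = "auc", B: int = 2000, seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI over resampled test subjects.

    For AUC the resampling is stratified by class, so every resample
    contains both classes and the metric is always defined.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels_or_values, dtype=float)
    if metric not in ("auc", "r_squared"):
        raise EvaluationError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    if metric == "auc":
        pos = s[y == 1]
        neg = s[y == 0]
        if pos.size == 0 or neg.size == 0:
            raise EvaluationError("AUC bootstrap requires both classes")
        vals = _auc_rows(rng.choice(pos, (B, pos.size), replace=True),
                         rng.choice(neg, (B, neg.size), replace=True))
    else:
        n = s.size
        idx = rng.integers(0, n, size=(B, n))
        degenerate = np.var(y[idx], axis=1) == 0
        while degenerate.any():
            idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
            degenerate = np.var(y[idx], axis=1) == 0
        ss_res = np.sum((y[idx] - s[idx]) ** 2, axis=1)
        ss_tot = np.sum((y[idx] - y[idx].mean(axis=1, keepdims=True)) ** 2, axis=1)
        vals = 1.0 - ss_res / ss_tot
    lo = (1.0 - ci_level) / 2.0
    return (float(np.quantile(vals, lo)), float(np.quantile(vals, 1.0 - lo)))


# ---------------------------------------------------------------------------
# Full model comparison
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    task: str
    fold_metrics: pd.DataFrame  # rows: model, columns: fold 1..k
    summary: pd.DataFrame  # model, mean, ci_lower, ci_upper, failed
    pairwise: pd.DataFrame  # model_a, model_b, U, p, significant

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "fold_metrics": self.fold_metrics.to_dict(orient="index"),
            "summary": self.summary.to_dict(orient="index"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


class ModelSpec:
    """Interface of a comparable model: fit on records, score records."""

    name: str

    def fit(self, records: list[SubjectRecord], outcome: pd.Series, seed: int):
        raise NotImplementedError

    def predict(self, fitted, records: list[SubjectRecord]) -> np.ndarray:
        raise NotImplementedError


def run_comparison(
    records: Sequence[SubjectRecord],
    outcome: pd.Series,
    specs: Sequence[ModelSpec],
    task: str,
    split: CohortSplit,
    folds: FoldAssignment,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Fit every model spec per fold and compare on the untouched test set.

    ``outcome`` is indexed by subject_id (bool for the progression task,
    float for the slope task; NaN slope drops the subject from the
    continuous analysis).  Returns per-fold test metrics, fold means with
    bootstrap CIs of the fold-mean statistic, and pairwise Mann-Whitney
    p-values over the fold scores.  A model whose fit fails on any fold is
    marked failed; the comparison proceeds for the others.
    """
    if len(specs) < 2:
        raise EvaluationError("run_comparison needs >= 2 model specs")
    by_id = {r.subject_id: r for r in records}
    metric = "auc" if task == "progression" else "r_squared"

    test_ids = [s for s in split.test_ids
                if task == "progression" or np.isfinite(outcome.loc[s])]
    test_records = [by_id[s] for s in test_ids]
    y_test = outcome.loc[test_ids].to_numpy(dtype=float)

    fold_rows: dict[str, list[float]] = {}
    predictions: dict[str, np.ndarray] = {}  # (k, n_test) per model
    failed: dict[str, str] = {}
    for spec in specs:
        scores = np.full((folds.k, len(test_ids)), np.nan)
        per_fold = []
        try:
            for fold in range(1, folds.k + 1):
                train_ids = [s for s in folds.train_ids(fold)
                             if task == "progression" or np.isfinite(outcome.loc[s])]
                train_records = [by_id[s] for s in train_ids]
                fitted = spec.fit(train_records, outcome.loc[train_ids], seed=seed + fold)
                pred = np.asarray(spec.predict(fitted, test_records), dtype=float)
                scores[fold - 1] = pred
                per_fold.append(auc(pred, y_test) if metric == "auc"
                                else r_squared(pred, y_test))
        except Exception as exc:  # a failing model must not sink the comparison
            failed[spec.name] = f"{type(exc).__name__}: {exc}"
            continue
        fold_rows[spec.name] = per_fold
        predictions[spec.name] = scores

    fold_metrics = pd.DataFrame.from_dict(fold_rows, orient="index",
                                          columns=[f"fold_{i}" for i in range(1, folds.k + 1)])

    summary_rows = {}
    rng = np.random.default_rng(seed)
    for name, per_fold in fold_rows.items():
        ci = _bootstrap_fold_mean(predictions[name], y_test, metric,
                                  B=B, seed=int(rng.integers(2**31)))
        summary_rows[name] = {
            "mean": float(np.mean(per_fold)),
            "ci_lower": ci[0], "ci_upper": ci[1], "failed": "",
        }
    for name, why in failed.items():
        summary_rows[name] = {"mean": np.nan, "ci_lower": np.nan,
                              "ci_upper": np.nan, "failed": why}
    summary = pd.DataFrame.from_dict(summary_rows, orient="index")

    pairs = []
    names = list(fold_rows)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u, p = mann_whitney_u(fold_rows[a], fold_rows[b])
            pairs.append({"model_a": a, "model_b": b, "U": u, "p": p,
                          "significant": bool(p < alpha)})
    pairwise = pd.DataFrame(pairs, columns=["model_a", "model_b", "U", "p", "significant"])
    return EvaluationReport(task=task, fold_metrics=fold_metrics,
                            summary=summary, pairwise=pairwise)


def _bootstrap_fold_mean(pred: np.ndarray, y: np.ndarray, metric: str,
                         B: int, seed: int) -> tuple[float, float]:
    """CI of the mean-over-folds metric under resampling of test subjects."""
    rng = np.random.default_rng(seed)
    k, n = pred.shape
    if metric == "auc":
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        idx_pos = rng.choice(pos, (B, pos.size), replace=True)
        idx_neg = rng.choice(neg, (B, neg.size), replace=True)
        vals = np.mean([_auc_rows(pred[f][idx_pos], pred[f][idx_neg])
                        for f in range(k)], axis=0)
    else:
        idx = rng.integers(0, n, size=(B, n))
        degenerate = np.var(y[idx], axis=1) == 0
        while degenerate.any():
            idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
            degenerate = np.var(y[idx], axis=1) == 0
        yb = y[idx]
        ss_tot = np.sum((yb - yb.mean(axis=1, keepdims=True)) ** 2, axis=1)
        vals = np.mean([1.0 - np.sum((yb - pred[f][idx]) ** 2, axis=1) / ss_tot
                        for f in range(k)], axis=0)
    return float(np.quantile(vals, 0.025)), float(np.quantile(vals, 0.975))
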