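"""Evaluation: AUC/ACC, split-series summaries (mean +/- SD, 95% CI),
model comparisons, and cohort grade arithmetic.

The 95% CI convention is the normal approximation for the mean of the split
series, ``mean +/- 1.96 * SD / sqrt(n_splits)``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "UndefinedAUCError",
    "auc",
    "accuracy",
    "MetricSummary",
    "summarize",
    "compare_models",
    "GradeSummary",
    "summarize_grades",
    "performance_table",
]


class UndefinedAUCError(ValueError):
    """AUC requested with only one outcome class present."""


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("AUC is undefined with a single outcome class")
    return float(roc_auc_score(labels, scores))


def accuracy(labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction of correct calls at the probability threshold."""
    labels = np.asarray(labels)
    probs = np.asarray(probabilities, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities must have the same length")
    return float(np.mean((probs >= threshold).astype(int) == labels))


class MetricSummary(NamedTuple):
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int

    def format(self, dp: int = 3, ci_dp: int = 2) -> str:
        return (f"{self.mean:.{dp}f} ± {self.sd:.{dp}f} "
                f"[{self.ci_low:.{ci_dp}f}, {self.ci_high:.{ci_dp}f}]")


def summarize(values: Sequence[float]) -> MetricSummary:
    """Mean, sample SD and normal-approximation 95% CI over split repetitions."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("summary requires at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = 1.96 * sd / np.sqrt(v.size)
    return MetricSummary(mean, sd, mean - half, mean + half, v.size)


def compare_models(
    auc_a: Sequence[float],
    auc_b: Sequence[float],
    paired: bool = True,
    method: str = "ttest",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for a difference in per-split AUC series.

    Default is a paired t-test across the shared splits; ``method=
    'permutation'`` runs a sign-flip permutation test on the differences.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length series")
    if paired:
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            # a constant non-zero difference is a perfectly consistent
            # dominance (t -> inf); a zero difference is identity
            if np.allclose(diff.mean(), 0.0):
                warnings.warn("zero-variance AUC differences; p-value set to 1")
                return 1.0
            warnings.warn("constant non-zero AUC differences; p-value set to 0")
            return 0.0
        if method == "ttest":
            return float(stats.ttest_rel(a, b).pvalue)
        if method == "permutation":
            rng = np.random.default_rng(seed)
            obs = abs(diff.mean())
            signs = rng.choice((-1.0, 1.0), size=(n_permutations, diff.size))
            null = np.abs((signs * diff).mean(axis=1))
            return float((np.sum(null >= obs - 1e-12) + 1) / (n_permutations + 1))
        raise ValueError(f"unknown method {method!r}")
    return float(stats.ttest_ind(a, b).pvalue)


class GradeSummary(NamedTuple):
    n_patients: int
    n_events: int
    incidence_pct: float


def summarize_grades(
    grade_counts: Sequence[int],
    n_patients: int | None = None,
    event_grade: int = 2,
) -> GradeSummary:
    """Cohort toxicity arithmetic from per-grade patient counts.

    ``grade_counts[i]`` is the number of patients with grade ``i+1``; an
    event is grade >= ``event_grade``.  ``n_patients`` defaults to the sum of
    the counts but can be given explicitly when ungraded patients exist.
    """
    counts = [int(c) for c in grade_counts]
    if any(c < 0 for c in counts):
        raise ValueError("grade counts must be non-negative")
    events = sum(c for grade, c in enumerate(counts, start=1) if grade >= event_grade)
    n = int(n_patients) if n_patients is not None else sum(counts)
    if n <= 0:
        raise ValueError("cohort size must be positive")
    return GradeSummary(n, events, 100.0 * events / n)


def performance_table(results: Mapping[str, "pd.DataFrame"]) -> pd.DataFrame:
    """Model x cohort x metric report over the split series.

    ``results`` maps a model name (e.g. ``"hf"``) to its per-split records
    with columns ``train_auc/train_acc/test_auc/test_acc``.
    """
    rows = []
    for model, records in results.items():
        for metric in ("auc", "acc"):
            row: dict[str, object] = {"model": model.upper() + "M", "metric": metric.upper()}
            for cohort in ("train", "test"):
                s = summarize(records[f"{cohort}_{metric}"])
                row[f"{cohort}_mean"] = round(s.mean, 3)
                row[f"{cohort}_sd"] = round(s.sd, 3)
                row[f"{cohort}_ci_low"] = round(s.ci_low, 2)
                row[f"{cohort}_ci_high"] = round(s.ci_high, 2)
            rows.append(row)
    return pd.DataFrame(rows)
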