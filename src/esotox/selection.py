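"""Bootstrap stability feature selection.

Four stages, run inside the training data only:

1. *Bootstrap screening* — 100 random 70% patient subsamples (stratified by
   outcome); in each, a feature survives iff its subsample variance is
   positive and its one-way ANOVA F-test p-value against the label is <= 0.1.
   The per-feature survival count is its stability frequency.
2. *Frequency filter* — keep the top 10% most frequent surviving features,
   with a floor of 10 features.
3. *Correlation pruning* — greedy scan in frequency-rank order dropping any
   feature with |Pearson r| > 0.5 against an already-kept one.
4. *CV subset search* — nested prefixes of the pruned ranking scored by mean
   validation AUC of a ridge classifier over 20 repetitions of stratified
   5-fold CV; the smallest prefix within one standard error of the best mean
   is selected (parsimony rule for near-ties).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "EmptySelectionError",
    "SelectionReport",
    "bootstrap_screen",
    "frequency_filter",
    "correlation_prune",
    "cv_subset_search",
    "select_features",
]


class EmptySelectionError(RuntimeError):
    """No feature survived screening."""


def _as_frame(table) -> pd.DataFrame:
    if hasattr(table, "data"):  # FeatureTable
        return table.data
    return pd.DataFrame(table)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must be binary 0/1 with both classes present, got {classes}")
    return y


def _stratified_subsample(y: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Without-replacement subsample of floor(frac*n) patients, stratified by
    label so both classes are always present."""
    n = len(y)
    total = int(math.floor(frac * n))
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n1 = max(1, int(round(total * len(idx1) / n)))
    n0 = max(1, total - n1)
    take0 = rng.choice(idx0, size=min(n0, len(idx0)), replace=False)
    take1 = rng.choice(idx1, size=min(n1, len(idx1)), replace=False)
    return np.sort(np.concatenate([take0, take1]))


def _f_test_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA (two groups) p-values per feature column."""
    n = len(y)
    out = np.ones(x.shape[1])
    g0, g1 = x[y == 0], x[y == 1]
    n0, n1 = len(g0), len(g1)
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    grand = x.mean(axis=0)
    ssb = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ssw = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    dfw = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / dfw)
    p = stats.f.sf(f, 1, dfw)
    # perfect separation (ssw == 0, ssb > 0) -> p = 0; constant feature -> p = 1
    p = np.where((ssw == 0) & (ssb > 0), 0.0, p)
    p = np.where((ssw == 0) & (ssb == 0), 1.0, p)
    out[:] = p
    return out


def bootstrap_screen(
    table,
    labels: Sequence[int],
    n_iter: int = 100,
    sample_frac: float = 0.7,
    p_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability screening; returns a frame indexed by feature with columns
    ``frequency`` (0..n_iter survival count) and ``median_p``."""
    df = _as_frame(table)
    y = _check_labels(np.asarray(labels))
    if len(df) != len(y):
        raise ValueError("table and labels disagree on patient count")
    x = df.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    survive = np.zeros(x.shape[1], dtype=int)
    pvals = np.empty((n_iter, x.shape[1]))
    for it in range(n_iter):
        idx = _stratified_subsample(y, sample_frac, rng)
        xs, ys = x[idx], y[idx]
        var_ok = xs.var(axis=0) > 0
        p = _f_test_pvalues(xs, ys)
        pvals[it] = p
        survive += (var_ok & (p <= p_threshold)).astype(int)
    return pd.DataFrame(
        {"frequency": survive, "median_p": np.median(pvals, axis=0)},
        index=df.columns,
    )


def frequency_filter(
    screen: pd.DataFrame,
    top_frac: float = 0.10,
    min_features: int = 10,
    quota_base: str = "nonzero",
) -> list[str]:
    """Top-frequency candidates, ordered; quota = max(ceil(top_frac * m),
    min_features) where ``m`` counts features that survived at least once
    (``quota_base='all'`` counts every feature instead).  Ties at the cutoff
    break deterministically by (frequency desc, median p asc, name)."""
    nonzero = screen[screen["frequency"] > 0]
    if nonzero.empty:
        raise EmptySelectionError("no feature survived any screening iteration")
    m = len(nonzero) if quota_base == "nonzero" else len(screen)
    k = max(math.ceil(top_frac * m), min_features)
    k = min(k, len(nonzero))
    ranked = nonzero.sort_values(
        by=["frequency", "median_p"], ascending=[False, True], kind="mergesort",
    )
    # stable mergesort + name order as final key
    ranked = ranked.loc[
        sorted(ranked.index, key=lambda name: (-ranked.at[name, "frequency"],
                                               ranked.at[name, "median_p"], name))
    ]
    return list(ranked.index[:k])


def correlation_prune(table, candidates: Sequence[str], r_threshold: float = 0.5) -> list[str]:
    """Greedy scan in rank order; drop a feature iff |Pearson r| with any
    already-kept feature exceeds the threshold (keeps the higher-ranked,
    i.e. more frequent, member of each violating pair)."""
    df = _as_frame(table)
    kept: list[str] = []
    kept_matrix: list[np.ndarray] = []
    for name in candidates:
        v = df[name].to_numpy(dtype=float)
        sv = v.std()
        ok = True
        for other in kept_matrix:
            if sv == 0 or other.std() == 0:
                r = 1.0  # constant features are redundant by convention
            else:
                r = abs(float(np.corrcoef(v, other)[0, 1]))
            if r > r_threshold:
                ok = False
                break
        if ok:
            kept.append(name)
            kept_matrix.append(v)
    return kept


def _ridge_decision(xtr: np.ndarray, y_pm: np.ndarray, xte: np.ndarray,
                    alpha: float) -> np.ndarray:
    """Closed-form ridge decision scores, identical to a fitted
    ``sklearn.linear_model.RidgeClassifier`` (y mapped to +/-1, X and y
    centred, penalty on the slopes only)."""
    xm = xtr.mean(axis=0)
    ym = y_pm.mean()
    xc = xtr - xm
    a = xc.T @ xc + alpha * np.eye(xc.shape[1])
    w = np.linalg.solve(a, xc.T @ (y_pm - ym))
    return (xte - xm) @ w + ym


def _fold_auc(x: np.ndarray, y: np.ndarray, train, test, alpha: float) -> float:
    mu = x[train].mean(axis=0)
    sd = x[train].std(axis=0)
    sd[sd == 0] = 1.0
    xtr = (x[train] - mu) / sd
    xte = (x[test] - mu) / sd
    scores = _ridge_decision(xtr, 2.0 * y[train] - 1.0, xte, alpha)
    return float(roc_auc_score(y[test], scores))


def cv_subset_search(
    table,
    labels: Sequence[int],
    ranked: Sequence[str],
    k_fold: int = 5,
    n_rep: int = 20,
    seed: int = 0,
    alpha: float = 1.0,
) -> tuple[list[str], pd.DataFrame]:
    """Score nested prefixes of the ranked list by repeated stratified k-fold
    ridge AUC; return (selected subset, trace).

    The selected subset is the smallest prefix whose mean validation AUC lies
    within one standard error of the best prefix's mean.
    """
    if not ranked:
        raise EmptySelectionError("cv_subset_search received an empty candidate list")
    df = _as_frame(table)
    y = _check_labels(np.asarray(labels))
    cv = RepeatedStratifiedKFold(n_splits=k_fold, n_repeats=n_rep, random_state=seed)
    splits = list(cv.split(np.zeros(len(y)), y))
    means, ses, scores_by_size = [], [], []
    for size in range(1, len(ranked) + 1):
        x = df[list(ranked[:size])].to_numpy(dtype=float)
        scores = np.array([_fold_auc(x, y, tr, te, alpha) for tr, te in splits])
        means.append(scores.mean())
        ses.append(scores.std(ddof=1) / np.sqrt(len(scores)))
        scores_by_size.append(scores)
    means_arr = np.asarray(means)
    best = int(np.argmax(means_arr))
    threshold = means_arr[best] - ses[best]
    chosen_size = int(np.flatnonzero(means_arr >= threshold)[0]) + 1
    trace = pd.DataFrame({
        "subset_size": np.arange(1, len(ranked) + 1),
        "mean_auc": means_arr,
        "se_auc": ses,
    })
    return list(ranked[:chosen_size]), trace


@dataclass
class SelectionReport:
    """Full record of the selection pipeline for one feature table."""

    frequencies: pd.Series
    median_p: pd.Series
    decisions: dict[str, str]          # feature -> kept | variance/f_test | frequency | correlation | cv_search
    candidates: list[str]
    pruned: list[str]
    selected: list[str]
    trace: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.pruned) <= set(self.candidates):
            raise ValueError("selection stages are not nested")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "frequencies": self.frequencies.to_dict(),
            "median_p": self.median_p.to_dict(),
            "decisions": self.decisions,
            "candidates": self.candidates,
            "pruned": self.pruned,
            "selected": self.selected,
            "trace": self.trace.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def select_features(
    table,
    labels: Sequence[int],
    n_iter: int = 100,
    sample_frac: float = 0.7,
    p_threshold: float = 0.1,
    top_frac: float = 0.10,
    min_features: int = 10,
    r_threshold: float = 0.5,
    k_fold: int = 5,
    n_rep: int = 20,
    seed: int = 0,
) -> SelectionReport:
    """Run all four selection stages; deterministic given (table, labels, seed)."""
    df = _as_frame(table)
    screen = bootstrap_screen(df, labels, n_iter=n_iter, sample_frac=sample_frac,
                              p_threshold=p_threshold, seed=seed)
    candidates = frequency_filter(screen, top_frac=top_frac, min_features=min_features)
    pruned = correlation_prune(df, candidates, r_threshold=r_threshold)
    selected, trace = cv_subset_search(df, labels, pruned, k_fold=k_fold,
                                       n_rep=n_rep, seed=seed)
    decisions: dict[str, str] = {}
    cand_set, pruned_set, sel_set = set(candidates), set(pruned), set(selected)
    for name in df.columns:
        if name in sel_set:
            decisions[name] = "kept"
        elif name in pruned_set:
            decisions[name] = "cv_search"
        elif name in cand_set:
            decisions[name] = "correlation"
        elif screen.at[name, "frequency"] > 0:
            decisions[name] = "frequency"
        else:
            decisions[name] = "variance_or_f_test"
    # post-hoc re-check of the correlation bound among selected features
    sel = df[selected].to_numpy(dtype=float)
    if len(selected) > 1:
        corr = np.corrcoef(sel, rowvar=False)
        off = np.abs(corr[~np.eye(len(selected), dtype=bool)])
        if np.any(off > r_threshold + 1e-12):
            raise AssertionError("correlation bound violated among selected features")
    return SelectionReport(
        frequencies=screen["frequency"],
        median_p=screen["median_p"],
        decisions=decisions,
        candidates=candidates,
        pruned=pruned,
        selected=selected,
        trace=trace,
    )
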