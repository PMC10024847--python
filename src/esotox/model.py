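"""Easy-ensemble ridge classification of toxicity outcomes.

The estimator follows the statsmodels shape: a model object is built from
data and ``fit()`` returns a results object carrying estimates, diagnostics
and a ``summary()``.

* :class:`RidgeEnsembleClassifier` — ridge penalty chosen by tenfold
  cross-validated grid search on the training cohort, then an easy ensemble
  of ``n_bags`` bags.  Each bag subsamples 2/3 of the training patients
  (stratified) and balances classes by keeping every minority-class patient
  plus an equal-count draw from the majority class; the ensemble score is the
  arithmetic mean of the bag decision scores.  Ridge margins are mapped to
  probabilities by logistic (Platt) calibration on the training scores.
* :class:`RepeatedSplitExperiment` — 30 independent stratified 2/3-1/3
  train-test splits, one fitted ensemble per split, AUC/ACC recorded on both
  cohorts (161 patients split as 107 train / 54 test).
* :func:`combine_models` — the super-ensemble averaging the split models'
  scores, used for the nomogram.
* :func:`build_nomogram` — per-feature point mappings normalized to a 0-100
  total-points axis over the observed RadScore range, with the calibrated
  logistic probability map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import metrics as _metrics

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "RidgeEnsembleClassifier",
    "RidgeEnsembleResults",
    "RepeatedSplitExperiment",
    "SplitExperimentResults",
    "combine_models",
    "NomogramTable",
    "build_nomogram",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 13))


def _as_frame(X) -> pd.DataFrame:
    if hasattr(X, "data"):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class _Bag:
    """One ensemble member: standardization statistics estimated on the bag's
    balanced training sample, plus the fitted ridge hyperplane."""

    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    intercept: float

    def decision(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.mean) / self.sd) @ self.coef + self.intercept


class RidgeEnsembleClassifier:
    """Imbalance-aware ridge model for a binary toxicity outcome.

    Parameters
    ----------
    X, y : training feature matrix (patients x features) and binary labels.
    alpha_grid : ridge penalties searched by tenfold CV (default 13
        log-spaced values between 1e-3 and 1e3).
    n_bags : ensemble size of the easy-ensemble stage.
    bag_fraction : per-bag patient subsample fraction before balancing.
    """

    def __init__(
        self,
        X,
        y: Sequence[int],
        alpha_grid: Sequence[float] | None = None,
        n_bags: int = 10,
        bag_fraction: float = 2 / 3,
        cv_folds: int = 10,
    ):
        self.X = _as_frame(X)
        self.y = np.asarray(y).astype(int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y disagree on patient count")
        if np.unique(self.y).size < 2:
            raise ValueError("both outcome classes must be present for training")
        self.alpha_grid = tuple(float(a) for a in (alpha_grid or DEFAULT_ALPHA_GRID))
        if len(self.alpha_grid) == 0 or any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alpha grid must contain positive penalties")
        self.n_bags = int(n_bags)
        self.bag_fraction = float(bag_fraction)
        self.cv_folds = int(cv_folds)

    # -- hyper-parameter search ------------------------------------------
    def _grid_search(self, seed: int) -> tuple[float, pd.DataFrame]:
        x = self.X.to_numpy(dtype=float)
        folds = min(self.cv_folds, int(np.bincount(self.y).min()))
        folds = max(folds, 2)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        rows = []
        for alpha in self.alpha_grid:
            scores = []
            for tr, te in cv.split(x, self.y):
                mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
                sd[sd == 0] = 1.0
                clf = RidgeClassifier(alpha=alpha)
                clf.fit((x[tr] - mu) / sd, self.y[tr])
                scores.append(roc_auc_score(self.y[te], clf.decision_function((x[te] - mu) / sd)))
            rows.append({"alpha": alpha, "mean_cv_auc": float(np.mean(scores))})
        table = pd.DataFrame(rows)
        best = table.loc[table["mean_cv_auc"].idxmax(), "alpha"]
        return float(best), table

    def _draw_bag(self, rng: np.random.Generator) -> np.ndarray:
        """Stratified 2/3 subsample, then balance toward the minority class."""
        for _ in range(100):
            n = len(self.y)
            take = []
            for cls in (0, 1):
                idx = np.flatnonzero(self.y == cls)
                k = max(1, int(round(self.bag_fraction * len(idx))))
                take.append(rng.choice(idx, size=k, replace=False))
            sub = np.concatenate(take)
            ys = self.y[sub]
            if np.unique(ys).size < 2:
                continue  # redraw degenerate bag
            minority = 1 if ys.sum() <= len(ys) / 2 else 0
            idx_min = sub[ys == minority]
            idx_maj = sub[ys != minority]
            idx_maj = rng.choice(idx_maj, size=min(len(idx_min), len(idx_maj)), replace=False)
            return np.concatenate([idx_min, idx_maj])
        raise RuntimeError("could not draw a two-class bag")

    def fit(self, seed: int = 0) -> "RidgeEnsembleResults":
        alpha, cv_table = self._grid_search(seed)
        x = self.X.to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        bags: list[_Bag] = []
        for _ in range(self.n_bags):
            idx = self._draw_bag(rng)
            xb, yb = x[idx], self.y[idx]
            mu, sd = xb.mean(axis=0), xb.std(axis=0)
            sd = sd.copy()
            sd[sd == 0] = 1.0
            clf = RidgeClassifier(alpha=alpha)
            clf.fit((xb - mu) / sd, yb)
            bags.append(_Bag(mu, sd, clf.coef_.ravel().copy(), float(clf.intercept_[0])))
        results = RidgeEnsembleResults(
            feature_names=tuple(self.X.columns.astype(str)),
            alpha=alpha,
            bags=tuple(bags),
            cv_table=cv_table,
            train_mean=x.mean(axis=0),
            train_sd=np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0)),
        )
        results._calibrate(x, self.y)
        results.train_auc = _metrics.auc(self.y, results.decision(self.X))
        results.train_acc = _metrics.accuracy(self.y, results.predict_proba(self.X))
        return results


@dataclass
class RidgeEnsembleResults:
    """Fitted easy-ensemble ridge model."""

    feature_names: tuple[str, ...]
    alpha: float
    bags: tuple[_Bag, ...]
    cv_table: pd.DataFrame
    train_mean: np.ndarray
    train_sd: np.ndarray
    calibrator: tuple[float, float] | None = None
    train_auc: float | None = None
    train_acc: float | None = None

    # -- pooled linear form ----------------------------------------------
    @property
    def coef_(self) -> np.ndarray:
        """Pooled coefficients in original feature units (the ensemble's
        decision score is exactly ``x @ coef_ + intercept_``)."""
        return np.mean([b.coef / b.sd for b in self.bags], axis=0)

    @property
    def intercept_(self) -> float:
        return float(np.mean([b.intercept - (b.coef * b.mean / b.sd).sum() for b in self.bags]))

    @property
    def coef_standardized_(self) -> np.ndarray:
        """Pooled coefficients per training-cohort SD (nomogram scale)."""
        return self.coef_ * self.train_sd

    @property
    def intercept_standardized_(self) -> float:
        """RadScore at the reference patient (every feature at its
        training-cohort mean)."""
        return self.intercept_ + float(self.train_mean @ self.coef_)

    def _matrix(self, X) -> np.ndarray:
        df = _as_frame(X)
        missing = [f for f in self.feature_names if f not in df.columns]
        if missing:
            raise KeyError(f"input is missing model features: {missing[:5]}")
        return df[list(self.feature_names)].to_numpy(dtype=float)

    def decision(self, X) -> np.ndarray:
        """Ensemble score: arithmetic mean of the bag decision scores."""
        x = self._matrix(X)
        return np.mean([b.decision(x) for b in self.bags], axis=0)

    def rad_score(self, X) -> np.ndarray:
        """RadScore: the pooled linear risk score underlying the nomogram
        (identical to the ensemble decision score)."""
        return self.decision(X)

    def _calibrate(self, x: np.ndarray, y: np.ndarray) -> None:
        scores = np.mean([b.decision(x) for b in self.bags], axis=0)
        lr = LogisticRegression(C=1e6)
        lr.fit(scores[:, None], y)
        self.calibrator = (float(lr.coef_[0, 0]), float(lr.intercept_[0]))

    def predict_proba(self, X) -> np.ndarray:
        """Event probability via the logistic calibration of the RadScore."""
        if self.calibrator is None:
            raise RuntimeError("model has no probability calibration")
        a, b = self.calibrator
        return expit(a * self.decision(X) + b)

    def summary(self) -> str:
        lines = [
            "Easy-ensemble ridge classifier",
            f"  features: {len(self.feature_names)}  bags: {len(self.bags)}  alpha: {self.alpha:g}",
        ]
        if self.train_auc is not None:
            lines.append(f"  training AUC {self.train_auc:.3f}  ACC {self.train_acc:.3f}")
        order = np.argsort(-np.abs(self.coef_standardized_))
        lines.append("  standardized coefficients:")
        for i in order:
            lines.append(f"    {self.feature_names[i]:<50s} {self.coef_standardized_[i]:+.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "alpha": self.alpha,
            "calibrator": self.calibrator,
            "bags": [
                {"mean": b.mean.tolist(), "sd": b.sd.tolist(),
                 "coef": b.coef.tolist(), "intercept": b.intercept}
                for b in self.bags
            ],
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
        }


class RepeatedSplitExperiment:
    """30 stratified 2/3-1/3 train-test repetitions of the ensemble model.

    When ``selection`` parameters are given, the bootstrap stability feature
    selection is re-run *inside every training cohort* before fitting, so the
    test metrics never see features chosen on their own data.  Without it the
    supplied feature matrix is used as-is (the published procedure: one
    selection per model variant, shared by all split models — required for
    the combined model and nomogram, but optimistic on null data).
    """

    def __init__(
        self,
        X,
        y: Sequence[int],
        n_splits: int = 30,
        train_frac: float = 2 / 3,
        selection: dict | None = None,
        **model_kwargs,
    ):
        self.X = _as_frame(X)
        self.y = np.asarray(y).astype(int)
        if len(self.y) < 30:
            raise ValueError("repeated splitting requires at least 30 patients")
        self.n_splits = int(n_splits)
        self.test_size = int(math.ceil(len(self.y) * (1.0 - train_frac)))
        self.selection = selection
        self.model_kwargs = model_kwargs

    def fit(self, seed: int = 0) -> "SplitExperimentResults":
        from .selection import select_features  # deferred: avoids module cycle

        splitter = StratifiedShuffleSplit(
            n_splits=self.n_splits, test_size=self.test_size, random_state=seed % 2**31,
        )
        records, models, splits, selected = [], [], [], []
        for k, (tr, te) in enumerate(splitter.split(np.zeros(len(self.y)), self.y)):
            split_seed = seed + 1000 * (k + 1)
            if self.selection is not None:
                report = select_features(self.X.iloc[tr], self.y[tr],
                                         seed=split_seed, **self.selection)
                feats = report.selected
            else:
                feats = list(self.X.columns)
            model = RidgeEnsembleClassifier(self.X.iloc[tr][feats], self.y[tr],
                                            **self.model_kwargs)
            res = model.fit(seed=split_seed)
            p_tr = res.predict_proba(self.X.iloc[tr])
            p_te = res.predict_proba(self.X.iloc[te])
            records.append({
                "split": k,
                "train_auc": _metrics.auc(self.y[tr], res.decision(self.X.iloc[tr])),
                "train_acc": _metrics.accuracy(self.y[tr], p_tr),
                "test_auc": _metrics.auc(self.y[te], res.decision(self.X.iloc[te])),
                "test_acc": _metrics.accuracy(self.y[te], p_te),
                "n_features": len(feats),
            })
            models.append(res)
            splits.append((tr.copy(), te.copy()))
            selected.append(feats)
        return SplitExperimentResults(
            records=pd.DataFrame(records).set_index("split"),
            models=models,
            splits=splits,
            feature_names=tuple(self.X.columns.astype(str)),
            n_patients=len(self.y),
            selected_per_split=selected,
        )


@dataclass
class SplitExperimentResults:
    records: pd.DataFrame
    models: list[RidgeEnsembleResults]
    splits: list[tuple[np.ndarray, np.ndarray]]
    feature_names: tuple[str, ...]
    n_patients: int
    selected_per_split: list[list[str]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD and 95% CI of AUC/ACC over the split series."""
        rows = []
        for metric in ("auc", "acc"):
            for cohort in ("train", "test"):
                s = _metrics.summarize(self.records[f"{cohort}_{metric}"])
                rows.append({
                    "metric": metric.upper(), "cohort": cohort,
                    "mean": s.mean, "sd": s.sd,
                    "ci_low": s.ci_low, "ci_high": s.ci_high,
                })
        return pd.DataFrame(rows)

    def combined(self) -> "RidgeEnsembleResults":
        return combine_models(self.models)


def combine_models(models: Sequence[RidgeEnsembleResults]) -> "CombinedEnsemble":
    """Super-ensemble: the combined score of any patient is the arithmetic
    mean of the member models' ensemble scores."""
    models = list(models)
    if not models:
        raise ValueError("combine_models requires at least one fitted model")
    names = models[0].feature_names
    if any(m.feature_names != names for m in models):
        raise ValueError("models disagree on the feature list")
    return CombinedEnsemble(tuple(models))


@dataclass
class CombinedEnsemble:
    """Average of fitted split models; exposes pooled linear coefficients for
    the nomogram."""

    members: tuple[RidgeEnsembleResults, ...]
    calibrator: tuple[float, float] | None = None

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.members[0].feature_names

    @property
    def coef_(self) -> np.ndarray:
        return np.mean([m.coef_ for m in self.members], axis=0)

    @property
    def intercept_(self) -> float:
        return float(np.mean([m.intercept_ for m in self.members]))

    @property
    def train_mean(self) -> np.ndarray:
        return np.mean([m.train_mean for m in self.members], axis=0)

    @property
    def train_sd(self) -> np.ndarray:
        return np.mean([m.train_sd for m in self.members], axis=0)

    @property
    def coef_standardized_(self) -> np.ndarray:
        return self.coef_ * self.train_sd

    def decision(self, X) -> np.ndarray:
        return np.mean([m.decision(X) for m in self.members], axis=0)

    rad_score = decision

    def calibrate(self, X, y: Sequence[int]) -> "CombinedEnsemble":
        scores = self.decision(X)
        lr = LogisticRegression(C=1e6)
        lr.fit(np.asarray(scores)[:, None], np.asarray(y).astype(int))
        self.calibrator = (float(lr.coef_[0, 0]), float(lr.intercept_[0]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.calibrator is None:
            raise RuntimeError("call calibrate(X, y) before predict_proba")
        a, b = self.calibrator
        return expit(a * self.decision(X) + b)


@dataclass
class NomogramTable:
    """Per-feature point mappings and the total-points -> probability map.

    ``total_points(x)`` rescales the RadScore affinely to [0, 100] over the
    observed cohort range; per-feature points are each feature's share of the
    total score range.  Probability is the calibrated logistic of the
    RadScore and is strictly increasing in total points.
    """

    table: pd.DataFrame
    score_range: tuple[float, float]
    calibrator: tuple[float, float]
    coef: np.ndarray
    intercept: float
    feature_names: tuple[str, ...]

    def rad_score(self, X) -> np.ndarray:
        df = _as_frame(X)
        x = df[list(self.feature_names)].to_numpy(dtype=float)
        return x @ self.coef + self.intercept

    def total_points(self, X) -> np.ndarray:
        smin, smax = self.score_range
        return 100.0 * (self.rad_score(X) - smin) / (smax - smin)

    def probability_at_total_points(self, tp) -> np.ndarray:
        """Read a probability off the nomogram's total-points axis."""
        smin, smax = self.score_range
        score = smin + np.asarray(tp, dtype=float) / 100.0 * (smax - smin)
        a, b = self.calibrator
        return expit(a * score + b)

    def probability(self, X) -> np.ndarray:
        return self.probability_at_total_points(self.total_points(X))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        meta = {
            "score_range": list(self.score_range),
            "calibrator": list(self.calibrator),
            "intercept": self.intercept,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
        return path


def build_nomogram(model, X) -> NomogramTable:
    """Nomogram table for a fitted (combined) ensemble over an observed cohort.

    Requires a calibrated model (probabilities defined).  The cohort supplies
    the observed feature ranges and the RadScore range used for the 0-100
    normalization.
    """
    if getattr(model, "calibrator", None) is None:
        raise RuntimeError("nomogram requires a probability-calibrated model")
    df = _as_frame(X)
    names = list(model.feature_names)
    x = df[names].to_numpy(dtype=float)
    coef = np.asarray(model.coef_, dtype=float)
    scores = x @ coef + model.intercept_
    smin, smax = float(scores.min()), float(scores.max())
    if smax <= smin:
        raise ValueError("degenerate cohort: RadScore has no observed range")
    fmin, fmax = x.min(axis=0), x.max(axis=0)
    contrib = np.abs(coef) * (fmax - fmin)
    share = contrib / contrib.sum() if contrib.sum() > 0 else contrib
    ref = getattr(model, "train_mean", x.mean(axis=0))
    if len(np.atleast_1d(ref)) != len(names):
        ref = x.mean(axis=0)
    table = pd.DataFrame({
        "feature": names,
        "coefficient": coef,
        "reference_value": np.asarray(ref, dtype=float),
        "axis_min": fmin,
        "axis_max": fmax,
        "points_per_unit": 100.0 * np.abs(coef) / (smax - smin),
        "points_share": 100.0 * share,
    })
    return NomogramTable(
        table=table,
        score_range=(smin, smax),
        calibrator=tuple(model.calibrator),
        coef=coef,
        intercept=float(model.intercept_),
        feature_names=tuple(names),
    )
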