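"""Replication-scale synthetic study runners.

These functions run the headline experiments of the package on the default
study conditions (161 patients, ~37 cc esophagus, 31.7% target prevalence):

* the *signal* experiment — planted effects on one GLCM contrast and one
  scale-invariant dose moment; 30 stratified 2/3-1/3 splits with the
  stability selection re-run inside each training cohort;
* the *recovery* sweep — across master seeds, do the planted features rank in
  the top decile of bootstrap-screening frequency, and does the final subset
  retain each planted signal (the feature itself or a |r| > 0.5 proxy kept by
  correlation pruning);
* the *null* calibration — cohorts with no planted effects, where the mean
  test AUC must hover at chance.

Extraction uses the reduced profiles (original image, bin counts {20, 50},
GLCM texture) so that repeated full-pipeline runs stay affordable; see the
methods note for the exact problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosiomics import DosiomicsConfig
from .metrics import summarize
from .model import RepeatedSplitExperiment
from .phantom import (Calibration, OutcomeModel, PhantomConfig,
                      calibrate_intercept, generate_cohort)
from .pipeline import extract_cohort_features
from .radiomics import RadiomicsConfig
from .selection import bootstrap_screen, select_features

__all__ = [
    "PLANTED_FEATURES",
    "SignalStudyResult",
    "build_cohort_table",
    "run_signal_experiment",
    "run_recovery_sweep",
    "run_null_calibration",
]

PLANTED_FEATURES = ("original_glcm_Contrast_bin20", "dose_moment_eta_200")


def _profiles() -> tuple[RadiomicsConfig, DosiomicsConfig]:
    return RadiomicsConfig.fast(), DosiomicsConfig.fast()


def build_cohort_table(config: PhantomConfig, calibration: Calibration | None = None):
    """Generate one cohort and its multi-omics feature table (fast profiles)."""
    cohort = generate_cohort(config, calibration=calibration)
    rad, dos = _profiles()
    table = extract_cohort_features(cohort.cases, rad, dos)
    return cohort, table


@dataclass
class SignalStudyResult:
    mean_test_auc: float
    sd_test_auc: float
    mean_train_auc: float
    mean_test_acc: float
    prevalence: float
    n_patients: int
    n_splits: int


def run_signal_experiment(seed: int, calibration: Calibration,
                          n_splits: int = 30) -> SignalStudyResult:
    """One cohort with planted effects, evaluated over repeated splits with
    in-training selection."""
    config = PhantomConfig(seed=seed)
    cohort, table = build_cohort_table(config, calibration)
    exp = RepeatedSplitExperiment(table.data, cohort.labels, n_splits=n_splits,
                                  selection={})
    results = exp.fit(seed=seed)
    test_auc = summarize(results.records["test_auc"])
    return SignalStudyResult(
        mean_test_auc=test_auc.mean,
        sd_test_auc=test_auc.sd,
        mean_train_auc=float(results.records["train_auc"].mean()),
        mean_test_acc=float(results.records["test_acc"].mean()),
        prevalence=cohort.prevalence,
        n_patients=cohort.n_patients,
        n_splits=n_splits,
    )


@dataclass
class RecoverySweepResult:
    n_seeds: int
    top_decile_hits: int          # seeds where BOTH planted rank in top decile
    final_subset_hits: int        # seeds where both planted clusters survive
    any_cluster_hits: int         # seeds where the subset carries planted signal
    pooled_prevalence: float
    per_seed_frequencies: list[dict[str, int]] = field(default_factory=list)


def run_recovery_sweep(master_seed: int, n_seeds: int = 10) -> RecoverySweepResult:
    """Across master seeds: screen frequencies + final-subset retention of the
    planted signals."""
    calibration = calibrate_intercept(PhantomConfig(seed=master_seed),
                                      n_mc=1000, seed=master_seed + 101)
    top_hits = subset_hits = any_hits = 0
    labels_pool = []
    freq_records = []
    for k in range(n_seeds):
        config = PhantomConfig(seed=master_seed + 1000 + k)
        cohort, table = build_cohort_table(config, calibration)
        labels_pool.append(cohort.labels)
        screen = bootstrap_screen(table.data, cohort.labels,
                                  seed=master_seed + 2000 + k)
        nonzero = screen[screen["frequency"] > 0]
        # top decile of the bootstrap-frequency distribution (ties included)
        q90 = float(np.quantile(nonzero["frequency"], 0.90))
        freq_records.append({name: int(screen.at[name, "frequency"])
                             for name in PLANTED_FEATURES})
        if all(screen.at[name, "frequency"] >= q90 for name in PLANTED_FEATURES):
            top_hits += 1
        report = select_features(table.data, cohort.labels,
                                 seed=master_seed + 3000 + k)
        corr = table.data.corr()
        cluster_hits = [
            any(abs(corr.at[name, kept]) > 0.5 or kept == name
                for kept in report.selected)
            for name in PLANTED_FEATURES
        ]
        if all(cluster_hits):
            subset_hits += 1
        if any(cluster_hits):
            any_hits += 1
    pooled = np.concatenate(labels_pool)
    return RecoverySweepResult(
        n_seeds=n_seeds,
        top_decile_hits=top_hits,
        final_subset_hits=subset_hits,
        any_cluster_hits=any_hits,
        pooled_prevalence=float(pooled.mean()),
        per_seed_frequencies=freq_records,
    )


def run_null_calibration(master_seed: int, n_cohorts: int = 3,
                         n_splits: int = 30) -> dict:
    """Cohorts with no planted effects: mean test AUC over all splits of all
    cohorts estimates the pipeline's null operating point."""
    per_cohort = []
    for k in range(n_cohorts):
        config = PhantomConfig(seed=master_seed + 5000 + k,
                               outcome_model=OutcomeModel.null())
        cohort, table = build_cohort_table(config)
        exp = RepeatedSplitExperiment(table.data, cohort.labels,
                                      n_splits=n_splits, selection={})
        results = exp.fit(seed=master_seed + 5000 + k)
        per_cohort.append(float(results.records["test_auc"].mean()))
    return {
        "per_cohort_mean_test_auc": per_cohort,
        "mean_test_auc": float(np.mean(per_cohort)),
        "n_cohorts": n_cohorts,
        "n_splits": n_splits,
    }
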