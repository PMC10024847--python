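"""End-to-end orchestration: simulate -> extract -> select -> train ->
evaluate -> nomogram, as one configured, seeded, file-chained run.

Stages communicate through files in the run directory (volumes as NRRD when
requested, feature tables as CSV with a JSON schema sidecar, reports as
JSON/CSV), so a rerun with the same config and seed reproduces identical
outputs.  The four model variants (cf/df/rf/hf) are routed by feature
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import metrics as _metrics
from .dosiomics import DosiomicsConfig, extract_dosiomics
from .features import MODEL_SETS, FeatureTable
from .model import RepeatedSplitExperiment, build_nomogram
from .phantom import (Cohort, PhantomCase, PhantomConfig, DoseModel,
                      HuTextureModel, OutcomeModel, encode_clinical,
                      generate_cohort)
from .radiomics import RadiomicsConfig, extract_radiomics
from .selection import SelectionReport, select_features
from .volume import (VolumeGrid, read_volume, refine_mask_by_hu, resample_isotropic,
                     resample_like, write_volume)

__all__ = [
    "RunConfig",
    "extract_case_features",
    "extract_cohort_features",
    "simulate_stage",
    "extract_stage",
    "select_stage",
    "train_stage",
    "run_all",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, plus the mandatory master seed."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig.fast)
    dosiomics: DosiomicsConfig = field(default_factory=DosiomicsConfig.fast)
    hu_window: tuple[float, float] = (-150.0, 180.0)
    hu_window_scope: str = "both"  # "both" | "ct_only"
    selection: dict = field(default_factory=dict)
    modeling: dict = field(default_factory=dict)
    n_splits: int = 30
    model_sets: tuple[str, ...] = ("cf", "df", "rf", "hf")
    seed: int = 0
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if self.hu_window_scope not in ("both", "ct_only"):
            raise ValueError("hu_window_scope must be 'both' or 'ct_only'")
        unknown = set(self.model_sets) - set(MODEL_SETS)
        if unknown:
            raise ValueError(f"unknown model sets {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: Mapping, seed: int | None = None) -> "RunConfig":
        kwargs: dict = {}
        ph = dict(raw.get("phantom", {}))
        for key, klass in (("hu_texture", HuTextureModel), ("dose_model", DoseModel),
                           ("outcome_model", OutcomeModel)):
            if key in ph:
                sub = dict(ph[key])
                if key == "outcome_model" and "planted" in sub:
                    sub["planted"] = tuple((str(k), float(v)) for k, v in dict(sub["planted"]).items())
                ph[key] = klass(**sub)
        for tup_key in ("grid_shape", "spacing_mm"):
            if tup_key in ph:
                ph[tup_key] = tuple(ph[tup_key])
        if seed is not None:
            ph["seed"] = seed
        kwargs["phantom"] = PhantomConfig(**ph)
        for key, klass in (("radiomics", RadiomicsConfig), ("dosiomics", DosiomicsConfig)):
            spec = raw.get(key, "fast")
            if spec == "fast":
                kwargs[key] = klass.fast()
            elif spec in ("default", "paper"):
                kwargs[key] = klass()
            else:
                sub = dict(spec)
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = klass(**sub)
        for key in ("hu_window_scope", "selection", "modeling", "n_splits",
                    "write_volumes"):
            if key in raw:
                kwargs[key] = raw[key]
        if "hu_window" in raw:
            kwargs["hu_window"] = tuple(raw["hu_window"])
        if "model_sets" in raw:
            kwargs["model_sets"] = tuple(raw["model_sets"])
        kwargs["seed"] = seed if seed is not None else int(raw.get("seed", 0))
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_case_features(
    ct: VolumeGrid,
    dose: VolumeGrid,
    mask: VolumeGrid,
    clinical: Mapping[str, object] | None = None,
    radiomics_config: RadiomicsConfig | None = None,
    dosiomics_config: DosiomicsConfig | None = None,
    hu_window: tuple[float, float] = (-150.0, 180.0),
    hu_window_scope: str = "both",
) -> tuple[dict[str, float], dict[str, str]]:
    """Full multi-omics vector of one patient, with provenance tags.

    Volumes are resampled to isotropic 1 mm, the dose is enforced onto the CT
    grid, and the mask is refined by the HU window before extraction.
    """
    ct_r = resample_isotropic(ct, (1.0, 1.0, 1.0), "linear")
    mask_r = resample_isotropic(mask, (1.0, 1.0, 1.0), "nearest")
    dose_r = resample_like(dose, ct_r, "linear")
    refined = refine_mask_by_hu(ct_r, mask_r, hu_window)
    dose_mask = refined if hu_window_scope == "both" else mask_r
    features: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for name, value in extract_radiomics(ct_r, refined, radiomics_config).items():
        features[name] = value
        provenance[name] = "radiomic"
    for name, value in extract_dosiomics(dose_r, dose_mask, dosiomics_config).items():
        features[name] = value
        provenance[name] = "dosiomic"
    if clinical is not None:
        for name, value in encode_clinical(clinical).items():
            features[name] = value
            provenance[name] = "clinical"
    return features, provenance


def extract_cohort_features(
    cases: Sequence[PhantomCase],
    radiomics_config: RadiomicsConfig | None = None,
    dosiomics_config: DosiomicsConfig | None = None,
    hu_window: tuple[float, float] = (-150.0, 180.0),
    hu_window_scope: str = "both",
) -> FeatureTable:
    rows, provenance = [], {}
    for case in cases:
        feats, prov = extract_case_features(
            case.ct, case.dose, case.mask,
            {k: v for k, v in case.clinical.items() if k != "latents"},
            radiomics_config, dosiomics_config, hu_window, hu_window_scope,
        )
        rows.append(feats)
        provenance = prov
    return FeatureTable.from_records(rows, provenance)


# ---------------------------------------------------------------------------
# Stages (file-chained)
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig, out_dir: str | Path) -> Cohort:
    """Generate the cohort; write cohort.csv (and volume triplets when
    requested)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.phantom)
    frame = cohort.clinical_frame
    frame.insert(0, "patient_id", [f"P{i:04d}" for i in range(cohort.n_patients)])
    frame.to_csv(out / "cohort.csv", index=False)
    if config.write_volumes:
        vol_dir = out / "volumes"
        for i, case in enumerate(cohort.cases):
            pid = f"P{i:04d}"
            write_volume(case.ct, vol_dir / pid / "ct.nrrd")
            write_volume(case.dose, vol_dir / pid / "dose.nrrd")
            write_volume(case.mask, vol_dir / pid / "mask.nrrd")
    return cohort


def extract_stage(config: RunConfig, out_dir: str | Path,
                  cohort: Cohort | None = None) -> FeatureTable:
    """Extract multi-omics features and write features.csv (+ schema).

    If no in-memory cohort is supplied, volumes and clinical data are read
    back from the files the simulate stage wrote.
    """
    out = Path(out_dir)
    frame = pd.read_csv(out / "cohort.csv")
    if cohort is not None:
        table = extract_cohort_features(
            cohort.cases, config.radiomics, config.dosiomics,
            config.hu_window, config.hu_window_scope,
        )
    else:
        rows, provenance = [], {}
        for pid, clin in zip(frame["patient_id"],
                             frame.drop(columns=["patient_id", "label"]).to_dict("records")):
            vol_dir = out / "volumes" / pid
            feats, provenance = extract_case_features(
                read_volume(vol_dir / "ct.nrrd"),
                read_volume(vol_dir / "dose.nrrd"),
                read_volume(vol_dir / "mask.nrrd"),
                clin, config.radiomics, config.dosiomics,
                config.hu_window, config.hu_window_scope,
            )
            rows.append(feats)
        table = FeatureTable.from_records(rows, provenance)
    table.data.index = frame["patient_id"]
    table.to_csv(out / "features.csv")
    return table


def select_stage(config: RunConfig, out_dir: str | Path,
                 model_set: str) -> SelectionReport:
    """Feature selection for one model variant, from features.csv on disk."""
    out = Path(out_dir)
    table = FeatureTable.read_csv(out / "features.csv")
    labels = pd.read_csv(out / "cohort.csv")["label"].to_numpy()
    subset = table.model_set(model_set)
    report = select_features(subset, labels, seed=config.seed, **config.selection)
    report.to_json(out / f"selection_{model_set}.json")
    (out / f"selected_{model_set}.txt").write_text("\n".join(report.selected) + "\n")
    return report


def train_stage(config: RunConfig, out_dir: str | Path, model_set: str):
    """Repeated-split training/evaluation for one model variant.

    The stability selection is re-run inside every training cohort, so the
    recorded test metrics are free of selection leakage.
    """
    out = Path(out_dir)
    table = FeatureTable.read_csv(out / "features.csv")
    labels = pd.read_csv(out / "cohort.csv")["label"].to_numpy()
    X = table.model_set(model_set).data
    experiment = RepeatedSplitExperiment(X, labels, n_splits=config.n_splits,
                                         selection=dict(config.selection),
                                         **config.modeling)
    results = experiment.fit(seed=config.seed)
    results.records.to_csv(out / f"records_{model_set}.csv")
    (out / f"model_{model_set}.json").write_text(
        json.dumps([m.to_dict() for m in results.models], indent=1))
    return results


def nomogram_stage(config: RunConfig, out_dir: str | Path, model_set: str,
                   results=None) -> None:
    """Combined model + nomogram on the cohort-level selected features (the
    published-style final model: the 30 split models share one feature list)."""
    out = Path(out_dir)
    table = FeatureTable.read_csv(out / "features.csv")
    labels = pd.read_csv(out / "cohort.csv")["label"].to_numpy()
    selected = (out / f"selected_{model_set}.txt").read_text().split()
    X = table.data[selected]
    experiment = RepeatedSplitExperiment(X, labels, n_splits=config.n_splits,
                                         **config.modeling)
    shared = experiment.fit(seed=config.seed)
    combined = shared.combined().calibrate(X, labels)
    nomogram = build_nomogram(combined, X)
    nomogram.to_csv(out / f"nomogram_{model_set}.csv")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """The full four-model comparison; rerunning with the same config and
    seed reproduces identical CSV/JSON outputs."""
    import hashlib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    (out / "run_config.json").write_text(json.dumps(
        {"seed": config.seed, "model_sets": list(config.model_sets),
         "n_patients": config.phantom.n_patients,
         "config_hash": config_hash}, indent=1))
    cohort = simulate_stage(config, out)
    extract_stage(config, out, cohort=None if config.write_volumes else cohort)
    results = {}
    for model_set in config.model_sets:
        select_stage(config, out, model_set)
        results[model_set] = train_stage(config, out, model_set)
    summary = _metrics.performance_table({k: v.records for k, v in results.items()})
    summary.to_csv(out / "summary.csv", index=False)
    if "hf" in results:
        nomogram_stage(config, out, "hf")
    _write_report(out, summary)
    return {"cohort": cohort, "results": results, "summary": summary, "out_dir": out}


def _write_report(out: Path, summary: pd.DataFrame) -> None:
    lines = ["# Model performance over repeated train-test splits", ""]
    header = "| model | metric | train (mean ± SD) | train 95% CI | test (mean ± SD) | test 95% CI |"
    lines += [header, "|" + "---|" * 6]
    for _, row in summary.iterrows():
        lines.append(
            f"| {row['model']} | {row['metric']} "
            f"| {row['train_mean']:.3f} ± {row['train_sd']:.3f} "
            f"| [{row['train_ci_low']:.2f}, {row['train_ci_high']:.2f}] "
            f"| {row['test_mean']:.3f} ± {row['test_sd']:.3f} "
            f"| [{row['test_ci_low']:.2f}, {row['test_ci_high']:.2f}] |"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
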