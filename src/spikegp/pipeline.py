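"""Experiment runner: patient grouping, three-stage workflow, manifests.

Ties the stages together the way the clinical study is organized: a pool
of training patients is split at the *patient* level into a KNN-reference
group and a GP-validation group (preventing leakage between them), the
formula is evolved, and the frozen formula + reference points are applied
to an entirely disjoint set of evaluation patients.  Every run writes its
configuration and seeds to a YAML manifest from which it can be re-executed
bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import ConfusionCounts, report_text
from .gp import FitnessContext, GPConfig
from .model import SpikeDetector, SpikeDetectorResults
from .preprocess import (
    FEATURE_NAMES,
    SPIKE,
    Recording,
    SegmentationConfig,
    feature_table,
)
from .simulate import AnnotatedRecording, SimulationConfig, simulate


class DataError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Whole-workflow configuration mirroring the study design.

    Eight training patients (4 reference + 4 validation) feed the GP
    stage; the remaining patients are held out for classification-stage
    evaluation.  Groups are class-balanced by seeded undersampling and
    capped at `max_per_class` segments per class, keeping the wrapper
    KNN small.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    knn_k: int = 100
    n_reference_patients: int = 4
    n_validation_patients: int = 4
    balance_seed: int = 0
    max_per_class: int | None = 200

    def __post_init__(self) -> None:
        if self.n_reference_patients < 1 or self.n_validation_patients < 1:
            raise ValueError("group sizes must be >= 1")


def _balanced_subsample(features: np.ndarray, labels: np.ndarray,
                        rng: np.random.Generator,
                        max_per_class: int | None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    pos = np.flatnonzero(labels == SPIKE)
    neg = np.flatnonzero(labels != SPIKE)
    if pos.size == 0:
        raise DataError("group contains zero spike segments")
    if neg.size == 0:
        raise DataError("group contains zero nonspike segments")
    n = min(pos.size, neg.size)
    if max_per_class is not None:
        n = min(n, max_per_class)
    take = np.concatenate([
        rng.choice(pos, size=n, replace=False),
        rng.choice(neg, size=n, replace=False),
    ])
    take.sort()
    return features[take], labels[take]


def build_groups(feature_tables: Sequence[pd.DataFrame],
                 n_reference: int = 4, n_validation: int = 4,
                 balance_seed: int = 0, k: int = 100,
                 max_per_class: int | None = 200,
                 ) -> tuple[FitnessContext, dict[str, list[int]]]:
    """Patient-level split into balanced reference/validation groups.

    `feature_tables` holds one labeled feature table per patient (columns
    X1..X8 and label).  The first `n_reference` patients form the KNN
    reference group and the next `n_validation` the GP validation group;
    within each group the majority class is randomly undersampled (seeded)
    to the minority count, then both classes are capped at
    `max_per_class`.  Returns the fitness context and the patient
    assignment {"reference": [...], "validation": [...]}.
    """
    if len(feature_tables) < n_reference + n_validation:
        raise DataError(
            f"need >= {n_reference + n_validation} patients, "
            f"got {len(feature_tables)}")
    rng = np.random.default_rng(balance_seed)
    assignment = {
        "reference": list(range(n_reference)),
        "validation": list(range(n_reference, n_reference + n_validation)),
    }

    def stack(idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
        df = pd.concat([feature_tables[i] for i in idx], ignore_index=True)
        return df[list(FEATURE_NAMES)].to_numpy(float), \
            df["label"].to_numpy(int)

    ref_f, ref_l = _balanced_subsample(*stack(assignment["reference"]),
                                       rng, max_per_class)
    val_f, val_l = _balanced_subsample(*stack(assignment["validation"]),
                                       rng, max_per_class)
    ctx = FitnessContext(ref_f, ref_l, val_f, val_l,
                         k=min(k, ref_l.size))
    return ctx, assignment


@dataclass
class PipelineResult:
    results: SpikeDetectorResults
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts
    assignment: dict[str, list[int]]


def run_pipeline(
    training: Sequence[AnnotatedRecording],
    evaluation: Sequence[AnnotatedRecording],
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    manifest_extra: dict | None = None,
) -> PipelineResult:
    """Preprocess -> group -> evolve -> freeze -> detect+evaluate.

    Training and evaluation recordings must be disjoint sets of patients;
    the evaluation stage reuses the reference points frozen in the GP
    stage (patient-independent detection).
    """
    tables = [
        feature_table(ar.recording, cfg.segmentation, ar.events)
        for ar in training
    ]
    ctx, assignment = build_groups(
        tables, cfg.n_reference_patients, cfg.n_validation_patients,
        cfg.balance_seed, cfg.knn_k, cfg.max_per_class)
    overlap = set(assignment["reference"]) & set(assignment["validation"])
    if overlap:
        raise DataError(f"patients in both groups: {sorted(overlap)}")

    detector = SpikeDetector(
        ctx.reference_features, ctx.reference_labels,
        ctx.validation_features, ctx.validation_labels,
        seg_cfg=cfg.segmentation, gp_config=cfg.gp, knn_k=cfg.knn_k)
    results = detector.fit()

    sens, spec, counts = results.evaluate(
        [(ar.recording, ar.events) for ar in evaluation])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "formula.sexp").write_text(results.formula_sexp + "\n")
        results.knn.to_tsv(out / "reference_points.tsv")
        pd.DataFrame({
            "generation": np.arange(results.trace.size),
            "best_error": results.trace,
        }).to_csv(out / "fitness_trace.tsv", sep="\t", index=False)
        (out / "evaluation.txt").write_text(report_text(sens, spec, counts))
        manifest = {
            "spikegp_version": __version__,
            "config": _config_dict(cfg),
            "patient_assignment": assignment,
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(results=results, sensitivity=sens,
                          specificity=spec, counts=counts,
                          assignment=assignment)


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["gp"]["terminal_subset"] = list(cfg.gp.terminal_subset)
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    seg = SegmentationConfig(**d.get("segmentation", {}))
    gp_d = dict(d.get("gp", {}))
    if "terminal_subset" in gp_d:
        gp_d["terminal_subset"] = tuple(gp_d["terminal_subset"])
    gp = GPConfig(**gp_d)
    rest = {key: d[key] for key in (
        "knn_k", "n_reference_patients", "n_validation_patients",
        "balance_seed", "max_per_class") if key in d}
    return ExperimentConfig(segmentation=seg, gp=gp, **rest)


# ---------------------------------------------------------------------------
# fully synthetic experiment (the desk-scale stand-in for the clinical study)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudyConfig:
    """Simulated cohort mirroring the study layout at desk scale.

    8 training patients feed the GP stage and `n_evaluation_patients`
    held-out patients the classification stage; per-patient durations are
    kept short enough for interactive runs while leaving hundreds of
    spike windows in each stage.
    """

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    n_evaluation_patients: int = 20
    training_duration_s: float = 30.0
    evaluation_duration_s: float = 15.0
    n_channels: int = 26
    spike_rate: float = 10.0
    snr: float = 5.0
    seed: int = 0


def patient_seeds(seed: int, n: int) -> list[int]:
    """Independent per-patient child seeds, each below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def simulate_cohort(cfg: SyntheticStudyConfig,
                    ) -> tuple[list[AnnotatedRecording],
                               list[AnnotatedRecording]]:
    n_train = (cfg.experiment.n_reference_patients
               + cfg.experiment.n_validation_patients)
    seeds = patient_seeds(cfg.seed, n_train + cfg.n_evaluation_patients)
    training = [
        simulate(SimulationConfig(
            duration_s=cfg.training_duration_s, n_channels=cfg.n_channels,
            spike_rate=cfg.spike_rate, snr=cfg.snr, rng_seed=s))
        for s in seeds[:n_train]
    ]
    evaluation = [
        simulate(SimulationConfig(
            duration_s=cfg.evaluation_duration_s, n_channels=cfg.n_channels,
            spike_rate=cfg.spike_rate, snr=cfg.snr, rng_seed=s))
        for s in seeds[n_train:]
    ]
    return training, evaluation


def run_synthetic_experiment(cfg: SyntheticStudyConfig,
                             out_dir: str | Path | None = None,
                             ) -> PipelineResult:
    training, evaluation = simulate_cohort(cfg)
    extra = {
        "synthetic_study": {
            "seed": cfg.seed,
            "n_evaluation_patients": cfg.n_evaluation_patients,
            "training_duration_s": cfg.training_duration_s,
            "evaluation_duration_s": cfg.evaluation_duration_s,
            "n_channels": cfg.n_channels,
            "spike_rate": cfg.spike_rate,
            "snr": cfg.snr,
        },
    }
    return run_pipeline(training, evaluation, cfg.experiment,
                        out_dir=out_dir, manifest_extra=extra)


def run_from_manifest(path: str | Path,
                      out_dir: str | Path | None = None) -> PipelineResult:
    """Re-execute a synthetic run from its manifest, bit-identically."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if "synthetic_study" not in manifest:
        raise DataError("manifest does not describe a synthetic run")
    syn = manifest["synthetic_study"]
    cfg = SyntheticStudyConfig(
        experiment=config_from_dict(manifest["config"]), **syn)
    return run_synthetic_experiment(cfg, out_dir=out_dir)
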