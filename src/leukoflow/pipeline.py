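"""End-to-end three-phase workflow on a cohort manifest.

Phase II trains the per-event EverFlow classifier on pooled, manually-labeled
events from training patients (amalgamating identical cell types across
patients); gating the cohort with that model yields each patient's AI-derived
cellular composition; Phase III trains the patient-level classifier on those
compositions; Phase I (diagnosis straight from raw event clouds via density
images) is optional. Evaluation is always on a held-out stratified test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alot_synth import SimConfig, default_phenotypes, default_templates, simulate_cohort
from .errors import DegenerateTraining
from .evaluation import FoldSplit, MetricsReport, evaluate_predictions, split_cohort
from .everflow_model import (
    EventClassifier,
    EverFlowConfig,
    classify_events,
    per_class_recall,
    train_event_classifier,
)
from .features import (
    CompositionVector,
    composition_vector,
    composition_with_summaries,
    transform_events,
)
from .fcs_io import read_fcs, read_label_sidecar
from .patient_model import (
    PatientClassifier,
    PatientModelConfig,
    predict_patients,
    train_phase1,
    train_phase3,
)
from .vocab import CELL_TYPES, DIAGNOSES


def pool_labeled_events(
    manifest: pd.DataFrame,
    max_per_class: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool transformed events + sidecar labels across samples, capped per class.

    Mirrors manual gating practice: identical cell types from different
    patients are amalgamated into one training pool.
    """
    rng = np.random.default_rng(seed)
    xs, ls = [], []
    for row in manifest.itertuples(index=False):
        em = read_fcs(row.fcs_path, sample_id=row.sample_id)
        labels = read_label_sidecar(row.label_path, em.n_events)
        xs.append(transform_events(em))
        ls.append(labels)
    X = np.concatenate(xs)
    labels = np.concatenate(ls)
    keep = []
    for c in CELL_TYPES:
        idx = np.flatnonzero(labels == c)
        if len(idx) > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False)
        keep.append(idx)
    keep = rng.permutation(np.concatenate(keep))
    return X[keep], labels[keep]


def gate_cohort(
    model: EventClassifier,
    manifest: pd.DataFrame,
    with_summaries: bool = False,
) -> list[CompositionVector]:
    """AI-gate every sample: per-event labels -> composition vector per patient."""
    out = []
    for row in manifest.itertuples(index=False):
        em = read_fcs(row.fcs_path, sample_id=row.sample_id)
        labels, _ = classify_events(model, em)
        if with_summaries:
            out.append(composition_with_summaries(em, labels))
        else:
            out.append(composition_vector(labels, sample_id=row.sample_id))
    return out


@dataclass
class PipelineResult:
    manifest: pd.DataFrame
    split: FoldSplit
    event_model: EventClassifier
    patient_model: PatientClassifier
    report: MetricsReport
    event_recall: dict[str, float | None]
    test_true: np.ndarray
    test_pred: np.ndarray
    phase1_model: PatientClassifier | None = None
    phase1_report: MetricsReport | None = None


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    n_patients_per_diagnosis: dict[str, int] | None = None,
    n_events: int = 3000,
    separation: float = 1.0,
    pool_per_class: int = 2000,
    with_summaries: bool = False,
    everflow_config: EverFlowConfig | None = None,
    patient_config: PatientModelConfig | None = None,
    include_phase1: bool = False,
    test_fraction: float = 0.2,
) -> PipelineResult:
    """Simulate a cohort, run the three-phase workflow, evaluate on held-out data."""
    out_dir = Path(out_dir)
    if n_patients_per_diagnosis is None:
        n_patients_per_diagnosis = {d: 20 for d in DIAGNOSES}
    sim = SimConfig(
        n_patients_per_diagnosis=n_patients_per_diagnosis,
        n_events=n_events,
        seed=seed,
        templates=default_templates(separation),
        phenotypes=default_phenotypes(),
    )
    manifest_path = simulate_cohort(sim, out_dir / "cohort")
    manifest = pd.read_csv(manifest_path, dtype=str)
    split = split_cohort(manifest, test_fraction=test_fraction, seed=seed)

    train_manifest = manifest[manifest["sample_id"].isin(split.train_ids)]
    test_manifest = manifest[manifest["sample_id"].isin(split.test_ids)]

    # Phase II: per-event classifier on the pooled manually-labeled events.
    X_pool, y_pool = pool_labeled_events(
        train_manifest, max_per_class=pool_per_class, seed=seed + 1
    )
    ef_cfg = everflow_config if everflow_config is not None else EverFlowConfig(
        seed=seed + 1
    )
    event_model = train_event_classifier(X_pool, y_pool, ef_cfg)

    # Per-event recall measured on events from held-out patients only.
    X_test_pool, y_test_pool = pool_labeled_events(
        test_manifest, max_per_class=pool_per_class, seed=seed + 2
    )
    from .everflow_model import classify_transformed

    pred_pool, _ = classify_transformed(event_model, X_test_pool)
    event_recall = per_class_recall(y_test_pool, pred_pool)

    # Phase III: patient classifier on AI-derived compositions.
    comp_train = gate_cohort(event_model, train_manifest, with_summaries)
    comp_test = gate_cohort(event_model, test_manifest, with_summaries)
    pm_cfg = patient_config if patient_config is not None else PatientModelConfig(
        seed=seed + 3, batch_size=16
    )
    pmodel = train_phase3(
        comp_train,
        train_manifest["diagnosis"].to_numpy(),
        with_summaries=with_summaries,
        config=pm_cfg,
    )
    test_pred, _ = predict_patients(pmodel, comp_test)
    report = evaluate_predictions(split, test_manifest, test_pred)

    result = PipelineResult(
        manifest=manifest,
        split=split,
        event_model=event_model,
        patient_model=pmodel,
        report=report,
        event_recall=event_recall,
        test_true=test_manifest["diagnosis"].to_numpy(),
        test_pred=test_pred,
    )

    if include_phase1:
        p1_cfg = patient_config if patient_config is not None else PatientModelConfig(
            seed=seed + 4
        )
        result.phase1_model = train_phase1(train_manifest, p1_cfg)
        from .patient_model import density_images_from_manifest

        X1, _, _ = density_images_from_manifest(test_manifest, p1_cfg)
        p1_pred, _ = predict_patients(result.phase1_model, X1)
        result.phase1_report = evaluate_predictions(split, test_manifest, p1_pred)
    return result
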