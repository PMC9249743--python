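"""End-to-end cross-validated pipeline and the equal-budget single-CNN baseline.

Folds are assigned at patient level with class stratification, so no
patient's images ever straddle a fold's train/test boundary.  Per fold, the
training half is split into n disjoint subsets, one CNN is trained per
subset (train = fold minus subset, validation = subset), the CNN margins
form the feature matrix, a Gini forest is grown on it, and the held-out
fold is scored by feeding each test image through the n CNNs and voting the
forest.  The baseline trains one CNN per fold on the whole training half
with an epoch budget of n_cnns x epochs ("matched").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cnn import (
    CnnSpec,
    FeatureExtractor,
    build_feature_matrix,
    partition_subsets,
    train_cnn,
)
from .forest import ForestModel, ForestParams, build_forest, predict_forest_matrix
from .io import Dataset
from .metrics import MetricsReport, compute_metrics

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Patient-level fold assignment for k-fold cross-validation."""

    k: int
    assignment: dict[str, int]  # patient_id -> fold index

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds.issubset(set(range(self.k))):
            raise ValueError("fold indices must lie in [0, k)")

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)

    def image_indices(self, dataset: Dataset, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for the given held-out fold."""
        pids = dataset.patient_ids
        test = np.array([i for i, p in enumerate(pids) if self.assignment[p] == fold])
        train = np.array([i for i, p in enumerate(pids) if self.assignment[p] != fold])
        return train, test


def assign_patient_folds(
    patient_labels: Mapping[str, int], k: int, rng_seed: int | np.random.SeedSequence
) -> dict[str, int]:
    """Stratified patient-level fold assignment.

    Patients of each class are shuffled and dealt round-robin, the dealing
    pointer carrying over between classes, so per-fold class counts match
    the global proportions within one patient.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng_seed)
    assignment: dict[str, int] = {}
    pointer = int(rng.integers(k))
    for cls in sorted(set(patient_labels.values())):
        patients = sorted(p for p, lab in patient_labels.items() if lab == cls)
        if len(patients) < k:
            raise ValueError(
                f"class {cls} has only {len(patients)} patients; need at least k={k}"
            )
        order = rng.permutation(len(patients))
        for idx in order:
            assignment[patients[idx]] = pointer % k
            pointer += 1
    return assignment


def stratified_group_kfold(
    dataset: Dataset, k: int = 5, rng_seed: int | np.random.SeedSequence = 0
) -> FoldPlan:
    """Build a :class:`FoldPlan` for a dataset (all of a patient's images together)."""
    return FoldPlan(k=k, assignment=assign_patient_folds(dataset.patient_labels, k, rng_seed))


@dataclass
class PipelineConfig:
    n_cnns: int = 10
    folds: int = 5
    cnn_spec: CnnSpec = field(default_factory=CnnSpec)
    forest_params: ForestParams = field(default_factory=ForestParams)
    optimizer: str | None = None  # overrides cnn_spec.optimizer when set
    global_seed: int = 0
    baseline_epoch_budget: str | int = "matched"

    def __post_init__(self) -> None:
        if self.n_cnns < 2:
            raise ValueError("n_cnns must be >= 2")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if isinstance(self.baseline_epoch_budget, str) and self.baseline_epoch_budget != "matched":
            raise ValueError("baseline_epoch_budget must be 'matched' or an int")

    def effective_spec(self) -> CnnSpec:
        spec = CnnSpec.from_dict(self.cnn_spec.to_dict())
        if self.optimizer is not None:
            spec.optimizer = self.optimizer
        return spec

    def baseline_epochs(self) -> int:
        if self.baseline_epoch_budget == "matched":
            return self.n_cnns * self.cnn_spec.epochs
        return int(self.baseline_epoch_budget)


@dataclass
class FoldResult:
    fold: int
    forest: ForestModel
    extractors: list[FeatureExtractor]
    metrics: MetricsReport
    test_indices: np.ndarray
    predictions: np.ndarray
    vote_fractions: np.ndarray


def _check_no_leakage(dataset: Dataset, train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    pids = dataset.patient_ids
    shared = {pids[i] for i in train_idx} & {pids[i] for i in test_idx}
    if shared:
        raise AssertionError(f"patient leakage between train and test: {sorted(shared)[:5]}")


def run_fold(
    dataset: Dataset, plan: FoldPlan, fold_index: int, config: PipelineConfig
) -> FoldResult:
    """Execute one cross-validation iteration (train ensemble, score held-out fold)."""
    if not 0 <= fold_index < plan.k:
        raise ValueError(f"fold_index must be in [0, {plan.k})")
    spec = config.effective_spec()
    train_idx, test_idx = plan.image_indices(dataset, fold_index)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError(f"fold {fold_index} has an empty train or test side")
    _check_no_leakage(dataset, train_idx, test_idx)
    labels = dataset.labels
    if len(np.unique(labels[train_idx])) < 2:
        raise ValueError(f"fold {fold_index}: training half lacks a class")

    subsets = partition_subsets(
        train_idx,
        labels[train_idx],
        config.n_cnns,
        np.random.SeedSequence([config.global_seed, fold_index, 1001]),
    )
    extractors = []
    for i, val_ids in enumerate(subsets):
        cnn_train = np.setdiff1d(train_idx, val_ids)
        extractors.append(
            train_cnn(
                cnn_train,
                val_ids,
                dataset,
                spec,
                np.random.SeedSequence([config.global_seed, fold_index, i]),
            )
        )
        logger.info("fold %d: trained cnn %d/%d", fold_index, i + 1, config.n_cnns)

    P = build_feature_matrix(extractors, train_idx, dataset)
    fparams = ForestParams.from_dict(config.forest_params.to_dict())
    fparams.rng_seed = int(
        np.random.SeedSequence([config.global_seed, fold_index, 2002]).generate_state(1)[0]
    )
    forest = build_forest(P.values, labels[train_idx], fparams)

    x_test = dataset.pixel_stack(test_idx)
    test_features = np.stack([ext.score(x_test) for ext in extractors], axis=1)
    preds, fracs = predict_forest_matrix(forest, test_features)
    metrics = compute_metrics(labels[test_idx], preds, fracs)
    logger.info("fold %d: accuracy %.4f on %d test images", fold_index, metrics.accuracy, len(test_idx))
    return FoldResult(
        fold=fold_index,
        forest=forest,
        extractors=extractors,
        metrics=metrics,
        test_indices=test_idx,
        predictions=preds,
        vote_fractions=fracs,
    )


def _pool_fold_outputs(
    dataset: Dataset, fold_outputs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    per_fold: list[MetricsReport],
) -> MetricsReport:
    labels = dataset.labels
    all_idx = np.concatenate([o[0] for o in fold_outputs])
    all_pred = np.concatenate([o[1] for o in fold_outputs])
    all_score = np.concatenate([o[2] for o in fold_outputs])
    report = compute_metrics(labels[all_idx], all_pred, all_score)
    report.per_fold = per_fold
    return report


def run_pipeline(
    dataset: Dataset,
    config: PipelineConfig,
    plan: FoldPlan | None = None,
    collect_models: bool = False,
) -> MetricsReport | tuple[MetricsReport, list[FoldResult]]:
    """Full k-fold run; pools fold confusion tables into one report.

    The pooled confusion table is the element-wise sum of the per-fold
    tables (every image is scored exactly once, by the fold holding it out).
    """
    plan = plan or stratified_group_kfold(
        dataset, config.folds, np.random.SeedSequence([config.global_seed, 555])
    )
    results = [run_fold(dataset, plan, k, config) for k in range(plan.k)]
    report = _pool_fold_outputs(
        dataset,
        [(r.test_indices, r.predictions, r.vote_fractions) for r in results],
        [r.metrics for r in results],
    )
    logger.info("pooled accuracy %.4f over %d images", report.accuracy, report.n)
    if collect_models:
        return report, results
    return report


def run_baseline_cnn(
    dataset: Dataset, plan: FoldPlan, config: PipelineConfig
) -> MetricsReport:
    """Single-CNN comparator trained per fold with a matched epoch budget.

    Trains on the entire training half (no validation subset, final-epoch
    weights) for ``n_cnns x epochs`` epochs by default; the sign of the
    margin is the predicted class and the margin itself the ranking score.
    """
    spec = config.effective_spec()
    spec.epochs = config.baseline_epochs()
    spec.select_best_epoch = False
    labels = dataset.labels
    outputs, per_fold = [], []
    for k in range(plan.k):
        train_idx, test_idx = plan.image_indices(dataset, k)
        _check_no_leakage(dataset, train_idx, test_idx)
        extractor = train_cnn(
            train_idx,
            None,
            dataset,
            spec,
            np.random.SeedSequence([config.global_seed, k, 777]),
        )
        scores = extractor.score(dataset.pixel_stack(test_idx))
        preds = (scores > 0).astype(np.int64)
        per_fold.append(compute_metrics(labels[test_idx], preds, scores))
        outputs.append((test_idx, preds, scores))
        logger.info("baseline fold %d: accuracy %.4f", k, per_fold[-1].accuracy)
    return _pool_fold_outputs(dataset, outputs, per_fold)


def predictions_tsv(
    dataset: Dataset, results: Sequence[FoldResult], out: str | Path
) -> Path:
    """Write per-image predictions (one row per held-out image) as TSV."""
    out = Path(out)
    lines = ["sample_id\tpatient_id\tfold\ttrue_label\tpredicted_label\tvote_fraction"]
    for r in results:
        for idx, pred, frac in zip(r.test_indices, r.predictions, r.vote_fractions):
            s = dataset.samples[idx]
            lines.append(f"{idx}\t{s.patient_id}\t{r.fold}\t{s.label}\t{pred}\t{frac:.6f}")
    out.write_text("\n".join(lines) + "\n")
    return out
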