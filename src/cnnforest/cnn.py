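"""Lightweight CNN feature extractors and the per-fold feature matrix.

Each extractor is a small strided convolutional net with a single linear
output unit trained with hinge loss on +-1 targets; the raw margin is the
feature value handed to the forest.  Within a cross-validation training
fold the samples are partitioned into n disjoint, class-stratified subsets;
extractor i trains on everything except subset i and uses subset i for
validation-based epoch selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import Dataset
from .nn import Conv2D, Dense, Flatten, ReLU, Sequential, hinge_loss, make_optimizer

_SPEC_FILENAME = "spec.yaml"
_WEIGHTS_FILENAME = "weights.npz"


@dataclass
class CnnSpec:
    """Architecture and training hyperparameters of one extractor."""

    input_shape: tuple[int, int] = (100, 100)
    n_conv_layers: int = 2
    filters: tuple[int, ...] = (32, 64)
    kernel_size: tuple[int, int] = (3, 3)
    stride: int = 2
    activation: str = "relu"
    n_dense_layers: int = 1
    dense_units: int = 128
    loss: str = "hinge"
    l2_coefficient: float = 0.001
    batch_size: int = 256
    optimizer: str = "adam"
    epochs: int = 10
    learning_rate: float | None = None  # None -> the optimizer's default
    select_best_epoch: bool = True

    def __post_init__(self) -> None:
        self.input_shape = tuple(self.input_shape)
        self.filters = tuple(self.filters)
        self.kernel_size = tuple(self.kernel_size)
        if len(self.filters) != self.n_conv_layers:
            raise ValueError("filters length must equal n_conv_layers")
        if min(self.filters, default=0) < 1 or self.n_conv_layers < 1:
            raise ValueError("filter counts and n_conv_layers must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.dense_units < 1:
            raise ValueError("epochs, batch_size and dense_units must be positive")
        if self.stride < 1:
            raise ValueError("stride must be positive")
        if self.activation.lower() != "relu":
            raise ValueError("only ReLU activation is supported")
        if self.loss.lower() != "hinge":
            raise ValueError("only hinge loss is supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        d["filters"] = list(self.filters)
        d["kernel_size"] = list(self.kernel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CnnSpec":
        return cls(**d)


def build_model(spec: CnnSpec, rng: np.random.Generator) -> Sequential:
    """Instantiate the network with seeded uniform fan-in-scaled weights."""
    layers: list = []
    h, w = spec.input_shape
    channels = 1
    for f in spec.filters:
        layers.append(Conv2D(channels, f, spec.kernel_size, spec.stride, rng))
        layers.append(ReLU())
        h = (h - spec.kernel_size[0]) // spec.stride + 1
        w = (w - spec.kernel_size[1]) // spec.stride + 1
        if h < 1 or w < 1:
            raise ValueError(f"input shape {spec.input_shape} too small for the conv stack")
        channels = f
    layers.append(Flatten())
    flat = h * w * channels
    for _ in range(spec.n_dense_layers):
        layers.append(Dense(flat, spec.dense_units, rng))
        layers.append(ReLU())
        flat = spec.dense_units
    layers.append(Dense(flat, 1, rng))  # linear margin head
    return Sequential(layers)


@dataclass
class FeatureExtractor:
    """A trained CNN whose scalar margin output is the forest feature."""

    spec: CnnSpec
    model: Sequential
    training_log: list[dict] = field(default_factory=list)
    initial_train_loss: float | None = None
    best_epoch: int | None = None

    def score(self, images: np.ndarray) -> np.ndarray:
        """Margin scores for an (N, H, W) stack; larger = more positive-class."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3 or images.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"images must be (N, {self.spec.input_shape[0]}, "
                f"{self.spec.input_shape[1]}), got {images.shape}"
            )
        # one image per forward pass so batch scoring, per-sample scoring and
        # the feature matrix share bit-identical inference (BLAS blocking in
        # the dense layers otherwise varies with batch size)
        out = [self.model.forward(images[i : i + 1, None, :, :], train=False)
               for i in range(images.shape[0])]
        return np.concatenate(out).reshape(-1).astype(np.float64)

    # -- persistence ------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / _SPEC_FILENAME).write_text(
            yaml.safe_dump(
                {
                    "spec": self.spec.to_dict(),
                    "training_log": self.training_log,
                    "initial_train_loss": self.initial_train_loss,
                    "best_epoch": self.best_epoch,
                },
                sort_keys=False,
            )
        )
        weights = {f"w{i}": w for i, w in enumerate(self.model.weight_arrays())}
        np.savez(out_dir / _WEIGHTS_FILENAME, **weights)
        return out_dir

    @classmethod
    def load(cls, in_dir: str | Path) -> "FeatureExtractor":
        in_dir = Path(in_dir)
        meta = yaml.safe_load((in_dir / _SPEC_FILENAME).read_text())
        spec = CnnSpec.from_dict(meta["spec"])
        model = build_model(spec, np.random.default_rng(0))
        with np.load(in_dir / _WEIGHTS_FILENAME) as z:
            model.set_weights([z[f"w{i}"] for i in range(len(z.files))])
        return cls(
            spec=spec,
            model=model,
            training_log=meta.get("training_log", []),
            initial_train_loss=meta.get("initial_train_loss"),
            best_epoch=meta.get("best_epoch"),
        )


def partition_subsets(
    sample_ids: Sequence[int],
    labels: Sequence[int],
    n: int,
    rng_seed: int | np.random.SeedSequence,
) -> list[np.ndarray]:
    """Split ``sample_ids`` into n disjoint, class-stratified subsets.

    Subset sizes differ by at most one overall and within each class
    (shuffled round-robin dealing with a pointer that carries over between
    classes).  The union is exactly ``sample_ids``.
    """
    ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if n < 2:
        raise ValueError("n must be >= 2")
    if len(ids) < n:
        raise ValueError(f"cannot split {len(ids)} samples into {n} subsets")
    if len(ids) != len(labels):
        raise ValueError("sample_ids and labels must align")
    rng = np.random.default_rng(rng_seed)
    buckets: list[list] = [[] for _ in range(n)]
    pointer = int(rng.integers(n))
    for cls in np.unique(labels):
        cls_ids = ids[labels == cls]
        cls_ids = cls_ids[rng.permutation(len(cls_ids))]
        for sid in cls_ids:
            buckets[pointer % n].append(sid)
            pointer += 1
    return [np.array(sorted(b)) for b in buckets]


def _loss_on(
    model: Sequential, x: np.ndarray, y: np.ndarray, l2: float, batch_size: int
) -> float:
    """Mean hinge loss + L2 penalty, evaluated without storing activations."""
    total, n = 0.0, len(y)
    for start in range(0, n, batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        scores = model.forward(xb, train=False).reshape(-1)
        total += float(np.sum(np.maximum(1.0 - yb * scores, 0.0)))
    return total / n + model.l2_penalty(l2)


def train_cnn(
    train_ids: Sequence[int],
    val_ids: Sequence[int] | None,
    dataset: Dataset,
    spec: CnnSpec,
    rng_seed: int | np.random.SeedSequence,
) -> FeatureExtractor:
    """Train one extractor on ``train_ids``; ``val_ids`` drives epoch selection.

    The returned weights are those of the epoch with the lowest validation
    loss when ``spec.select_best_epoch`` and a validation set is given,
    otherwise the final epoch's.  ``training_log`` has one entry per epoch.
    """
    train_ids = np.asarray(train_ids)
    if train_ids.size == 0:
        raise ValueError("training set is empty")
    if val_ids is not None:
        val_ids = np.asarray(val_ids)
        if val_ids.size == 0:
            raise ValueError("validation set is empty (pass None to skip validation)")
        if np.intersect1d(train_ids, val_ids).size:
            raise ValueError("train and validation ids overlap")
    labels = dataset.labels
    if len(np.unique(labels[train_ids])) < 2:
        raise ValueError("training set must contain both classes (hinge targets need +-1)")

    x_train = dataset.pixel_stack(train_ids)[:, None, :, :]
    if x_train.shape[2:] != spec.input_shape:
        raise ValueError(
            f"dataset images have shape {x_train.shape[2:]}, spec expects {spec.input_shape}"
        )
    y_train = (labels[train_ids] * 2 - 1).astype(np.float32)
    if val_ids is not None:
        x_val = dataset.pixel_stack(val_ids)[:, None, :, :]
        y_val = (labels[val_ids] * 2 - 1).astype(np.float32)

    rng = np.random.default_rng(rng_seed)
    model = build_model(spec, rng)
    optimizer = make_optimizer(spec.optimizer, spec.learning_rate)
    l2 = spec.l2_coefficient

    initial_loss = _loss_on(model, x_train, y_train, l2, spec.batch_size)
    log: list[dict] = []
    best = (np.inf, None, None)  # (val_loss, epoch, weights)
    n = len(y_train)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            scores = model.forward(xb, train=True)
            loss, grad = hinge_loss(scores, yb)
            model.backward(grad)
            model.apply_l2_gradients(l2)
            optimizer.step(model)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_loss / seen + model.l2_penalty(l2)}
        if val_ids is not None:
            val_loss = _loss_on(model, x_val, y_val, l2, spec.batch_size)
            entry["val_loss"] = val_loss
            if spec.select_best_epoch and val_loss < best[0]:
                best = (val_loss, epoch, model.copy_weights())
        log.append(entry)

    best_epoch = spec.epochs - 1
    if best[2] is not None:
        model.set_weights(best[2])
        best_epoch = best[1]
    return FeatureExtractor(
        spec=spec,
        model=model,
        training_log=log,
        initial_train_loss=initial_loss,
        best_epoch=best_epoch,
    )


def cnn_score(extractor: FeatureExtractor, image: np.ndarray) -> float:
    """Scalar margin for one preprocessed image (shape must match the spec)."""
    image = np.asarray(image)
    if image.shape != extractor.spec.input_shape:
        raise ValueError(
            f"image shape {image.shape} does not match spec {extractor.spec.input_shape}"
        )
    return float(extractor.score(image[None])[0])


@dataclass
class FeatureMatrix:
    """The |fold| x n matrix of extractor margins for a training fold."""

    values: np.ndarray
    row_index: np.ndarray  # sample ids of the fold
    col_index: list[str]  # extractor identifiers

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.row_index = np.asarray(self.row_index)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError("feature matrix shape does not match its indexes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_tsv(self, out: str | Path) -> Path:
        out = Path(out)
        header = "sample_id\t" + "\t".join(self.col_index)
        lines = [header]
        for sid, row in zip(self.row_index, self.values):
            lines.append(str(sid) + "\t" + "\t".join(f"{v:.10g}" for v in row))
        out.write_text("\n".join(lines) + "\n")
        return out


def build_feature_matrix(
    extractors: Sequence[FeatureExtractor],
    fold_samples: Sequence[int],
    dataset: Dataset,
) -> FeatureMatrix:
    """Score every fold sample with every extractor: values[i, j] = score_j(sample_i)."""
    if len(extractors) == 0:
        raise ValueError("need at least one extractor")
    shapes = {e.spec.input_shape for e in extractors}
    if len(shapes) > 1:
        raise ValueError(f"extractors disagree on input shape: {shapes}")
    fold_samples = np.asarray(fold_samples)
    x = dataset.pixel_stack(fold_samples)
    cols = [ext.score(x) for ext in extractors]
    return FeatureMatrix(
        values=np.stack(cols, axis=1),
        row_index=fold_samples,
        col_index=[f"cnn{j}" for j in range(len(extractors))],
    )
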