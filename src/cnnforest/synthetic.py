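"""Synthetic two-class image cohort with patient grouping and lesion contrast.

Positive-class images carry 1-3 bright elliptical "lesions" over a smooth
per-patient sinusoidal background; negative-class images carry background
and noise only.  The generator is fully determined by its integer seed, so
cohorts are bit-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import Dataset, ImageSample, save_dataset

SEQUENCE_TAGS = ("LGE", "Perfusion", "T2", "SSFP")
VIEW_TAGS = ("SAX", "LAX2ch", "LAX3ch", "LAX4ch")

_BACKGROUND_BASE = 0.35
_BACKGROUND_AMPLITUDE = 0.06


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort; identical configs yield identical cohorts."""

    n_healthy_patients: int = 40
    n_cad_patients: int = 40
    images_per_patient: int = 8
    image_size: tuple[int, int] = (32, 32)
    lesion_intensity: float = 0.8
    lesion_radius_px: int = 5
    noise_sd: float = 0.05
    background_texture_scale: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_healthy_patients, self.n_cad_patients, self.images_per_patient) < 1:
            raise ValueError("patient and image counts must be strictly positive")
        if len(self.image_size) != 2 or min(self.image_size) < 4:
            raise ValueError("image_size must be two ints >= 4")
        if not 0.0 <= self.lesion_intensity <= 1.0:
            raise ValueError("lesion_intensity must lie in [0, 1]")
        if not 0 < self.lesion_radius_px < min(self.image_size) / 2:
            raise ValueError("lesion_radius_px must be in (0, min(image_size)/2)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_texture_scale <= 0:
            raise ValueError("background_texture_scale must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)


def _background(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-patient texture: two oriented sinusoids with random phase."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    img = np.full(shape, _BACKGROUND_BASE, dtype=np.float64)
    for _ in range(2):
        theta = rng.uniform(0, np.pi)
        freq = 2.0 * np.pi / (scale * rng.uniform(0.7, 1.5))
        phase = rng.uniform(0, 2 * np.pi)
        proj = rows * np.cos(theta) + cols * np.sin(theta)
        img += _BACKGROUND_AMPLITUDE * np.sin(freq * proj + phase)
    return img


def _add_lesions(
    img: np.ndarray,
    intensity: float,
    radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add 1-3 bright soft ellipses; each has peak added intensity ``intensity``."""
    shape = img.shape
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    n_lesions = rng.integers(1, 4)
    out = img.copy()
    margin = radius + 1
    for _ in range(n_lesions):
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        a = radius * rng.uniform(0.7, 1.3)
        b = radius * rng.uniform(0.7, 1.3)
        theta = rng.uniform(0, np.pi)
        dy, dx = rows - cy, cols - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        q = (u / a) ** 2 + (v / b) ** 2
        profile = np.clip(1.0 - q, 0.0, 1.0)  # peak 1 at centre, 0 outside ellipse
        out += intensity * profile
    return out


def generate_cohort(config: CohortConfig) -> Dataset:
    """Generate a :class:`~cnnforest.io.Dataset` from ``config``.

    Patient ids are ``H####`` (label 0) and ``C####`` (label 1).  Background
    texture parameters are drawn once per patient, so all of a patient's
    images share appearance; lesions and pixel noise are per image.
    """
    config.validate()
    samples: list[ImageSample] = []
    n_total = config.n_healthy_patients + config.n_cad_patients
    for p_idx in range(n_total):
        is_cad = p_idx >= config.n_healthy_patients
        label = int(is_cad)
        pid = (f"C{p_idx - config.n_healthy_patients:04d}" if is_cad else f"H{p_idx:04d}")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, p_idx]))
        bg_rng_state = rng.spawn(1)[0]
        background = _background(config.image_size, config.background_texture_scale, bg_rng_state)
        for i in range(config.images_per_patient):
            img = background + rng.normal(0.0, 0.01, size=config.image_size)  # slice jitter
            if is_cad:
                img = _add_lesions(img, config.lesion_intensity, config.lesion_radius_px, rng)
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, size=config.image_size)
            img = np.clip(img, 0.0, 1.0)
            samples.append(
                ImageSample(
                    pixels=img.astype(np.float32),
                    label=label,
                    patient_id=pid,
                    sequence_tag=SEQUENCE_TAGS[i % len(SEQUENCE_TAGS)],
                    view_tag=VIEW_TAGS[(i // len(SEQUENCE_TAGS)) % len(VIEW_TAGS)],
                )
            )
    return Dataset(samples)


def cohort_manifest(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write ``dataset`` as PNG images + TSV manifest; returns the manifest path."""
    if len(dataset) == 0:
        raise ValueError("cannot write a manifest for an empty dataset")
    return save_dataset(dataset, out_dir)


def class_contrast(dataset: Dataset) -> float:
    """Classifier-free separability statistic.

    Difference between the mean pixel intensity of positive-class images and
    negative-class images.  Increases monotonically with ``lesion_intensity``
    at fixed noise level; ~0 when lesions carry no added intensity.
    """
    labels = dataset.labels
    means = np.array([s.pixels.mean() for s in dataset.samples])
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ValueError("both classes are required to compute a contrast")
    return float(means[labels == 1].mean() - means[labels == 0].mean())
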