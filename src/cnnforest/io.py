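"""Image / manifest I/O and preprocessing for two-class grayscale cohorts.

A cohort on disk is a directory of 8-bit PNG/JPEG images plus a TSV manifest
(``path  patient_id  label  sequence_tag  view_tag``).  When no manifest is
given the layout is inferred from class subfolders, with the patient id
parsed from each filename.

Preprocessing follows a fixed recipe: collapse any colour channels to a
luminance average, scale intensities by the bit-depth maximum to [0, 1],
then bilinearly resize to the target shape (default 100x100).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SHAPE = (100, 100)
DEFAULT_CLASS_NAMES = ("healthy", "cad")
#: patient id = everything before the first underscore of the stem
DEFAULT_PATIENT_REGEX = r"^(?P<patient>[^_]+)"

MANIFEST_COLUMNS = ("path", "patient_id", "label", "sequence_tag", "view_tag")


class ManifestError(ValueError):
    """Raised for malformed manifests or label-inconsistent cohorts."""


def preprocess_image(
    raw: np.ndarray,
    target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
    max_value: float | None = None,
) -> np.ndarray:
    """Scale a raw image to [0, 1] and resize it to ``target_shape``.

    Parameters
    ----------
    raw
        2-D grayscale or 3-D (H, W, C) colour array.  Integer arrays are
        divided by the dtype maximum (255 for 8-bit); floating arrays must
        already lie in [0, 1] and are passed through unscaled.
    target_shape
        Output (rows, cols); resampling is bilinear.  Resizing is skipped
        when the shape already matches, so conforming inputs are fixed
        points of this function.
    max_value
        Override for the intensity maximum (e.g. 4095 for 12-bit data
        stored in uint16).

    Returns
    -------
    numpy.ndarray
        float32 array of shape ``target_shape`` with values in [0, 1].
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("cannot preprocess an empty image array")
    if len(target_shape) != 2 or min(target_shape) < 1:
        raise ValueError(f"target_shape must be two positive ints, got {target_shape!r}")
    raw_dtype = arr.dtype  # bit depth of the file, before the channel collapse
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D image, got ndim={arr.ndim}")

    if max_value is None:
        if np.issubdtype(raw_dtype, np.integer):
            max_value = float(np.iinfo(raw_dtype).max)
        else:
            max_value = 1.0
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    scaled = arr.astype(np.float64) / max_value
    if scaled.min() < -1e-9 or scaled.max() > 1 + 1e-9:
        raise ValueError("pixel values fall outside [0, max_value]")
    scaled = np.clip(scaled, 0.0, 1.0)

    if tuple(scaled.shape) != tuple(target_shape):
        im = Image.fromarray(scaled.astype(np.float32), mode="F")
        # PIL size is (width, height) = (cols, rows)
        im = im.resize((target_shape[1], target_shape[0]), Image.BILINEAR)
        scaled = np.asarray(im, dtype=np.float64)
        scaled = np.clip(scaled, 0.0, 1.0)
    return scaled.astype(np.float32)


@dataclass
class ImageSample:
    """One grayscale image with its patient id and class label."""

    pixels: np.ndarray
    label: int
    patient_id: str
    sequence_tag: str | None = None
    view_tag: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class Dataset:
    """Ordered collection of :class:`ImageSample` with consistent labels.

    Invariant: every patient id maps to exactly one class label.
    """

    samples: list[ImageSample]
    class_names: tuple[str, str] = DEFAULT_CLASS_NAMES

    _patient_labels: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        patient_labels: dict[str, int] = {}
        for s in self.samples:
            prev = patient_labels.setdefault(s.patient_id, s.label)
            if prev != s.label:
                raise ManifestError(
                    f"patient {s.patient_id!r} appears with both class labels"
                )
        self._patient_labels = patient_labels

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.samples]

    @property
    def patient_labels(self) -> dict[str, int]:
        """Mapping patient id -> class label (one entry per patient)."""
        return dict(self._patient_labels)

    @property
    def n_patients(self) -> int:
        return len(self._patient_labels)

    def class_counts(self) -> np.ndarray:
        """Per-class image counts; sums to ``len(self)``."""
        counts = np.zeros(2, dtype=np.int64)
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def pixel_stack(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Stack sample pixels into an (N, H, W) float32 array."""
        idx = range(len(self.samples)) if indices is None else indices
        return np.stack([self.samples[i].pixels for i in idx]).astype(np.float32)


def count_patients(total_images: int, images_per_patient: int) -> int:
    """Number of patients implied by a fixed per-patient image count.

    Integer division; a remainder triggers a warning, not an error.
    """
    if images_per_patient <= 0:
        raise ValueError("images_per_patient must be positive")
    q, r = divmod(total_images, images_per_patient)
    if r:
        warnings.warn(
            f"{total_images} images are not an exact multiple of "
            f"{images_per_patient} per patient (remainder {r})",
            stacklevel=2,
        )
    return q


def _read_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im)
    except Exception as exc:  # pragma: no cover - message content only
        raise OSError(f"could not read image file {path}") from exc


def _parse_label(token: str, class_names: Sequence[str]) -> int:
    if token in ("0", "1"):
        return int(token)
    if token in class_names:
        return list(class_names).index(token)
    raise ManifestError(f"unrecognised label {token!r}")


def read_manifest(manifest: Path) -> list[dict[str, str]]:
    """Parse a TSV manifest into row dicts, in file order."""
    lines = Path(manifest).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ManifestError(f"manifest {manifest} is empty")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in MANIFEST_COLUMNS[:3] if c not in header]
    if missing:
        raise ManifestError(f"manifest {manifest} lacks columns {missing}")
    rows = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ManifestError(f"manifest row has {len(fields)} fields, expected {len(header)}")
        rows.append(dict(zip(header, fields)))
    return rows


def write_manifest(rows: Iterable[Mapping[str, str]], out: Path) -> Path:
    out = Path(out)
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in MANIFEST_COLUMNS))
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


def _rows_from_layout(
    image_root: Path,
    class_names: Sequence[str],
    patient_regex: str,
) -> list[dict[str, str]]:
    pattern = re.compile(patient_regex)
    rows: list[dict[str, str]] = []
    for label, cls in enumerate(class_names):
        cls_dir = image_root / cls
        if not cls_dir.is_dir():
            raise ManifestError(
                f"expected class subfolder {cls_dir} (layout inference needs "
                f"subfolders named {tuple(class_names)})"
            )
        for p in sorted(cls_dir.rglob("*")):
            if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            m = pattern.match(p.stem)
            if not m:
                raise ManifestError(f"cannot parse patient id from filename {p.name!r}")
            rows.append(
                {
                    "path": str(p.relative_to(image_root)),
                    "patient_id": m.group("patient"),
                    "label": str(label),
                    "sequence_tag": "",
                    "view_tag": "",
                }
            )
    return rows


def load_dataset(
    image_root: str | Path,
    manifest: str | Path | None = None,
    *,
    target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
    class_names: tuple[str, str] = DEFAULT_CLASS_NAMES,
    patient_regex: str = DEFAULT_PATIENT_REGEX,
) -> Dataset:
    """Load and preprocess a cohort from disk.

    ``manifest`` is a TSV file (paths relative to ``image_root``); when
    omitted the layout must be class-subfolder based and patient ids are
    parsed from filenames via ``patient_regex`` (named group ``patient``).

    Sample order is the manifest row order (or sorted path order for
    layout inference), so repeated loads are identical.
    """
    image_root = Path(image_root)
    if not image_root.is_dir():
        raise FileNotFoundError(f"image root {image_root} does not exist")

    if manifest is not None:
        rows = read_manifest(Path(manifest))
    else:
        rows = _rows_from_layout(image_root, class_names, patient_regex)
    if not rows:
        raise ManifestError(f"no images found under {image_root}")

    samples = []
    for row in rows:
        path = image_root / row["path"]
        raw = _read_image(path)
        samples.append(
            ImageSample(
                pixels=preprocess_image(raw, target_shape),
                label=_parse_label(row["label"], class_names),
                patient_id=row["patient_id"],
                sequence_tag=row.get("sequence_tag") or None,
                view_tag=row.get("view_tag") or None,
                source=str(path),
            )
        )
    ds = Dataset(samples, class_names=tuple(class_names))
    counts = ds.class_counts()
    logger.info(
        "loaded %d images from %d patients (%s=%d, %s=%d)",
        len(ds), ds.n_patients, class_names[0], counts[0], class_names[1], counts[1],
    )
    return ds


def save_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset as 8-bit PNGs plus a TSV manifest; returns the manifest path.

    Images land under ``out_dir/<class_name>/`` so the class-subfolder
    layout inference of :func:`load_dataset` also works on the result.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seq_counter: dict[str, int] = {}
    for s in dataset.samples:
        i = seq_counter.get(s.patient_id, 0)
        seq_counter[s.patient_id] = i + 1
        cls = dataset.class_names[s.label]
        rel = Path(cls) / f"{s.patient_id}_{i:03d}.png"
        (out_dir / cls).mkdir(exist_ok=True)
        data = np.clip(np.rint(s.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(data, mode="L").save(out_dir / rel)
        rows.append(
            {
                "path": str(rel),
                "patient_id": s.patient_id,
                "label": str(s.label),
                "sequence_tag": s.sequence_tag or "",
                "view_tag": s.view_tag or "",
            }
        )
    return write_manifest(rows, out_dir / "manifest.tsv")
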