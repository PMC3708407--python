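"""Labeled image-patch data model and file I/O.

A *pattern* is a small 2D grayscale CT patch containing either a pulmonary
nodule or a visually similar distractor (vessel crossing, scar, ...), paired
with a binary segmentation mask, a class label and the pixel spacing in mm.
Patterns are listed in a manifest CSV with columns
``id, image_path, mask_path, label, pixel_spacing_mm``; images are 8- or
16-bit grayscale PNG/TIFF, masks are {0,255} or {0,1} PNGs.

Intensities are min-max normalized to [0, 1] per patch on load, which makes
the downstream 2D-PCA features invariant to acquisition windowing.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

LABELS = ("nodule", "nonnodule")
Label = Literal["nodule", "nonnodule"]
SplitTag = Literal["train", "test", "unsplit"]


class PatternError(Exception):
    """Base class for pattern data errors."""


class MissingFileError(PatternError):
    """A path referenced by the manifest does not exist."""


class ShapeMismatchError(PatternError):
    """Image and mask dimensions differ."""


class UnknownLabelError(PatternError):
    """Label is not 'nodule' or 'nonnodule'."""


class EmptyMaskError(PatternError):
    """Mask has no foreground pixels."""


class InvalidSpacingError(PatternError):
    """Pixel spacing is not a positive finite number."""


class DuplicateFeatureNameError(PatternError):
    """Feature table has repeated column names."""


class RaggedTableError(PatternError):
    """Feature table rows have inconsistent lengths or missing values."""


def _normalize_intensity(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi > lo:
        return (image - lo) / (hi - lo)
    return np.zeros_like(image)


@dataclasses.dataclass
class Pattern:
    """One labeled patch: intensity matrix, binary mask, label, spacing.

    The mask uses the convention nonzero = foreground, row-major 0-based
    coordinates. Intensities are dimensionless in [0, 1].
    """

    id: str
    image: np.ndarray
    mask: np.ndarray
    label: Label
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = (np.asarray(self.mask) != 0).astype(np.uint8)
        if self.image.ndim != 2:
            raise ShapeMismatchError(f"image of pattern {self.id!r} is not 2D")
        if self.image.shape != self.mask.shape:
            raise ShapeMismatchError(
                f"pattern {self.id!r}: image {self.image.shape} vs mask {self.mask.shape}"
            )
        if self.label not in LABELS:
            raise UnknownLabelError(f"pattern {self.id!r}: label {self.label!r}")
        if not self.mask.any():
            raise EmptyMaskError(f"pattern {self.id!r}: empty mask")
        if not (math.isfinite(self.pixel_spacing_mm) and self.pixel_spacing_mm > 0):
            raise InvalidSpacingError(
                f"pattern {self.id!r}: pixel_spacing_mm={self.pixel_spacing_mm}"
            )
        self.image = _normalize_intensity(self.image)

    @property
    def is_nodule(self) -> bool:
        return self.label == "nodule"


class PatternSet:
    """Ordered collection of patterns with an optional train/test split tag."""

    def __init__(
        self,
        patterns: Sequence[Pattern],
        split_tags: Sequence[SplitTag] | None = None,
    ) -> None:
        self.patterns = list(patterns)
        ids = [p.id for p in self.patterns]
        if len(set(ids)) != len(ids):
            raise PatternError("duplicate pattern ids")
        if split_tags is None:
            split_tags = ["unsplit"] * len(self.patterns)
        if len(split_tags) != len(self.patterns):
            raise PatternError("split_tags length mismatch")
        self.split_tags = list(split_tags)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __getitem__(self, i: int) -> Pattern:
        return self.patterns[i]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.patterns]

    @property
    def labels(self) -> list[Label]:
        return [p.label for p in self.patterns]

    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for p in self.patterns:
            counts[p.label] += 1
        return counts

    def subset(self, tag: SplitTag) -> "PatternSet":
        pairs = [
            (p, t) for p, t in zip(self.patterns, self.split_tags) if t == tag
        ]
        return PatternSet([p for p, _ in pairs], [t for _, t in pairs])

    def train_test(self) -> tuple["PatternSet", "PatternSet"]:
        return self.subset("train"), self.subset("test")


def _load_gray(path: Path) -> np.ndarray:
    if not path.exists():
        raise MissingFileError(str(path))
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A) saved grayscale
        arr = arr[..., 0]
    return np.asarray(arr, dtype=np.float64)


def read_manifest(path: str | Path) -> PatternSet:
    """Read a manifest CSV and load, validate and normalize every patch.

    Row order is preserved.  An optional ``split`` column carrying
    train/test/unsplit tags is honoured.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    df = pd.read_csv(path)
    required = {"id", "image_path", "mask_path", "label", "pixel_spacing_mm"}
    missing = required - set(df.columns)
    if missing:
        raise PatternError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    patterns: list[Pattern] = []
    tags: list[SplitTag] = []
    for row in df.itertuples(index=False):
        image = _normalize_intensity(_load_gray(base / str(row.image_path)))
        mask = _load_gray(base / str(row.mask_path))
        patterns.append(
            Pattern(
                id=str(row.id),
                image=image,
                mask=mask,
                label=str(row.label),  # type: ignore[arg-type]
                pixel_spacing_mm=float(row.pixel_spacing_mm),
            )
        )
        tags.append(getattr(row, "split", "unsplit"))
    return PatternSet(patterns, tags)


def write_manifest(pset: PatternSet, directory: str | Path) -> Path:
    """Write patches as 16-bit grayscale PNGs plus a manifest CSV.

    Returns the manifest path; ``read_manifest`` of it round-trips the set
    (intensities to 16-bit quantization, ~1.5e-5).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p, tag in zip(pset.patterns, pset.split_tags):
        img_name, mask_name = f"{p.id}_img.png", f"{p.id}_mask.png"
        img16 = np.round(np.clip(p.image, 0, 1) * 65535).astype(np.uint16)
        Image.fromarray(img16).save(directory / img_name)
        Image.fromarray((p.mask * 255).astype(np.uint8), mode="L").save(
            directory / mask_name
        )
        rows.append(
            {
                "id": p.id,
                "image_path": img_name,
                "mask_path": mask_name,
                "label": p.label,
                "pixel_spacing_mm": p.pixel_spacing_mm,
                "split": tag,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dicom_patch(
    path: str | Path,
    crop_box: tuple[int, int, int, int],
    mask: np.ndarray,
    label: Label,
    pattern_id: str | None = None,
) -> Pattern:
    """Extract a labeled patch from a DICOM slice given a (row0, col0, row1, col1) crop box."""
    import pydicom

    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    r0, c0, r1, c1 = crop_box
    patch = arr[r0:r1, c0:c1]
    spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
    return Pattern(
        id=pattern_id or path.stem,
        image=_normalize_intensity(patch),
        mask=mask,
        label=label,
        pixel_spacing_mm=spacing,
    )


def normalize_patch(p: Pattern, side: int = 64) -> Pattern:
    """Resample a patch to ``side`` x ``side`` pixels.

    Intensity is interpolated bilinearly, the mask by nearest neighbour (so
    it stays binary).  The pixel spacing is rescaled by the geometric-mean
    original extent over ``side`` so that physical area is preserved.
    Idempotent at the target size.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    h, w = p.image.shape
    if (h, w) == (side, side):
        return p
    image = resize(p.image, (side, side), order=1, anti_aliasing=False,
                   preserve_range=True)
    mask = resize(p.mask.astype(float), (side, side), order=0,
                  anti_aliasing=False, preserve_range=True)
    spacing = p.pixel_spacing_mm * math.sqrt(h * w) / side
    return Pattern(p.id, np.clip(image, 0.0, 1.0), mask > 0.5, p.label, spacing)


@dataclasses.dataclass
class FeatureTable:
    """Named feature vectors per pattern with class labels.

    Column names are namespaced by extraction method (``pca_*``, ``stat_*``,
    ``geo_*``).  Stored as plain arrays; round-trips through CSV with the
    label column last.
    """

    pattern_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[Label]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RaggedTableError("values must be a 2D matrix")
        if self.values.shape != (len(self.pattern_ids), len(self.feature_names)):
            raise RaggedTableError(
                f"values shape {self.values.shape} vs "
                f"{len(self.pattern_ids)} ids x {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DuplicateFeatureNameError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise RaggedTableError("non-finite or missing feature values")
        for lab in self.labels:
            if lab not in LABELS:
                raise UnknownLabelError(repr(lab))

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_ids)

    @property
    def y(self) -> np.ndarray:
        """Binary label vector, 1 = nodule (positive class)."""
        return np.array([1 if lab == "nodule" else 0 for lab in self.labels])

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.pattern_ids), list(names), self.values[:, idx], list(self.labels)
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.pattern_ids)
        df["label"] = self.labels
        return df

    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        tables = list(tables)
        first = tables[0]
        names: list[str] = []
        blocks = []
        for t in tables:
            if t.pattern_ids != first.pattern_ids or t.labels != first.labels:
                raise PatternError("feature tables do not align on patterns")
            names.extend(t.feature_names)
            blocks.append(t.values)
        return FeatureTable(
            list(first.pattern_ids), names, np.hstack(blocks), list(first.labels)
        )


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_dataframe().to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        raise DuplicateFeatureNameError(f"duplicate columns in {path}")
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise RaggedTableError(f"missing values in {path}")
    names = [c for c in df.columns if c not in ("id", "label")]
    return FeatureTable(
        pattern_ids=[str(i) for i in df["id"]],
        feature_names=names,
        values=df[names].to_numpy(dtype=np.float64),
        labels=list(df["label"]),
    )
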