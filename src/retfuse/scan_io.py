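"""Reading and writing retinal scans, masks and dataset manifests.

A scan is a 2-D grayscale grid (OCT B-scan) or an H x W x 3 color grid
(fundus photograph), normalized to [0, 1] on load. Manifests are plain
CSV files with the exact header ``path,modality,label,split``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("oct", "fundus")
LABELS = ("healthy", "me")
SPLITS = ("train", "validation")

_MANIFEST_COLUMNS = ["path", "modality", "label", "split"]


@dataclass
class RetinalScan:
    """A single retinal image plus the metadata every stage needs.

    ``pixels`` is float64 in [0, 1], either (rows, cols) or (rows, cols, 3).
    ``um_per_pixel`` is the lateral calibration; an optional separate axial
    value may be carried in ``um_per_pixel_axial``.
    """

    pixels: np.ndarray
    modality: str = "unknown"
    um_per_pixel: float | None = None
    um_per_pixel_axial: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 2-D x 3-channel")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color scans must have exactly 3 channels")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("scan must have at least one row and column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("scan intensities must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("scan intensities must lie in [0, 1]")
        if self.modality not in ("unknown",) + MODALITIES:
            raise ValueError(f"unknown modality tag {self.modality!r}")
        if self.um_per_pixel is not None and self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    def gray(self) -> np.ndarray:
        """Working grayscale channel: the green channel for color scans.

        The green channel carries the strongest vessel/exudate contrast in
        fundus photographs; grayscale scans are returned as-is.
        """
        if self.is_color:
            return self.pixels[:, :, 1]
        return self.pixels

    def with_pixels(self, pixels: np.ndarray) -> "RetinalScan":
        return replace(self, pixels=pixels)


@dataclass
class ManifestRecord:
    path: str
    modality: str
    label: str
    split: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, *, modality: str | None = None, split: str | None = None) -> "DatasetManifest":
        recs = [
            r
            for r in self.records
            if (modality is None or r.modality == modality)
            and (split is None or r.split == split)
        ]
        return DatasetManifest(recs)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame([vars(r) for r in self.records], columns=_MANIFEST_COLUMNS)
        df.to_csv(path, index=False)


def read_scan(path: str | Path) -> RetinalScan:
    """Load a PNG/TIFF/JPEG image as a [0, 1]-normalized scan.

    Grayscale files stay 2-D; RGB(A) files keep three channels. The
    modality tag starts as ``unknown`` until recognition sets it.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image file {path}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] != 3:
            raise IOError(f"unsupported channel count in {path}")
    elif arr.ndim != 2:
        raise IOError(f"unsupported image layout in {path}")
    arr = arr.astype(float)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        info = np.iinfo(np.asarray(raw).dtype)
        arr = arr / float(info.max)
    else:
        peak = arr.max()
        if peak > 1.0:
            arr = arr / peak
    return RetinalScan(pixels=np.clip(arr, 0.0, 1.0), source_id=str(path))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask losslessly as an 8-bit single-channel PNG/TIFF."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D grid")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1, False, True))):
        raise ValueError("mask must be binary (values 0/1)")
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError("masks must be written as PNG or TIFF")
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back as a boolean grid."""
    scan = read_scan(path)
    return scan.gray() > 0.5


def load_manifest(path: str | Path) -> DatasetManifest:
    """Parse and validate a ``path,modality,label,split`` CSV manifest.

    Only the two study classes are admitted: labels other than
    healthy/me (the datasets exclude other retinal pathologies) raise a
    parse error naming the offending line.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != _MANIFEST_COLUMNS:
        raise ValueError(
            f"manifest header must be exactly {','.join(_MANIFEST_COLUMNS)}, got {','.join(df.columns)}"
        )
    records: list[ManifestRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        modality = str(row["modality"]).strip().lower()
        label = str(row["label"]).strip().lower()
        split = str(row["split"]).strip().lower()
        if modality not in MODALITIES:
            raise ValueError(f"line {line_no}: unknown modality {row['modality']!r}")
        if label not in LABELS:
            raise ValueError(
                f"line {line_no}: unknown label {row['label']!r} (only healthy/me are in scope)"
            )
        if split not in SPLITS:
            raise ValueError(f"line {line_no}: unknown split {row['split']!r}")
        p = str(row["path"]).strip()
        if p in seen:
            raise ValueError(f"line {line_no}: duplicate path {p!r}")
        seen.add(p)
        records.append(ManifestRecord(p, modality, label, split))
    manifest = DatasetManifest(records)
    counts = pd.Series(
        [(r.modality, r.label, r.split) for r in records]
    ).value_counts()
    logger.info("manifest %s: %d records\n%s", path, len(records), counts.to_string())
    return manifest
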