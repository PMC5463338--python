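"""Volume data model, readers/writers and dataset manifests.

Conventions: a B-scan is a 2-D array with axial depth along rows (row 0
on the vitreous side) and the lateral dimension along columns; all
coordinates are 0-based with half-open ranges.  Pixels are either
integer (8/16-bit, range [0, 2^bits - 1]) or floating point in [0, 1].
Internal processing happens in floating point; quantization back to
8-bit occurs only at write time using round-half-even.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class Label(str, Enum):
    DME = "DME"
    NORMAL = "NORMAL"
    UNKNOWN = "UNKNOWN"


class FormatError(ValueError):
    """Raised when an on-disk volume violates the expected layout."""


def validate_bscan(img: np.ndarray, *, name: str = "B-scan") -> np.ndarray:
    """Check that ``img`` is a finite 2-D grayscale array within its declared range."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.floating):
        if not np.all(np.isfinite(img)):
            raise ValueError(f"{name} contains non-finite pixels")
        if img.min() < 0 or img.max() > 1:
            raise ValueError(f"{name} float intensities must lie in [0, 1]")
    return img


# one 2-D slice; alias kept for signature clarity
BScan = np.ndarray


@dataclass
class OCTVolume:
    """Ordered stack of same-shape B-scans; the unit of diagnosis."""

    scans: np.ndarray  # (n_scans, rows, cols)
    patient_id: str = ""
    label: Label = Label.UNKNOWN
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans)
        if self.scans.ndim != 3 or self.scans.shape[0] < 1:
            raise ValueError("OCTVolume requires a non-empty (n_scans, rows, cols) stack")
        if isinstance(self.label, str) and not isinstance(self.label, Label):
            self.label = Label(self.label.upper())
        if self.intensity_range is None:
            if np.issubdtype(self.scans.dtype, np.floating):
                self.intensity_range = (0.0, 1.0)
            else:
                self.intensity_range = (0, int(np.iinfo(self.scans.dtype).max))
        validate_bscan(self.scans[0])

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.scans.shape[1], self.scans.shape[2]


@dataclass
class DatasetManifest:
    """Rows of ``(volume_path, patient_id, label)`` describing a dataset."""

    entries: list[tuple[str, str, Label]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, lab in self.entries:
            out[lab.value] = out.get(lab.value, 0) + 1
        return out

    @property
    def patient_ids(self) -> list[str]:
        return [pid for _, pid, _ in self.entries]

    def by_label(self, label: Label) -> list[tuple[str, str, Label]]:
        return [e for e in self.entries if e[2] == label]


def _meta_path(path: Path, fmt: str) -> Path:
    if fmt == "PNG_DIR":
        return Path(path) / "volume.json"
    return Path(str(path) + ".json")


def read_volume(path: str | Path, fmt: str | None = None) -> OCTVolume:
    """Read an OCT volume from a multi-page TIFF or a directory of PNG slices.

    PNG slices are stacked in lexicographic filename order.  A JSON
    sidecar written by :func:`write_volume`, when present, restores the
    patient id, label and intensity range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if fmt is None:
        fmt = "PNG_DIR" if path.is_dir() else "TIFF_STACK"
    if fmt == "TIFF_STACK":
        scans = tifffile.imread(path)
        if scans.ndim == 2:
            scans = scans[None]
    elif fmt == "PNG_DIR":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FormatError(f"no PNG slices under {path}")
        slices = []
        shape = None
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # collapse grayscale-encoded RGB
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(f"slice {f.name} has shape {img.shape}, expected {shape}")
            slices.append(img)
        scans = np.stack(slices)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    meta = _meta_path(path, fmt)
    kwargs: dict = {}
    if meta.exists():
        info = json.loads(meta.read_text())
        kwargs = {
            "patient_id": info.get("patient_id", ""),
            "label": Label(info.get("label", "UNKNOWN")),
        }
        if "intensity_range" in info:
            kwargs["intensity_range"] = tuple(info["intensity_range"])
    return OCTVolume(scans=scans, **kwargs)


def to_uint8(scans: np.ndarray) -> np.ndarray:
    """Quantize float [0,1] data to 8-bit with round-half-even; pass integers through."""
    if np.issubdtype(scans.dtype, np.floating):
        return np.round(np.clip(scans, 0.0, 1.0) * 255.0).astype(np.uint8)
    return scans


def write_volume(vol: OCTVolume, path: str | Path, fmt: str = "TIFF_STACK") -> Path:
    """Write a volume as a multi-page TIFF or a PNG slice directory.

    Integer volumes (8/16-bit) round-trip losslessly; float volumes are
    quantized to 8-bit.  Patient id, label and intensity range go to a
    JSON sidecar next to the data.
    """
    if vol.scans.shape[0] < 1:
        raise ValueError("cannot write an empty volume")
    path = Path(path)
    data = to_uint8(vol.scans)
    if fmt == "TIFF_STACK":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
    elif fmt == "PNG_DIR":
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(vol.n_scans - 1)))
        for i, img in enumerate(data):
            iio.imwrite(path / f"b{i:0{width}d}.png", img)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta = {
        "patient_id": vol.patient_id,
        "label": vol.label.value,
        "intensity_range": list(vol.intensity_range),
    }
    _meta_path(path, fmt).write_text(json.dumps(meta))
    return path


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load a ``volume_path,patient_id,label`` CSV; labels normalize case-insensitively."""
    df = pd.read_csv(path, dtype=str)
    required = {"volume_path", "patient_id", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    entries: list[tuple[str, str, Label]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        token = str(row["label"]).strip().upper()
        if token not in (Label.DME.value, Label.NORMAL.value):
            raise ValueError(
                f"unknown label {row['label']!r} for {row['patient_id']!r}; allowed: DME, NORMAL"
            )
        pid = str(row["patient_id"])
        if pid in seen:
            raise ValueError(f"duplicate patient_id {pid!r} in manifest")
        seen.add(pid)
        entries.append((str(row["volume_path"]), pid, Label(token)))
    return DatasetManifest(entries=entries)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(p, pid, lab.value) for p, pid, lab in manifest.entries],
        columns=["volume_path", "patient_id", "label"],
    )
    df.to_csv(path, index=False)
    return path
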