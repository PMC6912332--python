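"""Image and cohort I/O.

Images are carried as :class:`GrayImage` — a float array on the 0–255 scale.
The 0–255 convention is kept end-to-end (no silent rescale to [0, 1]) because
the background/artifact intensity landmarks used by ROI extraction are
described on that scale.

Cohort manifests are CSV files with header ``patient_id,image_path,tirads``
(one row per image, optional ``split`` column with ``train``/``test``).
TI-RADS scores 2–3 map to the benign label, 4a/4b/4c/5 to malign.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "PatientRecord",
    "Cohort",
    "BENIGN",
    "MALIGN",
    "TIRADS_TOKENS",
    "tirads_to_label",
    "load_image",
    "read_manifest",
    "write_manifest",
]

BENIGN = "benign"
MALIGN = "malign"

#: TI-RADS vocabulary and the induced binary label.
TIRADS_TOKENS: dict[str, str] = {
    "2": BENIGN,
    "3": BENIGN,
    "4a": MALIGN,
    "4b": MALIGN,
    "4c": MALIGN,
    "5": MALIGN,
}

# ITU-R BT.601 luminance weights for RGB -> gray reduction.
_BT601 = np.array([0.299, 0.587, 0.114])


class ManifestError(ValueError):
    """Raised for malformed or inconsistent cohort manifests."""


class UnsupportedImageError(ValueError):
    """Raised for image files the pipeline cannot ingest (e.g. 16-bit depth)."""


@dataclass
class GrayImage:
    """A single-channel intensity image on the 0–255 float scale."""

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("GrayImage intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PatientRecord:
    """All images and the TI-RADS score of one patient."""

    patient_id: str
    image_paths: list[str]
    tirads: str
    split: str | None = None

    @property
    def label(self) -> str:
        return TIRADS_TOKENS[self.tirads]


@dataclass
class Cohort:
    """A set of patients with derived per-class counts."""

    records: list[PatientRecord] = field(default_factory=list)

    @property
    def n_benign(self) -> int:
        return sum(r.label == BENIGN for r in self.records)

    @property
    def n_malign(self) -> int:
        return sum(r.label == MALIGN for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, PatientRecord]:
        return {r.patient_id: r for r in self.records}


def tirads_to_label(token: str) -> str:
    """Map a TI-RADS token to ``benign``/``malign``.

    Tokens are case-insensitive and whitespace-trimmed; anything outside
    {2, 3, 4a, 4b, 4c, 5} raises :class:`ManifestError`.
    """
    key = token.strip().lower()
    if key not in TIRADS_TOKENS:
        raise ManifestError(f"unknown TI-RADS token {token!r}")
    return TIRADS_TOKENS[key]


def load_image(path: str | Path) -> GrayImage:
    """Load an 8-bit PNG/JPEG/BMP frame as a :class:`GrayImage`.

    Three-channel inputs are reduced to one luminance channel with the
    BT.601 combination 0.299 R + 0.587 G + 0.114 B; grayscale inputs pass
    through unchanged. 16-bit and palette-exotic depths are rejected.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("I;16", "I;16B", "I;16L", "I", "F"):
                raise UnsupportedImageError(
                    f"unsupported bit depth (mode {mode}) in {path}"
                )
            if mode == "P":
                im = im.convert("RGB")
                mode = "RGB"
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr @ _BT601
    arr = np.clip(arr, 0.0, 255.0)
    return GrayImage(arr, source_path=str(path))


def read_manifest(path: str | Path) -> Cohort:
    """Read a cohort manifest CSV, grouping rows by patient.

    Raises :class:`ManifestError` for an empty manifest, an unknown TI-RADS
    token (citing the row), or a patient whose rows disagree on TI-RADS.
    """
    path = Path(path)
    groups: dict[str, PatientRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "image_path", "tirads"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(
                f"manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            tok = row["tirads"].strip().lower()
            if tok not in TIRADS_TOKENS:
                raise ManifestError(
                    f"row {i}: unknown TI-RADS token {row['tirads']!r}"
                )
            split = (row.get("split") or "").strip().lower() or None
            if split is not None and split not in ("train", "test"):
                raise ManifestError(f"row {i}: bad split value {row['split']!r}")
            rec = groups.get(pid)
            if rec is None:
                groups[pid] = PatientRecord(pid, [row["image_path"]], tok, split)
            else:
                if rec.tirads != tok:
                    raise ManifestError(
                        f"row {i}: patient {pid!r} has conflicting TI-RADS "
                        f"values {rec.tirads!r} and {tok!r}"
                    )
                rec.image_paths.append(row["image_path"])
    if not groups:
        raise ManifestError(f"empty manifest: {path}")
    return Cohort(list(groups.values()))


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to manifest CSV form (inverse of read_manifest)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        has_split = any(r.split for r in cohort.records)
        header = ["patient_id", "image_path", "tirads"]
        if has_split:
            header.append("split")
        writer.writerow(header)
        for rec in cohort.records:
            for img in rec.image_paths:
                row = [rec.patient_id, img, rec.tirads]
                if has_split:
                    row.append(rec.split or "")
                writer.writerow(row)
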