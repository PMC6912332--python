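"""Synthetic ultrasound-phantom generator.

Emulates the gross structure of a clinical thyroid ultrasound frame so the
whole pipeline is testable without patient data: a near-zero background, a
few near-255 annotation glyphs outside the tissue, one large speckled
tissue region (the largest bright connected component by construction),
and — in malign phantoms — a hypoechoic nodule disc carrying bright
punctate calcifications. Calcifications sit on a jittered axis-aligned
lattice, so their spacing injects periodic energy along the spectral axes;
this is what makes the bar-family frequency masks discriminative on these
phantoms.

Speckle is the standard fully-developed-speckle surrogate: a
gamma-distributed multiplicative factor with mean one. A phantom's label
is determined by its calcification count (zero means benign); everything
else about the two classes is generated identically, so a "malign" spec
with the calcifications removed reproduces the benign image bit for bit.

All randomness flows from the spec's seed through one named generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .dataio import BENIGN, MALIGN, Cohort, GrayImage, PatientRecord, write_manifest

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_cohort"]


@dataclass
class PhantomSpec:
    frame_size: tuple[int, int] = (360, 560)        # (height, width)
    tissue_box: tuple[int, int, int, int] = (60, 120, 300, 440)  # half-open
    background_level: float = 8.0
    n_artifact_glyphs: int = 3
    artifact_intensity: float = 250.0
    speckle_mean: float = 120.0
    speckle_shape: float = 4.0       # gamma shape; larger = smoother speckle
    nodule_radius: int = 42
    nodule_contrast: float = 0.55    # hypoechoic factor applied inside the disc
    n_calcifications: int = 0        # 0 <=> benign
    calcification_radius: int = 2
    calcification_intensity: float = 245.0
    calcification_spacing: int = 9   # lattice pitch, px
    seed: int = 0

    @property
    def label(self) -> str:
        return BENIGN if self.n_calcifications == 0 else MALIGN

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.tissue_box
        h, w = self.frame_size
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError("tissue_box must lie inside the frame")
        for v in (self.background_level, self.artifact_intensity,
                  self.speckle_mean, self.calcification_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")


@dataclass
class PhantomTruth:
    tissue_box: tuple[int, int, int, int]
    nodule_center: tuple[int, int] | None
    nodule_radius: int
    calcification_centers: list[tuple[int, int]] = field(default_factory=list)


def _lattice_points(center, radius, spacing, n_wanted, jitter_rng):
    """Axis-aligned lattice inside a disc, nearest-to-center first."""
    reach = int(radius // spacing) + 1
    offs = np.arange(-reach, reach + 1) * spacing
    pts = [(center[0] + dr, center[1] + dc) for dr in offs for dc in offs
           if dr * dr + dc * dc <= radius * radius]
    pts.sort(key=lambda p: ((p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2,
                            p))
    if len(pts) < n_wanted:
        raise ValueError(
            f"nodule radius {radius} fits only {len(pts)} calcifications "
            f"at spacing {spacing}; {n_wanted} requested"
        )
    chosen = pts[:n_wanted]
    jit = jitter_rng.integers(-1, 2, size=(n_wanted, 2))
    return [(int(r + jr), int(c + jc)) for (r, c), (jr, jc) in zip(chosen, jit)]


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, str, PhantomTruth]:
    """Render one phantom frame; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    img = np.clip(spec.background_level + rng.normal(0, 2.0, (h, w)), 0, 255)

    r0, c0, r1, c1 = spec.tissue_box
    th, tw = r1 - r0, c1 - c0
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, (th, tw))
    tissue = spec.speckle_mean * speckle

    # hypoechoic nodule disc (both classes; benign nodules simply lack
    # calcifications)
    nodule_center = None
    if spec.nodule_radius > 0:
        margin = spec.nodule_radius + 4
        cr = int(rng.integers(margin, th - margin))
        cc = int(rng.integers(margin, tw - margin))
        rows, cols = np.ogrid[:th, :tw]
        disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= spec.nodule_radius ** 2
        tissue[disc] *= spec.nodule_contrast
        nodule_center = (r0 + cr, c0 + cc)

    img[r0:r1, c0:c1] = np.clip(tissue, 0, 255)

    # bright annotation glyphs in the margins, clear of the tissue box so
    # morphological closing cannot merge them into it
    gh, gw, clearance = 6, 10, 20
    for _ in range(spec.n_artifact_glyphs):
        for _attempt in range(100):
            gr = int(rng.integers(0, h - gh))
            gc = int(rng.integers(0, w - gw))
            if (gr + gh + clearance <= r0 or gr >= r1 + clearance or
                    gc + gw + clearance <= c0 or gc >= c1 + clearance):
                img[gr:gr + gh, gc:gc + gw] = spec.artifact_intensity
                break

    truth = PhantomTruth(tissue_box=spec.tissue_box,
                         nodule_center=nodule_center,
                         nodule_radius=spec.nodule_radius)

    if spec.n_calcifications > 0:
        if nodule_center is None:
            raise ValueError("calcifications require a nodule")
        inner = spec.nodule_radius - spec.calcification_radius - 1
        if inner <= 0:
            raise ValueError("nodule_radius too small to contain calcifications")
        centers = _lattice_points(nodule_center, inner,
                                  spec.calcification_spacing,
                                  spec.n_calcifications, rng)
        rows, cols = np.ogrid[:h, :w]
        for (pr, pc) in centers:
            disc = (rows - pr) ** 2 + (cols - pc) ** 2 \
                <= spec.calcification_radius ** 2
            img[disc] = spec.calcification_intensity
        truth.calcification_centers = centers

    return GrayImage(np.clip(img, 0, 255)), spec.label, truth


_BENIGN_TOKENS = ("2", "3")
_MALIGN_TOKENS = ("4a", "4b", "4c", "5")


def generate_cohort(n_benign: int, n_malign: int, out_dir: str | Path,
                    base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> Cohort:
    """Write a phantom cohort (PNGs + manifest.csv + ground_truth.json).

    Per-patient geometry (tissue-box placement, speckle mean, calcification
    count) is jittered from the base spec; benign patients get zero
    calcifications, malign patients around a dozen. Returns the cohort that
    ``read_manifest`` would reconstruct from the written manifest.
    """
    if n_benign < 0 or n_malign < 0:
        raise ValueError("counts must be >= 0")
    if n_benign + n_malign == 0:
        raise ValueError("cohort must contain at least one patient")
    base = base_spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records, truths = [], {}
    labels = [BENIGN] * n_benign + [MALIGN] * n_malign
    h, w = base.frame_size
    br0, bc0, br1, bc1 = base.tissue_box
    for i, label in enumerate(labels):
        pid = f"P{i:03d}"
        dr = int(rng.integers(-15, 16))
        dc = int(rng.integers(-15, 16))
        box = (max(0, br0 + dr), max(0, bc0 + dc),
               min(h, br1 + dr), min(w, bc1 + dc))
        n_cal = 0 if label == BENIGN else int(rng.integers(10, 15))
        spec = replace(
            base,
            tissue_box=box,
            speckle_mean=float(base.speckle_mean + rng.uniform(-10, 10)),
            n_calcifications=n_cal,
            seed=int(rng.integers(2**31)),
        )
        img, lab, truth = generate_phantom(spec)
        assert lab == label
        fname = f"{pid}.png"
        Image.fromarray(img.pixels.astype(np.uint8)).save(out_dir / fname)
        token = rng.choice(_BENIGN_TOKENS if label == BENIGN else _MALIGN_TOKENS)
        records.append(PatientRecord(pid, [str(out_dir / fname)], str(token)))
        truths[pid] = {
            "tissue_box": list(truth.tissue_box),
            "nodule_center": (list(truth.nodule_center)
                              if truth.nodule_center else None),
            "nodule_radius": truth.nodule_radius,
            "calcification_centers": [list(c) for c in
                                      truth.calcification_centers],
            "label": label,
        }
    cohort = Cohort(records)
    write_manifest(cohort, out_dir / "manifest.csv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truths, indent=2))
    return cohort
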