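"""Frequency-domain texture scoring and tri-state pre-classification.

The first cascade stage measures how much of a crop's spectral power falls
inside a selected frequency region. Punctate calcifications in malign
nodules shift energy into directional high frequencies, so the ratio

    fftscore = P_i / P

(selected power over total power, zero-frequency bin excluded from both)
separates the classes. Two thresholds calibrated on training scores split
the score axis into benign / benign-malign / malign; the middle band is an
abstention forwarded to the CNN stage.

Conventions: the crop is resampled to a fixed square (default 256) by
bilinear interpolation, mean-subtracted, transformed with the orthonormal
2-D DFT and center-shifted; power is the squared magnitude, so total power
equals side^2 x image variance (Parseval).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.metrics import roc_auc_score

from .dataio import GrayImage

__all__ = [
    "Spectrum", "FrequencyMask", "ThresholdModel", "TriState",
    "MASK_SHAPES", "power_spectrum", "make_mask", "fftscore",
    "calibrate_thresholds", "classify_frequency", "tune_mask",
    "DegenerateSpectrumError",
]

MASK_SHAPES = ("circle", "horizontal", "vertical", "plus", "circle_plus")

BENIGN_STATE = "benign"
UNDECIDED_STATE = "benign_malign"
MALIGN_STATE = "malign"


class DegenerateSpectrumError(ValueError):
    """Raised when scoring a spectrum with no off-DC power (flat image)."""


@dataclass
class Spectrum:
    """Centered 2-D power spectrum of a resampled crop."""

    power: np.ndarray          # side x side, non-negative, DC at (side/2, side/2)
    side: int
    total_power: float
    degenerate: bool = False   # True when the resampled image was constant

    @property
    def center(self) -> tuple[int, int]:
        return self.side // 2, self.side // 2


@dataclass
class FrequencyMask:
    """Boolean spectral-selection grid for one of the five mask shapes."""

    shape_kind: str
    side: int
    radius: float = 0.0
    bar_half_width: float = 0.0
    select: np.ndarray = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return int(self.select.sum())


@dataclass
class TriState:
    value: str  # benign | benign_malign | malign

    def __post_init__(self) -> None:
        if self.value not in (BENIGN_STATE, UNDECIDED_STATE, MALIGN_STATE):
            raise ValueError(f"bad tri-state {self.value!r}")


@dataclass
class ThresholdModel:
    """Calibrated (TH_LOW, TH_HIGH) pair with score orientation and mask."""

    th_low: float
    th_high: float
    direction: int               # +1: larger score => more malign
    mask: FrequencyMask | None = None
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.th_low > self.th_high:
            raise ValueError("th_low must be <= th_high")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def to_json(self, path: str | Path) -> None:
        m = self.mask
        payload = {
            "th_low": self.th_low, "th_high": self.th_high,
            "direction": self.direction, "alpha": self.alpha,
            "shape_kind": m.shape_kind if m else None,
            "radius": m.radius if m else None,
            "bar_half_width": m.bar_half_width if m else None,
            "side": m.side if m else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        d = json.loads(Path(path).read_text())
        mask = None
        if d.get("shape_kind"):
            mask = make_mask(d["shape_kind"], d["side"],
                             radius=d["radius"] or 0.0,
                             bar_half_width=d["bar_half_width"] or 0.0)
        return cls(d["th_low"], d["th_high"], d["direction"], mask, d["alpha"])


def power_spectrum(image: GrayImage, side: int = 256) -> Spectrum:
    """Resample to side x side, mean-subtract, orthonormal 2-D DFT, shift, square."""
    if side < 8 or side % 2:
        raise ValueError("side must be even and >= 8")
    px = resize(image.pixels, (side, side), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    px = px - px.mean()
    spec = np.fft.fftshift(np.fft.fft2(px, norm="ortho"))
    power = np.abs(spec) ** 2
    total = float(power.sum())
    return Spectrum(power=power, side=side, total_power=total,
                    degenerate=total <= 1e-12)


def make_mask(shape_kind: str, side: int, radius: float = 0.0,
              bar_half_width: float = 0.0) -> FrequencyMask:
    """Build one of the five spectral masks.

    circle: bins within Euclidean distance ``radius`` of the DC bin;
    horizontal / vertical: bands of rows / columns within
    ``bar_half_width`` of the center; plus and circle_plus are set unions.
    Geometry larger than the grid is simply clipped.
    """
    if shape_kind not in MASK_SHAPES:
        raise ValueError(f"shape_kind must be one of {MASK_SHAPES}")
    if radius < 0 or bar_half_width < 0:
        raise ValueError("radius and bar_half_width must be >= 0")
    cr = cc = side // 2
    rows, cols = np.ogrid[:side, :side]
    circle = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius ** 2
    horizontal = np.broadcast_to(np.abs(rows - cr) <= bar_half_width, (side, side))
    vertical = np.broadcast_to(np.abs(cols - cc) <= bar_half_width, (side, side))
    if shape_kind == "circle":
        select = circle
    elif shape_kind == "horizontal":
        select = horizontal.copy()
    elif shape_kind == "vertical":
        select = vertical.copy()
    elif shape_kind == "plus":
        select = horizontal | vertical
    else:
        select = circle | horizontal | vertical
    return FrequencyMask(shape_kind=shape_kind, side=side, radius=radius,
                         bar_half_width=bar_half_width, select=np.asarray(select))


def fftscore(spectrum: Spectrum, mask: FrequencyMask) -> float:
    """Ratio of selected to total spectral power, DC bin excluded from both."""
    if mask.side != spectrum.side:
        raise ValueError("mask side does not match spectrum side")
    cr, cc = spectrum.center
    power = spectrum.power.copy()
    power[cr, cc] = 0.0
    total = power.sum()
    if total <= 1e-12:
        raise DegenerateSpectrumError("no off-DC power; score undefined")
    return float(power[mask.select].sum() / total)


def calibrate_thresholds(benign_scores, malign_scores,
                         alpha: float = 0.0,
                         mask: FrequencyMask | None = None) -> ThresholdModel:
    """Calibrate (TH_LOW, TH_HIGH) from training scores.

    The score axis is oriented so malign sits high (direction learned from
    class medians). TH_LOW is the alpha-quantile of oriented malign scores
    (at most a fraction alpha of training malign falls below it) and
    TH_HIGH the (1-alpha)-quantile of oriented benign scores; quantiles use
    linear interpolation between order statistics. When the classes are
    separable (TH_LOW > TH_HIGH) both collapse to their midpoint, leaving
    an empty undecided band.
    """
    b = np.asarray(list(benign_scores), dtype=np.float64)
    m = np.asarray(list(malign_scores), dtype=np.float64)
    if len(b) < 2 or len(m) < 2:
        raise ValueError("need at least 2 scores per class to calibrate")
    if not 0 <= alpha < 0.5:
        raise ValueError("alpha must be in [0, 0.5)")
    direction = 1 if np.median(m) >= np.median(b) else -1
    ob, om = direction * b, direction * m
    th_low = float(np.quantile(om, alpha))
    th_high = float(np.quantile(ob, 1.0 - alpha))
    if th_low > th_high:
        mid = 0.5 * (th_low + th_high)
        th_low = th_high = mid
    return ThresholdModel(th_low=th_low, th_high=th_high,
                          direction=direction, mask=mask, alpha=alpha)


def classify_frequency(score: float, model: ThresholdModel) -> TriState:
    """Map a score through the tri-state rule; boundary values abstain."""
    s = model.direction * score
    if s < model.th_low:
        return TriState(BENIGN_STATE)
    if s > model.th_high:
        return TriState(MALIGN_STATE)
    return TriState(UNDECIDED_STATE)


def _candidate_masks(side, radii, bar_half_widths):
    for r in radii:
        yield make_mask("circle", side, radius=r)
    for w in bar_half_widths:
        for kind in ("horizontal", "vertical", "plus"):
            yield make_mask(kind, side, bar_half_width=w)
    for r in radii:
        for w in bar_half_widths:
            yield make_mask("circle_plus", side, radius=r, bar_half_width=w)


DEFAULT_RADII = (8, 16, 24, 32, 48)
DEFAULT_BAR_HALF_WIDTHS = (1, 2, 4, 8)


def tune_mask(images, labels, side: int = 256,
              radii=DEFAULT_RADII,
              bar_half_widths=DEFAULT_BAR_HALF_WIDTHS):
    """Pick the mask geometry whose scores best rank benign vs malign.

    Every (shape, geometry) candidate from the grid is scored on the
    training crops; candidates are ranked by ROC area of the benign-vs-
    malign score separation (orientation-free: AUC below 0.5 is flipped),
    ties broken toward the smaller selected-bin count. Returns
    (best_mask, best_auc).
    """
    radii, bar_half_widths = list(radii), list(bar_half_widths)
    if not radii and not bar_half_widths:
        raise ValueError("empty tuning grid")
    y = np.array([1 if lab == "malign" else 0 for lab in labels])
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples per class to tune")
    spectra = [power_spectrum(img, side) for img in images]
    best = None
    for mask in _candidate_masks(side, radii, bar_half_widths):
        scores = np.array([fftscore(sp, mask) for sp in spectra])
        auc = roc_auc_score(y, scores)
        auc = max(auc, 1.0 - auc)
        key = (auc, -mask.n_selected)
        if best is None or key > best[0]:
            best = (key, mask, auc)
    return best[1], best[2]
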