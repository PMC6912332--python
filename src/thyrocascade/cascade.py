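"""The two-stage cascade: FFT-score tri-state, then CNN on the undecided band.

Each image is ROI-extracted, spectrally scored and pushed through the
tri-state rule. A confident first-stage call (benign or malign) is final
and the CNN never runs; the benign-malign abstention is handed to the CNN,
whose label decides. Images whose crop has a degenerate spectrum (no off-DC
power) cannot be scored and fall through to the CNN as well.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cnn import TrainedModel, predict
from .dataio import Cohort, GrayImage, load_image
from .freqdomain import (BENIGN_STATE, MALIGN_STATE, UNDECIDED_STATE,
                         DegenerateSpectrumError, ThresholdModel,
                         classify_frequency, fftscore, power_spectrum)
from .roi import RoiParams, extract_roi

__all__ = ["CascadeDecision", "classify_image", "classify_cohort"]


@dataclass
class CascadeDecision:
    final_label: str                  # benign | malign
    stage: str                        # "fft" | "cnn"
    fft_score: float | None           # None if the spectrum was degenerate
    fft_state: str                    # tri-state value
    cnn_probability: float | None     # present iff stage == "cnn"


def classify_image(image: GrayImage,
                   threshold_model: ThresholdModel,
                   cnn_model: TrainedModel | None,
                   roi_params: RoiParams | None = None,
                   side: int = 256) -> CascadeDecision:
    """Run the full pipeline on one frame and return the decision."""
    roi = extract_roi(image, roi_params)
    spectrum = power_spectrum(roi.cropped, side=side)
    mask = threshold_model.mask
    if mask is None:
        raise ValueError("threshold model carries no frequency mask")
    try:
        score = fftscore(spectrum, mask)
        state = classify_frequency(score, threshold_model).value
    except DegenerateSpectrumError:
        score, state = None, UNDECIDED_STATE
    if state in (BENIGN_STATE, MALIGN_STATE):
        return CascadeDecision(final_label=state, stage="fft",
                               fft_score=score, fft_state=state,
                               cnn_probability=None)
    if cnn_model is None:
        raise ValueError("undecided image but no CNN model supplied")
    label, p_malign = predict(cnn_model, roi.cropped)
    return CascadeDecision(final_label=label, stage="cnn",
                           fft_score=score, fft_state=state,
                           cnn_probability=p_malign)


def classify_cohort(cohort: Cohort,
                    threshold_model: ThresholdModel,
                    cnn_model: TrainedModel | None,
                    roi_params: RoiParams | None = None,
                    side: int = 256):
    """Classify every image of a cohort in manifest order.

    Returns (decisions, failures): decisions are
    (patient_id, image_path, CascadeDecision) triples; per-image failures
    are collected as (patient_id, image_path, error-string) and do not stop
    the run.
    """
    decisions, failures = [], []
    for rec in cohort.records:
        for path in rec.image_paths:
            try:
                img = load_image(path)
                d = classify_image(img, threshold_model, cnn_model,
                                   roi_params=roi_params, side=side)
                decisions.append((rec.patient_id, path, d))
            except Exception as exc:  # noqa: BLE001 - partial-failure contract
                failures.append((rec.patient_id, path, str(exc)))
    return decisions, failures
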