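"""End-to-end pipeline assembly: fit both cascade stages from a cohort.

``fit_cascade`` performs the full training recipe on one cohort — ROI
extraction, mask selection, score calibration, CNN training — and
``cascade_pipeline_factory`` adapts it to the signature
``cross_validate`` expects (cohort in, per-image-path predictor out).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cascade import classify_image
from .cnn import TrainConfig, TrainedModel, build_classifier, train_classifier
from .dataio import Cohort, load_image
from .freqdomain import (FrequencyMask, ThresholdModel, calibrate_thresholds,
                         fftscore, power_spectrum, tune_mask)
from .roi import RoiParams, extract_roi

__all__ = ["FittedCascade", "fit_cascade", "cascade_pipeline_factory"]


@dataclass
class FittedCascade:
    threshold_model: ThresholdModel
    cnn_model: TrainedModel | None
    roi_params: RoiParams
    side: int

    def predict_image(self, image) -> str:
        return classify_image(image, self.threshold_model, self.cnn_model,
                              roi_params=self.roi_params,
                              side=self.side).final_label

    def predict_path(self, path: str) -> str:
        return self.predict_image(load_image(path))


def fit_cascade(cohort: Cohort,
                mask: FrequencyMask | None = None,
                alpha: float = 0.0,
                side: int = 256,
                backbone: str = "tiny_test",
                train_config: TrainConfig | None = None,
                roi_params: RoiParams | None = None,
                seed: int = 0,
                train_cnn: bool = True) -> FittedCascade:
    """Fit both cascade stages on one (training) cohort.

    With ``mask=None`` the mask geometry is tuned on the training scores;
    the threshold pair is then calibrated at ``alpha`` and the CNN stage is
    trained on every training crop (set ``train_cnn=False`` to skip it,
    e.g. when the calibration is known to be separable).
    """
    roi_params = roi_params or RoiParams()
    crops, labels = [], []
    for rec in cohort.records:
        for path in rec.image_paths:
            crops.append(extract_roi(load_image(path), roi_params).cropped)
            labels.append(rec.label)
    if mask is None:
        mask, _ = tune_mask(crops, labels, side)
    scores = [fftscore(power_spectrum(c, side), mask) for c in crops]
    benign = [s for s, lab in zip(scores, labels) if lab == "benign"]
    malign = [s for s, lab in zip(scores, labels) if lab == "malign"]
    tmodel = calibrate_thresholds(benign, malign, alpha=alpha, mask=mask)
    cnn_model = None
    if train_cnn:
        config = train_config or TrainConfig(seed=seed)
        spec, net = build_classifier(backbone, seed=seed)
        cnn_model = train_classifier(net, list(zip(crops, labels)), config,
                                     spec=spec)
    return FittedCascade(threshold_model=tmodel, cnn_model=cnn_model,
                         roi_params=roi_params, side=side)


def cascade_pipeline_factory(**fit_kwargs):
    """Factory adapter for :func:`thyrocascade.evaluation.cross_validate`."""

    def factory(train_cohort: Cohort):
        fitted = fit_cascade(train_cohort, **fit_kwargs)
        return fitted.predict_path

    return factory
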