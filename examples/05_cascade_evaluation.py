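"""Cross-validate the full cascade on a phantom cohort.

Per fold: mask tuning, threshold calibration and CNN training happen on
the training patients only; the held-out patients are classified through
the two-stage cascade and scored with sensitivity (malign caught),
specificity (benign cleared) and accuracy.
"""

from pathlib import Path

from thyrocascade import (SplitScheme, cascade_pipeline_factory,
                          cross_validate, generate_cohort)

out = Path("scratch/eval_cohort")
cohort = generate_cohort(20, 20, out, seed=7)
scheme = SplitScheme(n_folds=2, test_benign=5, test_malign=5, seed=7)
report = cross_validate(cohort, scheme, cascade_pipeline_factory(seed=7))

for k, fold in enumerate(report.per_fold):
    c = fold.counts
    print(f"fold {k}: TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}  "
          f"sens={fold.sensitivity:.3f} spec={fold.specificity:.3f} "
          f"acc={fold.accuracy:.3f}")
print(f"mean accuracy    {report.mean_accuracy:.3f}")
print(f"mean sensitivity {report.mean_sensitivity:.3f}")
print(f"mean specificity {report.mean_specificity:.3f}")
# On these separable phantoms the frequency stage alone decides nearly
# every image, so the cascade reaches perfect or near-perfect accuracy.
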