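"""Generate a synthetic ultrasound-phantom cohort and inspect one frame.

Each phantom mimics the gross structure of a clinical thyroid frame:
near-zero background, bright annotation glyphs, a large speckled tissue
region, and (for malign cases) a hypoechoic nodule carrying bright
punctate calcifications.
"""

from pathlib import Path

import numpy as np

from thyrocascade import PhantomSpec, generate_cohort, generate_phantom

out = Path("scratch/example_cohort")
cohort = generate_cohort(5, 5, out, seed=7)
print(f"wrote {len(cohort)} phantoms ({cohort.n_benign} benign, "
      f"{cohort.n_malign} malign) to {out}/")
print(f"manifest: {out / 'manifest.csv'}")

img, label, truth = generate_phantom(PhantomSpec(seed=1, n_calcifications=12))
px = img.pixels
r0, c0, r1, c1 = truth.tissue_box
print(f"\nsingle malign phantom ({img.height}x{img.width}):")
print(f"  background median {np.median(px[:40, :40]):.1f}  "
      f"(dark, near the nominal level of 8)")
print(f"  tissue mean {px[r0:r1, c0:c1].mean():.1f}  (speckled, bright)")
print(f"  {len(truth.calcification_centers)} calcifications inside the "
      f"nodule at {truth.nodule_center}")
# The calcification count is what makes this phantom 'malign'; a benign
# phantom with the same seed is identical except for those discs.
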