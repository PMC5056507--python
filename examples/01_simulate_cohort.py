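"""Simulate a paired nodule cohort under the four CT acquisition groups.

Each subject gets one base texture observed four ways: group 1 is the
reference (non-contrast, thin slice, standard kernel), group 2 adds
contrast enhancement, group 3 thick-slice partial-volume blurring, and
group 4 additionally the sharp, noisy lung kernel.
"""

import numpy as np

from spnradiomics import CohortSpec, ImageSlice, roi_geometry, simulate_cohort

spec = CohortSpec(n_benign=5, n_malignant=5, seed=1)
cohort = simulate_cohort(spec)

print(f"{len(cohort)} subjects x {len(cohort[0].images)} acquisition groups")
for subject in cohort[:3]:
    area, diam = roi_geometry(subject.images[1], subject.mask)
    in_mask = subject.images[1].pixels[subject.mask.mask]
    print(
        f"{subject.subject_id} ({subject.class_label:9s}) "
        f"ROI {area:6.1f} mm^2, diameter {diam:4.1f} mm, "
        f"in-mask HU sd {in_mask.std():5.1f}"
    )

# the same subject differs between groups only through the acquisition
# operator; the lung kernel (group 4) visibly raises high-frequency content
s = cohort[0]
for gid, img in s.images.items():
    vals = img.pixels[s.mask.mask]
    grad = np.abs(np.diff(img.pixels, axis=1))[s.mask.mask[:, 1:]].mean()
    print(f"group {gid}: in-mask mean {vals.mean():6.1f} HU, "
          f"mean |horizontal gradient| {grad:5.1f} HU")
print("Malignant nodules are simulated with higher HU variance and finer "
      "texture than benign ones; group operators degrade or confound that "
      "signal.")
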