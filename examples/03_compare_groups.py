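"""Compare two participant groups on a synthetic cohort.

Generates a small cohort in which clinicians attend the condition
feature and non-clinicians only the landmarks, builds group-average maps
at both noise thresholds, and shows the characteristic trend: the groups
diverge more (lower IoU, higher KL) at the high threshold.
"""

import numpy as np

from gazesal import (ThresholdSpec, apply_noise_threshold, average_maps,
                     common_attention, iou, smooth, subtract_common,
                     symmetric_kl)
from gazesal.synthetic import generate_cohort, generate_layout

cohort = generate_cohort(n_clin=8, n_nonclin=8, n_images=4, seed=3)
layout = generate_layout(3, image_ids=cohort.affected_ids)

by_group = {"clinician": [], "nonclinician": []}
for m in cohort.maps:
    by_group[m.group].append(m)
common = {g: common_attention(ms) for g, ms in by_group.items()}

for level, frac in (("low", 0.07), ("high", 0.035)):
    spec = ThresholdSpec("coverage_fraction", frac)
    ious, kls = [], []
    for image_id in cohort.image_ids:
        avgs = {}
        for g, ms in by_group.items():
            members = [subtract_common(m, common[g]) for m in ms
                       if m.image_id == image_id]
            avg = smooth(average_maps(members), 15)
            avgs[g] = apply_noise_threshold(avg, spec, mask=layout.mask,
                                            level=level)
        ious.append(iou(avgs["clinician"].values, avgs["nonclinician"].values))
        kls.append(symmetric_kl(avgs["clinician"].values,
                                avgs["nonclinician"].values, mask=layout.mask))
    print(f"{level:>4} threshold ({frac:.1%} of face region): "
          f"mean IoU {np.mean(ious):.3f}, mean KL {np.mean(kls):.2f} nats")
# Expected: IoU drops and KL rises from low to high — restricting the
# analysis to peak attention exposes the groups' different priorities.
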