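"""Detection metrics and segmentation-consistency errors.

First computes the five confusion metrics from a batch of predicted/actual
records, then compares two segmentations of the same phantom (different
noise realisations) with the Martin consistency errors and the object-level
consistency error.
"""

import numpy as np

from ctstroke import (ConfusionCounts, PhantomSpec, confusion_metrics,
                      consistency_errors, extract_brain, generate_phantom,
                      to_display, urga)

counts = ConfusionCounts(tpn=51, fpn=6, tnn=26, fnn=7)
rep = confusion_metrics(counts)
print(f"confusion counts: TPN={counts.tpn} FPN={counts.fpn} "
      f"TNN={counts.tnn} FNN={counts.fnn} (n={counts.total})")
print(f"  sensitivity/DR {rep.dr:.2f}%   specificity {rep.specificity:.2f}%")
print(f"  precision      {rep.precision:.2f}%   accuracy/CR {rep.cr:.2f}%")
print(f"  false alarms   {rep.far:.2f}%  (= 100 - specificity)")

segs = []
for seed in (1, 2):
    ct, truth = generate_phantom(PhantomSpec(size=192, lesion_side="none",
                                             seed=seed, noise_sd=1.0))
    mask = extract_brain(to_display(ct))
    segs.append(urga(to_display(ct), mask, canny_low=2.0, canny_high=8.0,
                     min_seed_intensity=0.0))
support = (segs[0] > 0) & (segs[1] > 0)
cons = consistency_errors(segs[0], segs[1], support=support)
print(f"consistency between two noise realisations: "
      f"LCE {cons.lce:.4f}  GCE {cons.gce:.4f}  OCE {cons.oce:.4f}")
print("(0 = identical up to refinement; 1 = total disagreement)")
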