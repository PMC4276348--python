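"""Inspect the intermediate stages: enhancement, segmentation, partition.

Shows the fitted cubic tone curve, the number of regions the unsupervised
region-growing segmentation finds, and the mean brightness of the eight
hemispheric regions that drive lateralization.  The planted lesion darkens
the left-side regions, which is exactly the asymmetry the method looks for.
"""

import numpy as np

from ctstroke import (PhantomSpec, anisotropic_smooth, enhance, extract_brain,
                      generate_phantom, partition_eight, region_means,
                      to_display, urga)

ct, truth = generate_phantom(PhantomSpec(size=256, seed=3, lesion_side="left"))
display = to_display(ct)                       # brain window: 35 +/- 40 HU
enhanced, curve = enhance(display)
print(f"tone curve: a={curve.a:.3e} b={curve.b:.3e} c={curve.c:.3f} "
      f"(inflection at {curve.inflection:.1f}/255)")

mask = extract_brain(display)
print(f"brain mask: {mask.sum()} px "
      f"({100 * mask.sum() / truth.brain_mask.sum():.1f}% of ground truth)")

smoothed = anisotropic_smooth(enhanced)
labels = urga(smoothed, mask)
print(f"segmentation: {labels.max()} region(s) cover every masked pixel")

parts = partition_eight(mask)
means = region_means(smoothed, parts)
print("region mean brightness (display units; lower = more hypodense):")
for key in sorted(means, key=lambda k: means[k]):
    print(f"  {'-'.join(key):24s} {means[key]:7.2f}")
left = np.mean([v for k, v in means.items() if k[0] == "left"])
right = np.mean([v for k, v in means.items() if k[0] == "right"])
print(f"hemisphere means: left {left:.2f} vs right {right:.2f} "
      "(the darker side carries the suspected stroke)")
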