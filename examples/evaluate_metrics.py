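"""Evaluate perturbed masks: DSC with bootstrap CI, HD95 and ASD.

Takes ten phantom ground-truth masks, simulates a systematically
oversegmenting model by dilating each region one pixel, and runs the full
evaluation report.  DSC captures overlap, HD95 the worst boundary error
(95th percentile, robust to stray pixels), ASD the mean boundary error.
"""

import numpy as np
from scipy.ndimage import binary_dilation

from fundusseg import PhantomSpec, evaluate_dataset, generate_phantom

gts, preds = [], []
for i in range(10):
    _, mask, _ = generate_phantom(PhantomSpec(image_size=256,
                                              disc_radii=(34, 30),
                                              cup_to_disc_ratio=0.45 + 0.02 * i,
                                              seed=300 + i))
    pred = np.zeros_like(mask)
    pred[binary_dilation(mask >= 1)] = 1
    pred[binary_dilation(mask == 2)] = 2
    gts.append(mask)
    preds.append(pred)

report = evaluate_dataset(preds, gts, num_classes=3, reps=10_000, seed=112316)
for region, entry in report.summary["regions"].items():
    lo, hi = entry["dsc_ci95"]
    print(f"{region}: DSC {entry['dsc_mean']:.4f} (95% CI {lo:.4f}–{hi:.4f})  "
          f"HD95 {entry['hd95_mean']:.2f} px  ASD {entry['asd_mean']:.2f} px")

print("\nA 1-px dilation leaves DSC near 1 while HD95/ASD sit near 1 px — the "
      "distance metrics expose boundary errors that overlap metrics dilute.")
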