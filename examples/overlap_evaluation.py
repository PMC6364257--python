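"""The sigma-overlap pixel protocol on hand-made masks.

Shows how the component rules reshape raw pixel counts: a detection
covering a quarter of a lesion promotes the whole lesion to true
positive once its overlap ratio clears sigma.
"""

import numpy as np

from exudate import pixel_level_eval, pixel_metrics

truth = np.zeros((64, 64), dtype=bool)
truth[10:30, 10:30] = True            # one 400-px lesion

detected = np.zeros_like(truth)
detected[12:22, 12:22] = True         # 100 px inside it  (ratio 0.25)
detected[45:50, 45:50] = True         # 25 px of false alarm

for sigma in (0.0, 0.2, 0.3, 1.0):
    res = pixel_level_eval(detected, truth, sigma=sigma)
    met = pixel_metrics(res)
    print(f"sigma={sigma:<4}  TP={res.tp:<4} FP={res.fp:<3} FN={res.fn:<4} "
          f"S={met.sensitivity:.2f} PPV={met.ppv:.2f} F={met.fscore:.2f}")

print()
print("At sigma <= 0.2 the 0.25 overlap ratio promotes the whole 400-px")
print("lesion (TP=400, FN=0); at sigma=0.3 only the overlapping 100 px")
print("count and the rest of the lesion becomes FN. The disjoint 25-px")
print("detection is FP at every sigma.")
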