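"""Remove specular glare from a synthetic colposcopy phantom and score it.

Builds a 224×224 phantom (pink tissue, vessels, 5 glare spots, 2 acetowhite
patches), runs the three-stage pipeline, and compares the repaired image to
the glare-free reference over the damaged region.
"""

import numpy as np

from despeckle import default_phantom, run_arrays, score_detection, score_restoration

phantom = default_phantom(seed=1)
result = run_arrays(phantom.corrupted)

precision, recall, iou = score_detection(result.union_mask, phantom.truth_mask)
psnr_in, mae_in = score_restoration(phantom.corrupted, phantom.clean, phantom.truth_mask)
psnr_out, mae_out = score_restoration(result.final, phantom.clean, phantom.truth_mask)
aw_hits = np.count_nonzero(result.union_mask & phantom.aw_mask)

print(f"planted glare pixels      : {phantom.truth_mask.sum()}")
print(f"detected mask pixels      : {result.union_mask.sum()}")
print(f"detection recall          : {recall:.3f}")
print(f"acetowhite pixels flagged : {aw_hits}")
print(f"PSNR over glare, before   : {psnr_in:.1f} dB  (MAE {mae_in:.1f})")
print(f"PSNR over glare, after    : {psnr_out:.1f} dB  (MAE {mae_out:.1f})")

# Recall near 1 with zero acetowhite hits means the pipeline removed the
# glare without touching the diagnostically meaningful white patches; the
# PSNR jump is the quality of the tissue synthesized where glare was.
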