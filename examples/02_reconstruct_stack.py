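"""Reconstruct a 3D stain volume from misaligned, drifted sections.

Segments each section, serially aligns the stack with the two-stage rigid
procedure, removes the intensity drift per stain, and stacks the CO
sections into an isotropic volume. Prints the recovered alignment quality
against the phantom's planted ground truth.
"""

import numpy as np

from stainmap import default_config, generate_phantom
from stainmap.registration import (correct_intensity_drift, dice_coefficient,
                                   serial_align, stack_to_volume)

ds = generate_phantom(default_config(n_sections=12, seed=7))
aln = serial_align(ds.sections)

gm = [s.gm_mask for s in aln.aligned_segmentations]
dices = [dice_coefficient(a, b) for a, b in zip(gm[:-1], gm[1:])]
print(f"adjacent GM Dice after alignment: min {min(dices):.3f}, "
      f"mean {np.mean(dices):.3f}")
# >= 0.95 everywhere means neighboring sections overlay like a coherent
# 3D block rather than a scrambled deck

co_idx = [i for i, s in enumerate(ds.sections) if s.stain == "co"]
imgs = [aln.aligned_images[i] for i in co_idx]
masks = [aln.aligned_segmentations[i].labels > 0 for i in co_idx]
fixed, model = correct_intensity_drift(imgs, masks, section_indices=co_idx)
print("drift fit (a, b, c):", np.round(model.coefficients, 4))
print("per-section deviations removed:", np.round(model.residuals, 2))

vol = stack_to_volume(fixed, spacing_um=100.0, pixel_size_um=25.0, stain="co")
print(f"CO volume: {vol.n_slices} slices of {vol.data.shape[1:]} "
      f"({sum(p.startswith('section') for p in vol.provenance)} original, "
      f"rest interpolated)")
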