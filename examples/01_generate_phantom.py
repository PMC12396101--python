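"""Generate a synthetic serial-section dataset and look at its ground truth.

Builds a 12-section phantom hemisphere (alternating CO / myelin stains,
misaligned and drifted), prints the planted nuisance parameters, and
writes the sections plus the reference volume to ./phantom_out.
"""

import numpy as np

from stainmap import default_config, generate_phantom
from stainmap.io import save_json, save_nifti, save_sections

cfg = default_config(n_sections=12, seed=7)
ds = generate_phantom(cfg)

print(f"{ds.n_sections} sections, image shape {cfg.image_shape}, "
      f"{cfg.section_spacing_um:g} um spacing, {cfg.pixel_size_um:g} um pixels")
for i in (0, 5, 11):
    tf = ds.truth_transforms[i]
    print(f"  section {i:2d} ({ds.sections[i].stain:6s}): planted rotation "
          f"{tf.rotation_deg:+.2f} deg, translation "
          f"({tf.translation[0]:+.1f}, {tf.translation[1]:+.1f}) px, "
          f"drift offset {ds.truth_drift[i]:+.4f} darkness")
print("ROIs:", {k: int(sum(m.sum() for m in v))
               for k, v in ds.roi_masks.items()}, "(total truth pixels)")

save_sections(ds.sections, "phantom_out/sections")
save_nifti(ds.reference_volume, "phantom_out/reference.nii.gz",
           (0.05, 0.025, 0.025))
save_json({"truth_drift": ds.truth_drift.tolist()}, "phantom_out/truth.json")
print("wrote phantom_out/  (sections as 8-bit TIFF, reference as NIfTI)")

# the per-section rotations/translations above are what the serial
# registration stage must recover; the drift offsets are what the
# quadratic intensity correction must remove
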