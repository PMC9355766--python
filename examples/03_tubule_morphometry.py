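"""Measure peritubule size and organization on a synthetic SHG image.

A stripe field with a 5.93 µm period — the width-age line evaluated at
age 82 — is generated at 20° with mild orientation jitter; the dominant
orientation is found by Hough voting, the size by valley spacing on
perpendicular cross-sections, and the organization by the structure
tensor's structural dispersion (SD).
"""

from dentinemp import (MPImage, TubuleFieldParams, estimate_orientation_hough,
                       generate_patchwork_field, generate_tubule_field,
                       peritubule_width, structure_tensor_sd)

params = TubuleFieldParams(period_um=5.93, orientation_deg=20.0,
                           jitter_deg=3.0, n_px=512, field_um=180.0)
img = MPImage(generate_tubule_field(params, seed=2), "SHG",
              params.pixel_size_um)

ori = estimate_orientation_hough(img)
tm = peritubule_width(img, ori)
om = structure_tensor_sd(img)

print(f"dominant orientation (Hough)  : {ori:.1f} deg   (truth 20.0)")
print(f"peritubule size               : {tm.width_um:.2f} um  (truth 5.93)")
print(f"  from {tm.n_valleys} valleys on {tm.sections_used} cross-sections")
print(f"structural dispersion SD      : {om.sd_deg:.1f} deg -> {om.org_class}")
print()

# a disorganized counter-example: stripe patches at random orientations
patch = MPImage(generate_patchwork_field(params, seed=2), "SHG",
                params.pixel_size_um)
om2 = structure_tensor_sd(patch)
print(f"random patchwork SD           : {om2.sd_deg:.1f} deg -> {om2.org_class}")
print()
print("SD <= 20 deg marks a quasi-aligned (organized) tubular arrangement;")
print("SD > 40 deg a disorganized one.  Real dentine stays organized with age")
print("even as the peritubule size grows.")
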