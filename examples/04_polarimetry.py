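"""Invert three polarimetric SHG images into a signed rho map.

A stack at incident polarizations 0°/90°/60° is rendered with the
hyperpolarizability ratio rho = −1.25 (a value reported for a young
specimen) and fibers at 0°; the inversion takes |rho| from the
parallel/perpendicular intensity ratio and the sign from the 60° state.
"""

from dentinemp import (PolarimetricRenderParams, TubuleFieldParams,
                       generate_tubule_field, render_polarimetric_stack,
                       rho_map)

params = TubuleFieldParams(period_um=5.0, n_px=256, field_um=90.0)
pattern = generate_tubule_field(params, seed=3)
stack = render_polarimetric_stack(
    pattern, PolarimetricRenderParams(rho=-1.25, baseline=0.15),
    fiber_orientation_deg=0.0, seed=3, pixel_size_um=params.pixel_size_um)

rm = rho_map(stack)  # fiber orientation estimated from the stack itself

print(f"fiber orientation used : {rm.fiber_orientation_deg:.1f} deg")
print(f"recovered rho          : {rm.summary_mean:.4f} ± {rm.summary_sd:.4f}")
print(f"masked pixel fraction  : {rm.masked_fraction:.3f}")
print()
print("The noiseless inversion recovers rho = -1.25 essentially exactly.")
print("Negative rho reflects collagen chirality; its magnitude grows (more")
print("negative values) as the internal nanoscale order increases with age.")
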