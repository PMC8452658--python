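"""Measure the spatial scale effect of the nonlinear NDVI-LAI inversion.

Compares the two upscaling routes on two scenes: a bright-soil landscape of
small mixed fields, and a uniform dark-soil crop scene. U1 inverts at fine
resolution and then averages; U2 averages reflectance first and inverts
once per coarse pixel. Their difference is the scale effect.
"""

from lairef import ModelParams, SceneConfig, ndvi, scaling_difference, \
    upscale_u1, upscale_u2
from lairef.synthetic import generate_landscape, render_reflectance

params = ModelParams(0.93, 0.15, 1.58)

for label, cfg in [
    ("bright soil, mixed fields", SceneConfig(
        seed=2, n_rows=60, n_cols=60, field_block_pixels=5,
        crop_fraction=0.5, soil_brightness="bright", ndvi_noise_sd=0.0)),
    ("dark soil, uniform crop", SceneConfig(
        seed=2, n_rows=60, n_cols=60, field_block_pixels=60,
        crop_fraction=1.0, soil_brightness="dark", ndvi_noise_sd=0.0)),
]:
    truth = render_reflectance(generate_landscape(cfg), cfg)
    u1 = upscale_u1(ndvi(truth.red, truth.nir), params, cfg.coarse_factor)
    u2 = upscale_u2(truth.red, truth.nir, params, cfg.coarse_factor)
    res = scaling_difference(u1, u2)
    print(f"{label}: mean U1 {res.mean_u1:.3f}  mean U2 {res.mean_u2:.3f}  "
          f"scaling difference {res.mean_difference:+.3f}")

print("A positive difference means the average-first route (which a coarse "
      "sensor resembles) underestimates LAI on mixed pixels; the effect "
      "nearly vanishes on homogeneous scenes.")
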