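"""Identify mitochondria in a noisy LAC volume by their attenuation signature.

Mitochondria in buffer occupy a characteristic LAC band; a window
threshold plus connectivity and size filtering separates them from
buffer and from denser debris.
"""

from sxtmorph import PhantomSpec, RunConfig, apply_optics, identify_objects, make_phantom

spec = PhantomSpec(n_objects=3, shape=(112, 112, 112), noise_scale=3000.0, seed=42)
truth = make_phantom(spec)
lac = apply_optics(truth.lac_volume, spec.psf_fwhm, spec.noise_scale, seed=42)

cfg = RunConfig(lac_window=(0.20, 0.35), size_window=(0.02, 1.0), seed=42)
objects = identify_objects(lac, cfg)

print(f"true objects: {spec.n_objects}, identified: {len(objects)}")
print(f"{'id':>3} {'volume µm³':>11} {'mean LAC µm⁻¹':>14}")
for obj in objects:
    print(f"{obj.object_id:>3} {obj.volume:>11.3f} {obj.mean_lac:>14.3f}")
# mean LAC per object should sit near 0.25 — inside the mitochondrial
# window and well separated from the 0.10 buffer
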