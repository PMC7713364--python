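"""LAC conversion, Beer-Lambert projection, and the absorbed-dose calculator.

Shows that per-voxel absorbance divided by the voxel size gives a LAC
map, that projection + log-inversion recovers ray-mean LAC exactly, and
what dose a typical water-window acquisition deposits.
"""

import numpy as np

from sxtmorph import (
    AcquisitionParams,
    PhantomSpec,
    Units,
    VoxelGrid3D,
    absorbance_to_lac,
    compute_dose,
    make_phantom,
    project_beer_lambert,
)

# absorbance 0.00494 per 20-nm voxel -> LAC 0.247 µm^-1 (the measured
# mean for isolated mitochondria)
absorbance = VoxelGrid3D(np.full((8, 8, 8), 0.00494), 0.02, Units.ABSORBANCE)
lac = absorbance_to_lac(absorbance)
print(f"absorbance 0.00494 / 0.02 µm -> LAC {lac.data[0,0,0]:.3f} µm⁻¹")

truth = make_phantom(PhantomSpec(n_objects=1, shape=(80, 80, 80), seed=0))
proj = project_beer_lambert(truth.lac_volume, axis="z")
n = truth.lac_volume.shape[0]
recovered = -np.log(proj.data[0]) / (n * 0.02)
err = np.abs(recovered - truth.lac_volume.data.mean(axis=0)).max()
print(f"Beer-Lambert round trip: max ray-mean LAC error {err:.1e} µm⁻¹ (machine precision)")

# 90 projections × 0.3 s at 517 eV through µ = 0.247 µm^-1 material
dose = compute_dose(AcquisitionParams.from_ev(
    F=1e18, mu=2.47e5, energy_ev=517, Et=27, rho=1050,
))
print(f"dose for flux 1e18 ph/m²/s, 27 s total exposure: {dose.D:.3g} Gy")
# cryo-preserved specimens tolerate up to ~1e10 Gy, so this is safe
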