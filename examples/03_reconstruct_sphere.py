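"""Tomographic reconstruction of a weak-contrast sphere.

Simulates a 60-angle scan of a Δn = 0.002 sphere, reconstructs the RI map
via the Fourier diffraction theorem, and shows how Gerchberg–Papoulis
missing-cone regularization restores the underestimated contrast.
"""

import numpy as np

from odtquant import (
    OpticalConfig,
    RITomogram,
    forward_scatter_stack,
    generate_angles,
    invert_spectrum,
    map_fields_to_spectrum,
    regularize_missing_cone,
)

config = OpticalConfig(voxel_size_um=(0.25, 0.25, 0.25))
n = 64
ax = (np.arange(n) - (n - 1) / 2) * 0.25
z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
mask = z**2 + y**2 + x**2 <= 2.0**2
vals = np.full((n, n, n), config.medium_ri)
vals[mask] += 0.002
tomo = RITomogram(vals, config.voxel_size_um, config.medium_ri)

scheme = generate_angles("circular", 60, config, seed=0)
fields = forward_scatter_stack(tomo, scheme, config)
kvol = map_fields_to_spectrum(fields, scheme, config, tomo.shape)
print(f"k-space coverage: {100 * (kvol.weights > 0).mean():.1f}% of voxels "
      f"(the rest includes the missing cone)")

raw = invert_spectrum(kvol, config)
reg = regularize_missing_cone(raw, kvol, config, n_iter=100)
for label, rec in [("unregularized", raw), ("regularized  ", reg)]:
    dn = rec.values[mask].mean() - config.medium_ri
    print(f"{label}: mean Δn inside sphere {dn:.5f}  "
          f"({100 * dn / 0.002:.1f}% of the true 0.00200)")
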