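"""System characteristics and the RI ↔ mass-density model.

Prints the diffraction-limited resolution of the tomographic microscope,
converts compartment refractive indices to dry-mass densities, and
evaluates the Van't Hoff osmotic pressure of a protein solution.
"""

from odtquant import (
    OpticalConfig,
    osmotic_pressure,
    ri_to_density,
    theoretical_resolution,
)

config = OpticalConfig()  # 532 nm, NA 1.2 / 1.0, medium RI 1.3370
lateral, axial = theoretical_resolution(config)
print(f"lateral resolution : {lateral:6.1f} nm  (half-period of the synthetic aperture)")
print(f"axial resolution   : {axial:6.1f} nm  (inverse axial k-support)")

for name, ri in [("cytoplasm", 1.3538), ("nucleoplasm", 1.3528)]:
    rho = ri_to_density(ri, config)
    print(f"{name:12s} RI {ri:.4f} -> {rho:6.2f} mg/mL dry-mass density")

# precision of the RI measurement expressed as a density
print(f"RI SE 4.15e-5      -> {ri_to_density(1.3370 + 4.15e-5):.2f} mg/mL")

# osmotic pressure of an 80 mg/mL solution of 50 kDa protein at 37 °C
pi = osmotic_pressure(80.0, 310.15, 50_000.0)
print(f"osmotic pressure   : {pi:7.0f} Pa  (Π = ρRT/M)")
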