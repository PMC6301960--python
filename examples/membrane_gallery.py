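"""Membrane geometries: query heights and normals for the three surface kinds.

Builds a flat membrane, the papillary-scale sinusoid, and the #255 textile
fiber grid, and prints surface heights at landmark points. Heights are in um;
the sinusoid's amplitude is peak-to-trough; the fiber crown rises one fiber
thickness above the base plane.
"""

import numpy as np

from epidermsim import MembraneSpec, membrane_gap, membrane_height

flat = MembraneSpec(kind="flat")
sin = MembraneSpec(kind="sinusoidal", amplitude_um=50, wavelength_um=100)
fiber = MembraneSpec.from_preset("#255")  # thickness 60 um, interval 101 um

print("flat     h(12, 34)          =", membrane_height(flat, 12.0, 34.0))
print("sinusoid h(25, 25) [peak]   =", membrane_height(sin, 25.0, 25.0))
print("sinusoid h(75, 25) [trough] =", membrane_height(sin, 75.0, 25.0))
print("fiber    h on axis          =", membrane_height(fiber, 0.0, 50.0))
mid = fiber.fiber_period_um / 2
print("fiber    h between fibers   =", membrane_height(fiber, mid, mid))

gap, normal = membrane_gap(sin, [25.0, 25.0, 30.0])
print("clearance of a point 30 um up over the peak:", gap,
      "(5 um above the 25 um crest); outward normal", np.round(normal, 3))
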