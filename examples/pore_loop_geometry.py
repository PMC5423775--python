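"""Geometry of the substrate-gripping pore-loop staircase.

Builds a synthetic pore-loop point set — five gripping protomers on an ideal
helix plus an off-helix seam protomer, with coordinate jitter — fits the
helical parameters with leave-one-out seam detection, and computes the
derived measurements: pore aperture, inter-ring pore tilt, grip extent and
the filament layer line implied by the helical pitch.
"""

import numpy as np

from ringmotor import (
    aperture,
    fit_helix,
    gen_pore_loop_helix,
    grip_extent,
    layer_line,
    measure_layer_line,
    pore_tilt,
)

loops = gen_pore_loop_helix(n=6, rise=13.0, twist=60.0, radius=14.0,
                            jitter_sd=0.3, seed=21)
h = fit_helix(loops)
print(f"fitted rise  {h.rise:6.2f} A   (programmed 13.0)")
print(f"fitted twist {h.twist:6.2f} deg (programmed 60.0)")
print(f"pitch        {h.pitch:6.2f} A   seam protomer index {h.seam_index}")

grip_pts = loops.coords("NBD1-PL1")[:5]  # the five gripping protomers
print(f"grip extent  {grip_extent(grip_pts, h.axis_direction):6.2f} A")
print(f"aperture     {aperture(grip_pts, h.axis_point, h.axis_direction):6.2f} A")

ang = np.deg2rad(np.arange(6) * 60.0)
ring1 = np.column_stack([14 * np.cos(ang), 14 * np.sin(ang), np.zeros(6)])
ring2 = ring1 + np.array([25 * np.tan(np.deg2rad(15.0)), 0, 25.0])
print(f"pore tilt    {pore_tilt(ring1, ring2):6.2f} deg (programmed 15.0)")

z = np.arange(1024.0)
profile = np.cos(2 * np.pi * z / 55.0)
print(f"layer line   predicted 1/pitch = {layer_line(55.0):.5f} 1/A, "
      f"measured {measure_layer_line(profile, 1.0):.5f} 1/A")
print("These are the measurements used to characterize the helical sheath a")
print("hexameric unfoldase wraps around its substrate.")
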