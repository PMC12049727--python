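"""Correct fluorescence target depths for the refractive-index mismatch.

A dry NA 0.85 objective focusing through vacuum into vitreous ice
(n2 = 1.28) compresses the measured axial coordinate: the true emitter
always sits deeper than the microscope reports.  This script prints the
axial scaling factor, a focal-shift table over the linear regime, and the
asymmetric rough-milling pattern that guarantees the target ends up
inside the lamella.
"""
import numpy as np

from lamellometer import AxialScalingModel, focal_shift, place_asymmetric_pattern, scaling_factor

model = AxialScalingModel(na=0.85, n1=1.0, n2=1.28, linear_limit_um=9.0)

S = scaling_factor(model)
print(f"axial scaling factor S = z_actual / z_nominal = {S:.3f}")
print(f"focal shift per um of emitter depth: {1000 * focal_shift(model, 1.0):.0f} nm")
print()
print("depth_um  shift_um")
for depth in np.arange(0.0, 9.1, 1.5):
    print(f"{depth:8.1f}  {focal_shift(model, depth):8.3f}")

placement = place_asymmetric_pattern(model)
print()
print("asymmetric rough-milling pattern around the coincident point:")
print(f"  bottom offset: {placement.bottom_offset_um:.2f} um  (safety margin below)")
print(f"  top offset:    {placement.top_offset_um:.2f} um  (covers the worst-case shift)")
print()
print("Reading: an emitter measured at the coincident point can actually sit")
print(f"up to ~{placement.top_offset_um - placement.bottom_offset_um:.1f} um deeper, "
      "so the pattern is opened asymmetrically upward.")
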