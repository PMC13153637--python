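"""Coupled image-plane shifts versus 3D target displacement.

The two kV views sit at +-45 degrees in the axial plane, so a lateral
target displacement splits between the views while a superior-inferior
displacement moves both images together.  This script back-projects a
few coupled shifts and inverts a displacement.
"""

import numpy as np

from kvtrack.geometry import CoupledShift, backproject, project

for shift in [(1.0, 1.0, 0.0), (-1.0, 1.0, 5.0), (2.0, -2.0, -3.0)]:
    pos = backproject(CoupledShift(*shift))
    print(f"shifts I_A={shift[0]:+.1f} I_B={shift[1]:+.1f} J_AB={shift[2]:+.1f} mm"
          f"  ->  target offset (x, y, z) = ({pos[0]:+.3f}, {pos[1]:+.3f}, {pos[2]:+.3f}) mm")

offset = np.array([3.0, -4.0, 7.0])
s = project(offset)
print(f"\ntarget offset {offset} mm projects to I_A={s.I_A:+.3f}, "
      f"I_B={s.I_B:+.3f}, J_AB={s.J_AB:+.3f} mm")
print("round trip error:", np.max(np.abs(backproject(s) - offset)), "mm")
# x is the sum of the lateral view shifts (scaled by sqrt(2)/2), y their
# difference, and z is minus the shared row shift - the linear system the
# motion model generalises.
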