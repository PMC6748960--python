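"""Build one hemisphere and inspect the arm, its maps and the closed loop.

Motor babbling exercises the two-link arm; the proprioceptive map organizes
over muscle lengths, the motor-cortex map over proprioceptive sheets, and
the readout is trained until the loop reproduces babbled commands.
"""

import numpy as np

from cbgreach.arm import forward_kinematics, joint_angles_to_muscle_lengths, \
    mn_to_joint_angles
from cbgreach.config import RunConfig
from cbgreach.model import build_hemisphere

cfg = RunConfig()
rng = np.random.default_rng(0)

phi = np.array([0.8, 0.2, 0.3, 0.7])
theta = mn_to_joint_angles(phi)
print("motor command      ", phi)
print("joint angles (rad) ", theta.round(4))
print("muscle lengths     ", joint_angles_to_muscle_lengths(theta).round(4))
print("end effector       ", forward_kinematics(theta).round(4))

hemi = build_hemisphere(cfg, rng)
sheet = hemi.g_pc(theta)
ci, cj = np.unravel_index(sheet.argmax(), sheet.shape)
print(f"\nmotor-cortex map response to this posture peaks at node ({ci},{cj}) "
      f"with activation {sheet.max():.3f}")
print("(nearby nodes respond to nearby postures: the map is topographic)")

# loop consistency: drive the arm, read the cortex back out
G, phi_back = hemi.loop_response(phi, hemi.readout)
th_back = mn_to_joint_angles(np.clip(phi_back, 0, 1))
err = np.linalg.norm(forward_kinematics(th_back, hemi.geom)
                     - forward_kinematics(theta, hemi.geom))
print(f"\nclosed sensory-motor loop: position error after one loop traversal "
      f"= {err:.4f} workspace units")
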