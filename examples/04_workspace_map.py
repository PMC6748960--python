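"""Map the workspace a motor cortex can express, before and after a lesion.

Each motor-cortex node is stimulated in turn and the arm position it
produces is recorded; coverage is the number of distinct workspace cells
those positions fill. Lesioned nodes express nothing, leaving a hole;
masked retraining redistributes the surviving map over the lost region.
"""

import numpy as np

from cbgreach.config import RunConfig
from cbgreach.motor_cortex import retrain_post_lesion
from cbgreach.protocols import lesion_for_target, make_task, map_workspace, \
    pretrain_model

model = pretrain_model(RunConfig(), seed=0)
targ = make_task(model, "symmetric", "bimanual").targets["right"]
lesion = lesion_for_target(model.right, targ, 5)
print(f"5x5 lesion centred on node {lesion.centre} (the goal representation)\n")

normal, _ = map_workspace(model.right)
lesioned, _ = map_workspace(model.right, lesion=lesion)
retrained_h = retrain_post_lesion(model.right, lesion, np.random.default_rng(1))
retrained, _ = map_workspace(retrained_h, lesion=lesion)

print(f"workspace cells covered:  intact {normal}")
print(f"                        lesioned {lesioned}")
print(f"                       retrained {retrained}")
print("\nThe lesion removes the cells its nodes expressed; retraining the "
      "map and readout around the lesion recovers the lost coverage (the "
      "extra readout training can even push the count past the intact one).")
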