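# cbgreach

A bimanual cortico-basal-ganglia reaching simulator for studying hemiparetic
stroke and comparing rehabilitation strategies (unimanual training, bimanual
training, constraint-induced movement therapy).

## The scientific problem

After a unilateral motor-cortex stroke, should the paretic arm train alone, paired
with the healthy arm, or with the healthy arm constrained? The clinical literature
supports both bimanual training and its apparent opposite, CIMT. `cbgreach`
implements a network-level model in which this question can be asked mechanistically:
two hemispheric sensorimotor systems — proprioceptive map → motor-cortex sheet →
motor neurons → two-link arm, with an inner basal-ganglia loop providing value-gated
exploration — are coupled at the motor-cortex level, a lesion silences part of one
motor cortex, and the three therapy conditions are simulated directly.

It is a library first: the importable API plus the short narrative scripts in
`examples/` are the intended interface; a thin `cbgreach` CLI wraps the common
workflows (train / run / sweep / fixtures / report).

## The model in brief

Each hemisphere controls a planar two-link arm whose joints are set by
agonist/antagonist motor-neuron pairs, `θ = (φ_Ag − φ_An)·π/2 + π/2`. A
self-organizing map over muscle lengths (proprioceptive cortex) feeds a motor-cortex
sheet that combines a second SOM with continuous-attractor dynamics

```
τ dg/dt = −g + W_lat ⊛ G + I,      G = g² / (1 + (2π/N²)·b·Σg²)
```

whose output projects linearly onto the motor neurons. The afferent input `I` sums
proprioceptive, basal-ganglia and prefrontal drives plus the contralateral motor
cortex scaled by a signed coupling factor ε (the bimanual substrate). The basal
ganglia compute a Gaussian value `V = exp(−‖x_targ − x_arm‖²/σ_V²)` over arm-target
distance; its temporal difference gates direct ("go") versus indirect ("explore")
pathways, with exploratory drive generated by chaotic STN-GPe lattice oscillations.
Reaching is learned by stochastic hill climbing on V; successful reaches teach a
prefrontal goal-to-motor projection, and control crossfades from basal ganglia to
cortex across trials. Stroke is a square lesion that suppresses motor-cortex state
each step; therapies differ only in the coupling regime during testing/retraining.
See `docs/methods.md` for the full account, all parameters and known limitations.

## A worked example

`python examples/03_stroke_and_therapy.py` builds two trained models, lesions the
right motor cortex at 2×2, 5×5 and 7×7, and compares therapies:

```
mean reaching error of the paretic arm (workspace units):

size                   2      5      7
stage   condition
acute   bimanual   0.020  0.059  0.144
        cimt       0.019  0.032  0.167
        unimanual  0.020  0.023  0.156
chronic bimanual   0.020  0.019  0.038
        cimt       0.040  0.030  0.033
        unimanual  0.038  0.029  0.027
```

Reading: reaching error is the closest approach to the target (targets are 0.3 units
away, so ≤0.05 is an essentially complete reach). Acutely, error grows with lesion
size in every condition. Chronic retraining — remapping the cortex around the lesion
and re-closing the readout, then a therapy session — restores small- and mid-lesion
performance, with the bimanual condition best at mid sizes (0.019 at 5×5); at the
largest lesion bimanual is the condition that fails (0.038 vs 0.027 unimanual),
i.e. the preferred therapy depends on lesion size.

`examples/01_arm_and_maps.py` walks the kinematic chain and the map/loop formation,
`02_learning_to_reach.py` shows the exploration-to-exploitation handoff trial by
trial, and `04_workspace_map.py` maps the expressible workspace before and after a
lesion.

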