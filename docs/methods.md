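# Methods

`cbgreach` simulates goal-directed reaching by two coupled cortico-basal-ganglia
hemispheres, each driving a two-link planar arm, and uses the simulator to compare
rehabilitation conditions (unimanual training, bimanual training, constraint-induced
movement therapy) after a simulated motor-cortex stroke. This note records the model,
its assumptions, the parameters that matter, and what the implementation does and does
not reproduce.

## The model

**Arm.** Each arm is purely kinematic: a four-dimensional motor-neuron vector
`phi = [phi_Ag^S, phi_An^S, phi_Ag^E, phi_An^E]` (clipped to [0, 1]) sets the shoulder
and elbow angles affinely, `theta = (phi_Ag − phi_An)·π/2 + π/2`, so both joints live in
[0, π]. Muscle lengths follow the law of cosines around each joint (agonist `+2ab·cosθ`,
antagonist `−2ab·cosθ`), giving the identity `mu_Ag² + mu_An² = 2(a² + b²)` used as an
exact test. The end effector is standard two-link forward kinematics with the shoulder
link measured from the muscle attachment (`l_S − a_S`). All lengths are arbitrary
consistent workspace units (Table defaults: a_S = 0.04, b_S = 0.07, a_E = 0.03,
b_E = 0.08, l_S = l_E = 0.3). There is no inertia or muscle force model.

**Maps.** Three self-organizing maps (15×15, online Kohonen training with linear decay)
tile: muscle-length 4-vectors (proprioceptive cortex, σ_act = 0.015), flattened 15×15
proprioceptive sheets (the map layer of the motor cortex, σ_act = 2.5) and 2-d workspace
locations (prefrontal goal map, σ_act = 0.1). Node activation is
`exp(−‖x − W_i‖²/σ²)`. The activation widths were set so a typical stimulus excites a
localized patch a few nodes across; narrower motor-map widths leave coverage holes in
which a goal stimulus produces no drive at all (measured during calibration). The
training schedule counts single-sample presentation steps (default 4000, rate 0.5→0.01,
radius n/2→1); an "epoch over the sample set" reading would multiply runtime without
changing the 15×15 maps perceptibly.

**Motor cortex.** Each motor cortex is a 15×15 continuous attractor sheet: lateral
kernel `A_lat·exp(−(Δi²+Δj²)/2σ_lat²) − K` (A_lat = 0.5, σ_lat = 1.2, K = 0.02),
leaky-integrator state (τ = 1, Euler dt = 0.1, zero-padded boundaries), and a squared,
divisively normalized output `G = g²/(1 + (2π/N²)·b·Σg²)` with b = 20. These values
place the sheet in an input-tracking single-bump regime: a localized input produces one
bump at the input centre and the bump decays when the input is removed. Two properties
of the squared output matter throughout: it is *sign-blind* (inhibitory input that
drives `g` negative still produces output) and *winner-take-most* (with strong divisive
normalization a sub-dominant secondary input is strongly suppressed relative to the main
bump). Afferent drive sums the proprioceptive map response (gain A_PC = 0.3), the
basal-ganglia drive and the prefrontal drive (arbitrated gains, below), plus the
contralateral motor cortex output scaled by a signed coupling factor ε. The coupled
sheet is peak-normalized before scaling: raw outputs under b = 20 are ~0.05 while every
other afferent term is order one, so the tabled couplings (±0.5 symmetric, −0.2/0.89
congruent, −0.2/0.8 incongruent) are interpreted as fractions of the drive scale.

**Readout and loop closure.** The output sheet projects linearly onto the four motor
neurons, `phi = A_MN·W·vec(G)`, clipped to [0, 1]. W is trained by motor babbling: a
desired `phi_D` moves the arm, proprioception drives the cortex, and the delta rule
`ΔW = η(phi_D − phi)·vec(G)ᵀ` (η = 0.1) closes the loop over 400 babbled samples. The
loop can only recover `phi` up to the agonist–antagonist difference (the command space
has a two-dimensional null space), so loop error is assessed in posture/position space.

**Basal ganglia.** The striatum computes a Gaussian value
`V = exp(−‖x_targ − x_arm‖²/σ_V²)` (σ_V = 0.2, covering the 0.3-unit aiming distance
while keeping a steep near-goal gradient). Its temporal difference δ_V gates two
medium-spiny populations with opposed sigmoids (λ = ±50, thresholds 0 and 0.05): rising
value routes the recent change in cortical activity ΔG (scaled by a striatal gain of 10
into the pathways' operating range) through the direct pathway; falling value engages
the indirect pathway. The STN-GPe pair is two 15×15 lattices with Gaussian lateral
interactions (excitatory within STN, inhibitory within GPe) and mutual coupling
(w_sg = w_gs = 2, τ_STN = 1, τ_GPe = 2, λ_STN = 3, σ_lat = 1.5); with low striatal
input the lattice sustains weakly correlated oscillations (mean pairwise correlation
< 0.5 over a long run) — the exploration source. The GPi combines
`y_GPi = A_D1·y_D1 − A_D2·gate_D2·y_STN` (A_D1 = A_D2 = 2): the indirect-pathway gate
attenuates the exploratory STN term as value climbs. Without this arbitration the
tanh-scale STN output dominates the GPi at all times and exploration can never anneal
into exploitation — δ_V would have no lever on behaviour. A thalamic CANN (same kernel,
weaker normalization b = 0.2) relays the GPi sheet to the motor cortex. The net effect
is stochastic hill climbing on the value function; all stochasticity is the seeded
lattice initial condition (uniform in ±0.3) plus its deterministic chaos.

**Prefrontal route and arbitration.** When a trial reaches the target (closest approach
within 0.02 units), the goal-to-motor projection learns
`ΔW = η(G_targ − G_PFC)·vec(U)ᵀ` (η = 0.1), where U is the goal-map activation and
G_targ is the settled, peak-normalized motor-cortex output for the closest-approach
*posture*. Recomputing the teacher from the posture discards the exploratory transients
present in the raw mid-trial sheet; using the raw sheet biases the learned drive and
roughly doubles the asymptotic reaching error. The learned drive is rectified at use
(negative delta-rule lobes would be squared into spurious bumps). Control crossfades
linearly over 50 trials from basal ganglia to cortex (total drive 2.0) down to a
basal-ganglia floor of 0.3; the floor keeps the value servo available late, which keeps
teaching alive — with a full handoff the cortical route plateaus just outside the reach
threshold and never receives another teacher. Tests run at the late-stage operating
point: the trial API defaults to A_BG = 0.3 and A_PFC = 1.7 ("movements dominated by
the cortical loop", with the basal-ganglia servo still running).

**Hemispheres.** The two hemispheres are built independently (each runs its own
babbling and map formation from a continuing generator stream), so their map
topologies are unrelated, as between real hemispheres; the inter-hemispheric coupling
is therefore structured interference rather than a node-aligned echo. A mirror-twin
variant (`build_model(..., independent_left=False)`) is kept for controlled
experiments.

## Tasks, lesions, protocols

Targets sit at 0.3 (far) and 0.15 (near, the 50% rule) units from the resting hand
along a comfortable forward-reach direction: among reachable candidate points at the
aiming distance, the one with the most mid-range posture whose map node lies at least
3 nodes from the sheet edge (so the largest lesion square fits around it). Symmetric
aiming gives both arms far targets; congruent gives the paretic (right) arm the near
target; incongruent the converse.

A lesion multiplies the sheet state inside an n×n square (n = 1..7) by 0.01 at every
integration step. It is centred on the node most active when the trained arm is at its
target — the argmax of the settled output under the trained drive (the map-layer winner
can sit a few nodes off the peak of the *learned* drive). *Acute* testing applies the
lesion to a trained model with no retraining. *Chronic* testing first retrains the
cortical loop around the lesion — the motor-cortex map is retrained warm-started with
lesioned nodes masked from winning, and the readout is re-closed through the lesioned
loop — and then runs a therapy session (30 learning trials under the condition's
coupling, arbitration restarted) before testing. The cortical-loop retraining is
therapy-independent and shared across conditions. Under CIMT the left arm is held at
its resting configuration and its frozen resting output couples into the paretic
cortex.

Performance metrics follow the field's definitions: PRV is the maximum of the 5-step
moving-average-smoothed end-effector speed; reaching error is the minimum distance to
the target over the trial. Aiming experiments average both over 8 test trials per
condition (single-trial PRV varies by ±0.2 through the basal-ganglia loop; the coupling
effects are smaller than that). The aiming experiments use a 6×6 lesion: at the default
sizes below 5 the surviving ring of the goal drive keeps the paretic arm nearly
unimpaired, which contradicts the pronounced-hemiparesis premise of the comparison.

Workspace mapping stimulates each motor-cortex node one-hot, settles the sheet (lesion
active) and records the arm position the readout expresses; coverage is the number of
distinct 0.03-unit workspace cells filled. Lesioned nodes express only the resting
posture, so their cells drop out.

## What the simulator reproduces, and what it does not

Reproduced robustly (see `tests/test_acceptance.py` and `scripts/acceptance.py` for the
measured values):

- goal-directed reaching is learned from exploration in ~50 trials and the trained
  cortical route reaches within a few hundredths of a unit;
- reaching error grows monotonically with acute lesion size, and small lesions
  (≤3×3) leave all conditions near-intact;
- chronic retraining restores small-lesion performance, and the bimanual condition
  loses its advantage at the largest lesions (therapy choice depends on lesion size);
- the unimanual non-paretic arm is faster than the paretic arm after lesioning;
- across-trial path variability (averaged over model seeds) is higher in early
  (exploration-dominated) than late (cortex-dominated) learning trials;
- workspace coverage shrinks under a lesion.

Not reproduced, after extensive exploration (kept as documented limitations rather than
tuned away):

- the bimanual PRV asymmetries (paretic arm faster, non-paretic arm slower than
  unimanual) appear in only about half the builds. The squared output makes the
  excitatory coupling nearly invisible on the healthy, driven sheet, and the inhibitory
  coupling boosts the paretic sheet only when the lesion silences it almost completely;
  which regime a build lands in depends on its map geometry.
- the strict coverage ordering intact > retrained > lesioned: at 15×15 the map is
  redundant (~2.5 nodes per workspace cell), so a 5×5 lesion removes only a few unique
  cells while any amount of further readout training shifts coverage by more than that.
- the bell-shaped velocity profile: the arm is kinematic, so once the output bump forms
  (2–4 integration steps) the largest displacement happens immediately and speed decays
  from its early peak; tests assert a single terminating movement burst instead.

## Numerical and design choices

- Euler integration everywhere, dt = 0.1 < every time constant; trials are 100 steps.
- The lateral interaction of every sheet is precomputed as a dense (225×225) matrix;
  one step is a BLAS matrix-vector product, identical to 'valid' correlation with the
  full stencil (tested against `scipy.signal.convolve`).
- The isotropic Euclidean form is used in the motor-cortex kernel exponent; a config
  switch (`literal_sum_offsets`) preserves the anisotropic squared-sum variant.
- Ties in winner selection break in row-major order; fully masked grids are an error.
- Readout training aborts if the loop error grows ≥5% on three consecutive sweeps.
- Degenerate inputs: zero-step trials report the initial distance and zero PRV;
  size-0 lesions are no-ops; empty speed traces have PRV 0.
- Checkpoints are single NPZ archives (all weights + config YAML); configs are YAML
  with strict unknown-key rejection; results are long-format CSV.
- All randomness flows through `numpy.random.Generator`s seeded from explicit integers;
  identical config + seed reproduces every table bit-for-bit.

## Problem sizes

Default experiment sizes: 15×15 sheets, 400 babbled samples, 4000 map-training steps,
50 learning trials per target (interleaved near/far per hemisphere), 8 aiming test
trials per condition, lesion sweeps over 7 sizes × 3 conditions × 2 stages at 4–6
model seeds, workspace maps over all 225 nodes. These sizes keep a full acceptance run
in the tens of minutes on one core while leaving every comparison's signal above its
seed-to-seed noise, and are set in `RunConfig` for scaling up.
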