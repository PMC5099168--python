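# Methods

## The model

`olfnet` simulates a closed loop of three networks: the olfactory bulb (OB),
the piriform cortex (PC), and the horizontal limb of the diagonal band
(HDB), the basal-forebrain source of acetylcholine (ACh) for both olfactory
areas.  The loop implements a simple idea: cortical *recall* of a stored
odor suppresses cholinergic tone, and cholinergic tone in turn decides
whether the cortex is in a *learning* state (plasticity on, recurrent
transmission suppressed, adaptation off) or a *recall* state (plasticity
off, recurrent transmission restored, adaptation on).

Ten populations of 100 units each are simulated (the mitral cell
contributes two electrically coupled compartments):

| area | group | type | role |
|------|-------|------|------|
| OB   | OSN   | graded | sensory input channels (one per glomerulus) |
| OB   | PG    | graded | periglomerular inhibition of the mitral apical tuft |
| OB   | Mi    | spiking, 2 compartments | principal output of the bulb |
| OB   | Gr    | spiking | granule-cell feedback inhibition of Mi |
| PC   | Ff    | spiking | feedforward inhibition onto pyramidal cells |
| PC   | Pyr   | spiking, adapting | pyramidal cells with plastic recurrent collaterals |
| PC   | Fb    | spiking | feedback inhibition onto pyramidal cells |
| HDB  | Gb    | spiking | GABAergic interneurons driven by Pyr |
| HDB  | Ac    | spiking | cholinergic cells, spontaneously active, inhibited by Gb |

### Unit dynamics

Each unit is a leaky integrator, `tau dv/dt + v = V_ext(t)` (forward Euler,
dt = 0.5 ms), where `V_ext` sums conductance-based synaptic inputs
`w * g(t) * (E_N − v)`.  The synaptic conductance is a difference of
exponentials, `g(t) = g_max (e^{−t/τ_decay} − e^{−t/τ_rise})`, realised as
two per-source exponential state variables so that superposition over all
past spikes is exact with O(1) work per step.  Graded sources (OSN, PG)
transmit continuously: their output passes through a unit-DC-gain two-pole
low-pass with the same two time constants.

The output function is a clipped power law,
`F(v) = ((v − θ_min)/(θ_max − θ_min))^β` in [0, 1].  For graded groups it
is the transmitted rate; for spiking groups the firing probability per
0.5 ms step (rescaled by `dt/0.5` when the grid is refined, so rates are
approximately invariant under `dt → dt/2`).  Spiking units reset to
−10 mV and are refractory for 2 ms.  Negative `θ_min` values give the
Ac, Fb, Gr, Mi and Ff groups spontaneous activity at rest; no noise
current is injected anywhere.

Pyramidal cells carry a spike-frequency-adaptation conductance
(`τ = 100 ms`, reversal −15 mV) incremented in the step after each spike;
its amplitude scales from 10 to 0 with cholinergic modulation, so
adaptation bites only when ACh is low.

### Cholinergic loop

Ac population firing is low-pass filtered (`τ_ACh`) into an activation
trace A(t), scaled so that the resting (spontaneous) value sits near the
top of the 0–0.6 working range.  The modulation level is a Hill function

    M = A^β_ACh / (A^β_ACh + Y_half^β_ACh)

and every ACh-sensitive parameter interpolates linearly between its
"without" (M = 0) and "with" (M = 1) endpoint: Mi θ_max 7→3, PG θ_max
10→5, Gr θ_max 9.5→7, Fb θ_min −0.03→−0.13, Fb→Pyr g 0.55→0.28,
Pyr→Pyr g 650→300, Pyr adaptation amplitude 10→0.  Modulation is uniform
across OB and PC and is updated each step from the previous step's A.

### Plasticity

Only the Pyr→Pyr association fibers learn.  The rule is ACh-gated Hebbian
with a soft saturation bound:

    dw_ij/dt = M (1 − w_ij/w_max) i_post,i b_glu,j(t − t_delay) / τ_pp

`b_glu` is an NMDA glutamate-binding trace that restarts at 1 on each
presynaptic spike and decays as the literal product of two exponentials
(effective τ ≈ 9.1 ms; a difference-of-exponentials mode with a genuine
rise phase is selectable).  `i_post` is the postsynaptic suprathreshold
depolarisation taken from a *shadow membrane*: the pyramidal membrane
equation integrated without spike resets.  With the spiking membrane the
strongest cells would contribute least (every spike resets v to −10 mV)
and learning would anti-select the odor pattern.  `i_post` is rectified
2.5 mV above threshold — a voltage floor for potentiation in the spirit of
the NMDA receptor's Mg-block — and saturated at θ_max.  Weights start
uniform on [0, 0.04] (~10% of `w_max` = 0.4) with a structurally zero
diagonal.

### Association-fiber summation

The printed recurrent conductance (650|300) combined with naive summation
over ~99 partners at the stated weight scale yields drives of order
10^2–10^3 mV and instant runaway; the published rates (naive ~4 Hz,
trained recall ~8.6 Hz population mean) require recurrent drives of a few
mV.  The recurrent drive is therefore normalised:
`V = g_max Σ_j w_ij z_j (E − v) / D` with the divisor D = 350 fixed by
the calibration described below.  The without|with ratio of the printed
conductances (650/300) is preserved exactly.

### Odor stimuli

An odor is the fixed Gaussian affinity profile (normal density over
channels 1..100, mean 50, width 10, peak-normalised to 1) under a random
permutation, so every odor delivers the same total input and differs only
in which channels it drives.  Affinity a maps to the OSN input voltage
a·θ_max(OSN).  Random permutations concentrate around pairwise input
distance ~0.65 and essentially never fall below ~0.4, so probe odors at
*controlled* distances are generated by `morph_odor`: channels are rank-
paired (rank r with rank r+50) and a chosen fraction of pairs exchange
their affinities, sweeping the measured distance continuously from 0
towards ~1.  The classical pool approach (simulate many random odors on
the naive circuit, store pyramidal signatures, select pairs by cosine
distance) is also implemented (`build_pool` / `select_pair`); pool
signature runs reset state, disable plasticity, and use a dedicated
random stream so probing cannot train the network.

### Statistics

* population sparseness `S = [1 − mean(R)²/mean(R²)] / (1 − 1/N)`
  (1 = one active cell, 0 = uniform activity);
* pairwise coherence: observed spike coincidences in 2 ms bins versus one
  draw of rate-matched homogeneous-Poisson surrogates, linearly rectified,
  averaged over sampled pairs (default 500), with pairs lacking observed
  coincidences contributing 0;
* representation distance `D = 1 − cos(O₁, O₂)` on non-negative activity
  vectors.

## Calibration of the unpublished constants

Four loop constants (`gain`, `Y_half`, `β_ACh`, `τ_ACh`) and three
plasticity/coupling constants (`τ_pp`, the recurrent divisor, the
learning threshold) are not published.  They were fixed once by the
following procedure (`neuromodulation.calibrate` automates the first two
steps; `olfnet calibrate` exposes it from the shell) and then frozen as
package defaults:

1. **gain** — run the circuit without odor, measure the spontaneous Ac
   firing fraction per step, and set the filter's fixed point to A = 0.6
   (the top of the published working range): gain = 88.7.
2. **Y_half** — measure the self-consistent resting activation with the
   loop closed (A_rest ≈ 0.52; spontaneous cortical activity feeds back
   weakly on Ac) and place the Hill half-point so that rest maps to
   M ≈ 0.99: Y_half = 0.217.
3. **β_ACh = 5.25** — steep, per the sigmoidal dose-response relation the
   model assumes, and chosen jointly with Y_half so the trained-odor
   recall state (A ≈ 0.16–0.18) lands at the published modulation floor
   (~0.27).  The steepness is what lets modest firing-rate changes produce
   the published ~3× swing in modulation.
4. **τ_ACh = 100 ms** — "slow" relative to membrane constants (20–50×)
   yet fast enough that a 1 s recall session reaches the published
   session-mean modulation; with τ_ACh ≥ 500 ms the activation trace
   cannot decay far enough within a session.
5. **τ_pp = 18 000 ms, divisor = 350, learning threshold = 2.5 mV** — set
   jointly so that (i) nine 1 s sessions produce a gradual, monotone rise
   of pyramidal rates and fall of Ac activity, (ii) the trained-odor probe
   lands in the published 8.6 Hz / M ≈ 0.27 corner while a maximally
   dissimilar probe stays near 4.2 Hz / M ≈ 0.85, and (iii) the naive
   circuit is stable (no attractor ignition without training).

Connection densities not stated anywhere were likewise design choices:
the one published density (Mi→Pyr, 20%) is kept exactly (20 inputs per
pyramidal cell); Mi↔Gr, Mi→Ff and Pyr→Fb default to the same 20%;
feedforward and feedback inhibition onto Pyr are dense (all-to-all), which
the low published cortical rates require; Pyr→Gb convergence is 40% and
Gb→Ac is all-to-all, which places the HDB relay at an operating point
where only strong (recall-level) cortical output silences the
thin-threshold (θ_min = −0.5 mV) cholinergic cells, while naive odor
responses leave them near their spontaneous rate.

One deliberate deviation from the printed parameter table: the Mi→Ff
synapse is implemented as excitatory (+70 mV, fast kernel).  The printed
row (−10 mV, slow kernel) would make odor input *silence* the tonically
active feedforward interneurons — feedforward inhibition would amplify
rather than damp the input — contradicting the model's own description of
Ff as mitral-driven inhibitory cells and making the published naive rates
unreachable.

## Experiment protocols

A session is one 1 s odor presentation (2000 Euler steps).  Between
sessions all dynamic state (membranes, conductances, adaptation, the
cholinergic trace) resets; weights persist.  The training protocol is
nine sessions of one random odor followed by probes.  The distance sweep
trains a fresh network per repeat, then probes once per morph fraction
with the trained weights restored before each probe (independent "10th
sessions").  A probe is classified *recall* when its mean modulation is
below the midpoint of the naive and trained-odor reference values **and**
its mean pyramidal rate is above the corresponding midpoint; otherwise
*learning*.  The switch distance is the smallest mean probe distance at
which the majority of repeats are in learning mode.

The novel-odor onset experiment equilibrates an untrained network for
200 ms, presents a random odor for 1 s, and averages the modulation trace
over repeats.  Two latencies are reported: the time of the trough of the
averaged trace within the first 200 ms (the onset transient of pyramidal
firing maximally suppresses modulation there, ≈75 ms) and the first time
the trace falls more than two standard errors below its onset value
(which shrinks with the number of repeats and therefore measures
detection power rather than circuit latency).

### Problem sizes

Default experiment sizes are the study's: 100-unit groups, 1 s sessions,
nine training sessions.  The acceptance script uses 50 sweep repeats over
8 probe distances and 40 onset repeats; the test suite uses 16 sweep
repeats and 3-seed training averages.  A 1 s session simulates in
~0.2 s (the inner loop is JIT-compiled; the first call in a fresh process
compiles for a few seconds).

## What the synthetic stimuli do and do not capture

The permuted-Gaussian odor model guarantees equal total drive across
odors and gives full control over pairwise similarity, which is exactly
what the learning/recall switch experiments need.  It does not model
receptor-affinity correlations, concentration series, mixtures, or
temporally structured (sniff-locked) input, so quantitative rates here
say nothing about those regimes; conclusions are about the *relative*
changes between naive, trained and morphed-probe conditions.

## Numerical choices

* Forward Euler at dt = 0.5 ms for all state variables; synaptic kernel
  states decay by exact exponential factors.
* Spike probability per step is `F(v)` at the reference 0.5 ms grid and
  is hazard-rescaled by `dt/0.5` for other step sizes (mean rates change
  by <10% under dt halving).
* A unit firing at step k is refractory for exactly `t_refrac`; the
  clock advances after the eligibility check, so the earliest next spike
  is at k + t_refrac/dt + 1.
* Refractory units hold the reset potential and do not integrate input.
* The modulation level used in a step is computed from the activation
  trace at the end of the previous step.
* Ties in `select_pair` break to the smallest odor indices; the
  all-zero-signature corner case maps to distance 1 from everything.
* Coherence pairs with zero observed coincidences contribute 0; one
  surrogate draw per pair per evaluation, seeded.

## Known limitations

* **Sparseness trend.**  In this implementation the population sparseness
  of the cortical response *decreases* over training and recall, while
  the study this model reproduces reports an increase.  The cause is the
  breadth of recurrent amplification: cells with mid-tier input (the
  Gaussian affinity profile is graded, so pattern membership is not
  binary) are recruited by the strengthened collaterals faster than
  dense feedback inhibition prunes them.  Attempts to concentrate
  learning further (higher potentiation threshold, faster learning)
  destabilise the attractor before they reverse the trend.  The
  corresponding trend assertion in the acceptance suite is expected to
  fail and is left failing deliberately.
* The learning/recall attractor transition is sharp: near the ignition
  boundary, single repeats can land on either side, so session-mean
  quantities need tens of repeats to stabilise (all shipped protocols
  average accordingly).
* The two-compartment mitral cell is a minimal electrical coupling
  (apical potential applied to the soma as drive), not a cable model.
* HDB GABAergic projections to OB/PC, centrifugal cortical feedback to
  granule cells, receptor-subtype-specific ACh effects, and spatially
  non-uniform modulation are out of scope.
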