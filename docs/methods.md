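# Methods

`whorfnet` simulates how verbal labels influence the formation of concrete
and abstract semantic categories in a brain-constrained spiking network,
and analyses the resulting "categorical perception" of the network with
representational-dissimilarity statistics.  This note documents the model,
the free parameters and their defaults, the scaled-down operating regime
used by the packaged checks, and the known limitations.

## Input patterns

Each concept is grounded in three binary "instance" patterns of 12 active
cells per primary extrasylvian area (*V1, *M1_L), out of 625 cells per
area.  Concrete concepts share 6 cells across all three instances
(feature overlap) with 6 instance-unique cells each; abstract concepts
share no cell across all three instances, but each unordered instance
pair shares a 4-cell set and each instance keeps 4 unique cells (family
resemblance).  Word-form (label) patterns are 12-cell patterns on the
primary perisylvian areas (*A1, *M1_i), identical for a concept's three
instances.  Cells never recur across concepts.

These counts fix the input correlation structure: over a concept's three
presentations the mean pairwise co-occurrence probability is 1 among
concrete shared cells and between them and the word form; for abstract
concepts it is 2/3 between the word form and the union of pairwise-shared
cells, but only 1/3 among shared cells belonging to different pair-shared
sets — the asymmetry that lets a label act as correlational "glue" for
family-resemblance categories.

**Cell placement.** Within an area each concept's cell pool is drawn from
its own square grid patch; patches tile the 25 × 25 grid and are as large
as the concept count allows (5 × 5 at 25 concepts, 6 × 6 at 10, 12 × 12 at
≤ 4).  Placement is a free design choice (the overlap statistics are
placement-invariant).  We cluster cells because excitatory connectivity is
spatially local (Gaussian kernel, cut-off radius 9 grid units): only cells
within one another's projection range can be bound into a cell assembly by
Hebbian learning, and a spatially dispersed 12-cell pattern in a 625-cell
area has almost no intra-pattern connectivity.  A consequence worth
keeping in mind when interpreting results: part of the between-concept
response separation stems from the spatial disjointness of concept
territories, for abstract as well as concrete concepts.

## Network

Twelve areas (four streams of primary → secondary → central areas:
auditory, articulatory, visual, hand-motor), each a 25 × 25 grid of
excitatory cells paired 1:1 with local inhibitory cells.  Between-area
pathways are reciprocal and comprise 8 next-neighbour links within
streams, 4 "jumping" links (primary ↔ central within a stream) and all 6
pairs of the four central multimodal areas — 18 pairs in total.

Cell-to-cell connectivity is sparse and random: a presynaptic cell reaches
targets with probability proportional to a 2-D Gaussian of the grid offset
(σ = 4.5, radius ≤ 9, expected out-degree ≈ 100 per projection; grid edges
clipped).  Next-neighbour and jumping projections use the same kernel
topographically (corresponding grid positions), mirroring the
retinotopic/somatotopic organisation of sensory hierarchies.  The six
long-distance projections between the multimodal hubs are spatially
*uniform* random with the same expected out-degree: association cortex
converges broadly, and with topographic hub links an assembly grounded at
one grid position in one stream would have essentially no synapses onto an
assembly at an unrelated position in another stream — cross-stream and
cross-modal Hebbian binding, the substrate of the label effect, would be
structurally impossible.  Initial weights are uniform on [0, 0.1·w_max].

Per discrete time step (Δt = 0.5 ms appears only inside the noise
amplitude formula), in order:

1. excitatory membrane integration
   V ← V + (1/τ)(−V + k1·(u + k2·η)), with total input
   u = Σ w·φ (recurrent, within- and between-area) + external drive
   − rectified local inhibition − kG·G(area), τ = 2.5;
   η is zero-mean unit-variance uniform white noise per cell, gated by the
   phase-specific noise switches;
2. inhibitory integration (τ = 5) of the summed spikes in the paired
   cell's 5 × 5 neighbourhood (unit weights);
3. spiking: φ = 1 iff V − α·a ≥ thresh (thresh 0.18, α 8);
4. adaptation a ← a + (1/τ_ADAPT)(−a + φ), τ_ADAPT = 10;
5. firing-rate estimate ω ← ω + (1/τ_Favg)(−ω + φ), τ_Favg = 30 during
   training and 5 during testing;
6. per-area global inhibition G ← G + (1/τ_GLOB)(−G + Σφ), τ_GLOB = 12.

The noise term is rescaled by k1 together with the rest of the input: k1
is the *total input* rescaling factor and k2 ≈ 48.5 is calibrated as a
background-input rate.  Left outside k1, the per-step noise deviation
(≈ 19) would dwarf every threshold in the model; inside it (≈ 0.19) it
produces sparse spontaneous firing (~2–3 % per step) and implements
probabilistic spiking by perturbing the membrane potential.

## Plasticity

Every excitatory→excitatory synapse is updated once per training step
after the dynamics update.  With ω the presynaptic low-pass output and V
the postsynaptic potential: LTP (+Δw) when ω ≥ ϑ_pre and V ≥ ϑ_+; LTD
(−Δw) when ω ≥ ϑ_pre and ϑ_− ≤ V < ϑ_+, or — heterosynaptic case, on by
default — when ω < ϑ_pre and V ≥ ϑ_+.  Weights are clipped to [0, w_max].
Thresholds: ϑ_pre 0.05, ϑ_+ 0.15, ϑ_− 0.14; learning rate Δw = 0.0008.
The presynaptic quantity is a rate estimate, not the instantaneous spike,
so "presynaptic output activity" is a level comparable to a threshold.

**Weight cap.** w_max is not a published quantity.  The default is 6.0,
chosen from the ignition arithmetic: a postsynaptic cell fires when its
summed weighted input exceeds thresh/k1 = 18, and self-sustained assembly
reverberation requires in-assembly synaptic mass per cell of roughly
α/k1 ≈ 800; with the kernel's ~100–200 in-assembly afferents per cell in
primary areas this needs mean assembly weights of ~4–8.  A cap of 0.5–2
makes reverberation impossible at any training length; much larger caps
push trained networks into spontaneous all-assembly ignition.  The value
is configurable and is reported with every run.

## Protocol

A subject is one random initialisation; its four condition models
(semantic-type × label) share connectivity, initial weights, pattern
streams, trial schedule *and noise realizations* (each trial's baseline,
ISI and extra-noise streams are re-seeded per trial from the subject
seed), so the models of one subject differ only in the manipulated
training inputs.  Like the frozen read-out noise below, this is common
random numbers: it removes training-luck variance from the paired
label/no-label contrasts without biasing either condition.  Each
training trial presents one grounding pattern to *V1/*M1_L for 16 steps at
drive amplitude 500 (k1·I = 5 ≫ thresh, so pattern cells fire reliably);
the label condition co-presents the concept's word form to *A1/*M1_i; the
no-label condition feeds those areas uncorrelated white noise (amplitude
k2) instead.  Baseline noise is always on.  Trials are separated by ISIs
in which only noise drives the network (with extra environmental noise
into all four primary areas) until global inhibition in *A1 and *PB falls
below a threshold, or a step cap is reached.  Hebbian learning stays on
during ISIs by default (noise-driven changes are small because of ϑ_pre);
it is switchable.

The ISI threshold is a configurable absolute level (default 30) set just
above the spontaneous steady state of G under ISI noise (≈ 16 in quiet
areas, ≈ 22 in primaries receiving extra noise); a relative criterion such
as a small fraction of the quiet steady state can never be reached while
baseline noise is on, because G fluctuates around that steady state.  The
step cap (default 50) bounds trial cost when trained assemblies reignite
spontaneously; cap hits are logged, counted and reported.

Testing is identical for all conditions and never changes weights
(enforced by a guard and a checksum).  Per pattern: global reset of all
state variables (zeroing ω is required for the read-out to be
input-driven), 2 stimulation steps with all noise off, then 28 free steps
with baseline noise; ω (τ_Favg = 5) of every excitatory cell at t₃₀,
counted from pattern onset, is the response.

**Frozen read-out noise.**  The background-noise realization of the test
phase is re-seeded identically for every pattern presentation and depends
only on the subject — not the condition.  Response differences between
patterns and between a subject's conditions therefore isolate the learned
signal from read-out noise (common random numbers, a standard
variance-reduction device for stochastic simulations).  At full scale the
assembly signal dominates the noise floor and this matters little; at the
reduced scales below it is what makes the dissimilarity structure
measurable.  Absolute dissimilarity values are consequently smaller than
they would be with independent noise; all comparisons used in the
analyses are within-measurement-scheme.

## Analysis

Per area (or over the 7 500-cell concatenation), a symmetric matrix of
pairwise Euclidean distances between response vectors (RDM).  Dissim_W is
the mean over unordered same-concept pairs (30 for the 10 × 3 design),
Dissim_B over different-concept pairs (405); DissimDiff = Dissim_B −
Dissim_W measures categorical separation.  "Collapsed" values are
arithmetic means of per-area values (linear, order-independent).  The
label effect is computed per subject as 100·(label − no label)/no label
and aggregated as the across-subject mean with a t-based 95 % CI
(per-subject percentage first, matching the repeated-measures design —
not a percentage of means).  Repeated-measures ANOVAs (statsmodels
AnovaRM) handle 2–3 two-level within-subject factors; post-hoc paired
t-tests are Bonferroni-corrected with the family size equal to the number
of contrasts tested.  The binary centrality factor averages the
extrasylvian primary areas (*V1, *M1_L) vs the central ones (*AT, *PF_L);
secondary areas are reported for plots only.  A permutation null
(shuffled concept assignments) centres DissimDiff on zero and serves as a
built-in sanity check.  p-values are reported to machine precision; the
conventional significance threshold for this design is 0.01.

## Scales

| preset | concepts | reps/instance | subjects | Δw | notes |
|---|---|---|---|---|---|
| full  | 10 | 4000 | 12 | 0.0008 | the reference design (days of CPU) |
| desk  | 4  | 300  | 3  | 0.0008 | hours on one CPU |
| micro | 3  | 100  | 3  | 0.03   | minutes; used by the packaged checks |

The micro preset compresses training by scaling the learning rate up as
the repetition count is scaled down: every plasticity event is linear in
Δw, so the trained weight structure is governed by the product
Δw × repetitions (≈ 3.0 for micro vs ≈ 3.2 at full scale), at the cost of
coarser weight granularity and noisier learning.  At the reference learning
rate, no sub-hour repetition count can move weights far enough from
initialisation for assemblies to ignite at all, which is why the micro
preset — unlike desk — touches a dynamics parameter.  All directional
conclusions exercised at micro scale (label benefits, concrete/abstract
asymmetries, centrality gradients) are comparisons between conditions run
under identical settings.

## What the generator emulates — and what passing tests do not show

The synthetic inputs reproduce exactly the overlap/correlation structure
of the study design: binary patterns, three instances per concept, fixed
sharing counts, label constancy, zero between-concept overlap.  Real
perceptual experience has graded features, many more instances, overlap
between categories and labels that vary in form; none of that is
modelled, so passing tests demonstrate the mechanism under the idealised
correlational structure, not robustness of the effect in natural data.
The spatial clustering of concept territories additionally contributes
between-concept separation that in cortex would have to emerge from
topographic organisation.

## Numerical choices and degenerate inputs

Explicit Euler with unit step; time constants in steps.  Uniform (not
Gaussian) noise, bounded at ±√3.  Synchronous updates; plasticity applied
once per step after the dynamics.  Ties at thresholds: all rule
comparisons are inclusive (≥) at the upper threshold.  Non-finite
membrane potentials raise immediately, naming the variable.  Empty cell
groups, malformed concept maps, incomplete ANOVA designs and zero
label-effect baselines raise or are excluded with a logged warning rather
than propagating silently.

## Known limitations

* The single-cell/synapse equations follow canonical leaky-integrator and
  threshold forms, with every named constant playing its documented role;
  the exact inhibitory transfer function and the precise noise composition
  of the model family this architecture belongs to are not fully
  determined, so details may differ between implementations.
* Kernel widths, connection densities, w_max, the ISI threshold and the
  stimulus amplitude are unpublished free parameters; defaults are
  documented above and echoed into every run's provenance.
* At micro/desk scale the statistics are directional only: F statistics
  and effect magnitudes are strongly scale- and seed-dependent and are not
  comparable to full-scale values.
* The abstract-specific label benefits (the larger Dissim_B gain and the
  within-category convergence for family-resemblance concepts) depend on
  saturation-complete, bidirectional concept↔word-form assemblies whose
  feedback performs pattern completion at read-out.  At micro scale the
  word-form reactivation is partial, so for abstract concepts (word-form
  coupling 2/3 rather than 1) it adds instance-specific response variance
  instead of pulling instances together; the micro-scale checks reproduce
  the concrete-side label benefits, the concrete-over-abstract no-label
  ordering and the centrality gradients, but not the abstract-side
  reversal.
* No conduction delays, neuromodulation, structural plasticity or
  additional sensory modalities; Euclidean distance only (its
  vector-length sensitivity inflates between- relative to within-category
  label effects).
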