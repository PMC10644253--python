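# Methods

`vnfc` classifies *which person produced a window of EEG* from the structure
of a functional-connectivity graph, using a graph convolutional network whose
input graph is augmented with virtual nodes that encode where the electrodes
sit on the scalp. This note records the model, the choices behind every
tunable, what the synthetic cohorts do and do not emulate, and the numerical
conventions.

## Pipeline

1. **Windowing.** Recordings (channels × samples) are cut into 1 s windows
   with 50% overlap; each window is one classification sample carrying its
   subject label. Trailing partial windows are dropped. No filtering,
   re-referencing or artifact handling is applied by default; an optional
   Butterworth band-pass hook exists but is off.
2. **Phase and PLV.** Each channel's instantaneous phase φ(t) is the angle of
   its analytic signal (Hilbert transform of the mean-removed, broadband
   signal). The phase-locking value of a channel pair is
   `PLV = |T⁻¹ Σ_t exp(i(φ_x(t) − φ_y(t)))| ∈ [0, 1]`; all n(n−1)/2 pairs form
   a symmetric matrix with unit diagonal, computed in one step via
   `|Z Z^H|/T` with `Z = exp(iφ)`. Phases are extracted once per recording
   and sliced per window, avoiding per-window Hilbert edge effects.
3. **Sparsification.** Edges below a threshold are zeroed. The default rule
   keeps the top q = 0.2 of off-diagonal values (a density target rather than
   a fixed τ, so the edge count is comparable across windows and montages);
   a fixed threshold is available. "Above threshold" is strict, the diagonal
   never participates, and self-loops enter only through the operator's A+I.
4. **Virtual-node augmentation.** The 64 electrodes are partitioned into 8
   spatial groups of 8. Each group gets a *local virtual node* connected to
   its members; one *global virtual node* connects the local nodes. Node
   order is fixed (reals in montage order, locals by group id, global last),
   so with the full montage the adjacency is 73 × 73. Virtual edges carry
   weight 1.0 (configurable) — comparable to the PLV range. Node features are
   an all-ones m × 32 matrix: only the connection pattern is informative.
5. **Classification.** The renormalised operator
   `L̃_sym = D̃^{-1/2}(A + I)D̃^{-1/2}` propagates features through two graph
   convolutions `X ← σ(L̃_sym X W + b)` with widths 32 and 8 and a per-node,
   per-feature bias `b ∈ R^{m×out}`; the m × 8 output is flattened (584 for
   m = 73), densely mapped to the class scores and softmax-normalised.
   Training minimises categorical cross-entropy.

Two baselines share the pipeline: `tinas_gcn` (same widths on the bare
64-node PLV graph, flatten 512) and `cnn_fc` (the 64 × 64 sparse PLV matrix
as an image through a 2×2 convolution to 32 channels, 2×2 max-pool, a 2×2
*depthwise* convolution, 2×2 max-pool, flatten 7200, dense). The depthwise
reading of the second convolution is deliberate: it is the only
interpretation under which that layer has 2·2·32 + 32 = 160 parameters,
matching that layer's 160-parameter budget in the reference description of
the model; a full 32→32 convolution would have 4,128. The architecture
manifest notes this, and also that the reference description lists the
first graph convolution's output as 63 × 32 — inconsistent with the 73-node
graph and its own flatten length 584 = 73·8; the package treats it as a
typo for 73 × 32.

### Parameter accounting

Per-node biases give: GC-I = 32·32 + m·32, GC-II = 32·8 + m·8,
dense = 8m·109 + 109. For m = 73: 3,360 + 840 + 63,765 = 67,965 (68.0 k);
for m = 64: 3,072 + 768 + 55,917 = 59,757 (59.8 k); CNN-FC:
160 + 160 + 784,909 = 785,229 (785.2 k). The per-node bias convention and
input feature width N = 32 are the unique pair reconciling every per-layer
count in the reference description; both are defaults and both are configurable.

## Montage conventions

Coordinates are a 2-D azimuthal projection of the standard 10-10 positions
onto the unit disc, vertex at the origin; only relative geometry matters.

* **Grouping.** The reference description shows the 8 groups only as a
  colour-coded figure and never lists memberships. The shipped grouping
  sorts channels by azimuth around the vertex and chunks them into 8
  consecutive wedges of 8 — balanced,
  spatially contiguous, deterministic. It is frozen in `data/groups8.json`
  (snapshot-tested against the algorithm) and can be overridden by a
  user-supplied JSON map.
* **Regions.** Five overlapping regions are assigned by label prefix:
  Fp/AF/F → frontal, C → central, P → parietal, O → occipital, T → temporal,
  with boundary prefixes in both neighbours (FC → frontal+central,
  CP → central+parietal, PO → parietal+occipital, FT/TP → temporal plus
  frontal/parietal). Iz is grouped with occipital. Region removal keeps the
  complement; an emptied group's local virtual node is dropped so the
  augmented graph stays connected.
* **Reduction layouts.** The retained-channel sets for 56…16 channels are a
  greedy farthest-point ordering seeded at the vertex, frozen in
  `data/reduction_layouts.json`; prefixes of one ordering, hence nested.
  They are documented reconstructions of spatially uniform thinning, not the
  reference description's exact sets, which exist only graphically.

## Training

Adam (β = 0.9/0.999), learning rate 3e-3, batch 64, 30 epochs, float32;
one model trained from scratch per fold. Cross-validation is stratified
five-fold by subject over windows, so every subject appears in every test
fold; the split is per-window (windows of one recording may fall on both
sides), with a per-block option for stricter separation — with overlapping
windows the per-window protocol is the more optimistic of the two, which is
why both are documented.

Hidden activations are **leaky ReLU (slope 0.01)** rather than plain ReLU.
Every input the graph models see is non-negative (operator entries, all-ones
features), so the pre-activations of a whole layer share sign structure; one
large early optimiser step can push them all negative at once, and with a
hard ReLU that state is absorbing (zero gradient everywhere, permanently
uniform output — observed in practice as occasional chance-level folds).
The leak makes the state recoverable and changes nothing else. Biases are
initialised uniformly in ±0.1 for the same reason; weights are Glorot-uniform.

Seeding: one global seed fans out to named per-stage seeds via
`numpy.random.SeedSequence.spawn` (cohort, folds, training), so any stage
can be reproduced independently; every experiment writes a JSON manifest
with the config hash, stage seeds and a digest of its results, and two runs
with the same config are digest-identical single-threaded.

## Synthetic cohorts

There is no public generative model for these data, so the package defines
one in which phase locking — the quantity PLV measures — is the controlled
ground truth. Each subject is a network of Kuramoto-style phase oscillators:

    θ_i(t+1) = θ_i(t) + 2π f_i(t)/fs
               + (g/fs) · mean_{j∈coupled(i)} K_ij sin(θ_j − θ_i) + ε_i(t)

with subject-specific symmetric coupling K ∈ [0,1]^{n×n}, coupling gain
g = 60 rad/s, per-step phase noise sd 0.1 rad, and per-channel frequency
f_i(t) = 10 Hz + jitter (sd 1 Hz) + a slow Ornstein–Uhlenbeck wander
(sd 3 Hz, τ = 1 s). The signal is sin θ mixed with a Gaussian spatial kernel
over the montage (width 0.08 on the unit disc — a volume-conduction
surrogate) plus independent white sensor noise (sd 0.5 relative).

Three features of this design matter:

* **Mean-field normalisation** of the coupling pull bounds the per-step
  update regardless of a channel's degree, keeping the Euler integration
  stable.
* **Sparse coupling** (default density 0.02, ≈40 of 2,016 pairs) keeps the
  coupled graph from forming one giant synchronised component; global
  synchrony would make all subjects look alike. With the defaults, coupled
  pairs reach windowed PLV ≈ 0.8, uncoupled pairs ≈ 0.3, and the estimated
  PLV matrix correlates with the generating K at r ≈ 0.6.
* **Frequency wander** is what separates those two populations *on average*:
  with fixed frequencies, uncoupled pairs that happen to share a frequency
  stay spuriously locked for a whole recording; the wander decoheres them
  across windows while coupled pairs stay locked because the pull dominates
  the drift.

A `separation` control mixes a cohort-shared coupling backbone with private
patterns; at separation 1 (default) two subjects overlap only by chance.
`simulate_planted_cohort` confines all coupling to the *pure* channels of
one scalp region (those no other region claims — for frontal: the 17
Fp/AF/F electrodes), at density 0.005 so the planted pairs lock pairwise
rather than fusing; removing that region then provably deletes the entire
identifying signal, which is the ground truth the region-removal ablation
is checked against.

What the generator does **not** emulate: 1/f spectra, artifacts (blinks,
EMG), non-stationary coupling, realistic head geometry. Passing tests on
these cohorts demonstrate that the pipeline recovers planted phase-coupling
structure and that the machinery (windowing, PLV, augmentation, training,
ablation bookkeeping) is correct — not that any particular accuracy will be
attained on real recordings. The real-data path (EDF ingestion ordered to
the montage) is wired and tested on synthetic round-trips, but real-dataset
accuracies require the datasets themselves and are reported, never asserted.

## Problem sizes used in the shipped studies

The reference synthetic study is 10 subjects × 3 runs × 60 s at 160 Hz
(3,570 windows); five-fold CV of the virtual-node model completes in a few
minutes on one CPU and reaches mean accuracy ≥ 0.99 at the default settings,
with label-shuffled controls at chance (≈ 0.10). The planted-region study
uses 6 subjects × 2 runs × 20 s over 3 generator seeds. These sizes are the
package's own defaults for a fast, fully reproducible demonstration; all are
configurable.

## Numerical conventions and edge cases

* Phases wrapped to (−π, π]; an all-zero (constant) channel is a flagged
  error, not a NaN.
* PLV values clipped at 1.0 against rounding; matrices symmetrised by
  averaging before use.
* Density sparsification breaks ties by strict comparison against the
  (k+1)-th largest value, so at most the target number of edges survives.
* `renormalized_operator` divides elementwise by √(d̃_i d̃_j), which keeps
  the two-node closed form exact in floating point.
* Emptied groups under ablation are dropped and group ids compacted.
* EDF writing quantises to 16-bit over the observed physical range; the
  round-trip error bound is one quantisation step.
* Training aborts with diagnostics on non-finite loss; zero-epoch training
  is a no-op by contract.

## Known limitations

* Local virtual nodes integrate only electrodes within a group; spatially
  adjacent electrodes in different groups are not linked (a stated property
  of the construction, kept as such).
* The shipped grouping and reduction layouts are reconstructions from the
  montage geometry; the reference sets exist only as figures.
* The numpy training loop is single-threaded CPU code; it is sized for the
  shipped studies, not for large-scale hyperparameter search.
* Whether the original cross-validation split windows or time blocks is
  unknown; both modes exist, defaults documented above.
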