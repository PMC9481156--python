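# Methods

## The problem

In a homeostatic epithelium such as the epidermal basal layer, cell
divisions and delaminations (irreversible departures to the suprabasal
layer) must balance. Whether and how neighboring cells coordinate these
fate decisions is encoded — weakly and noisily — in time-lapse cell-tracking
data. `fategnn` frames rule discovery as supervised fate classification on a
spatiotemporal graph followed by attribution: if a classifier can predict a
cell's next behavior from its surroundings, the features it relies on are
candidate interaction rules.

## Spatiotemporal graphs

Cells observed in frame *i* are nodes `(i, α)`. Spatial edges connect cells
in contact within a frame (from segmentation label images, two cells are in
contact when they share more than one boundary pixel pair at
4-connectivity; in simulations, when their Voronoi regions share a ridge).
Temporal edges follow the tracks: a division forks a node into two
daughters, a delamination terminates a track. Tracks that reach the imaged
region's spatial or temporal boundary are *censored* — they are never used
as prediction targets and never counted as delaminations.

Each node carries a feature vector of fixed length 6:

| slot | feature | notes |
|------|---------|-------|
| 0 | cell area | normalized by the maximum over training + test data |
| 1 | G1-reporter signal | normalized likewise |
| 2–4 | next-frame behavior (NFB) | one-hot NB/Del/Div; null for censored cells and in the final frame of each window, where it is the prediction target |
| 5 | random control | one U(0,1) draw per node, fixed at graph build |

Deactivating a feature zeroes its slot rather than shrinking the vector, so
model shapes are identical across ablations. The random slot is drawn once
per node (not per epoch) so that training and attribution are reproducible;
it carries no fate information by construction and calibrates the
attribution significance band.

Windows of `Nt` consecutive frames (default 4) are re-indexed
`t = −(Nt−1) … 0`; prediction targets are frame-0 cells with an observable
fate whose ancestor chain spans the window. Each target's unit of
computation is its receptive-field subgraph: the ancestor chain, the
`Ns`-step contact neighborhoods of every ancestor, and the within-window
descendant closure of those nodes (daughter forks of neighbors, sibling
subtrees), with all induced edges.

## The model family

Seven multilayer perceptrons (each: one hidden layer of 50 rectified units
with dropout 0.1 in training, then an affine output) implement three
message-passing stages over a window:

1. **Backward temporal** (`Nt−1` iterations): each node receives a message
   from each next-frame successor (its daughters if it divides, its own
   continuation otherwise), computed by an edge MLP on the concatenated
   endpoint states, summed, and absorbed by a node MLP. Final-frame states
   are never updated; delaminating or exiting cells receive a zero message.
2. **Spatial** (`Ns` iterations, default 1): directed contact edges carry
   edge-MLP messages aggregated at the receiver by *sum* or *mean* (mean of
   an empty neighbor set is the zero vector) and absorbed by a node MLP.
   Mean aggregation makes the neighbor count invisible to the model.
3. **Forward temporal** (`Nt−1` iterations): each node receives the message
   on the edge from its parent (its past self if it did not just appear);
   cells popping into the field of view receive zero.

The frame-0 state of the target is decoded to three logits and a softmax.
Variants: *unidirectional* skips stage 1 (neighbor fates are then supplied
explicitly by the NFB feature); *cell-external* additionally zeroes the
target's own lineage states entering stage 2, so predictions can use only
surrounding cells; *no-spatial* skips stage 2.

**Frame-freezing convention.** The description of the forward temporal pass
as leaving the *final* frame untouched cannot be combined with decoding the
final frame's updated state — the decoder would then see a constant. We
freeze the *first* frame (whose nodes have no parent) and update all later
frames including frame 0; the literal final-frame-frozen reading remains
available behind `ModelConfig.freeze_convention = "last"`.

Autodifferentiation is provided by a small reverse-mode engine written on
numpy (`fategnn.nn`): dense affine layers, fused MLP blocks, row
gather/scatter with precomputed segment plans, dropout, and fused
classification losses, with gradients for both parameters and inputs. Its
correctness is pinned by finite-difference checks and by a per-node
dict-loop oracle for the full forward pass.

**Exact pruning.** For per-target subgraph batches the decoded output
depends only on spatial messages that can still reach the ancestor chain
within the remaining spatial iterations, and on forward temporal messages
along the chain. The implementation therefore restricts those stages to the
relevant rows; tests verify agreement (to float tolerance) with the
unrestricted computation for every variant. For the cell-external variant
at Ns = 1 an additional exact sharing applies: every spatial edge whose
message is consumed has a zeroed (ancestor-chain) receiver, so the edge
message is a function of the sender alone and all targets of a window can
share one whole-window evaluation — training and evaluation use this path,
while attribution keeps per-target batches because integrated gradients are
pooled per target subgraph. Relabeling cell ids permutes float summation
order inside segment reductions, so permutation invariance holds to ~1e-9
relative tolerance rather than bit identity.

## Training and evaluation

Three-class weighted softmax cross-entropy, with per-class weights equal to
the inverse fate proportions of the training targets; Adam at learning rate
1e-4 (conventional β and ε); 2000 epochs by default. Within an epoch each
training window contributes one parameter update, optionally followed by an
update on the corresponding null graph (all features zero) with the
neutral-baseline loss

L_MSE = (1/N_sub) Σ_f Σ_n (p_n^{f,null} − 1/3)²,

which pushes null-graph softmax scores toward 1/3 so that the null graph is
a neutral attribution baseline; it does not measurably change AUC. Windows
are visited in a fixed order (reproducibility). The checkpoint kept is the
epoch with the best *test-set* macro-F1 — the study's selection rule, kept
for fidelity despite its optimistic bias; metrics (per-fate one-vs-rest
AUC, macro-F1, recall/precision, confusion matrix) are recorded on a
configurable cadence. Results are aggregated over independently seeded
replicates (six by default) as mean ± sd.

## Attribution

Integrated gradients against the null-graph baseline,

I_k^f = X_k · (1/M) Σ_j ∂F^f((j−½)/M · X)/∂X_k,

by a midpoint Riemann sum with M = 50 (completeness is verified at M = 200
to within 1 %); dropout is disabled. Because softmax scores sum to one,
Σ_f I_k^f = 0 exactly, and the property survives pooling. Attributions are
pooled by (feature type, relative frame, role ∈ {target lineage, neighbor});
daughters and siblings of neighbors pool with neighbors at their own frame.
NFB categories average only over cells whose behavior matches the category.
Pooled values are averaged within each target's subgraph, then over
subgraphs (test-set subgraphs by default), then over model replicates
(mean ± standard error). The significance band is
[min(mean − SE), max(mean + SE)] over all pooled random-feature rows.

## The homeostatic-layer simulator

Cells are points in a periodic `L × L` box under noiseless overdamped
dynamics with pair potential `u = K/2 (|r|−l)²` for `|r| < l` (K = 9 h⁻¹,
l = 0.125, L = 1, step Δt = 1.2 h). Fate events are paired:

- *delamination-induced division* (N0 = 612): uncommitted cells commit to
  delaminate at rate λ with lifetime U[32.4, 39.6] h; when a delamination
  fires, one uncommitted cell among its six nearest neighbors is committed
  to divide after U[44.4, 51.6] h;
- *division-induced delamination* (N0 = 412): the mirrored rules;
- *mixed* (N0 = 512): both at half rate.

Induced events are terminal (they do not themselves induce partners); if
all six candidates are committed, no partner is induced. A division places
one daughter within d = 0.001 L of the parent; both daughters are recorded
under the pre-division id. Commitment is discretized as a per-step
Bernoulli draw with p = λΔt. λ is not hard-coded: `calibrate_rate` starts
from the steady-state relation f = 24λ/(1 + λ(T_spont + T_induced)) for the
per-fate event fraction f per 24 h frame and refines by bisection on pilot
runs until f is within 10 % of the 7 % target (typical result
λ ≈ 0.0039 h⁻¹). The protocol is 100 mechanics-only relaxation steps, 300
burn-in steps with events, then 300 production steps sampled every 20 steps
(24 h). The different N0 absorb the standing commitment deficit/surplus so
all three setups settle near 500 cells; the central 0.65 L crop then holds
about 210, matching the tracked-region size of the tissue data.

**Integration.** At the study density every cell overlaps ~30 neighbors, so
the stiffest relaxation mode has rate ≈ K × 30 ≫ 1/Δt, and a single
explicit-Euler update per Δt is far beyond its stability limit — it melts
the packing into an agitated gas whose neighborhoods decorrelate within one
frame, destroying the very coordination signal the simulation implants.
Each Δt step therefore advances the same gradient flow with explicit-Euler
sub-steps bounded by the local stability limit
(`substep_safety/(K(1+max degree))`), stopping once the packing has relaxed
(max sub-step displacement < 2e-4 L, at most 30 sub-steps per Δt, neighbor
lists refreshed every 5 sub-steps with a 1.25 l skin). Under this
integrator potential energy is non-increasing between events, cells are
quasi-static between fate events (median displacement ≈ 0.014 L per 24 h
frame, a third of the mean spacing), and ~90 % of induced partners are
still Voronoi contacts of their inducer at the adjacent sampled frames.

**Export.** Sampled frames become track/contact tables: contacts from a
periodic Voronoi tessellation (3×3 tiling), areas from the Voronoi regions,
the G1 column zero (no cell-cycle reporter is simulated — runs on simulated
data use the NFB + random feature set). Fates come from the event log
between consecutive sampled frames; tracks crossing the crop boundary are
censored rather than assigned fates. The event timing implies the induced
partner's division is labeled ~2 frames after the inducing delamination
(48 h delay at 24 h sampling), which is where both the attribution signal
and the neighbor-imbalance peak are expected.

## Neighbor fate net imbalance

For each cell that divides or delaminates at frame *t*, its six nearest
cells by centroid distance at frame *t* are tracked forward (descendants
inherit tracked status; delaminated or censored neighbors stop
contributing). The curve reports the cumulative (#divisions −
#delaminations) among tracked neighbors in (t, t+τ], averaged over events
with standard error; events with horizons beyond the data contribute only
up to their horizon. The default statistic is this uncorrected cumulative
count; `background_correction=True` subtracts the population-wide expected
net imbalance per tracked cell per frame, which removes global fate-rate
fluctuations. Exact normalization choices for this family of statistics
vary; the uncorrected count is the package's default interpretation.

## Problem sizes used by the test suite

The acceptance-style tests train on simulations shrunk to a 0.55 L box at
the study's cell density (~64 cells per cropped frame), with 63 sampled
training frames and 55 test frames from two independent runs (the two
splits comparable in size, as with the tissue data), the cell-external
model with mean aggregation, NFB + random features, 500 epochs and two
replicates. This puts ~3400 cell-frames in the training set. The size
matters for two reasons: attribution quality saturates above roughly
2000–3000 cell-frames, and at the fixed learning rate the optimization
escapes its initial plateau only after a few tens of thousands of parameter
updates, so the number of training windows (one update per window per
epoch) must be large enough for the transition to fall reliably inside the
epoch budget. The steady-state checks run the full printed protocol. The
full-size defaults remain the package defaults throughout.

## Known limitations

- The simulator is a point-particle caricature: no cell shapes, no
  mechanics-dependent fate choice, no noise term in the equation of motion;
  contact graphs come from Voronoi adjacency rather than membrane
  segmentation. Passing rule-recovery tests shows the inference pipeline
  can extract implanted rules from data with realistic counts, rates and
  censoring — not that it will find rules in any particular tissue.
- Model selection on test-set macro-F1 reproduces the study protocol but is
  optimistically biased; use a third split for unbiased estimates.
- AUC values on stochastic fate data are intrinsically modest; the
  attribution signal, not the AUC, is the interpretable output.
- With 24 h sampling the inducing event is resolved ~2 frames before the
  induced one; finer sampling would shift the attribution peak accordingly.
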