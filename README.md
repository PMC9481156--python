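# fategnn

Interpretable spatiotemporal graph neural networks for inferring **cell-fate
coordination rules** from cell-tracking data, together with an agent-based
simulator of a homeostatic epithelial layer used to validate that the
pipeline recovers implanted rules.

## Who this is for

Groups with time-lapse tracking of a proliferative cell layer (e.g. the
epidermal basal layer) who want to ask: *do divisions and delaminations of
neighboring cells influence a cell's own fate, and on what time scale?*
Between frames every cell does one of three things — divides (**Div**),
delaminates (**Del**), or stays (**NB**). The package

1. builds a **spatiotemporal graph**: cells as nodes, cell-contact edges
   within frames, lineage edges (division forks, delamination terminals)
   between frames;
2. trains a message-passing classifier to predict each cell's next
   behavior from an `Nt`-frame window. The model family runs backward
   temporal, spatial, and forward temporal message passing with seven MLPs
   (Φ^B,edge, Φ^B,node, ϕ^edge, ϕ^node, Φ^F,edge, Φ^F,node, ψ^dec) and
   decodes softmax fate scores F^f for the target cell; variants ablate the
   backward pass (*unidirectional*), the target's own features
   (*cell-external*, so predictions use surrounding cells only), or the
   spatial pass, and spatial messages aggregate by sum or mean;
3. attributes predictions with **integrated gradients** against a null
   (all-features-zero) graph baseline,
   I_k^f = X_k · ∫ ∂F^f(α X)/∂X_k dα, pooled by (feature, relative frame,
   lineage/neighbor role), with a significance band calibrated by a
   deliberately uninformative uniform-random feature;
4. cross-checks findings with the **neighbor fate net imbalance** statistic
   (cumulative Div − Del among a cell's six nearest neighbors after its own
   fate event);
5. **simulates** a homeostatic layer of repulsive particles with paired
   stochastic fate rules (delamination-induced division, the mirror, or a
   mixture) to generate ground-truth data where the implanted rule is known.

The training loss is weighted softmax cross-entropy (weights = inverse fate
proportions) plus an auxiliary MSE loss that pins null-graph scores at 1/3
so the attribution baseline is neutral; model selection takes the epoch
with the best test macro-F1. Everything is deterministic given seeds. The
message-passing models and their gradients run on a small numpy
reverse-mode autodiff engine included in the package (`fategnn.nn`).

## Worked example

Simulate a delamination-induced-division tissue (calibrated so ~7 % of
cells divide and ~7 % delaminate per 24 h frame), train the cell-external
model, and read off the recovered rule:

```python
import numpy as np
import fategnn as fg
from fategnn import cli_io, train_eval as te

lam = fg.calibrate_rate(fg.SimConfig(setup="del_induced_div", seed=101), 0.07)
print(f"calibrated commitment rate: {lam:.5f} per cell per hour")

def tables(seed, production_steps):
    cfg = cli_io.scaled_sim_config("del_induced_div", seed, 0.55, lam,
                                   production_steps=production_steps)
    return fg.homeostasis_sim.crop_to_tracktable(fg.run(cfg))

fc = fg.FeatureConfig(area=False, g1=False, nfb=True, random=True, seed=11)
train_w, test_w = cli_io.build_dataset(tables(11, 1260), tables(511, 1100), fc, nt=4)

mc = fg.ModelConfig(variant="cell_external", aggregation="mean")
tc = fg.TrainConfig(epochs=500, n_replicates=2, seed=7, eval_every=10)
results = te.replicate_train(train_w, test_w, mc, tc)
for k in ("NB", "Del", "Div"):
    print(k, round(np.mean([r.best_report.auc[k] for r in results]), 3))

ig_batches = te.prepare_batches(test_w[:10], mc, per_target=True)
table = fg.aggregate_models([fg.attribute_model(r.best_model(), ig_batches)
                             for r in results])
print("band", np.round(table.band, 4))
print("IG(neighbor Del at t=-2 -> Div):",
      round(table.value("nfb_del", -2, "neighbor", "Div"), 3))
```

Output from this exact script:

```
calibrated commitment rate: 0.00386 per cell per hour
NB 0.672
Del 0.556
Div 0.819
band [-0.005   0.0029]
IG(neighbor Del at t=-2 -> Div): 0.238
```

Reading: induced divisions are predictable from the surroundings
(AUC 0.82) while the spontaneous delaminations stay close to chance
(AUC 0.56), and the attribution pinpoints *a neighbor's delamination two
frames (48 h) earlier* as the driver of division — 0.238, far above the
random-feature band — which is exactly the implanted rule and its induced
lifetime.

A command-line interface wraps the same steps
(`fategnn simulate | build-graph | train | imbalance | all`); e.g.

```bash
fategnn simulate --setup mixed --seed 1 --out out/mixed
fategnn build-graph --track out/mixed/track.tsv --contacts out/mixed/contacts.tsv
```

All tabular I/O is plain TSV (`frame cell_id parent_id fate area g1 [x y]`
for tracks; `frame cell_id_a cell_id_b` for contacts); contacts can also be
derived from integer label images.

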