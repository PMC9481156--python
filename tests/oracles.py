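"""Independent reference implementations used as test oracles.

These are deliberately naive (python dict loops, one value at a time) and
share nothing with the vectorized implementation except the trained weight
matrices they are handed.
"""

from __future__ import annotations

import numpy as np

from fategnn.gnn_core import FateGNN, ModelConfig
from fategnn.track_graph import TargetSubgraph


def mlp_eval(mlp, x: np.ndarray) -> np.ndarray:
    """Evaluate one MLP on a single vector (eval mode)."""
    h = x.astype(np.float64)
    last = len(mlp.weights) - 1
    for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
        h = h @ w.data.astype(np.float64) + b.data.astype(np.float64)
        if i < last:
            h = np.maximum(h, 0)
    return h


def manual_forward(model: FateGNN, subgraph: TargetSubgraph) -> np.ndarray:
    """Direct per-node transcription of the message-passing equations.

    Returns the softmax fate scores of the subgraph's target cell.
    """
    cfg: ModelConfig = model.config
    g = subgraph.graph
    keys = sorted(g.nodes)
    t0 = subgraph.t0
    first = t0 - (cfg.nt - 1)
    x = {k: g.nodes[k].features.astype(np.float64) for k in keys}

    def daughters(k):
        return sorted(g.nodes[k].daughters)

    def neighbors(k):
        f, cid = k
        return [(f, other) for other in g.neighbors(f, cid)]

    h = {k: x[k].copy() for k in keys}

    if cfg.variant == "bidirectional":
        for _ in range(cfg.nt - 1):
            new = {}
            for k in keys:
                if k[0] == t0:  # final frame never updated
                    new[k] = h[k]
                    continue
                msgs = [mlp_eval(model.mlps["bwd_edge"], np.concatenate([h[k], h[d]])) for d in daughters(k)]
                B = np.sum(msgs, axis=0) if msgs else np.zeros_like(h[k])
                new[k] = mlp_eval(model.mlps["bwd_node"], np.concatenate([B, h[k]]))
            h = new
    elif cfg.variant == "cell_external":
        for k in subgraph.lineage:
            h[k] = np.zeros_like(h[k])

    if cfg.variant != "no_spatial":
        for _ in range(cfg.ns):
            new = {}
            for k in keys:
                msgs = [mlp_eval(model.mlps["sp_edge"], np.concatenate([h[k], h[nb]])) for nb in neighbors(k)]
                if not msgs:
                    agg = np.zeros_like(h[k])
                elif cfg.aggregation == "sum":
                    agg = np.sum(msgs, axis=0)
                else:
                    agg = np.mean(msgs, axis=0)
                new[k] = mlp_eval(model.mlps["sp_node"], np.concatenate([agg, h[k]]))
            h = new

    frozen_frame = first if cfg.freeze_convention == "first" else t0
    for _ in range(cfg.nt - 1):
        new = {}
        for k in keys:
            if k[0] == frozen_frame:
                new[k] = h[k]
                continue
            parent = g.nodes[k].parent
            if parent is None:
                V = np.zeros_like(h[k])
            else:
                V = mlp_eval(model.mlps["fwd_edge"], np.concatenate([h[k], h[parent]]))
            new[k] = mlp_eval(model.mlps["fwd_node"], np.concatenate([V, h[k]]))
        h = new

    logits = mlp_eval(model.mlps["dec"], h[subgraph.target])
    e = np.exp(logits - logits.max())
    return e / e.sum()


def auc_pair_count(labels: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUC by exhaustive pair comparison (ties count half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def subgraph_nodes_reachability(window, target, nt: int, ns: int) -> set:
    """Receptive field of the target under the information-flow order:
    ancestors, their in-frame <=ns-step contact neighborhoods, and the
    within-window descendant closure of all of those (BFS formulation)."""
    chain = [target]
    while window.nodes[chain[-1]].parent is not None:
        chain.append(window.nodes[chain[-1]].parent)
    wanted = set(chain)
    for f, cid in chain:
        frontier = {cid}
        seen = {cid}
        for _ in range(ns):
            frontier = {
                nb for c in frontier for nb in window.neighbors(f, c) if nb not in seen
            }
            seen |= frontier
        wanted |= {(f, c) for c in seen}
    grew = True
    while grew:
        grew = False
        for k in list(wanted):
            for d in window.nodes[k].daughters:
                if d not in wanted:
                    wanted.add(d)
                    grew = True
    return wanted
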