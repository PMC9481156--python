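"""Message-passing models over spatiotemporal cell graphs.

The full (bidirectional) model runs three stages on an Nt-frame window:

1. backward temporal passes (Nt-1 iterations): every node receives a message
   from each of its next-frame successors (its daughters if it divides, its
   own continuation otherwise), computed by an edge MLP on the concatenated
   endpoint states, summed, and absorbed by a node MLP.  Final-frame states
   are never updated; nodes that delaminate or leave the field of view
   receive a zero message.
2. spatial passes (Ns iterations): within each frame, directed contact edges
   carry edge-MLP messages that are aggregated (sum or mean) and absorbed.
3. forward temporal passes (Nt-1 iterations): each node receives the message
   on the edge from its parent (or its own past self); nodes popping into
   the field of view receive zero.

The frame-0 state of the target cell is decoded to three fate logits.
Variants: ``unidirectional`` skips stage 1; ``cell_external`` additionally
zeroes the target's own lineage states entering stage 2, so the prediction
can only use surrounding cells; ``no_spatial`` skips stage 2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .track_graph import (
    FATE_INDEX,
    N_FEATURES,
    TargetSubgraph,
    Window,
)

__all__ = [
    "ModelConfig",
    "GraphBatch",
    "build_batch",
    "build_window_batch",
    "FateGNN",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("bidirectional", "unidirectional", "cell_external", "no_spatial")


@dataclass
class ModelConfig:
    variant: str = "cell_external"
    aggregation: str = "mean"  # "sum" or "mean"
    nt: int = 4
    ns: int = 1
    n_features: int = N_FEATURES
    hidden: int = 50
    n_layer: int = 1
    p_dropout: float = 0.1
    # which frame the forward temporal pass leaves untouched; "first" is the
    # architecture-consistent reading (first-frame nodes have no parent),
    # "last" is the literal one
    freeze_convention: str = "first"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")
        if self.nt < 2:
            raise ValueError("nt must be >= 2")
        if self.ns < 0:
            raise ValueError("ns must be >= 0")
        if self.freeze_convention not in ("first", "last"):
            raise ValueError("freeze_convention must be 'first' or 'last'")


class GraphBatch:
    """A flat, vectorized encoding of one or many (sub)graphs.

    Nodes of all member graphs are stacked; edges are index pairs into the
    stack.  Temporal edges are stored parent -> child.  Spatial edges are
    directed (both orientations present).  ``subgraph_id`` maps each node to
    the target it belongs to (per-target batches) and ``lineage_mask`` marks
    the target ancestor chains for the cell-external variant.
    """

    def __init__(self, nt: int):
        self.nt = nt
        self.X = np.zeros((0, N_FEATURES))
        self.t_off = np.zeros(0, dtype=np.intp)
        self.temporal_src = np.zeros(0, dtype=np.intp)
        self.temporal_dst = np.zeros(0, dtype=np.intp)
        self.spatial_src = np.zeros(0, dtype=np.intp)
        self.spatial_dst = np.zeros(0, dtype=np.intp)
        self.target_idx = np.zeros(0, dtype=np.intp)
        self.labels: np.ndarray | None = None
        self.subgraph_id = np.zeros(0, dtype=np.intp)
        self.lineage_mask = np.zeros(0, dtype=bool)
        self.node_keys: list = []
        # filled by _finalize
        self._plans: dict | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.X)

    @property
    def n_targets(self) -> int:
        return len(self.target_idx)

    def _finalize(self, ns: int = 1):
        n = self.n_nodes
        self._plans = {
            "bwd": nn.SegmentPlan(self.temporal_src, n),  # messages flow child -> parent slot
            "fwd": nn.SegmentPlan(self.temporal_dst, n),  # parent edge -> child slot
            "spatial": nn.SegmentPlan(self.spatial_dst, n),
            "spatial_src": nn.SegmentPlan(self.spatial_src, n),
        }
        self.first_mask = (self.t_off == -(self.nt - 1)).astype(float)[:, None]
        self.last_mask = (self.t_off == 0).astype(float)[:, None]
        counts = self._plans["spatial"].counts.astype(float)
        with np.errstate(divide="ignore"):
            inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        self.inv_spatial_counts = inv[:, None]
        self._build_stages(ns)

    def _build_stages(self, ns: int) -> None:
        """Exact pruning for per-target batches: the decoded output depends
        only on spatial messages reaching the ancestor chain within the
        remaining spatial iterations, and on forward temporal messages along
        the chain, so those stages can skip every other row."""
        self._spatial_stages = None
        self._fwd_stage = None
        if not self.lineage_mask.any():
            return
        n = self.n_nodes
        big = n + ns + 2
        dist = np.where(self.lineage_mask, 0, big)
        for _ in range(ns):  # in-frame BFS distance from the lineage chain
            if len(self.spatial_src):
                np.minimum.at(dist, self.spatial_dst, dist[self.spatial_src] + 1)
        self._spatial_stages = []
        for l in range(ns):
            recv = dist <= (ns - 1 - l)
            sel = recv[self.spatial_dst]
            src_l, dst_l = self.spatial_src[sel], self.spatial_dst[sel]
            rows = np.flatnonzero(recv)
            self._spatial_stages.append(
                {
                    "src": src_l,
                    "dst": dst_l,
                    "dst_plan": nn.SegmentPlan(dst_l, n),
                    "src_plan": nn.SegmentPlan(src_l, n),
                    "rows": rows,
                    "rows_plan": nn.SegmentPlan(rows, n),
                }
            )
        sel = self.lineage_mask[self.temporal_dst]
        fsrc, fdst = self.temporal_src[sel], self.temporal_dst[sel]
        self._fwd_stage = {
            "src": fsrc,
            "dst": fdst,
            "dst_plan": nn.SegmentPlan(fdst, n),
            "src_plan": nn.SegmentPlan(fsrc, n),
        }

    def null_features(self) -> np.ndarray:
        if not hasattr(self, "_null"):
            self._null = np.zeros_like(self.X, dtype=np.float32)
        return self._null


def _append_graph(batch: GraphBatch, graph, t0: int, sub_id: int, lineage: frozenset, target) -> None:
    base = batch.n_nodes
    keys = sorted(graph.nodes)
    index = {k: base + i for i, k in enumerate(keys)}
    X = np.stack([graph.nodes[k].features for k in keys]) if keys else np.zeros((0, N_FEATURES))
    batch.X = np.vstack([batch.X, X])
    batch.t_off = np.concatenate([batch.t_off, np.array([k[0] - t0 for k in keys], dtype=np.intp)])
    tsrc, tdst = [], []
    for k in keys:
        for d in sorted(graph.nodes[k].daughters):
            tsrc.append(index[k])
            tdst.append(index[d])
    ssrc, sdst = [], []
    for f in graph.frames:
        for a, b in sorted(graph.spatial.get(f, set())):
            ia, ib = index[(f, a)], index[(f, b)]
            ssrc += [ia, ib]
            sdst += [ib, ia]
    batch.temporal_src = np.concatenate([batch.temporal_src, np.array(tsrc, dtype=np.intp)])
    batch.temporal_dst = np.concatenate([batch.temporal_dst, np.array(tdst, dtype=np.intp)])
    batch.spatial_src = np.concatenate([batch.spatial_src, np.array(ssrc, dtype=np.intp)])
    batch.spatial_dst = np.concatenate([batch.spatial_dst, np.array(sdst, dtype=np.intp)])
    batch.subgraph_id = np.concatenate([batch.subgraph_id, np.full(len(keys), sub_id, dtype=np.intp)])
    lin = np.array([k in lineage for k in keys], dtype=bool)
    batch.lineage_mask = np.concatenate([batch.lineage_mask, lin])
    batch.node_keys += [(sub_id, k) for k in keys]
    if target is not None:
        batch.target_idx = np.append(batch.target_idx, index[target]).astype(np.intp)


def build_batch(subgraphs: list[TargetSubgraph], labels: bool = True, nt: int | None = None, ns: int = 1) -> GraphBatch:
    """Stack per-target subgraphs into one block-diagonal batch."""
    if not subgraphs:
        raise ValueError("empty subgraph list")
    if nt is None:
        nt = max(sg.t0 - min(sg.graph.frames) + 1 for sg in subgraphs)
    batch = GraphBatch(nt=nt)
    for i, sg in enumerate(subgraphs):
        _append_graph(batch, sg.graph, sg.t0, i, sg.lineage, sg.target)
    if labels:
        batch.labels = np.array(
            [FATE_INDEX[sg.graph.nodes[sg.target].fate] for sg in subgraphs], dtype=np.intp
        )
    batch._finalize(ns)
    return batch


def build_window_batch(
    window: Window, targets: list | None = None, labels: bool = True, external: bool = False
) -> GraphBatch:
    """Encode a whole window once, decoding all its targets.

    Equivalent to the per-target batch for every variant except
    ``cell_external``, whose per-target feature nulling is target-specific.
    With ``external=True`` the batch additionally carries the union of the
    targets' ancestor chains, which enables the shared cell-external
    evaluation at Ns = 1 (see FateGNN.forward): because every zeroed
    receiver makes the spatial edge message a function of the sender alone,
    and every value consumed downstream lives on an ancestor chain, all
    targets of the window can share one computation.
    """
    targets = window.targets() if targets is None else targets
    batch = GraphBatch(nt=len(window.frames))
    lineage: set = set()
    if external:
        for t in targets:
            key = t
            lineage.add(key)
            while window.nodes[key].parent is not None:
                key = window.nodes[key].parent
                lineage.add(key)
    _append_graph(batch, window, window.t0, 0, frozenset(lineage), None)
    index = {k: i for i, (sid, k) in enumerate(batch.node_keys)}
    batch.target_idx = np.array([index[t] for t in targets], dtype=np.intp)
    if labels:
        batch.labels = np.array([FATE_INDEX[window.nodes[t].fate] for t in targets], dtype=np.intp)
    batch.shared_external = external
    if external:
        batch._finalize(ns=1)
    else:
        batch._finalize()
    return batch


class FateGNN:
    """The seven-MLP message-passing model family."""

    MLP_NAMES = {
        "bidirectional": ("bwd_edge", "bwd_node", "sp_edge", "sp_node", "fwd_edge", "fwd_node", "dec"),
        "unidirectional": ("sp_edge", "sp_node", "fwd_edge", "fwd_node", "dec"),
        "cell_external": ("sp_edge", "sp_node", "fwd_edge", "fwd_node", "dec"),
        "no_spatial": ("fwd_edge", "fwd_node", "dec"),
    }

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.seed = int(seed)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        n = config.n_features
        self.mlps: dict[str, nn.MLP] = {}
        for name in self.MLP_NAMES[config.variant]:
            in_dim = n if name == "dec" else 2 * n
            out_dim = 3 if name == "dec" else n
            self.mlps[name] = nn.MLP(
                in_dim, out_dim, hidden=config.hidden, n_layer=config.n_layer,
                p_dropout=config.p_dropout, rng=rng, dtype=dtype,
            )

    def parameters(self) -> list[nn.Tensor]:
        return [p for m in self.mlps.values() for p in m.parameters()]

    # -- passes ------------------------------------------------------------

    def _edge_node_iter(self, h, src, dst, plan, edge_mlp, node_mlp, freeze_mask, h0,
                        train, rng, scale=None, src_plan=None):
        """One message-passing iteration: edge MLP on (receiver, sender)
        states, segment aggregation at the receiver, node MLP on (message,
        state), with optional frozen rows restored from ``h0``."""
        msg_in = nn.concat(nn.gather(h, dst, back_plan=plan), nn.gather(h, src, back_plan=src_plan))
        e = edge_mlp(msg_in, train=train, rng=rng)
        agg = nn.segment_sum(e, plan)
        if scale is not None:
            agg = nn.mul(agg, scale)
        h_new = node_mlp(nn.concat(agg, h), train=train, rng=rng)
        if freeze_mask is not None:
            h_new = nn.add(nn.mul(h_new, 1.0 - freeze_mask), nn.mul(h0, freeze_mask))
        return h_new

    def _pruned_iter(self, h, stage, edge_mlp, node_mlp, rows, rows_plan, train, rng, scale):
        """Message-passing iteration computed only for the rows that can
        still influence the decoded targets (exact, see _build_stages)."""
        msg_in = nn.gather2_concat(h, stage["dst"], stage["src"], stage["dst_plan"], stage["src_plan"])
        e = edge_mlp(msg_in, train=train, rng=rng)
        agg = nn.segment_sum(e, stage["dst_plan"])
        if scale is not None:
            agg = nn.mul(agg, scale)
        node_in = nn.gathers_concat(agg, h, rows, rows_plan)
        return nn.row_update(h, rows, node_mlp(node_in, train=train, rng=rng))

    def forward(self, batch: GraphBatch, features: np.ndarray | None = None,
                train: bool = False, rng: np.random.Generator | None = None) -> nn.Tensor:
        """Return the (n_targets, 3) fate logits as an autodiff tensor.

        ``features`` overrides the batch's stored node features (used for
        integrated-gradients path points); pass a Tensor-worthy array.  The
        returned tensor's graph reaches back to the input features, so both
        parameter and input gradients are available.
        """
        cfg = self.config
        if features is None:
            cached = getattr(batch, "_x_cast", None)
            if cached is None or cached[0] is not batch.X or cached[1].dtype != self.dtype:
                batch._x_cast = (batch.X, np.ascontiguousarray(batch.X, dtype=self.dtype))
            X = batch._x_cast[1]
        else:
            X = np.ascontiguousarray(features, dtype=self.dtype)
        x_in = nn.Tensor(X, requires_grad=True)
        self._last_input = x_in
        h = x_in

        if cfg.variant == "bidirectional":
            # stage 1: future -> past along temporal edges; receiver is the parent
            plan = batch._plans["bwd"]
            h0 = h
            for _ in range(cfg.nt - 1):
                h = self._edge_node_iter(
                    h, src=batch.temporal_dst, dst=batch.temporal_src, plan=plan,
                    edge_mlp=self.mlps["bwd_edge"], node_mlp=self.mlps["bwd_node"],
                    freeze_mask=batch.last_mask, h0=h0, train=train, rng=rng,
                    src_plan=batch._plans["fwd"],
                )
        shared_external = cfg.variant == "cell_external" and getattr(batch, "shared_external", False)
        if cfg.variant == "cell_external" and not shared_external:
            if batch.lineage_mask.any():
                mask = getattr(batch, "_ext_mask", None)
                if mask is None or mask.dtype != self.dtype:
                    mask = batch._ext_mask = (~batch.lineage_mask).astype(self.dtype)[:, None]
                h = nn.mul(h, mask)
            else:
                raise ValueError("cell_external needs per-target batches or external=True window batches")

        pruned = (
            getattr(batch, "_spatial_stages", None) is not None
            and len(batch._spatial_stages) == cfg.ns
        )

        if cfg.variant != "no_spatial":
            scale = batch.inv_spatial_counts.astype(self.dtype) if cfg.aggregation == "mean" else None
            if shared_external:
                # Shared evaluation: every consumed spatial edge has a zeroed
                # (ancestor-chain) receiver, so the edge message is a function
                # of the sender alone -- evaluate it once per node and let all
                # targets of the window share it.  Exact for ns = 1.
                if cfg.ns != 1 or not pruned:
                    raise ValueError("shared cell-external evaluation requires ns = 1")
                st = batch._spatial_stages[0]
                zeros_n = nn.Tensor(np.zeros_like(h.data))
                e_all = self.mlps["sp_edge"](nn.concat(zeros_n, h), train=train, rng=rng)
                msg = nn.gather(e_all, st["src"], back_plan=st["src_plan"])
                agg = nn.segment_sum(msg, st["dst_plan"])
                if scale is not None:
                    agg = nn.mul(agg, scale)
                rows, rows_plan = st["rows"], st["rows_plan"]
                zeros_r = nn.Tensor(np.zeros((len(rows), h.data.shape[1]), dtype=self.dtype))
                node_in = nn.concat(nn.gather(agg, rows, back_plan=rows_plan), zeros_r)
                h = nn.row_update(h, rows, self.mlps["sp_node"](node_in, train=train, rng=rng))
            elif pruned:
                for l in range(cfg.ns):
                    st = batch._spatial_stages[l]
                    h = self._pruned_iter(h, st, self.mlps["sp_edge"], self.mlps["sp_node"],
                                          st["rows"], st["rows_plan"], train, rng, scale)
            else:
                for _ in range(cfg.ns):
                    h = self._edge_node_iter(
                        h, src=batch.spatial_src, dst=batch.spatial_dst, plan=batch._plans["spatial"],
                        edge_mlp=self.mlps["sp_edge"], node_mlp=self.mlps["sp_node"],
                        freeze_mask=None, h0=None, train=train, rng=rng, scale=scale,
                        src_plan=batch._plans["spatial_src"],
                    )

        # stage 3: past -> future; receiver is the child (one parent edge each)
        first_frozen = cfg.freeze_convention == "first"
        if pruned:
            st = batch._fwd_stage
            frozen_t = -(cfg.nt - 1) if first_frozen else 0
            cache = st.setdefault("rows_cache", {})
            if frozen_t not in cache:
                rows = np.flatnonzero(batch.lineage_mask & (batch.t_off != frozen_t))
                cache[frozen_t] = (rows, nn.SegmentPlan(rows, batch.n_nodes))
            rows, rows_plan = cache[frozen_t]
            for _ in range(cfg.nt - 1):
                h = self._pruned_iter(h, st, self.mlps["fwd_edge"], self.mlps["fwd_node"],
                                      rows, rows_plan, train, rng, None)
        else:
            freeze = batch.first_mask if first_frozen else batch.last_mask
            h0 = h
            for _ in range(cfg.nt - 1):
                h = self._edge_node_iter(
                    h, src=batch.temporal_src, dst=batch.temporal_dst, plan=batch._plans["fwd"],
                    edge_mlp=self.mlps["fwd_edge"], node_mlp=self.mlps["fwd_node"],
                    freeze_mask=freeze.astype(self.dtype), h0=h0, train=train, rng=rng,
                    src_plan=batch._plans["bwd"],
                )

        logits = self.mlps["dec"](nn.gather(h, batch.target_idx), train=train, rng=rng)
        return logits

    def predict_proba(self, batch: GraphBatch, features: np.ndarray | None = None) -> np.ndarray:
        """Softmax fate scores in eval mode (dropout off, deterministic)."""
        logits = self.forward(batch, features=features, train=False)
        return nn.softmax(logits).data

    # -- serialization -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, mlp in self.mlps.items():
            for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
                out[f"{name}.w{i}"] = w.data
                out[f"{name}.b{i}"] = b.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for name, mlp in self.mlps.items():
            for i in range(len(mlp.weights)):
                mlp.weights[i].data = np.asarray(arrays[f"{name}.w{i}"], dtype=self.dtype)
                mlp.biases[i].data = np.asarray(arrays[f"{name}.b{i}"], dtype=self.dtype)

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def save_checkpoint(path, model: FateGNN) -> None:
    """Portable array archive: all MLP weights plus the model config."""
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.state_arrays())


def load_checkpoint(path) -> FateGNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = FateGNN(ModelConfig(**meta["config"]), seed=meta["seed"])
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model
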