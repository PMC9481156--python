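"""Spatiotemporal cell graphs: lineage, contacts, features, windows, subgraphs.

Cells are nodes keyed by ``(frame_index, cell_id)``.  Temporal edges follow
the tracks (a division forks one node into two daughters; a delamination
terminates a track); spatial edges connect cells in contact within one frame.
Each node carries a fixed-length feature vector in the canonical order
``[area, g1, nfb_nb, nfb_del, nfb_div, random]`` — deactivating a feature
zeroes its slot rather than shrinking the vector, so model shapes are
identical across feature ablations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NB",
    "DEL",
    "DIV",
    "CENSORED",
    "FEATURE_NAMES",
    "N_FEATURES",
    "ValidationError",
    "CellNode",
    "SpatioTemporalGraph",
    "Window",
    "TargetSubgraph",
    "FeatureConfig",
    "build_graph",
    "contacts_from_labels",
    "set_nfb",
    "normalize_features",
    "add_random_feature",
    "apply_feature_config",
    "extract_windows",
    "extract_target_subgraph",
    "null_graph",
    "graph_to_tables",
]

# fate labels
NB = "NB"
DEL = "Del"
DIV = "Div"
CENSORED = "Censored"
TARGET_FATES = (NB, DEL, DIV)
FATE_INDEX = {NB: 0, DEL: 1, DIV: 2}

FEATURE_NAMES = ("area", "g1", "nfb_nb", "nfb_del", "nfb_div", "random")
N_FEATURES = 6
_NFB_SLICE = slice(2, 5)
_NFB_ONEHOT = {NB: (1.0, 0.0, 0.0), DEL: (0.0, 1.0, 0.0), DIV: (0.0, 0.0, 1.0), CENSORED: (0.0, 0.0, 0.0)}

# TSV fate spellings
_FATE_FROM_TSV = {"NB": NB, "DEL": DEL, "DIV": DIV, "CENSOR": CENSORED}
_FATE_TO_TSV = {v: k for k, v in _FATE_FROM_TSV.items()}


class ValidationError(ValueError):
    """Raised when a track/contact table violates the graph invariants."""


@dataclass
class CellNode:
    """One cell observed in one frame."""

    features: np.ndarray
    fate: str = CENSORED
    parent: tuple[int, int] | None = None
    daughters: set = field(default_factory=set)
    # auxiliary per-cell scalars (e.g. simulator positions) kept for analyses
    # that need centroids; not part of the model feature vector
    x: float = np.nan
    y: float = np.nan


class SpatioTemporalGraph:
    """Cells-as-nodes over frames with contact edges and lineage edges."""

    def __init__(self):
        self.frames: list[int] = []
        self.nodes: dict[tuple[int, int], CellNode] = {}
        # per frame: set of unordered (a, b) cell-id pairs with a < b
        self.spatial: dict[int, set[tuple[int, int]]] = {}

    # -- construction ------------------------------------------------------
    def add_node(self, frame: int, cell_id: int, node: CellNode) -> None:
        key = (frame, cell_id)
        if key in self.nodes:
            raise ValidationError(f"duplicate node {key}")
        if frame not in self.spatial:
            self.spatial[frame] = set()
            self.frames = sorted(set(self.frames) | {frame})
        self.nodes[key] = node

    def add_contact(self, frame: int, a: int, b: int) -> None:
        if a == b:
            raise ValidationError(f"self-contact of cell {a} in frame {frame}")
        for cid in (a, b):
            if (frame, cid) not in self.nodes:
                raise ValidationError(f"contact references missing cell {cid} in frame {frame}")
        self.spatial.setdefault(frame, set()).add((min(a, b), max(a, b)))

    # -- queries -----------------------------------------------------------
    def neighbors(self, frame: int, cell_id: int) -> list[int]:
        out = []
        for a, b in self.spatial.get(frame, ()):
            if a == cell_id:
                out.append(b)
            elif b == cell_id:
                out.append(a)
        return sorted(out)

    def cells_in_frame(self, frame: int) -> list[int]:
        return sorted(cid for (f, cid) in self.nodes if f == frame)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        """Check lineage and spatial invariants; raise ValidationError on failure."""
        frame_set = set(self.frames)
        for (f, cid), node in self.nodes.items():
            if f not in frame_set:
                raise ValidationError(f"node ({f},{cid}) in unknown frame")
            if node.parent is not None:
                pf, pcid = node.parent
                if pf != f - 1:
                    raise ValidationError(f"parent of ({f},{cid}) not in previous frame")
                pnode = self.nodes.get(node.parent)
                if pnode is None:
                    raise ValidationError(f"dangling parent reference {node.parent} of ({f},{cid})")
                if (f, cid) not in pnode.daughters:
                    raise ValidationError(f"daughter relation not inverse of parent for ({f},{cid})")
            for dkey in node.daughters:
                if dkey not in self.nodes:
                    raise ValidationError(f"dangling daughter {dkey} of ({f},{cid})")
                if self.nodes[dkey].parent != (f, cid):
                    raise ValidationError(f"parent relation not inverse of daughter for {dkey}")
            nd = len(node.daughters)
            if node.fate == DIV and nd != 2:
                raise ValidationError(f"Div node ({f},{cid}) has {nd} daughters")
            if node.fate == NB and nd != 1:
                raise ValidationError(f"NB node ({f},{cid}) has {nd} daughters")
            if node.fate in (DEL, CENSORED) and nd != 0:
                raise ValidationError(f"{node.fate} node ({f},{cid}) has daughters")
        for f, edges in self.spatial.items():
            for a, b in edges:
                if (f, a) not in self.nodes or (f, b) not in self.nodes:
                    raise ValidationError(f"spatial edge ({a},{b}) in frame {f} has missing endpoint")

    def copy(self) -> "SpatioTemporalGraph":
        g = SpatioTemporalGraph()
        g.frames = list(self.frames)
        g.nodes = {
            k: CellNode(n.features.copy(), n.fate, n.parent, set(n.daughters), n.x, n.y)
            for k, n in self.nodes.items()
        }
        g.spatial = {f: set(e) for f, e in self.spatial.items()}
        return g

    def restrict(self, frames: list[int]) -> "SpatioTemporalGraph":
        """Induced subgraph on a set of frames (lineage links outside are cut)."""
        fset = set(frames)
        g = SpatioTemporalGraph()
        g.frames = sorted(fset)
        for (f, cid), n in self.nodes.items():
            if f not in fset:
                continue
            parent = n.parent if (n.parent is not None and n.parent[0] in fset) else None
            daughters = {d for d in n.daughters if d[0] in fset}
            g.nodes[(f, cid)] = CellNode(n.features.copy(), n.fate, parent, daughters, n.x, n.y)
        g.spatial = {f: set(self.spatial.get(f, set())) for f in g.frames}
        return g


class Window(SpatioTemporalGraph):
    """An Nt-frame restriction with frames re-indexed t = -(Nt-1)..0."""

    def __init__(self, base: SpatioTemporalGraph, frames: list[int]):
        super().__init__()
        g = base.restrict(frames)
        self.frames = g.frames
        self.nodes = g.nodes
        self.spatial = g.spatial
        self.t0 = max(frames)

    def offset(self, frame: int) -> int:
        """Relative frame index t in -(Nt-1)..0."""
        return frame - self.t0

    def targets(self) -> list[tuple[int, int]]:
        """Valid prediction targets: frame-0 cells with an observable fate and
        an ancestor chain spanning the window (spatiotemporal-boundary cells
        are excluded)."""
        out = []
        first = min(self.frames)
        for (f, cid), node in self.nodes.items():
            if f != self.t0 or node.fate not in TARGET_FATES:
                continue
            key = (f, cid)
            while self.nodes[key].parent is not None:
                key = self.nodes[key].parent
            if key[0] == first:
                out.append((f, cid))
        return sorted(out)


@dataclass
class TargetSubgraph:
    """The receptive-field subgraph of one target cell in a window.

    Contains the target's ancestor chain, the Ns-step contact neighborhood of
    every ancestor, and all within-window descendants of those nodes (daughter
    forks of ancestor neighbors, sibling subtrees), with all induced edges.
    """

    graph: SpatioTemporalGraph
    target: tuple[int, int]
    lineage: frozenset
    t0: int

    def offset(self, frame: int) -> int:
        return frame - self.t0


@dataclass
class FeatureConfig:
    """Which features are active, plus normalization constants and the seed
    of the uninformative uniform-random control feature."""

    area: bool = True
    g1: bool = True
    nfb: bool = True
    random: bool = True
    maxima: dict = field(default_factory=dict)
    seed: int = 0

    def active_mask(self) -> np.ndarray:
        m = np.zeros(N_FEATURES)
        m[0] = float(self.area)
        m[1] = float(self.g1)
        m[2:5] = float(self.nfb)
        m[5] = float(self.random)
        return m


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_graph(track_table: pd.DataFrame, contact_table: pd.DataFrame) -> SpatioTemporalGraph:
    """Build a validated spatiotemporal graph from track and contact tables.

    ``track_table`` columns: frame, cell_id, parent_id (-1 if none), fate
    (NB/DEL/DIV/CENSOR), area, g1 and optionally x, y.  ``contact_table``
    columns: frame, cell_id_a, cell_id_b.  Fates are re-derived from the
    lineage structure (two daughters => Div, a track ending before the last
    frame => Del unless flagged CENSOR) and validated against the table.
    """
    g = SpatioTemporalGraph()
    has_xy = "x" in track_table.columns and "y" in track_table.columns
    for row in track_table.itertuples(index=False):
        f, cid = int(row.frame), int(row.cell_id)
        feats = np.zeros(N_FEATURES)
        feats[0] = float(row.area)
        feats[1] = float(row.g1)
        node = CellNode(feats)
        if has_xy:
            node.x, node.y = float(row.x), float(row.y)
        g.add_node(f, cid, node)

    last_frame = max(g.frames)
    # explicit lineage links (daughters carry parent_id); a non-dividing cell
    # keeps its id, so same-id nodes in consecutive frames are linked implicitly
    for row in track_table.itertuples(index=False):
        f, cid, pid = int(row.frame), int(row.cell_id), int(row.parent_id)
        if pid < 0:
            pkey = (f - 1, cid)
            if pkey in g.nodes:
                g.nodes[(f, cid)].parent = pkey
                g.nodes[pkey].daughters.add((f, cid))
            continue
        pkey = (f - 1, pid)
        if pkey not in g.nodes:
            raise ValidationError(
                f"row (frame={f}, cell_id={cid}): dangling parent reference {pid} "
                f"(no such cell in frame {f - 1})"
            )
        g.nodes[(f, cid)].parent = pkey
        g.nodes[pkey].daughters.add((f, cid))
        if len(g.nodes[pkey].daughters) > 2:
            raise ValidationError(f"row (frame={f}, cell_id={cid}): cell {pid} has >2 daughters")

    # derive fates from structure, honoring explicit CENSOR flags
    stated = {
        (int(r.frame), int(r.cell_id)): _FATE_FROM_TSV.get(str(r.fate).upper())
        for r in track_table.itertuples(index=False)
    }
    for key, flag in stated.items():
        if flag is None:
            raise ValidationError(f"row (frame={key[0]}, cell_id={key[1]}): unknown fate label")
    for (f, cid), node in g.nodes.items():
        nd = len(node.daughters)
        if nd == 2:
            derived = DIV
        elif nd == 1:
            derived = NB
        elif f == last_frame or stated[(f, cid)] == CENSORED:
            derived = CENSORED
        else:
            derived = DEL
        if f != last_frame and stated[(f, cid)] != CENSORED and stated[(f, cid)] != derived:
            raise ValidationError(
                f"row (frame={f}, cell_id={cid}): stated fate {stated[(f, cid)]} "
                f"inconsistent with lineage-derived fate {derived}"
            )
        if stated[(f, cid)] == CENSORED and nd > 0:
            raise ValidationError(f"row (frame={f}, cell_id={cid}): censored cell has daughters")
        node.fate = derived

    for row in contact_table.itertuples(index=False):
        f = int(row.frame)
        a, b = int(row.cell_id_a), int(row.cell_id_b)
        for cid in (a, b):
            if (f, cid) not in g.nodes:
                raise ValidationError(
                    f"contact row (frame={f}, {a}-{b}): cell {cid} not in track table frame {f}"
                )
        g.add_contact(f, a, b)

    g.validate()
    return g


def contacts_from_labels(label_image: np.ndarray) -> pd.DataFrame:
    """Contact pairs from a 2D integer label image (background = 0).

    Two regions are in contact iff they share more than one boundary-adjacent
    pixel pair under 4-connectivity.  Returns columns cell_id_a, cell_id_b.
    """
    lab = np.asarray(label_image)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("label image must have an integer dtype")
    pairs = []
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[m], b[m])
        hi = np.maximum(a[m], b[m])
        pairs.append(np.stack([lo, hi], axis=1))
    pairs = np.concatenate(pairs, axis=0)
    if len(pairs) == 0:
        return pd.DataFrame(columns=["cell_id_a", "cell_id_b"])
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    keep = uniq[counts > 1]
    return pd.DataFrame({"cell_id_a": keep[:, 0], "cell_id_b": keep[:, 1]})


def set_nfb(graph: SpatioTemporalGraph) -> SpatioTemporalGraph:
    """Write each node's next-frame behavior one-hot into its feature vector.

    NB -> [1,0,0], Del -> [0,1,0], Div -> [0,0,1]; censored cells (unknown
    behavior) get the null vector.  Nulling of the final frame of a window
    happens at window extraction, where "final" is defined.
    """
    for node in graph.nodes.values():
        node.features[_NFB_SLICE] = _NFB_ONEHOT[node.fate]
    return graph


def normalize_features(graphs: list[SpatioTemporalGraph], config: FeatureConfig) -> list[SpatioTemporalGraph]:
    """Divide each active scalar feature by its maximum over all graphs
    (training and test pooled); the maxima are recorded in ``config``."""
    for name, idx, active in (("area", 0, config.area), ("g1", 1, config.g1)):
        if not active:
            continue
        mx = max((float(n.features[idx]) for g in graphs for n in g.nodes.values()), default=0.0)
        if mx <= 0:
            raise ValueError(f"feature '{name}' is zero everywhere; cannot normalize")
        config.maxima[name] = mx
        for g in graphs:
            for n in g.nodes.values():
                n.features[idx] /= mx
    return graphs


def add_random_feature(graph: SpatioTemporalGraph, seed: int) -> SpatioTemporalGraph:
    """One U(0,1) draw per node, fixed at build time, reproducible from seed."""
    rng = np.random.default_rng(seed)
    for key in sorted(graph.nodes):
        graph.nodes[key].features[5] = rng.random()
    return graph


def apply_feature_config(graph: SpatioTemporalGraph, config: FeatureConfig) -> SpatioTemporalGraph:
    """Zero the slots of inactive features in every node (dimension retained)."""
    mask = config.active_mask()
    for node in graph.nodes.values():
        node.features *= mask
    return graph


# ---------------------------------------------------------------------------
# windows and subgraphs
# ---------------------------------------------------------------------------


def extract_windows(graph: SpatioTemporalGraph, nt: int) -> list[Window]:
    """One window per contiguous run of ``nt`` frames.

    The next-frame-behavior slots of final-frame nodes are nulled in each
    window (that behavior is the prediction target)."""
    if nt < 2:
        raise ValueError("nt must be >= 2")
    frames = graph.frames
    if len(frames) < nt:
        raise ValueError(f"graph has {len(frames)} frames, fewer than nt={nt}")
    if frames != list(range(frames[0], frames[-1] + 1)):
        raise ValueError("frames must be contiguous")
    windows = []
    for start in range(frames[0], frames[-1] - nt + 2):
        w = Window(graph, list(range(start, start + nt)))
        for (f, cid), node in w.nodes.items():
            if f == w.t0:
                node.features[_NFB_SLICE] = 0.0
        windows.append(w)
    return windows


def extract_target_subgraph(window: Window, target: tuple[int, int], ns: int = 1) -> TargetSubgraph:
    """Receptive-field subgraph of ``target`` under the message-passing order.

    Backward temporal passes first pull each node's within-window descendant
    subtree into it, spatial passes then mix Ns-step neighborhoods, and
    forward temporal passes push ancestor states to the target.  The node set
    is therefore: ancestor chain, Ns-step contact neighbors of each ancestor,
    and the descendant closure of all of those.
    """
    if target not in window.nodes or target[0] != window.t0:
        raise ValueError(f"target {target} is not a frame-0 cell of the window")
    # ancestor chain
    chain = [target]
    while window.nodes[chain[-1]].parent is not None:
        chain.append(window.nodes[chain[-1]].parent)
    selected = set(chain)
    # Ns-step in-frame contact neighborhoods of each ancestor
    for f, cid in chain:
        layer = {cid}
        seen = {cid}
        for _ in range(ns):
            nxt = set()
            for c in layer:
                nxt.update(window.neighbors(f, c))
            layer = nxt - seen
            seen |= layer
        selected.update((f, c) for c in seen)
    # descendant closure
    stack = list(selected)
    while stack:
        key = stack.pop()
        for d in window.nodes[key].daughters:
            if d not in selected:
                selected.add(d)
                stack.append(d)
    sub = SpatioTemporalGraph()
    sub.frames = sorted({f for f, _ in selected})
    for key in selected:
        n = window.nodes[key]
        parent = n.parent if n.parent in selected else None
        daughters = {d for d in n.daughters if d in selected}
        sub.nodes[key] = CellNode(n.features.copy(), n.fate, parent, daughters, n.x, n.y)
    sub.spatial = {
        f: {(a, b) for (a, b) in window.spatial.get(f, set()) if (f, a) in selected and (f, b) in selected}
        for f in sub.frames
    }
    return TargetSubgraph(graph=sub, target=target, lineage=frozenset(chain), t0=window.t0)


def null_graph(subgraph: TargetSubgraph) -> TargetSubgraph:
    """Identical topology, all feature vectors zero (the attribution baseline)."""
    g = subgraph.graph.copy()
    for node in g.nodes.values():
        node.features[:] = 0.0
    return replace(subgraph, graph=g)


def graph_to_tables(graph: SpatioTemporalGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export a graph back to (track_table, contact_table) DataFrames."""
    rows = []
    has_xy = any(np.isfinite(n.x) for n in graph.nodes.values())
    for (f, cid) in sorted(graph.nodes):
        n = graph.nodes[(f, cid)]
        row = {
            "frame": f,
            "cell_id": cid,
            "parent_id": n.parent[1] if n.parent else -1,
            "fate": _FATE_TO_TSV[n.fate],
            "area": n.features[0],
            "g1": n.features[1],
        }
        if has_xy:
            row["x"], row["y"] = n.x, n.y
        rows.append(row)
    contacts = [
        {"frame": f, "cell_id_a": a, "cell_id_b": b}
        for f in graph.frames
        for (a, b) in sorted(graph.spatial.get(f, set()))
    ]
    return pd.DataFrame(rows), pd.DataFrame(contacts, columns=["frame", "cell_id_a", "cell_id_b"])
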