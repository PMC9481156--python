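"""Integrated-gradients attribution with spatiotemporal pooling.

For each target subgraph the attribution of feature k to fate f is

    I_k^f = (X_k - X'_k) * (1/M) sum_j dF^f(X' + (j-1/2)/M (X - X')) / dX_k

with the null graph (all features zero) as baseline X', evaluated by a
midpoint Riemann sum.  Because the softmax scores sum to one, the
attributions of any feature sum to zero across the three fates.

Attributions are pooled by (feature type, relative frame t, role), where the
role distinguishes the target's own lineage from surrounding cells; the
next-frame-behavior categories are averaged only over the cells whose
behavior matches the category.  A deliberately uninformative uniform-random
feature provides the significance band: over all its pooled rows, the band
is [min(mean - SE), max(mean + SE)] across model replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .gnn_core import FateGNN, GraphBatch
from .track_graph import FEATURE_NAMES

__all__ = [
    "AttributionTable",
    "integrated_gradients",
    "pool_attributions",
    "attribute_model",
    "aggregate_models",
    "random_baseline_band",
    "attribution_to_frame",
    "plot_attribution",
]

FATES = ("NB", "Del", "Div")
_NFB_FEATURES = {"nfb_nb": 2, "nfb_del": 3, "nfb_div": 4}


@dataclass
class AttributionTable:
    """Rows: (feature, t, role); columns: per-fate mean (and SE after
    aggregation over model replicates); band: random-feature envelope."""

    rows: dict  # (feature, t, role) -> {"mean": (3,), "se": (3,) | None, "n": int}
    band: tuple[float, float] | None = None

    def value(self, feature: str, t: int, role: str, fate: str) -> float:
        return float(self.rows[(feature, t, role)]["mean"][FATES.index(fate)])


def integrated_gradients(model: FateGNN, batch: GraphBatch, steps: int = 50) -> np.ndarray:
    """Per-node, per-feature, per-fate IG array of shape (n_nodes, 6, 3).

    The model is run in eval mode; the baseline is the null graph, so the
    path point at step j is (j - 1/2)/M * X.  Gradients of the three fate
    scores are accumulated in three backward sweeps per path point.
    """
    X = batch.X
    grads = np.zeros(X.shape + (3,))
    for j in range(1, steps + 1):
        alpha = (j - 0.5) / steps
        for f in range(3):
            logits = model.forward(batch, features=alpha * X, train=False)
            score = nn.softmax_class_sum(logits, f)
            nn.backward(score)
            grads[:, :, f] += model._last_input.grad
    return X[:, :, None] * grads / steps


def _subgraph_means(ig: np.ndarray, batch: GraphBatch, sid_offset: int = 0) -> dict:
    """Per-(category, subgraph) pooled means: category -> {sid: (3,) mean}."""
    role = np.where(batch.lineage_mask, "lineage", "neighbor")
    nfb = batch.X[:, 2:5]
    accum: dict = {}
    for i in range(batch.n_nodes):
        t, r, sid = int(batch.t_off[i]), role[i], int(batch.subgraph_id[i]) + sid_offset
        for feat in ("area", "g1", "random"):
            k = FEATURE_NAMES.index(feat)
            accum.setdefault((feat, t, r), {}).setdefault(sid, []).append(ig[i, k, :])
        hot = np.flatnonzero(nfb[i] > 0.5)
        if len(hot) == 1:
            feat = ("nfb_nb", "nfb_del", "nfb_div")[hot[0]]
            accum.setdefault((feat, t, r), {}).setdefault(sid, []).append(ig[i, 2 + hot[0], :])
    return {
        key: {sid: np.mean(vals, axis=0) for sid, vals in per_sub.items()}
        for key, per_sub in accum.items()
    }


def pool_attributions(ig: np.ndarray, batch: GraphBatch) -> AttributionTable:
    """Pool per-feature attributions into (feature, relative frame, role)
    categories: averaged within each target's subgraph first, then over
    subgraphs.  Subgraphs where a category is empty do not contribute to
    that row; a category empty everywhere is reported as missing."""
    rows = {}
    for key, per_sub in _subgraph_means(ig, batch).items():
        means = np.stack(list(per_sub.values()))
        rows[key] = {"mean": means.mean(axis=0), "se": None, "n": len(per_sub)}
    return AttributionTable(rows=rows)


def attribute_model(model: FateGNN, batches: list[GraphBatch], steps: int = 50) -> AttributionTable:
    """IG of one trained model pooled over all target subgraphs in ``batches``."""
    merged: dict = {}
    offset = 0
    for b in batches:
        ig = integrated_gradients(model, b, steps=steps)
        for key, per_sub in _subgraph_means(ig, b, sid_offset=offset).items():
            merged.setdefault(key, {}).update(per_sub)
        offset += b.n_targets
    rows = {}
    for key, per_sub in merged.items():
        means = np.stack(list(per_sub.values()))
        rows[key] = {"mean": means.mean(axis=0), "se": None, "n": len(per_sub)}
    return AttributionTable(rows=rows)


def aggregate_models(tables: list[AttributionTable]) -> AttributionTable:
    """Mean and standard error across model replicates, row by row."""
    keys = sorted({k for t in tables for k in t.rows}, key=str)
    rows = {}
    for key in keys:
        vals = np.stack([t.rows[key]["mean"] for t in tables if key in t.rows])
        se = vals.std(axis=0, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.zeros(3)
        rows[key] = {"mean": vals.mean(axis=0), "se": se, "n": len(vals)}
    out = AttributionTable(rows=rows)
    try:
        out.band = random_baseline_band(out)
    except ValueError:
        out.band = None
    return out


def random_baseline_band(table: AttributionTable) -> tuple[float, float]:
    """[min(mean - SE), max(mean + SE)] over all pooled random-feature rows."""
    lows, highs = [], []
    for (feat, t, r), row in table.rows.items():
        if feat != "random":
            continue
        se = row["se"] if row["se"] is not None else np.zeros(3)
        lows.append((row["mean"] - se).min())
        highs.append((row["mean"] + se).max())
    if not lows:
        raise ValueError("random feature rows absent; enable the random feature")
    return float(min(lows)), float(max(highs))


def attribution_to_frame(table: AttributionTable) -> pd.DataFrame:
    """Flatten to a DataFrame (one row per category, fate columns)."""
    recs = []
    for (feat, t, role), row in sorted(table.rows.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
        rec = {"feature": feat, "t": t, "role": role, "n": row["n"]}
        for i, f in enumerate(FATES):
            rec[f"ig_{f}"] = row["mean"][i]
            rec[f"se_{f}"] = row["se"][i] if row["se"] is not None else np.nan
        recs.append(rec)
    df = pd.DataFrame(recs)
    if table.band is not None:
        df.attrs["band"] = table.band
    return df


def plot_attribution(table: AttributionTable, path=None):
    """Bar panels of pooled IG per fate with the random-feature band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = attribution_to_frame(table)
    labels = [f"{r.feature} t={r.t} {r.role}" for r in df.itertuples()]
    fig, axes = plt.subplots(1, 3, figsize=(4 * 3, 0.3 * len(df) + 2), sharey=True)
    y = np.arange(len(df))
    for ax, fate in zip(axes, FATES):
        ax.barh(y, df[f"ig_{fate}"], xerr=df[f"se_{fate}"].fillna(0), color="steelblue")
        if table.band is not None:
            ax.axvspan(table.band[0], table.band[1], color="orange", alpha=0.3)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(fate)
    axes[0].set_yticks(y, labels, fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
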