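"""Neighbor fate net imbalance around division/delamination events.

For every cell that divides (or delaminates) at frame t, its six nearest
cells by centroid distance at frame t are tracked forward (descendants
inherit the tracked status; a delaminated or censored neighbor stops
contributing).  The net imbalance at lag tau is the cumulative number of
divisions minus delaminations among the tracked set in (t, t + tau],
averaged over events with its standard error.  An optional background
correction subtracts the population-wide expected net imbalance per tracked
cell so that global fate-rate fluctuations do not masquerade as coordination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["neighbor_fate_imbalance"]


def _normalize_fates(fates: pd.Series) -> pd.Series:
    return fates.astype(str).str.upper().map(
        {"NB": "NB", "DEL": "Del", "DIV": "Div", "CENSOR": "Censored", "CENSORED": "Censored"}
    )


def neighbor_fate_imbalance(
    track: pd.DataFrame,
    event_type: str = "Del",
    max_lag: int = 6,
    box: float | None = None,
    background_correction: bool = False,
) -> pd.DataFrame:
    """Mean net (Div - Del) imbalance among six nearest neighbors vs lag.

    ``track`` needs columns frame, cell_id, parent_id, fate and centroid
    columns x, y.  ``box`` enables the periodic metric (side length) for
    uncropped simulation exports.  Events with fewer than six other cells in
    their frame are skipped.  Returns a DataFrame with columns
    lag, mean, se, n_events.
    """
    if event_type not in ("Div", "Del"):
        raise ValueError("event_type must be 'Div' or 'Del'")
    t = track.copy()
    t["fate"] = _normalize_fates(t["fate"])
    frames = sorted(t.frame.unique())
    # per-frame plain-dict lookups (fast inner loop)
    fate_at: dict[int, dict[int, str]] = {}
    pos_at: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for f, g in t.groupby("frame"):
        fate_at[f] = dict(zip(g.cell_id.astype(int), g.fate))
        pos_at[f] = (g.cell_id.to_numpy(int), g[["x", "y"]].to_numpy(float))
    # children[(frame, cell)] -> ids at frame+1
    children: dict[tuple[int, int], list[int]] = {}
    for row in t.itertuples():
        f, cid = int(row.frame), int(row.cell_id)
        if row.parent_id >= 0:
            children.setdefault((f - 1, int(row.parent_id)), []).append(cid)
        if row.fate == "NB":
            children.setdefault((f, cid), []).append(cid)
    # background net rate per cell per frame
    bg_rate = {
        f: (sum(v == "Div" for v in fates.values()) - sum(v == "Del" for v in fates.values())) / len(fates)
        for f, fates in fate_at.items()
    }

    per_event: list[np.ndarray] = []
    for f in frames:
        ids, pos = pos_at[f]
        ev_ids = [cid for cid, fate in fate_at[f].items() if fate == event_type]
        if not ev_ids or len(ids) < 7:
            continue
        for ev in ev_ids:
            d = pos - pos[ids == ev][0]
            if box is not None:
                d -= box * np.round(d / box)
            dist = np.hypot(d[:, 0], d[:, 1])
            dist[ids == ev] = np.inf
            order = np.lexsort((ids, dist))
            tracked = set(int(i) for i in ids[order[:6]])
            curve = np.zeros(max_lag + 1)
            expected = np.zeros(max_lag + 1)
            net = 0.0
            exp = 0.0
            for lag in range(1, max_lag + 1):
                fr = f + lag - 1  # behaviors at frame fr happen in (fr, fr+1]
                if fr not in fate_at or f + lag > frames[-1]:
                    curve[lag:] = np.nan
                    expected[lag:] = np.nan
                    break
                fates = fate_at[fr]
                nxt = set()
                n_in = 0
                for cid in tracked:
                    fate = fates.get(cid)
                    if fate is None:
                        continue  # left the field of view
                    n_in += 1
                    if fate == "Div":
                        net += 1
                        nxt.update(children.get((fr, cid), []))
                    elif fate == "Del":
                        net -= 1
                    elif fate == "NB":
                        nxt.update(children.get((fr, cid), []))
                exp += bg_rate[fr] * n_in
                tracked = nxt
                curve[lag] = net
                expected[lag] = exp
            per_event.append(curve - expected if background_correction else curve)

    rows = []
    for lag in range(max_lag + 1):
        vals = np.array([c[lag] for c in per_event if np.isfinite(c[lag])])
        n = len(vals)
        rows.append(
            {
                "lag": lag,
                "mean": vals.mean() if n else np.nan,
                "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_events": n,
            }
        )
    return pd.DataFrame(rows)
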