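"""Shared fixtures: hand-built tables, tiny graphs, and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fategnn import cli_io, track_graph as tg


@pytest.fixture(scope="session")
def fixture_tables(tmp_path_factory):
    """The committed hand-built 4-frame, 12-cell fixture (one Div, one Del)."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = cli_io.make_fixtures(out)
    return cli_io.read_track_table(paths["track"]), cli_io.read_contact_table(paths["contacts"])


@pytest.fixture(scope="session")
def fixture_graph(fixture_tables):
    track, contacts = fixture_tables
    g = tg.build_graph(track, contacts)
    tg.set_nfb(g)
    tg.add_random_feature(g, seed=42)
    fc = tg.FeatureConfig(seed=42)
    tg.normalize_features([g], fc)
    tg.apply_feature_config(g, fc)
    return g


def two_frame_tables(rows, contacts=()):
    """Helper to build minimal track/contact DataFrames from tuples
    (frame, cell_id, parent_id, fate)."""
    track = pd.DataFrame(
        [dict(frame=f, cell_id=c, parent_id=p, fate=fate, area=1.0, g1=0.5) for f, c, p, fate in rows]
    )
    contact = pd.DataFrame(
        [dict(frame=f, cell_id_a=a, cell_id_b=b) for f, a, b in contacts],
        columns=["frame", "cell_id_a", "cell_id_b"],
    )
    return track, contact


@pytest.fixture(scope="session")
def mini_sim():
    """A small seeded simulation shared by fast tests (same density as the
    study conditions, smaller box)."""
    from fategnn import homeostasis_sim as hs

    cfg = hs.SimConfig(
        setup="del_induced_div", seed=5, L=0.4, N0=int(612 * 0.4**2), lam=0.004,
        relax_steps=40, burnin_steps=150, production_steps=200,
    )
    return hs.run(cfg)
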