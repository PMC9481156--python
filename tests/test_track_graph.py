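"""Graph construction, features, windows and subgraph extraction."""

import numpy as np
import pandas as pd
import pytest

from fategnn import track_graph as tg
from conftest import two_frame_tables
from oracles import subgraph_nodes_reachability


class TestBuildGraph:
    def test_two_daughters_derive_division(self):
        track, contacts = two_frame_tables(
            [(0, 1, -1, "DIV"), (1, 2, 1, "CENSOR"), (1, 3, 1, "CENSOR")]
        )
        g = tg.build_graph(track, contacts)
        assert g.nodes[(0, 1)].fate == tg.DIV
        assert g.nodes[(0, 1)].daughters == {(1, 2), (1, 3)}

    def test_disappearing_track_derives_delamination(self):
        track, contacts = two_frame_tables(
            [(0, 1, -1, "DEL"), (0, 2, -1, "NB"), (1, 2, -1, "CENSOR")]
        )
        g = tg.build_graph(track, contacts)
        assert g.nodes[(0, 1)].fate == tg.DEL
        assert len(g.nodes[(0, 1)].daughters) == 0

    def test_fixture_hand_enumeration(self, fixture_tables):
        """10 initial cells over 4 frames with one division and one
        delamination: 10 + 11 + 10 + 10 = 41 nodes, one Div fork, one Del
        terminal, last-frame cells censored."""
        g = tg.build_graph(*fixture_tables)
        assert g.n_nodes == 41
        fates = {k: n.fate for k, n in g.nodes.items()}
        assert fates[(0, 3)] == tg.DIV
        assert fates[(1, 7)] == tg.DEL
        assert all(fates[(3, c)] == tg.CENSORED for c in g.cells_in_frame(3))
        assert sum(f == tg.DIV for f in fates.values()) == 1
        assert sum(f == tg.DEL for f in fates.values()) == 1
        # hand count of contact edges: 13 + 15 + 14 + 14
        assert sum(len(e) for e in g.spatial.values()) == 56

    def test_dangling_parent_raises_with_row(self):
        track, contacts = two_frame_tables([(0, 1, -1, "NB"), (1, 1, -1, "CENSOR"), (1, 9, 7, "CENSOR")])
        with pytest.raises(tg.ValidationError, match="cell_id=9"):
            tg.build_graph(track, contacts)

    def test_more_than_two_daughters_raises(self):
        rows = [(0, 1, -1, "DIV")] + [(1, c, 1, "CENSOR") for c in (2, 3, 4)]
        track, contacts = two_frame_tables(rows)
        with pytest.raises(tg.ValidationError, match=">2 daughters"):
            tg.build_graph(track, contacts)

    def test_contact_referencing_missing_cell_raises(self):
        track, contacts = two_frame_tables(
            [(0, 1, -1, "NB"), (0, 2, -1, "NB"), (1, 1, -1, "CENSOR"), (1, 2, -1, "CENSOR")],
            contacts=[(0, 1, 5)],
        )
        with pytest.raises(tg.ValidationError, match="cell 5"):
            tg.build_graph(track, contacts)

    def test_lineage_is_involution(self, fixture_graph):
        """parent(daughter(x)) = x for every node (checked exhaustively)."""
        for key, node in fixture_graph.nodes.items():
            for d in node.daughters:
                assert fixture_graph.nodes[d].parent == key
            if node.parent is not None:
                assert key in fixture_graph.nodes[node.parent].daughters


class TestContactsFromLabels:
    def test_shared_border_gives_edge(self):
        img = np.zeros((6, 10), dtype=np.int32)
        img[1:6, 1:5] = 1
        img[1:6, 5:9] = 2
        df = tg.contacts_from_labels(img)
        assert {(1, 2)} == set(zip(df.cell_id_a, df.cell_id_b))

    def test_single_pixel_contact_is_not_an_edge(self):
        img = np.zeros((4, 6), dtype=np.int32)
        img[1, 1] = 1
        img[1, 2] = 2  # exactly one adjacent pixel pair
        df = tg.contacts_from_labels(img)
        assert len(df) == 0

    def test_matches_bruteforce_pixel_scan(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 4, size=(12, 12)).astype(np.int64)
        df = tg.contacts_from_labels(img)
        got = set(zip(df.cell_id_a, df.cell_id_b))
        counts = {}
        h, w = img.shape
        for i in range(h):
            for j in range(w):
                for di, dj in ((0, 1), (1, 0)):
                    if i + di < h and j + dj < w:
                        a, b = img[i, j], img[i + di, j + dj]
                        if a and b and a != b:
                            counts[(min(a, b), max(a, b))] = counts.get((min(a, b), max(a, b)), 0) + 1
        expected = {k for k, c in counts.items() if c > 1}
        assert got == expected

    def test_float_image_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            tg.contacts_from_labels(np.zeros((3, 3)))


class TestFeatures:
    def test_nfb_onehot_encoding(self, fixture_graph):
        assert list(fixture_graph.nodes[(0, 3)].features[2:5]) == [0, 0, 1]  # Div
        assert list(fixture_graph.nodes[(1, 7)].features[2:5]) == [0, 1, 0]  # Del
        assert list(fixture_graph.nodes[(0, 1)].features[2:5]) == [1, 0, 0]  # NB

    def test_window_final_frame_nfb_is_null(self, fixture_graph):
        w = tg.extract_windows(fixture_graph, 3)[0]
        for cid in w.cells_in_frame(w.t0):
            assert np.all(w.nodes[(w.t0, cid)].features[2:5] == 0)
        # non-final frames keep the one-hot (sums to 1 for known fates)
        for cid in w.cells_in_frame(0):
            assert w.nodes[(0, cid)].features[2:5].sum() == 1

    def test_normalization_uses_pooled_max(self):
        t1, c1 = two_frame_tables([(0, 1, -1, "NB"), (1, 1, -1, "CENSOR")])
        t2, c2 = two_frame_tables([(0, 1, -1, "NB"), (1, 1, -1, "CENSOR")])
        t1["area"] = [2.0, 4.0]
        t2["area"] = [8.0, 1.0]
        g1, g2 = tg.build_graph(t1, c1), tg.build_graph(t2, c2)
        fc = tg.FeatureConfig(g1=False)
        tg.normalize_features([g1, g2], fc)
        assert fc.maxima["area"] == 8.0
        assert g1.nodes[(0, 1)].features[0] == pytest.approx(0.25)
        assert g2.nodes[(0, 1)].features[0] == pytest.approx(1.0)

    def test_all_zero_active_feature_raises(self):
        t1, c1 = two_frame_tables([(0, 1, -1, "NB"), (1, 1, -1, "CENSOR")])
        t1["g1"] = 0.0
        g = tg.build_graph(t1, c1)
        with pytest.raises(ValueError, match="g1"):
            tg.normalize_features([g], tg.FeatureConfig())

    def test_random_feature_reproducible_in_range_uncorrelated(self):
        rows = [(0, c, -1, "NB") for c in range(1, 600)] + [(1, c, -1, "CENSOR") for c in range(1, 600)]
        track, contacts = two_frame_tables(rows)
        g1 = tg.add_random_feature(tg.build_graph(track, contacts), seed=9)
        g2 = tg.add_random_feature(tg.build_graph(track, contacts), seed=9)
        v1 = np.array([g1.nodes[k].features[5] for k in sorted(g1.nodes)])
        v2 = np.array([g2.nodes[k].features[5] for k in sorted(g2.nodes)])
        np.testing.assert_array_equal(v1, v2)
        assert v1.min() >= 0 and v1.max() <= 1
        # no correlation with fate by construction: NB cells vs censored cells
        fates = np.array([g1.nodes[k].fate == tg.NB for k in sorted(g1.nodes)])
        r = np.corrcoef(v1, fates)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(v1))

    def test_inactive_features_zeroed_dimension_kept(self, fixture_tables):
        g = tg.build_graph(*fixture_tables)
        tg.set_nfb(g)
        tg.apply_feature_config(g, tg.FeatureConfig(area=False, g1=False, nfb=True, random=False))
        node = g.nodes[(0, 3)]
        assert node.features.shape == (6,)
        assert node.features[0] == 0 and node.features[1] == 0 and node.features[5] == 0
        assert node.features[2:5].sum() == 1


class TestWindows:
    def test_window_count_is_frames_minus_nt_plus_one(self):
        rows = [(f, 1, -1, "NB" if f < 14 else "CENSOR") for f in range(15)]
        track, contacts = two_frame_tables(rows)
        g = tg.build_graph(track, contacts)
        assert len(tg.extract_windows(g, 4)) == 12

    def test_nt_larger_than_graph_raises(self, fixture_graph):
        with pytest.raises(ValueError, match="fewer than nt"):
            tg.extract_windows(fixture_graph, 6)
        with pytest.raises(ValueError, match="nt must be >= 2"):
            tg.extract_windows(fixture_graph, 1)

    def test_censored_cells_are_not_targets(self, fixture_graph):
        last = tg.extract_windows(fixture_graph, 3)[-1]
        assert last.targets() == []  # final data frame: all censored

    def test_window_edges_subset_of_graph(self, fixture_graph):
        for w in tg.extract_windows(fixture_graph, 3):
            for f, edges in w.spatial.items():
                assert edges <= fixture_graph.spatial[f]


class TestTargetSubgraph:
    def test_isolated_cell_gives_bare_chain(self):
        rows = [(f, 1, -1, "NB" if f < 2 else "CENSOR") for f in range(3)]
        track, contacts = two_frame_tables(rows)
        g = tg.build_graph(track, contacts)
        w = tg.extract_windows(g, 2)[0]
        sg = tg.extract_target_subgraph(w, (1, 1), ns=1)
        assert sorted(sg.graph.nodes) == [(0, 1), (1, 1)]

    def test_dividing_neighbor_daughters_included(self):
        rows = [
            (0, 1, -1, "NB"), (0, 2, -1, "DIV"),
            (1, 1, -1, "NB"), (1, 3, 2, "CENSOR"), (1, 4, 2, "CENSOR"),
            (2, 1, -1, "CENSOR"), (2, 3, -1, "CENSOR"), (2, 4, -1, "CENSOR"),
        ]
        # make frame-1 rows non-censored where continuation exists
        rows = [(f, c, p, ("NB" if (f, c) in ((1, 1), (1, 3), (1, 4)) else fate)) for f, c, p, fate in rows]
        track, contacts = two_frame_tables(rows, contacts=[(0, 1, 2)])
        g = tg.build_graph(track, contacts)
        w = tg.extract_windows(g, 2)[0]
        sg = tg.extract_target_subgraph(w, (1, 1), ns=1)
        assert {(1, 3), (1, 4)} <= set(sg.graph.nodes)

    @pytest.mark.parametrize("ns", [1, 2])
    def test_matches_reachability_oracle(self, fixture_graph, ns):
        for w in tg.extract_windows(fixture_graph, 3):
            for t in w.targets():
                sg = tg.extract_target_subgraph(w, t, ns=ns)
                assert set(sg.graph.nodes) == subgraph_nodes_reachability(w, t, 3, ns)

    def test_target_outside_frame_zero_raises(self, fixture_graph):
        w = tg.extract_windows(fixture_graph, 3)[0]
        with pytest.raises(ValueError):
            tg.extract_target_subgraph(w, (0, 1), ns=1)

    def test_null_graph_zeroes_features_keeps_topology(self, fixture_graph):
        w = tg.extract_windows(fixture_graph, 3)[0]
        sg = tg.extract_target_subgraph(w, w.targets()[0], ns=1)
        null = tg.null_graph(sg)
        assert set(null.graph.nodes) == set(sg.graph.nodes)
        assert null.graph.spatial == sg.graph.spatial
        assert all(np.all(n.features == 0) for n in null.graph.nodes.values())
        again = tg.null_graph(null)
        assert all(np.all(n.features == 0) for n in again.graph.nodes.values())


def test_tables_roundtrip(fixture_tables):
    track, contacts = fixture_tables
    g = tg.build_graph(track, contacts)
    track2, contacts2 = tg.graph_to_tables(g)
    g2 = tg.build_graph(track2, contacts2)
    assert set(g.nodes) == set(g2.nodes)
    assert {k: n.fate for k, n in g.nodes.items()} == {k: n.fate for k, n in g2.nodes.items()}
    assert g.spatial == g2.spatial
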