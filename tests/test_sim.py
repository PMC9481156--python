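"""Homeostatic-layer simulator: mechanics, fate rules, export, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from fategnn import homeostasis_sim as hs
from fategnn import track_graph as tg


def small_config(**kw):
    defaults = dict(setup="del_induced_div", seed=0, L=0.4, N0=int(612 * 0.4**2), lam=0.004,
                    relax_steps=30, burnin_steps=100, production_steps=100)
    defaults.update(kw)
    return hs.SimConfig(**defaults)


def fresh_state(n, L, seed=0):
    rng = np.random.default_rng(seed)
    return hs.SimState(pos=rng.uniform(0, L, size=(n, 2)), ids=np.arange(n),
                       commit=np.zeros(n, np.int8), tte=np.full(n, np.inf), next_id=n), rng


class TestMechanics:
    def test_pair_force_magnitude_and_cutoff(self):
        cfg = hs.SimConfig(setup="mixed", lam=0.0)
        # half-overlap pair: |r| = 0.0625, K = 9, l = 0.125 -> |F| = 0.5625
        pos = np.array([[0.5, 0.5], [0.5625, 0.5]])
        f = hs.pair_forces(pos, cfg)
        assert np.linalg.norm(f[0]) == pytest.approx(0.5625, rel=1e-12)
        assert f[0][0] < 0  # directed away from the other particle
        np.testing.assert_allclose(f[0], -f[1], atol=1e-14)  # action = -reaction
        # exactly at the cutoff: zero force
        pos = np.array([[0.5, 0.5], [0.625, 0.5]])
        assert np.all(hs.pair_forces(pos, cfg) == 0)

    def test_forces_match_naive_pair_sum(self):
        cfg = hs.SimConfig(setup="mixed", lam=0.0)
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 1, size=(30, 2))
        f = hs.pair_forces(pos, cfg)
        naive = np.zeros_like(pos)
        for a in range(30):
            for b in range(30):
                if a == b:
                    continue
                d = pos[a] - pos[b]
                d -= cfg.L * np.round(d / cfg.L)
                r = np.hypot(*d)
                if r < cfg.l:
                    naive[a] += cfg.K * (cfg.l - r) * d / r
        np.testing.assert_allclose(f, naive, atol=1e-10)

    def test_single_particle_stationary(self):
        cfg = small_config(lam=0.0)
        state, rng = fresh_state(1, cfg.L)
        before = state.pos.copy()
        hs.euler_step(state, cfg, rng)
        np.testing.assert_array_equal(state.pos, before)

    def test_overlapping_pair_separates(self):
        cfg = hs.SimConfig(setup="mixed", lam=0.0)
        state, rng = fresh_state(2, cfg.L)
        state.pos = np.array([[0.5, 0.5], [0.53, 0.5]])
        d0 = 0.03
        hs.euler_step(state, cfg, rng)
        d = state.pos[0] - state.pos[1]
        d -= cfg.L * np.round(d / cfg.L)
        assert np.hypot(*d) > d0

    def test_potential_energy_nonincreasing_over_50_steps(self):
        cfg = small_config(lam=0.0)
        state, rng = fresh_state(cfg.N0, cfg.L, seed=4)
        e_prev = hs.potential_energy(state.pos, cfg)
        for _ in range(50):
            hs.euler_step(state, cfg, rng)
            e = hs.potential_energy(state.pos, cfg)
            assert e <= e_prev * (1 + 1e-9)
            e_prev = e


class TestFateRules:
    def test_zero_rate_never_commits(self):
        cfg = small_config(lam=0.0)
        state, rng = fresh_state(50, cfg.L)
        for _ in range(20):
            hs.commit_spontaneous(state, cfg, rng)
        assert np.all(state.commit == 0)

    def test_commitment_frequency_matches_binomial(self):
        cfg = small_config(lam=0.01)
        state, rng = fresh_state(500, cfg.L)
        n_draws, n_commits = 0, 0
        for _ in range(40):
            free = int((state.commit == 0).sum())
            n_draws += free
            hs.commit_spontaneous(state, cfg, rng)
            n_commits = int((state.commit != 0).sum())
        p = cfg.lam * cfg.dt
        sigma = np.sqrt(n_draws * p * (1 - p))
        assert abs(n_commits - n_draws * p) < 3.5 * sigma

    def test_mixed_setup_commits_both_fates_evenly(self):
        cfg = small_config(setup="mixed", N0=2000, lam=0.02, L=1.0)
        state, rng = fresh_state(2000, cfg.L)
        for _ in range(10):
            hs.commit_spontaneous(state, cfg, rng)
        ndiv = int((state.commit == 1).sum())
        ndel = int((state.commit == 2).sum())
        assert ndiv + ndel > 100
        ratio = ndiv / (ndiv + ndel)
        assert ratio == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(ndiv + ndel))

    def test_rate_too_high_for_step_raises(self):
        cfg = small_config(lam=1.0)
        state, rng = fresh_state(5, cfg.L)
        with pytest.raises(ValueError, match="lam"):
            hs.commit_spontaneous(state, cfg, rng)

    def test_delamination_removes_one_and_division_stays_close(self):
        cfg = small_config()
        state, rng = fresh_state(40, cfg.L, seed=2)
        traj = hs.SimTrajectory(config=cfg)
        state.commit[3] = 2  # del
        state.tte[3] = 0.0
        state.spont[3] = True
        n0 = len(state.ids)
        hs.fire_due_events(state, cfg, rng, step=1, trajectory=traj)
        assert len(state.ids) == n0 - 1 + 0  # removed one, induced partner only committed
        state.commit[:] = 0
        state.tte[:] = np.inf
        state.commit[5] = 1  # div
        state.tte[5] = 0.0
        state.spont[5] = True
        parent_pos = state.pos[5].copy()
        hs.fire_due_events(state, cfg, rng, step=2, trajectory=traj)
        assert len(state.ids) == n0  # one removed earlier, one added now
        d = state.pos[-1] - parent_pos
        d -= cfg.L * np.round(d / cfg.L)
        assert np.hypot(*d) <= cfg.d_frac * cfg.L + 1e-12

    def test_induced_partner_is_among_six_nearest_by_bruteforce(self):
        cfg = small_config()
        for seed in range(5):
            state, rng = fresh_state(40, cfg.L, seed=seed)
            traj = hs.SimTrajectory(config=cfg)
            state.commit[0] = 2
            state.tte[0] = 0.0
            state.spont[0] = True
            pos0 = state.pos[0].copy()
            before_ids = state.ids.copy()
            before_pos = state.pos.copy()
            hs.fire_due_events(state, cfg, rng, step=1, trajectory=traj)
            ev = traj.events[-1]
            assert ev["induced"] is not None
            d = before_pos - pos0
            d -= cfg.L * np.round(d / cfg.L)
            dist = np.hypot(d[:, 0], d[:, 1])
            dist[0] = np.inf
            six = set(before_ids[np.argsort(dist)[:6]].tolist())
            assert ev["induced"] in six

    def test_induced_events_do_not_chain(self, mini_sim):
        """Every event pair is (spontaneous, induced): the number of events
        carrying an induced partner equals the number of spontaneous firings."""
        events = mini_sim.events
        spont_types = {"Del"}  # del_induced_div: delaminations are spontaneous
        for ev in events:
            if ev["type"] == "Div":
                # divisions are induced, so they never induce partners
                assert ev["induced"] is None

    def test_induced_partners_never_precommitted(self, mini_sim):
        """A cell already owning a commitment is never chosen as partner: its
        id cannot appear as `induced` between its commitment and firing."""
        pending = {}
        for ev in mini_sim.events:
            if ev["induced"] is not None:
                assert ev["induced"] not in pending
                pending[ev["induced"]] = True
            pending.pop(ev["cell"], None)


class TestRunAndExport:
    def test_zero_rate_conserves_population(self):
        cfg = small_config(lam=0.0, burnin_steps=40, production_steps=40)
        traj = hs.run(cfg)
        assert all(n == cfg.N0 for _, n in traj.population)

    def test_event_count_identity(self, mini_sim):
        ndiv = sum(1 for e in mini_sim.events if e["type"] == "Div")
        ndel = sum(1 for e in mini_sim.events if e["type"] == "Del")
        n_end = len(mini_sim.frames[-1][1])
        assert ndiv - ndel == n_end - mini_sim.config.N0

    def test_paired_rule_balance(self, mini_sim):
        prod = mini_sim.n_events_production
        assert abs(prod["Div"] - prod["Del"]) / max(prod["Del"], 1) < 0.2

    def test_crop_fraction_one_emits_every_particle(self, mini_sim):
        cfg = mini_sim.config
        track, contacts = hs.crop_to_tracktable(
            mini_sim, hs.SimConfig(**{**cfg.__dict__, "crop_fraction": 1.0})
        )
        for k, (_, ids, _) in enumerate(mini_sim.frames):
            assert (track.frame == k).sum() == len(ids)

    def test_delamination_inside_crop_labeled_del(self, mini_sim):
        track, _ = hs.crop_to_tracktable(mini_sim)
        steps = [s for s, _, _ in mini_sim.frames]
        deleted = {
            ev["cell"]
            for ev in mini_sim.events
            if ev["type"] == "Del" and steps[0] < ev["step"] <= steps[-1]
        }
        dels = track[track.fate == "DEL"]
        assert len(dels) > 0
        assert set(dels.cell_id) <= deleted

    def test_export_builds_valid_graph(self, mini_sim):
        track, contacts = hs.crop_to_tracktable(mini_sim)
        g = tg.build_graph(track, contacts)  # raises on any inconsistency
        assert g.n_nodes == len(track)


class TestVoronoi:
    def test_square_has_all_side_edges(self):
        pos = np.array([[0.25, 0.25], [0.75, 0.25], [0.75, 0.75], [0.25, 0.75]])
        pairs = set(map(tuple, hs.voronoi_contacts(pos, 1.0)))
        for e in [(0, 1), (1, 2), (2, 3), (0, 3)]:
            assert e in pairs

    def test_matches_delaunay_oracle(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 1, size=(100, 2))
        got = set(map(tuple, hs.voronoi_contacts(pos, 1.0)))
        # periodic Delaunay via 3x3 tiling
        offsets = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)])
        tiled = (pos[None] + offsets[:, None]).reshape(-1, 2)
        tri = Delaunay(tiled)
        expected = set()
        n = len(pos)
        central = 4 * n
        for simplex in tri.simplices:
            for i in range(3):
                for j in range(i + 1, 3):
                    a, b = simplex[i], simplex[j]
                    if (central <= a < central + n) or (central <= b < central + n):
                        x, y = a % n, b % n
                        if x != y:
                            expected.add((min(x, y), max(x, y)))
        assert got == expected

    def test_dense_configuration_min_degree(self, mini_sim):
        _, ids, pos = mini_sim.frames[-1]
        pairs = hs.voronoi_contacts(pos, mini_sim.config.L)
        deg = np.bincount(pairs.ravel(), minlength=len(ids))
        assert deg.min() >= 3

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            hs.voronoi_contacts(np.array([[0.1, 0.1], [0.2, 0.2]]), 1.0)


class TestCalibration:
    def test_invalid_target_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            hs.calibrate_rate(cfg, 0.0)
        with pytest.raises(ValueError):
            hs.calibrate_rate(cfg, 0.6)

    def test_event_fraction_increases_with_rate(self):
        """Doubling the commitment rate increases the measured per-fate
        event fraction (monotonicity of the calibration objective)."""
        results = []
        for lam in (0.002, 0.008):
            cfg = small_config(lam=lam, seed=3, burnin_steps=80, production_steps=80)
            traj = hs.run(cfg)
            nf = cfg.production_steps / cfg.sample_stride
            pop = np.mean([n for s, n in traj.population if s > cfg.burnin_steps])
            results.append(0.5 * sum(traj.n_events_production.values()) / (nf * pop))
        assert results[1] > results[0]
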