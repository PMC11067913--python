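"""Forward simulator: trees, histories, event logs and the backbone fixture."""

import collections
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import chisquare

from biogeodec import (
    ModelFamily,
    ModelParams,
    RangeState,
    build_clado_table,
    build_state_space,
    prune_likelihood,
    simulate_history,
    simulate_tree,
    replay_event_log,
)
from biogeodec.inference import constraint_masks
from biogeodec.io import read_geography, read_tree
from biogeodec.synthetic_data import SimConfig, draw_clado_event, make_fixture


class TestYuleTrees:
    def test_tip_count_and_ultrametric(self):
        for seed in range(20):
            tree = simulate_tree(7, 1.0, seed=seed)
            assert tree.n_tips == 7
            depths = tree.node_depths()
            tip_depths = [depths[i] for i in range(tree.n_nodes) if tree.is_tip(i)]
            assert max(tip_depths) - min(tip_depths) < 1e-9

    def test_deterministic_given_seed(self):
        a = simulate_tree(9, 0.5, seed=42).to_newick()
        b = simulate_tree(9, 0.5, seed=42).to_newick()
        assert a == b
        c = simulate_tree(9, 0.5, seed=43).to_newick()
        assert a != c

    def test_two_tip_tree(self):
        tree = simulate_tree(2, 1.0, seed=1)
        assert tree.n_tips == 2 and tree.n_nodes == 3
        assert all(t >= 0 for t in tree.lengths)


def config(seed=0, **kw):
    defaults = dict(
        n_tips=10,
        n_areas=3,
        max_range_size=3,
        model=ModelFamily("DEC", True),
        params=ModelParams(d=0.02, e=0.005, j=0.1),
        birth_rate=0.2,
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateHistory:
    def test_frozen_process_copies_root_range(self):
        cfg = config(
            model=ModelFamily("DEC", False),
            params=ModelParams(0, 0, 0),
            root_range=RangeState(0b001),
        )
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        out = simulate_history(tree, cfg)
        assert all(r == RangeState(0b001) for r in out.tips.values())
        assert all(e.type == "sympatry" for e in out.event_log)

    def test_jumps_without_dispersal_keep_singleton_ranges(self):
        cfg = config(
            params=ModelParams(d=0, e=0, j=0.5), root_range=RangeState(0b001)
        )
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        out = simulate_history(tree, cfg)
        assert all(r.size == 1 for r in out.tips.values())

    def test_deterministic_given_seed(self):
        cfg = config(seed=5)
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        a = simulate_history(tree, cfg)
        b = simulate_history(tree, cfg)
        assert a.tips == b.tips
        assert a.event_log == b.event_log
        assert a.true_states == b.true_states

    def test_no_null_tips_and_rejection_reported(self):
        cfg = config(seed=2, params=ModelParams(d=0.01, e=0.05, j=0.0),
                     model=ModelFamily("DEC", False))
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        out = simulate_history(tree, cfg)
        assert all(not r.is_null for r in out.tips.values())
        assert out.n_rejections >= 0

    def test_rejection_budget_exhaustion_signalled(self):
        cfg = config(
            seed=1,
            params=ModelParams(d=0.0, e=5.0, j=0.0),
            model=ModelFamily("DEC", False),
            birth_rate=0.05,
            max_rejections=3,
        )
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        with pytest.raises(RuntimeError, match="extirpation"):
            simulate_history(tree, cfg)

    @pytest.mark.parametrize("seed", range(100))
    def test_event_log_replay_reproduces_all_states(self, seed):
        cfg = config(seed=seed, n_tips=6)
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        out = simulate_history(tree, cfg)
        replayed = replay_event_log(tree, out.event_log, cfg.state_space())
        assert replayed == out.true_states

    def test_simulated_data_has_finite_likelihood_at_true_params(self):
        cfg = config(seed=3)
        tree = simulate_tree(cfg.n_tips, cfg.birth_rate, cfg.seed)
        out = simulate_history(tree, cfg)
        space = cfg.state_space()
        lnL = prune_likelihood(
            tree, out.tips, space, cfg.model, cfg.params
        ).lnL
        assert math.isfinite(lnL)


class TestGeneratorCalibration:
    def test_anagenetic_event_rates_match_generator(self):
        """Occupancy-weighted event rates over many long branches converge to
        d x (source areas) per expansion target and e x |R| for contraction,
        within 3 Monte-Carlo standard errors. Extirpation from singleton
        ranges is excluded: it creates a null range, so the simulator's
        rejection step censors those events entirely."""
        d, e = 0.04, 0.01
        cfg = config(
            n_tips=2,
            params=ModelParams(d=d, e=e, j=0.0),
            model=ModelFamily("DEC", False),
            birth_rate=0.02,  # two long branches
            root_range=RangeState(0b111),
            max_rejections=500,
        )
        space = cfg.state_space()
        occupancy = collections.Counter()  # state bits -> total time
        n_disp = collections.Counter()     # state bits -> dispersal count
        n_ext = collections.Counter()
        depth_total = 0.0
        for seed in range(300):
            tree = simulate_tree(2, cfg.birth_rate, seed=seed)
            out = simulate_history(tree, replace(cfg, seed=seed))
            depths = tree.node_depths()
            for branch in (0, 1):  # the two tip branches from the root
                t0, t1 = 0.0, depths[branch]
                state = out.true_states[tree.root]
                # root clado event decides the branch's start state
                root_ev = [r for r in out.event_log if r.node == tree.root][0]
                state = RangeState(
                    root_ev.detail["left" if branch == 0 else "right"]
                )
                t = t0
                for rec in sorted(
                    (r for r in out.event_log
                     if r.node == branch and r.type in ("dispersal", "extirpation")),
                    key=lambda r: r.time,
                ):
                    occupancy[state.bits] += rec.time - t
                    (n_disp if rec.type == "dispersal" else n_ext)[state.bits] += 1
                    state = RangeState(rec.detail["to_state"])
                    t = rec.time
                occupancy[state.bits] += t1 - t
        for bits, time_in_state in occupancy.items():
            if time_in_state < 50 or bits == 0:
                continue
            state = RangeState(bits)
            n_targets = cfg.n_areas - state.size if state.size < cfg.max_range_size else 0
            exp_disp_rate = d * state.size * n_targets
            exp_ext_rate = e * state.size if state.size > 1 else None
            for count, exp_rate in (
                (n_disp[bits], exp_disp_rate),
                (n_ext[bits], exp_ext_rate),
            ):
                if exp_rate is None:
                    continue
                expected = exp_rate * time_in_state
                se = math.sqrt(max(expected, 1.0))
                assert abs(count - expected) <= 3 * se, (
                    f"state {bits:b}: observed {count}, expected {expected:.1f}"
                )

    @pytest.mark.parametrize(
        "model, j",
        [(ModelFamily("DEC", True), 0.3), (ModelFamily("DIVALIKE", True), 0.5)],
    )
    def test_clado_event_frequencies_chi_square(self, model, j):
        """10,000 drawn cladogenetic events fit the table probabilities
        (goodness-of-fit not rejected at alpha = 0.01)."""
        space = build_state_space(4, 3, True)
        table = build_clado_table(model, j, space)
        parent = space.index_of[0b0011]
        events = table.events[parent]
        rng = np.random.default_rng(2024)
        counts = np.zeros(len(events))
        index = {(e.left.bits, e.right.bits, e.type): i for i, e in enumerate(events)}
        for _ in range(10_000):
            ev = draw_clado_event(table, parent, rng)
            counts[index[(ev.left.bits, ev.right.bits, ev.type)]] += 1
        expected = np.array([e.prob for e in events]) * 10_000
        stat, p = chisquare(counts, expected)
        assert p > 0.01


class TestFixtureBundle:
    def test_round_trip_through_io(self, tmp_path):
        cfg = config(seed=7, n_tips=50, n_areas=4, max_range_size=4)
        paths = make_fixture(cfg, tmp_path)
        assert sorted(p.name for p in tmp_path.iterdir()) == sorted(
            ["tree.nwk", "geography.data", "true_states.tsv", "events.tsv",
             "config.json"]
        )
        tree = read_tree(paths["tree"])
        names, tips = read_geography(paths["geography"])
        assert tree.n_tips == 50
        assert len(names) == 4
        assert set(tips) == set(tree.tip_labels())
        header = paths["geography"].read_text().splitlines()[0].split("\t")
        assert header[0] == "50" and header[1] == "4"
        # positive likelihood at the generating parameters
        space = cfg.state_space()
        lnL = prune_likelihood(tree, tips, space, cfg.model, cfg.params).lnL
        assert math.isfinite(lnL)

    def test_idempotent(self, tmp_path):
        cfg = config(seed=8, n_tips=10)
        make_fixture(cfg, tmp_path)
        first = {p.name: p.read_text() for p in tmp_path.iterdir()}
        make_fixture(cfg, tmp_path)
        second = {p.name: p.read_text() for p in tmp_path.iterdir()}
        assert first == second


class TestBackboneFixture:
    def test_four_constraints_all_eurasia_and_resolvable(self, backbone):
        assert len(backbone.constraints) == 4
        for c in backbone.constraints:
            assert c.required_areas == ("Eurasia",)
        masks = constraint_masks(backbone.constraints, backbone.tree, backbone.space)
        assert len(masks) == 4  # four distinct nodes, no resolution errors

    def test_constrained_clades_are_nested_as_named(self, backbone):
        tree = backbone.tree
        node = {c.name: tree.mrca(c.mrca_taxa) for c in backbone.constraints}
        tox = set(tree.subtree_tips(node["Toxicofera"]))
        iguang = set(tree.subtree_tips(node["Iguania+Anguimorpha"]))
        paleo = set(tree.subtree_tips(node["Paleoanguimorpha"]))
        lat = set(tree.subtree_tips(node["Laterata"]))
        assert paleo < iguang < tox
        assert lat.isdisjoint(tox)
        assert "Python_regius" in tox and "Python_regius" not in iguang

    def test_tip_ranges_cover_tree_and_fit_runs(self, backbone):
        assert set(backbone.tip_ranges) == set(backbone.tree.tip_labels())
        lnL = prune_likelihood(
            backbone.tree,
            backbone.tip_ranges,
            backbone.space,
            ModelFamily("DEC", True),
            ModelParams(d=0.005, e=0.001, j=0.05),
            constraints=backbone.constraints,
        ).lnL
        assert math.isfinite(lnL)
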