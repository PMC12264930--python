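"""The four-phase search loop: expansion cap, simulation, stopping, routes."""

from __future__ import annotations

import random

import pytest

from retromcts.core import RetroAction, SearchConfig, SearchState
from retromcts.engine import (
    MCTSSearch,
    extract_routes,
    is_terminal,
    rollout,
    run_search,
    select_leaf,
    simulate,
    state_reward,
)
from retromcts.environments import (
    NullExpansionModel,
    SetStock,
    SyntheticProblemSpec,
    binary_chain_problem,
    generate_problem,
)
from retromcts.policies import SelectionContext
from retromcts.serialize import routes_to_json


def _cfg(**kw):
    kw.setdefault("max_iterations", 50)
    return SearchConfig(**kw)


class TestRunSearchBasics:
    def test_target_already_in_stock(self):
        stock = SetStock(["aspirin"])
        result = run_search("aspirin", NullExpansionModel(), stock, _cfg())
        assert result.solved
        assert len(result.routes) == 1
        assert result.routes[0].n_steps() == 0
        assert result.routes[0].root.in_stock
        assert result.iterations_completed == 0
        assert result.node_count == 1

    def test_no_actions_and_not_in_stock(self):
        result = run_search("orphan", NullExpansionModel(), SetStock(), _cfg())
        assert not result.solved
        assert result.routes == ()

    def test_one_step_solve(self, dict_env):
        env, stock = dict_env(
            {"t": [RetroAction("a0", 0.9, ("p1", "p2"))]}, stock_items=["p1", "p2"]
        )
        result = run_search("t", env, stock, _cfg())
        assert result.solved
        route = result.routes[0]
        assert route.n_steps() == 1
        assert route.reward == 1.0
        assert all(leaf.in_stock for leaf in route.leaves())
        assert result.first_solution_iteration == 1

    def test_iterations_bounded_by_limit(self):
        target, env, stock = generate_problem(SyntheticProblemSpec(seed=5))
        result = run_search(target, env, stock, _cfg(max_iterations=17))
        assert result.iterations_completed <= 17

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            run_search("", NullExpansionModel(), SetStock(), _cfg())


class TestExpansion:
    def _search(self, table, stock_items, **kw):
        stock = SetStock(stock_items)

        class Env:
            def propose(self, state):
                for mol in state.open_molecules:
                    if not stock.contains(mol):
                        return list(table.get(mol, []))
                return []

        return MCTSSearch("t", Env(), stock, _cfg(**kw))

    def test_branching_cap_keeps_highest_priors(self):
        actions = [RetroAction(f"a{i}", (i % 60) / 60.0, (f"p{i}",)) for i in range(60)]
        search = self._search({"t": actions}, [], branching_factor=50)
        search.run()
        children = search.root.children
        assert len(children) == 50
        kept = {c.action_from_parent.action_id for c in children}
        dropped_priors = [a.prior for a in actions if a.action_id not in kept]
        kept_priors = [a.prior for a in actions if a.action_id in kept]
        assert max(dropped_priors) <= min(kept_priors)

    def test_fewer_actions_than_cap(self):
        actions = [RetroAction(f"a{i}", 0.5, (f"p{i}",)) for i in range(3)]
        search = self._search({"t": actions}, [], branching_factor=50)
        search.run()
        assert len(search.root.children) == 3

    def test_equal_priors_preserve_proposal_order(self):
        actions = [RetroAction(f"a{i}", 0.5, (f"p{i}",)) for i in range(8)]
        search = self._search({"t": actions}, [], branching_factor=4)
        search.run()
        ids = [c.action_from_parent.action_id for c in search.root.children]
        assert ids == ["a0", "a1", "a2", "a3"]

    def test_node_count_after_one_root_expansion(self):
        """One expansion of branching B with no deeper growth gives 1 + B
        nodes (children all terminal: precursors in stock)."""
        actions = [RetroAction(f"a{i}", 0.5, ("stocked",)) for i in range(5)]
        search = self._search({"t": actions}, ["stocked"], max_iterations=10)
        result = search.run()
        assert result.node_count == 1 + 5


class TestStateReward:
    def test_fraction_in_stock(self):
        stock = SetStock(["a", "b"])
        state = SearchState(("a", "b", "c", "d"), 2)
        assert state_reward(state, stock) == 0.5

    def test_all_in_stock_is_solved(self):
        stock = SetStock(["a"])
        assert state_reward(SearchState(("a",), 1), stock) == 1.0
        assert state_reward(SearchState((), 1), stock) == 1.0

    def test_none_in_stock(self):
        assert state_reward(SearchState(("x", "y"), 1), SetStock()) == 0.0


class TestIsTerminal:
    def test_solved_state(self, dict_env):
        env, stock = dict_env({}, stock_items=["a"])
        assert is_terminal(SearchState(("a",), 3), stock, env, _cfg()) == (True, "solved")

    def test_depth_limit(self, dict_env):
        env, stock = dict_env({"x": [RetroAction("a", 0.5, ("y",))]})
        cfg = _cfg(max_depth=4)
        assert is_terminal(SearchState(("x",), 4), stock, env, cfg) == (True, "depth")

    def test_no_actions(self, dict_env):
        env, stock = dict_env({})
        assert is_terminal(SearchState(("x",), 1), stock, env, _cfg()) == (
            True,
            "no_actions",
        )

    def test_live_state(self, dict_env):
        env, stock = dict_env({"x": [RetroAction("a", 0.5, ("y",))]})
        assert is_terminal(SearchState(("x",), 2), stock, env, _cfg()) == (False, None)


class TestSimulate:
    def test_value_prior_returns_the_action_prior(self, dict_env, rng):
        env, stock = dict_env({})
        search = MCTSSearch("t", env, stock, _cfg())
        action = RetroAction("a", 0.73, ("p",))
        child = search._make_node(SearchState(("p",), 1), search.root, action)
        assert simulate(child, "value_prior", stock, env, rng) == 0.73

    def test_rollout_from_solved_state_scores_one(self, dict_env, rng):
        env, stock = dict_env({}, stock_items=["p"])
        assert rollout(SearchState(("p",), 2), stock, env, rng, max_depth=7) == 1.0

    def test_rollout_reward_is_end_state_fraction(self, rng):
        target, env, stock = binary_chain_problem(3)
        rewards = {
            rollout(SearchState((target,), 0), stock, env, rng, max_depth=3)
            for _ in range(200)
        }
        assert rewards <= {0.0, 1.0}
        assert rewards == {0.0, 1.0}  # both outcomes occur at p=1/8


class TestSelectLeaf:
    def test_fresh_root_is_its_own_leaf(self, root_node):
        leaf, path = select_leaf(root_node, SelectionContext())
        assert leaf is root_node and path == [root_node]

    def test_single_child_chain(self, root_node, make_child):
        child = make_child(root_node, 0.5, 1)
        leaf, path = select_leaf(root_node, SelectionContext())
        assert leaf is child and path == [root_node, child]

    def test_path_replays_select_child_step_by_step(self):
        target, env, stock = generate_problem(SyntheticProblemSpec(seed=2, B0=6))
        search = MCTSSearch(target, env, stock, _cfg(max_iterations=30))
        search.run()
        ctx = SelectionContext.from_config(search.config, 0.5)
        leaf, path = select_leaf(search.root, ctx)
        node = search.root
        from retromcts.policies import select_child

        expected = [node]
        while node.expanded and node.children:
            node = select_child(node, ctx)
            expected.append(node)
        assert path == expected and leaf is expected[-1]


class TestRouteExtraction:
    def test_no_solved_nodes_gives_no_routes(self, root_node):
        assert extract_routes(root_node, 5) == ()

    def test_truncation_and_ordering(self):
        spec = SyntheticProblemSpec(seed=9)
        target, env, stock = generate_problem(spec)
        search = MCTSSearch(target, env, stock, _cfg(max_iterations=150, max_routes=5))
        result = search.run()
        assert result.solved
        assert len(result.routes) == 5
        all_routes = extract_routes(search.root, 10_000)
        rewards = [r.reward for r in all_routes]
        assert rewards == sorted(rewards, reverse=True)
        assert list(result.routes) == list(all_routes[:5])

    def test_routes_deduplicated_by_step_multiset(self):
        spec = SyntheticProblemSpec(seed=9)
        target, env, stock = generate_problem(spec)
        search = MCTSSearch(target, env, stock, _cfg(max_iterations=150))
        search.run()
        routes = extract_routes(search.root, 10_000)
        keys = [r.step_multiset() for r in routes]
        assert len(keys) == len(set(keys))

    def test_solving_routes_have_all_leaves_in_stock(self):
        target, env, stock = generate_problem(SyntheticProblemSpec(seed=4))
        result = run_search(target, env, stock, _cfg(max_iterations=120))
        assert result.solved
        for route in result.routes:
            assert all(leaf.in_stock for leaf in route.leaves())
            assert all(stock.contains(leaf.molecule) for leaf in route.leaves())


class TestDeterminismAndEquivalence:
    def test_same_seed_same_result(self):
        spec = SyntheticProblemSpec(seed=21)

        def once():
            target, env, stock = generate_problem(spec)
            res = run_search(
                target, env, stock, _cfg(max_iterations=80, seed=3, policy="duct")
            )
            return routes_to_json(res.routes), res.iterations_completed, res.node_count

        assert once() == once()

    def test_euct_with_pinned_zero_progress_replays_uct(self):
        """With S_n pinned at 0 the eUCT schedule is inert, so the whole
        trajectory (tree and routes) matches plain UCT with the same seed."""
        spec = SyntheticProblemSpec(seed=13)

        def run_policy(policy):
            target, env, stock = generate_problem(spec)
            cfg = _cfg(
                max_iterations=60,
                seed=7,
                policy=policy,
                progress_override=0.0 if policy == "euct" else None,
            )
            res = run_search(target, env, stock, cfg)
            return (
                routes_to_json(res.routes),
                res.node_count,
                res.iterations_completed,
                res.reward_events,
            )

        assert run_policy("euct") == run_policy("uct")

    def test_rollout_mode_deterministic_under_seed(self):
        spec = SyntheticProblemSpec(seed=5, B0=8, branching_decay=1)

        def once():
            target, env, stock = generate_problem(spec)
            cfg = _cfg(
                max_iterations=40, seed=11, simulation_mode="rollout_each_child"
            )
            res = run_search(target, env, stock, cfg)
            return routes_to_json(res.routes), res.node_count

        assert once() == once()


class TestConservationDuringSearch:
    def test_root_visits_equal_net_reward_events(self):
        target, env, stock = generate_problem(SyntheticProblemSpec(seed=30))
        search = MCTSSearch(target, env, stock, _cfg(max_iterations=60))
        result = search.run()
        assert search.root.n == result.reward_events

    def test_exhausted_tree_stops_early(self, dict_env):
        env, stock = dict_env({"t": [RetroAction("a0", 0.4, ("dead",))]})
        result = run_search("t", env, stock, _cfg(max_iterations=500))
        assert not result.solved
        assert result.iterations_completed < 500
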