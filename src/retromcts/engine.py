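"""The four-phase MCTS loop: selection, expansion, simulation, backpropagation.

One iteration is one descent from the root.  If the descent ends at an
unexpanded non-terminal node, that node is expanded (querying the expansion
model, keeping the top-B actions by prior), every new child is simulated for
a reward in [0, 1], and each child's reward event is backpropagated to the
root.  If the descent ends at a terminal node (solved, out of depth, or no
actions), its end-state reward is credited again along the path — a cheap
iteration that reinforces or discourages the line.

Two simulation modes are supported.  ``value_prior`` (default) takes the
child's action prior as its reward with no rollout, matching engines whose
value network scores nodes regardless of visits.  ``rollout_each_child``
performs the textbook random descent, sampling actions in proportion to
their priors until a terminal state, and rewards the end state.

Every new child receives exactly one reward event at expansion (a virtual
first visit), so visit counts are >= 1 before any selection and the UCT
equations never divide by zero.  When the child is itself later expanded,
that provisional prior-based event is retracted and replaced by its
children's simulation events, keeping the conservation law
``n == sum(child.n)``, ``W == sum(child.W)`` exact at every expanded node.

Besides wall-clock time the engine counts deterministic *work units*
(selected path length plus children created, per iteration), so benchmark
outputs can be byte-reproducible; see docs/methods.md.
"""

from __future__ import annotations

import random
import time
from typing import Optional

from .core import (
    MoleculeRef,
    RetroAction,
    Route,
    RouteNode,
    SearchConfig,
    SearchResult,
    SearchState,
    TreeNode,
    backpropagate,
    node_count,
    retract,
)
from .environments import ExpansionModel, StockChecker
from .policies import SelectionContext, progress_fraction, select_child

__all__ = [
    "MCTSSearch",
    "run_search",
    "select_leaf",
    "expand",
    "simulate",
    "rollout",
    "state_reward",
    "is_terminal",
    "extract_routes",
]


def state_reward(state: SearchState, stock: StockChecker) -> float:
    """Fraction of open molecules in stock; 1.0 for an empty open set."""
    if not state.open_molecules:
        return 1.0
    in_stock = sum(stock.contains(m) for m in state.open_molecules)
    return in_stock / len(state.open_molecules)


def is_terminal(
    state: SearchState,
    stock: StockChecker,
    env: ExpansionModel,
    config: SearchConfig,
) -> tuple[bool, Optional[str]]:
    """Terminal iff solved, at the depth limit, or without any actions.

    Returns (flag, reason) with reason one of "solved", "depth",
    "no_actions", or None when not terminal.  Querying the expansion model
    is the last resort; the engine itself defers that check to expansion.
    """
    if all(stock.contains(m) for m in state.open_molecules):
        return True, "solved"
    if state.depth >= config.max_depth:
        return True, "depth"
    if not env.propose(state):
        return True, "no_actions"
    return False, None


def select_leaf(
    root: TreeNode, ctx: SelectionContext
) -> tuple[TreeNode, list[TreeNode]]:
    """Descend from the root via select_child until an unexpanded or
    terminal node; returns the node and the root-to-node path."""
    node = root
    path = [node]
    while node.expanded and node.children:
        node = select_child(node, ctx)
        path.append(node)
    return node, path


def rollout(
    state: SearchState,
    stock: StockChecker,
    env: ExpansionModel,
    rng: random.Random,
    max_depth: int,
    choice: str = "prior",
) -> float:
    """Random descent to a terminal state; reward = end-state reward.

    Actions are sampled in proportion to their priors (``choice="prior"``)
    or uniformly (``choice="uniform"``).
    """
    while True:
        if all(stock.contains(m) for m in state.open_molecules):
            return 1.0
        if state.depth >= max_depth:
            return state_reward(state, stock)
        actions = env.propose(state)
        if not actions:
            return state_reward(state, stock)
        if choice == "uniform":
            action = rng.choice(actions)
        else:
            total = sum(a.prior for a in actions)
            if total <= 0.0:
                action = rng.choice(actions)
            else:
                pick = rng.random() * total
                acc = 0.0
                action = actions[-1]
                for a in actions:
                    acc += a.prior
                    if pick < acc:
                        action = a
                        break
        focus = next(
            i for i, m in enumerate(state.open_molecules) if not stock.contains(m)
        )
        state = state.apply(focus, action)


def simulate(
    child: TreeNode,
    mode: str,
    stock: StockChecker,
    env: ExpansionModel,
    rng: random.Random,
    max_depth: int = 7,
    rollout_choice: str = "prior",
) -> float:
    """Reward for a newly created child.

    ``value_prior``: the child's action prior, with no rollout.
    ``rollout_each_child``: a random descent from the child's state.
    """
    if mode == "value_prior":
        return child.action_from_parent.prior
    if mode == "rollout_each_child":
        return rollout(child.state, stock, env, rng, max_depth, rollout_choice)
    raise ValueError(f"unknown simulation mode {mode!r}")


class MCTSSearch:
    """One search instance; exposes the tree for inspection after running.

    Deterministic given (target, environment, stock, config.seed): two runs
    with identical inputs produce identical trees and results (wall-clock
    fields aside).
    """

    def __init__(
        self,
        target: MoleculeRef,
        env: ExpansionModel,
        stock: StockChecker,
        config: SearchConfig,
    ) -> None:
        if not target:
            raise ValueError("target must be a non-empty identifier")
        self.env = env
        self.stock = stock
        self.config = config
        self.rng = random.Random(config.seed)
        self._node_counter = 0
        self.reward_events = 0
        self.work_units = 0
        self.iterations_completed = 0
        self.first_solution_iteration: Optional[int] = None
        self._expandable = 0
        self._solved_leaves: list[TreeNode] = []
        self.root = self._make_node(SearchState((target,), 0), None, None)
        self.elapsed_seconds = 0.0

    # -- node lifecycle ----------------------------------------------------

    def _make_node(
        self,
        state: SearchState,
        parent: Optional[TreeNode],
        action: Optional[RetroAction],
    ) -> TreeNode:
        flags = tuple(self.stock.contains(m) for m in state.open_molecules)
        node = TreeNode(state, parent, action, flags, self._node_counter)
        self._node_counter += 1
        if node.solved:
            node.terminal = True
            node.terminal_reason = "solved"
            self._solved_leaves.append(node)
            if self.first_solution_iteration is None:
                self.first_solution_iteration = self.iterations_completed
        elif state.depth >= self.config.max_depth:
            node.terminal = True
            node.terminal_reason = "depth"
        else:
            self._expandable += 1
        return node

    def _expand(self, node: TreeNode) -> list[TreeNode]:
        """Expansion with the branching cap: keep the top-B actions by prior
        (stable, proposal order breaks ties); children keep proposal order."""
        assert not node.expanded and not node.terminal
        self._expandable -= 1
        actions = self.env.propose(node.state)
        if not actions:
            node.terminal = True
            node.terminal_reason = "no_actions"
            return []
        B = self.config.branching_factor
        if len(actions) > B:
            keep = sorted(
                sorted(range(len(actions)), key=lambda i: -actions[i].prior)[:B]
            )
            actions = [actions[i] for i in keep]
        focus = node.focus_index()
        node.expanded = True
        children = []
        for action in actions:
            child = self._make_node(node.state.apply(focus, action), node, action)
            node.children.append(child)
            children.append(child)
        return children

    def _credit(self, node: TreeNode, reward: float) -> None:
        backpropagate([(node, reward)])
        self.reward_events += 1

    # -- main loop -----------------------------------------------------------

    def _progress(self, elapsed: float) -> float:
        if self.config.progress_override is not None:
            return self.config.progress_override
        return progress_fraction(
            self.iterations_completed,
            self.config.max_iterations,
            elapsed,
            self.config.time_limit_seconds,
        )

    def run(self) -> SearchResult:
        cfg = self.config
        start = time.perf_counter()
        if not self.root.solved:
            while True:
                elapsed = time.perf_counter() - start
                if cfg.max_iterations is not None and (
                    self.iterations_completed >= cfg.max_iterations
                ):
                    break
                if cfg.time_limit_seconds is not None and (
                    elapsed >= cfg.time_limit_seconds
                ):
                    break
                if self._expandable == 0:
                    break  # no expandable nodes remain
                ctx = SelectionContext.from_config(cfg, self._progress(elapsed))
                leaf, path = select_leaf(self.root, ctx)
                self.iterations_completed += 1
                self.work_units += len(path)
                if leaf.terminal:
                    self._credit(leaf, state_reward(leaf.state, self.stock))
                else:
                    children = self._expand(leaf)
                    self.work_units += len(children)
                    if not children:
                        # Zero actions: the node turns terminal and this
                        # iteration's reward event is its own state reward.
                        self._credit(leaf, state_reward(leaf.state, self.stock))
                    else:
                        for child in children:
                            reward = simulate(
                                child,
                                cfg.simulation_mode,
                                self.stock,
                                self.env,
                                self.rng,
                                cfg.max_depth,
                                cfg.rollout_choice,
                            )
                            child.provisional_reward = reward
                            self._credit(child, reward)
                        if leaf.provisional_reward is not None:
                            retract(leaf, leaf.provisional_reward)
                            self.reward_events -= 1
                            leaf.provisional_reward = None
        self.elapsed_seconds = time.perf_counter() - start
        routes = extract_routes(self.root, cfg.max_routes)
        return SearchResult(
            solved=bool(routes),
            routes=routes,
            iterations_completed=self.iterations_completed,
            elapsed_seconds=self.elapsed_seconds,
            node_count=node_count(self.root),
            first_solution_iteration=(
                self.first_solution_iteration if routes else None
            ),
            work_units=self.work_units,
            reward_events=self.reward_events,
        )


def run_search(
    target: MoleculeRef,
    env: ExpansionModel,
    stock: StockChecker,
    config: SearchConfig,
) -> SearchResult:
    """Run one retrosynthesis search; see :class:`MCTSSearch`."""
    return MCTSSearch(target, env, stock, config).run()


# ---------------------------------------------------------------------------
# Route extraction


def _route_from_leaf(leaf: TreeNode) -> Route:
    """Replay the root-to-leaf action sequence into a route tree."""
    path: list[TreeNode] = []
    node: Optional[TreeNode] = leaf
    while node is not None:
        path.append(node)
        node = node.parent
    path.reverse()
    root_node = path[0]

    # Mutable builders mirroring the open-molecule list at each step.
    def builder(mol: MoleculeRef) -> dict:
        return {"molecule": mol, "action_id": None, "children": []}

    root_b = builder(root_node.state.open_molecules[0])
    opens: list[dict] = [root_b]
    for parent, child in zip(path, path[1:]):
        focus = parent.focus_index()
        action = child.action_from_parent
        prec_builders = [builder(m) for m in action.precursors]
        opens[focus]["action_id"] = action.action_id
        opens[focus]["children"] = prec_builders
        opens[focus : focus + 1] = prec_builders

    leaf_flags = dict(zip(leaf.state.open_molecules, leaf.in_stock_flags))

    def freeze(b: dict) -> RouteNode:
        if b["children"]:
            return RouteNode(
                b["molecule"],
                False,
                b["action_id"],
                tuple(freeze(c) for c in b["children"]),
            )
        return RouteNode(b["molecule"], leaf_flags.get(b["molecule"], False))

    return Route(freeze(root_b), state_reward_from_flags(leaf.in_stock_flags))


def state_reward_from_flags(flags: tuple[bool, ...]) -> float:
    if not flags:
        return 1.0
    return sum(flags) / len(flags)


def extract_routes(tree: TreeNode, max_routes: int) -> tuple[Route, ...]:
    """All distinct root-to-solved-leaf paths as routes, deduplicated by
    their step multiset, sorted best-first (reward, then discovery order)
    and truncated to ``max_routes``."""
    solved: list[TreeNode] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.terminal and node.terminal_reason == "solved":
            solved.append(node)
        stack.extend(node.children)
    solved.sort(key=lambda nd: nd.created_index)
    routes: list[Route] = []
    seen = set()
    for leaf in solved:
        route = _route_from_leaf(leaf)
        key = route.step_multiset()
        if key in seen:
            continue
        seen.add(key)
        routes.append(route)
    routes.sort(key=lambda r: -r.reward)  # stable: discovery order breaks ties
    return tuple(routes[:max_routes])
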