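"""Domain types and search-tree bookkeeping for retrosynthetic MCTS.

A retrosynthesis search works backwards from a target molecule: each
retro-action replaces one unresolved ("open") molecule in a state with the
precursor molecules that would produce it.  A state is *solved* when every
open molecule is a purchasable building block (is in *stock*).

Molecules are opaque identifier strings (in real use, canonical SMILES); the
engine never interprets them — equality is exact string match.  Each tree
node carries the statistics the selection policies read: a cumulative reward
``W`` and a visit count ``n``, with rewards always in ``[0, 1]``.

Statistics obey an exact conservation law: for every expanded node,
``n == sum(child.n)`` and ``W == sum(child.W)``.  Reward events live on the
tree frontier (unexpanded or terminal nodes) and internal-node statistics
are pure sums over their subtree, which makes the bookkeeping testable by
brute-force recomputation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

#: Molecules are opaque identifier strings, compared by exact match.
MoleculeRef = str

_W_TOL = 1e-9


@dataclass(frozen=True)
class RetroAction:
    """One scored single-step disconnection proposed by an expansion model.

    ``prior`` is the expansion model's feasibility score in [0, 1];
    ``precursors`` are the molecules that replace the disconnected one.
    """

    action_id: str
    prior: float
    precursors: tuple[MoleculeRef, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError(f"action prior must be in [0, 1], got {self.prior!r}")
        if not self.precursors:
            raise ValueError("an action must produce at least one precursor")
        if any(not m for m in self.precursors):
            raise ValueError("precursor identifiers must be non-empty")


@dataclass(frozen=True)
class SearchState:
    """An ordered collection of not-yet-resolved molecules plus retro depth.

    The root state has depth 0; applying one action increments depth by
    exactly 1.  Molecules already in stock stay in ``open_molecules`` (they
    are resolved by being purchasable, not by further disconnection).
    """

    open_molecules: tuple[MoleculeRef, ...]
    depth: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if any(not m for m in self.open_molecules):
            raise ValueError("molecule identifiers must be non-empty")

    def apply(self, focus: int, action: RetroAction) -> "SearchState":
        """Replace the open molecule at index ``focus`` with the action's
        precursors (in place, order preserved) and step depth by one."""
        if not 0 <= focus < len(self.open_molecules):
            raise IndexError(f"focus index {focus} out of range")
        opens = (
            self.open_molecules[:focus]
            + action.precursors
            + self.open_molecules[focus + 1 :]
        )
        return SearchState(opens, self.depth + 1)


class TreeNode:
    """A search-tree node with the statistics the selection equations read.

    ``W`` (cumulative reward) and ``n`` (visit count) are running sums in
    double precision.  ``in_stock_flags`` caches stock membership for each
    open molecule, aligned with ``state.open_molecules``.  ``children`` keep
    the order in which actions were proposed (after the branching cap); all
    tie-breaks use this order.
    """

    __slots__ = (
        "state",
        "parent",
        "action_from_parent",
        "children",
        "W",
        "n",
        "expanded",
        "terminal",
        "terminal_reason",
        "in_stock_flags",
        "created_index",
        "provisional_reward",
    )

    def __init__(
        self,
        state: SearchState,
        parent: Optional["TreeNode"] = None,
        action_from_parent: Optional[RetroAction] = None,
        in_stock_flags: tuple[bool, ...] = (),
        created_index: int = 0,
    ) -> None:
        self.state = state
        self.parent = parent
        self.action_from_parent = action_from_parent
        self.children: list[TreeNode] = []
        self.W: float = 0.0
        self.n: int = 0
        self.expanded: bool = False
        self.terminal: bool = False
        self.terminal_reason: Optional[str] = None
        self.in_stock_flags = in_stock_flags
        self.created_index = created_index
        # Reward credited at creation (the "virtual first visit"); retracted
        # when the node is expanded so conservation stays exact.
        self.provisional_reward: Optional[float] = None

    @property
    def mean(self) -> float:
        """Mean observed reward W/n (requires at least one visit)."""
        if self.n == 0:
            raise ValueError("node has no visits")
        return self.W / self.n

    @property
    def solved(self) -> bool:
        """True when every open molecule is in stock (or none remain)."""
        return all(self.in_stock_flags)

    def focus_index(self) -> Optional[int]:
        """Index of the first open molecule not in stock, or None if solved."""
        for i, in_stock in enumerate(self.in_stock_flags):
            if not in_stock:
                return i
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TreeNode(depth={self.state.depth}, n={self.n}, W={self.W:.3f}, "
            f"children={len(self.children)}, terminal={self.terminal})"
        )


def backpropagate(rewards: Iterable[tuple[TreeNode, float]]) -> None:
    """Credit reward events to their bearing nodes and every ancestor.

    Each event adds exactly 1 to ``n`` and the reward value to ``W`` of the
    bearing node and of every node on its path to the root; no other node
    changes.  Rewards outside [0, 1] are a contract violation.
    """
    for node, reward in rewards:
        if not 0.0 <= reward <= 1.0:
            raise ValueError(f"reward must be in [0, 1], got {reward!r}")
        cursor: Optional[TreeNode] = node
        while cursor is not None:
            cursor.n += 1
            cursor.W += reward
            cursor = cursor.parent


def retract(node: TreeNode, reward: float) -> None:
    """Remove one previously credited reward event from ``node`` and all its
    ancestors (used when an expanded node's provisional prior-based event is
    superseded by its children's simulation events)."""
    cursor: Optional[TreeNode] = node
    while cursor is not None:
        cursor.n -= 1
        cursor.W -= reward
        cursor = cursor.parent


def node_count(tree: TreeNode) -> int:
    """Number of nodes reachable from ``tree``, the root included."""
    count = 0
    stack = [tree]
    while stack:
        node = stack.pop()
        count += 1
        stack.extend(node.children)
    return count


def best_child_exploit(node: TreeNode) -> TreeNode:
    """The child maximizing mean reward W/n, ignoring exploration.

    Used for the final recommendation once the search budget is spent.
    Ties go to the lowest child index.
    """
    if not node.expanded or not node.children:
        raise ValueError("best_child_exploit requires an expanded node")
    best = node.children[0]
    best_mean = best.mean
    for child in node.children[1:]:
        m = child.mean
        if m > best_mean:
            best, best_mean = child, m
    return best


def check_conservation(root: TreeNode) -> None:
    """Assert the statistics conservation law over the whole tree.

    Every expanded node must satisfy ``n == sum(child.n)`` exactly and
    ``W == sum(child.W)`` to 1e-9, and every node ``0 <= W <= n``.
    Raises AssertionError on the first violation (diagnostic helper; the
    engine maintains the law by construction).
    """
    stack = [root]
    while stack:
        node = stack.pop()
        if node.n > 0 and not (-_W_TOL <= node.W <= node.n + _W_TOL):
            raise AssertionError(f"reward bound violated at {node!r}")
        if node.expanded:
            if node.n != sum(c.n for c in node.children):
                raise AssertionError(f"visit conservation violated at {node!r}")
            if abs(node.W - sum(c.W for c in node.children)) > _W_TOL:
                raise AssertionError(f"reward conservation violated at {node!r}")
        stack.extend(node.children)


# ---------------------------------------------------------------------------
# Routes


@dataclass(frozen=True)
class RouteNode:
    """One molecule in a route tree; ``action_id``/``children`` are set when
    the molecule was disconnected into precursors."""

    molecule: MoleculeRef
    in_stock: bool
    action_id: Optional[str] = None
    children: tuple["RouteNode", ...] = ()

    def __post_init__(self) -> None:
        if (self.action_id is None) != (len(self.children) == 0):
            raise ValueError("action_id and children must be set together")


@dataclass(frozen=True)
class Route:
    """A root-to-solved-state path rendered as a tree of disconnections.

    A solving route has every leaf in stock.  ``reward`` is the end-state
    reward in [0, 1] (1.0 for a solving route).
    """

    root: RouteNode
    reward: float

    def steps(self) -> tuple[tuple[str, str, tuple[str, ...]], ...]:
        """All (product, action_id, precursors) steps, in preorder."""
        out: list[tuple[str, str, tuple[str, ...]]] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.action_id is not None:
                out.append(
                    (node.molecule, node.action_id, tuple(c.molecule for c in node.children))
                )
                stack.extend(reversed(node.children))
        return tuple(out)

    def step_multiset(self) -> tuple:
        """Canonical dedup key: the sorted multiset of steps."""
        return tuple(sorted(self.steps()))

    def n_steps(self) -> int:
        return len(self.steps())

    def leaves(self) -> tuple[RouteNode, ...]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.children:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return tuple(out)


# ---------------------------------------------------------------------------
# Configuration and results

POLICIES = ("uct", "euct", "duct")
SIMULATION_MODES = ("value_prior", "rollout_each_child")
EXPLORATION_FORMS = ("sqrt", "linear")
DEPTH_CONVENTIONS = ("parent", "child")

#: Default exploration constant for UCT/eUCT; dUCT starts lower.
DEFAULT_C = 2.0
DEFAULT_C_DUCT = 1.5


class ConfigurationError(ValueError):
    """Raised for invalid search configurations."""


@dataclass
class SearchConfig:
    """Search settings.

    ``C`` defaults to 2.0 (the conventional UCT value) and to 1.5 when the
    policy is ``duct``.  ``incr`` is the per-depth increment of the dUCT
    exploration weight (0.7 for the v1 preset, 0.5 for v2).  At least one of
    ``max_iterations`` / ``time_limit_seconds`` must be set.
    """

    policy: str = "uct"
    C: Optional[float] = None
    incr: float = 0.5
    branching_factor: int = 50
    max_iterations: Optional[int] = None
    time_limit_seconds: Optional[float] = None
    max_depth: int = 7
    simulation_mode: str = "value_prior"
    max_routes: int = 100
    seed: int = 0
    exploration_form: str = "sqrt"
    depth_convention: str = "parent"
    rollout_choice: str = "prior"  # or "uniform"
    # Diagnostic hook: pin the search-progress fraction S_n to a constant
    # (e.g. 0.0 to make eUCT reduce exactly to UCT).
    progress_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ConfigurationError(f"unknown policy {self.policy!r}")
        if self.C is None:
            self.C = DEFAULT_C_DUCT if self.policy == "duct" else DEFAULT_C
        if self.C <= 0:
            raise ConfigurationError("C must be > 0")
        if self.incr <= 0:
            raise ConfigurationError("incr must be > 0")
        if self.branching_factor < 1:
            raise ConfigurationError("branching_factor must be a positive integer")
        if self.max_iterations is None and self.time_limit_seconds is None:
            raise ConfigurationError(
                "at least one of max_iterations / time_limit_seconds must be set"
            )
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")
        if self.time_limit_seconds is not None and self.time_limit_seconds <= 0:
            raise ConfigurationError("time_limit_seconds must be positive")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be positive")
        if self.simulation_mode not in SIMULATION_MODES:
            raise ConfigurationError(f"unknown simulation_mode {self.simulation_mode!r}")
        if self.max_routes < 1:
            raise ConfigurationError("max_routes must be positive")
        if self.exploration_form not in EXPLORATION_FORMS:
            raise ConfigurationError(f"unknown exploration_form {self.exploration_form!r}")
        if self.depth_convention not in DEPTH_CONVENTIONS:
            raise ConfigurationError(f"unknown depth_convention {self.depth_convention!r}")
        if self.rollout_choice not in ("prior", "uniform"):
            raise ConfigurationError(f"unknown rollout_choice {self.rollout_choice!r}")
        if self.progress_override is not None and not 0.0 <= self.progress_override <= 1.0:
            raise ConfigurationError("progress_override must be in [0, 1]")

    @classmethod
    def duct_v1(cls, **overrides) -> "SearchConfig":
        """dUCT variant 1: increment 0.7 with a branching factor of 20."""
        base = dict(policy="duct", C=DEFAULT_C_DUCT, incr=0.7, branching_factor=20)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def duct_v2(cls, **overrides) -> "SearchConfig":
        """dUCT variant 2: increment 0.5 with a branching factor of 50."""
        base = dict(policy="duct", C=DEFAULT_C_DUCT, incr=0.5, branching_factor=50)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "SearchConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one search run.

    ``routes`` are best-first and capped at ``max_routes``; ``solved`` is
    true iff at least one route was found.  ``work_units`` is a deterministic
    measure of search effort (see docs/methods.md) used where reproducible
    timing is required; ``elapsed_seconds`` is wall-clock.
    """

    solved: bool
    routes: tuple[Route, ...]
    iterations_completed: int
    elapsed_seconds: float
    node_count: int
    first_solution_iteration: Optional[int]
    work_units: int
    reward_events: int

    def __post_init__(self) -> None:
        if self.solved != bool(self.routes):
            raise ValueError("solved must hold exactly when routes are non-empty")
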