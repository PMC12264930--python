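"""UCT selection-policy variants.

The selection phase of MCTS picks, among a parent's children, the child
maximizing an upper-confidence score that balances the observed mean reward
(exploitation) against a visit-count bonus (exploration):

    UCT_i  = W_i/n_i + C * sqrt(ln(n_k) / n_i)

Two scheduled variants redistribute that balance over the course of a run:

* eUCT scales the exploration constant down with search progress,
  eC = C / (S_n + 1), where S_n in [0, 1] is the fraction of the iteration
  (or time) budget already spent.  Late iterations are thereby spent
  exploiting known-good lines instead of probing rarely visited ones, whose
  chance of reaching a solved leaf shrinks as the budget runs out.

* dUCT scales the exploration weight with tree depth,
  C * incr * D_curr, so that selection is purely exploitative at the root
  (where retrosynthetic branching is largest and priors are trusted to prune
  weak first disconnections) and increasingly explorative near the leaves
  (where fewer disconnections remain and success probability is higher).

All functions require n_i >= 1; the engine guarantees every child one
reward event at expansion, so visit counts never reach selection at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .core import ConfigurationError, SearchConfig, TreeNode

__all__ = [
    "SelectionContext",
    "exploration_term",
    "uct_score",
    "progress_fraction",
    "euct_coefficient",
    "euct_score",
    "duct_score",
    "select_child",
]


def exploration_term(n_i: int, n_k: int, form: str = "sqrt") -> float:
    """Exploration bonus for a child with ``n_i`` visits under a parent with
    ``n_k`` visits.

    The default is the conventional sqrt(ln(n_k)/n_i); ``form="linear"``
    gives the bare ratio ln(n_k)/n_i.  Strictly decreasing in ``n_i`` for
    fixed ``n_k``; zero at n_k = 1.
    """
    if n_i < 1:
        raise ValueError("n_i must be >= 1 (unvisited children never reach selection)")
    if n_k < n_i:
        raise ValueError("parent visits n_k must be >= child visits n_i")
    ratio = math.log(n_k) / n_i
    if form == "sqrt":
        return math.sqrt(ratio)
    if form == "linear":
        return ratio
    raise ValueError(f"unknown exploration form {form!r}")


def uct_score(W_i: float, n_i: int, n_k: int, C: float, form: str = "sqrt") -> float:
    """Plain UCT: mean reward plus C times the exploration bonus."""
    return W_i / n_i + C * exploration_term(n_i, n_k, form)


def progress_fraction(
    iteration: int,
    max_iterations: Optional[int] = None,
    elapsed: float = 0.0,
    time_limit: Optional[float] = None,
) -> float:
    """Search progress S_n in [0, 1].

    Under an iteration limit this is the current iteration number divided by
    the maximum number of iterations; under a pure time limit, elapsed time
    over the limit.  Clipped to [0, 1].
    """
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if max_iterations is not None:
        frac = iteration / max_iterations
    elif time_limit is not None:
        frac = elapsed / time_limit
    else:
        raise ConfigurationError("progress requires an iteration or time limit")
    return min(1.0, max(0.0, frac))


def euct_coefficient(C: float, S_n: float) -> float:
    """Scheduled exploration constant eC = C / (S_n + 1).

    Monotonically non-increasing in S_n; equals C at the start of the search
    and C/2 once the budget is exhausted, so eC always lies in [C/2, C].
    """
    if not 0.0 <= S_n <= 1.0:
        raise ValueError(f"S_n must be in [0, 1], got {S_n!r}")
    return C / (S_n + 1.0)


def euct_score(
    W_i: float, n_i: int, n_k: int, C: float, S_n: float, form: str = "sqrt"
) -> float:
    """eUCT: UCT with C replaced by the progress-scheduled eC."""
    return uct_score(W_i, n_i, n_k, euct_coefficient(C, S_n), form)


def duct_score(
    W_i: float, n_i: int, n_k: int, C: float, incr: float, D_curr: int, form: str = "sqrt"
) -> float:
    """dUCT: exploration weight C * incr * D_curr grows with depth.

    ``D_curr`` is the depth of the node whose children are being compared
    (root = 0), so selection at the root is purely exploitative.
    """
    if D_curr < 0:
        raise ValueError("D_curr must be >= 0")
    return W_i / n_i + C * incr * D_curr * exploration_term(n_i, n_k, form)


@dataclass
class SelectionContext:
    """Everything a selection step needs besides the node itself.

    ``S_n`` is the search-progress fraction (eUCT only); ``eC`` is derived.
    ``depth_convention`` picks what dUCT's D_curr means: the depth of the
    parent at the selection point (default, root = 0) or of the children
    (root children at 1).
    """

    policy: str = "uct"
    C: float = 2.0
    incr: float = 0.5
    S_n: float = 0.0
    exploration_form: str = "sqrt"
    depth_convention: str = "parent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.S_n <= 1.0:
            raise ValueError("S_n must be in [0, 1]")

    @property
    def eC(self) -> float:
        return euct_coefficient(self.C, self.S_n)

    @classmethod
    def from_config(cls, config: SearchConfig, S_n: float = 0.0) -> "SelectionContext":
        return cls(
            policy=config.policy,
            C=config.C,
            incr=config.incr,
            S_n=S_n,
            exploration_form=config.exploration_form,
            depth_convention=config.depth_convention,
        )

    def score(self, W_i: float, n_i: int, n_k: int, D_curr: int) -> float:
        if self.policy == "uct":
            return uct_score(W_i, n_i, n_k, self.C, self.exploration_form)
        if self.policy == "euct":
            return euct_score(W_i, n_i, n_k, self.C, self.S_n, self.exploration_form)
        if self.policy == "duct":
            return duct_score(
                W_i, n_i, n_k, self.C, self.incr, D_curr, self.exploration_form
            )
        raise ValueError(f"unknown policy {self.policy!r}")


def select_child(node: TreeNode, ctx: SelectionContext) -> TreeNode:
    """The child of ``node`` with the maximal policy score; ties go to the
    lowest child index."""
    if not node.expanded or not node.children:
        raise ValueError("select_child requires an expanded node with children")
    if ctx.depth_convention == "parent":
        d_curr = node.state.depth
    else:
        d_curr = node.state.depth + 1
    n_k = node.n
    best = node.children[0]
    best_score = ctx.score(best.W, best.n, n_k, d_curr)
    for child in node.children[1:]:
        s = ctx.score(child.W, child.n, n_k, d_curr)
        if s > best_score:
            best, best_score = child, s
    return best
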