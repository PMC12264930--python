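"""Expansion-model and stock contracts, plus seeded synthetic problems.

The engine only ever talks to two interfaces: an :class:`ExpansionModel`
proposing scored retro-actions for a state, and a :class:`StockChecker`
answering building-block membership.  Any template-based chemistry model can
be plugged in behind these contracts.

The built-in synthetic generator emulates the *structure* of retrosynthesis
search trees without any chemistry: branching is largest at shallow depth
and decays towards the leaves, stock probability rises with depth so that
typical solving routes are four to five steps deep, and per-action prior
scores have configurable fidelity to the true solvability of the subtree
they lead into.

Molecules are opaque synthetic identifier strings.  Problems are generated
lazily and hash-seeded: each molecule identifier embeds its creation depth,
a latent solvable/dead label and its stock flag, and a molecule's proposed
actions are a pure function of (seed, molecule, depth).  A *solvable* label
is a constructive promise — a solvable molecule is either in stock or has at
least one "golden" action whose precursors are all solvable — while *dead*
molecules are never in stock and every one of their actions contains at
least one dead precursor.  The labels therefore decide solvability exactly
(per chain), with no need to materialize the exponential tree.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence, runtime_checkable

from .core import MoleculeRef, RetroAction, SearchState

__all__ = [
    "ExpansionModel",
    "StockChecker",
    "SyntheticProblemSpec",
    "branching_at_depth",
    "p_stock",
    "generate_problem",
    "binary_chain_problem",
    "reference_route_depth",
    "SetStock",
    "NullExpansionModel",
]


@runtime_checkable
class ExpansionModel(Protocol):
    """Proposes an ordered list of scored retro-actions for a state.

    Must be deterministic for a given state; priors lie in [0, 1].  Actions
    apply to the state's first open molecule that is not in stock.
    """

    def propose(self, state: SearchState) -> list[RetroAction]: ...


@runtime_checkable
class StockChecker(Protocol):
    """Answers whether a molecule is a purchasable building block.

    Must be deterministic.  Exact stores have no false positives; bloom
    stores may (see :mod:`retromcts.bloom`), never false negatives.
    """

    def contains(self, molecule: MoleculeRef) -> bool: ...


class SetStock:
    """Exact stock backed by an in-memory set of identifiers."""

    def __init__(self, molecules: Sequence[MoleculeRef] = ()) -> None:
        self._members = frozenset(molecules)

    def contains(self, molecule: MoleculeRef) -> bool:
        return molecule in self._members

    def __len__(self) -> int:
        return len(self._members)


class NullExpansionModel:
    """An expansion model that never proposes anything (every non-stock
    target is immediately terminal)."""

    def propose(self, state: SearchState) -> list[RetroAction]:
        return []


# ---------------------------------------------------------------------------
# Hash plumbing: all synthetic randomness flows through seeded blake2b.

_SEP = "\x1f"


def _digest(*parts: object) -> int:
    data = _SEP.join(str(p) for p in parts).encode("utf-8")
    return int.from_bytes(hashlib.blake2b(data, digest_size=8).digest(), "little")


def _unit(*parts: object) -> float:
    """Deterministic uniform draw in [0, 1)."""
    return _digest(*parts) / 2.0**64


# ---------------------------------------------------------------------------
# Synthetic problem spec


@dataclass(frozen=True)
class SyntheticProblemSpec:
    """Generative parameters for retrosynthesis-like search problems.

    Branching at depth ``t`` is ``max(B0 - branching_decay*t, B_min)`` —
    largest at the root, decaying towards the leaves.  Stock probability for
    solvable molecules rises linearly from ``p_stock_start`` (depth 1) to
    ``p_stock_end`` (depth ``d_max``); with ``p_stock_end = 1.0`` the
    solvable/dead labels are a sharp solvability oracle.  ``prior_fidelity``
    (rho) blends the label-derived true action value with hash noise:
    rho = 1 gives perfect priors, rho = 0 independent noise.

    Defaults emulate the regime the selection enhancements target: root
    branching 50 and typical solving routes four to five steps deep.
    """

    B0: int = 50
    branching_decay: int = 8
    B_min: int = 3
    d_max: int = 7
    precursors_min: int = 1
    precursors_max: int = 2
    p_stock_start: float = 0.1
    p_stock_end: float = 1.0
    offspring_solvable: float = 0.4
    prior_fidelity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B0 < 1 or self.B_min < 1 or self.B_min > self.B0:
            raise ValueError("need 1 <= B_min <= B0")
        if self.branching_decay < 0:
            raise ValueError("branching_decay must be >= 0")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        if not 1 <= self.precursors_min <= self.precursors_max <= 3:
            raise ValueError("precursors per action must satisfy 1 <= min <= max <= 3")
        if not 0.0 <= self.p_stock_start <= self.p_stock_end <= 1.0:
            raise ValueError("stock probabilities must be non-decreasing within [0, 1]")
        if not 0.0 <= self.offspring_solvable <= 1.0:
            raise ValueError("offspring_solvable must be in [0, 1]")
        if not 0.0 <= self.prior_fidelity <= 1.0:
            raise ValueError("prior_fidelity must be in [0, 1]")

    def replace(self, **changes) -> "SyntheticProblemSpec":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticProblemSpec":
        return cls(**data)


def branching_at_depth(spec: SyntheticProblemSpec, depth: int) -> int:
    """Number of actions proposed at ``depth``: max(B0 - decay*depth, B_min),
    non-increasing in depth."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return max(spec.B0 - spec.branching_decay * depth, spec.B_min)


def p_stock(spec: SyntheticProblemSpec, depth: int) -> float:
    """In-stock probability for a solvable molecule created at ``depth``.

    Zero at the root (the target itself is never purchasable), rising
    linearly from ``p_stock_start`` at depth 1 to ``p_stock_end`` at d_max.
    Non-decreasing in depth.
    """
    if depth <= 0:
        return 0.0
    t = min(depth, spec.d_max)
    if spec.d_max == 1:
        return spec.p_stock_end
    frac = (t - 1) / (spec.d_max - 1)
    return spec.p_stock_start + (spec.p_stock_end - spec.p_stock_start) * frac


# Identifier format: "d<depth>.<label><stock>.<tag>" where label is
# 's' (solvable) or 'x' (dead) and stock is '1'/'0'.


def _mol_id(depth: int, solvable: bool, in_stock: bool, tag: str) -> str:
    return f"d{depth}.{'s' if solvable else 'x'}{'1' if in_stock else '0'}.{tag}"


def _parse_mol(molecule: MoleculeRef) -> tuple[int, bool, bool]:
    try:
        d, flags, _tag = molecule.split(".", 2)
        return int(d[1:]), flags[0] == "s", flags[1] == "1"
    except (ValueError, IndexError):
        raise ValueError(f"not a synthetic molecule identifier: {molecule!r}")


class SyntheticStock:
    """Stock oracle for generated problems: membership is encoded in the
    synthetic identifier itself (pure, deterministic, lazily consistent with
    the expansion model that minted the identifier)."""

    def contains(self, molecule: MoleculeRef) -> bool:
        try:
            return _parse_mol(molecule)[2]
        except ValueError:
            return False


class SyntheticExpansionModel:
    """Lazy hash-seeded expansion model for synthetic problems."""

    def __init__(self, spec: SyntheticProblemSpec) -> None:
        self.spec = spec
        self._stock = SyntheticStock()

    def propose(self, state: SearchState) -> list[RetroAction]:
        spec = self.spec
        if state.depth >= spec.d_max:
            return []
        focus = None
        for mol in state.open_molecules:
            if not self._stock.contains(mol):
                focus = mol
                break
        if focus is None:
            return []
        _, solvable, in_stock = _parse_mol(focus)
        if in_stock:
            return []
        child_depth = state.depth + 1
        n_actions = branching_at_depth(spec, state.depth)
        key = (spec.seed, focus, state.depth)
        golden = _digest(*key, "golden") % n_actions if solvable else -1
        p_in = p_stock(spec, child_depth)
        actions: list[RetroAction] = []
        for j in range(n_actions):
            span = spec.precursors_max - spec.precursors_min + 1
            n_prec = spec.precursors_min + _digest(*key, "np", j) % span
            dead_slot = _digest(*key, "dead", j) % n_prec if not solvable else -1
            precursors = []
            n_solv = 0
            for p in range(n_prec):
                if j == golden:
                    child_solv = True
                elif p == dead_slot:
                    child_solv = False
                else:
                    child_solv = _unit(*key, "solv", j, p) < spec.offspring_solvable
                child_stock = child_solv and _unit(*key, "stk", j, p) < p_in
                tag = f"{_digest(*key, 'tag', j, p):016x}"
                precursors.append(_mol_id(child_depth, child_solv, child_stock, tag))
                n_solv += child_solv
            true_value = n_solv / n_prec
            noise = _unit(*key, "prior", j)
            rho = spec.prior_fidelity
            prior = min(1.0, max(0.0, rho * true_value + (1.0 - rho) * noise))
            actions.append(RetroAction(f"a{j}", prior, tuple(precursors)))
        return actions


def generate_problem(
    spec: SyntheticProblemSpec,
) -> tuple[MoleculeRef, SyntheticExpansionModel, SyntheticStock]:
    """Materialize a (target, expansion model, stock) triple from a spec.

    Fully determined by ``spec.seed``; the target is always labelled
    solvable (whether a run actually solves it depends on the stock curve
    and the depth budget)."""
    tag = f"{_digest(spec.seed, 'target'):016x}"
    target = _mol_id(0, True, False, tag)
    return target, SyntheticExpansionModel(spec), SyntheticStock()


def reference_route_depth(spec: SyntheticProblemSpec) -> Optional[int]:
    """Steps taken by the label-guided (golden-action) descent, or None if
    the d_max budget is exceeded before all open molecules reach stock.

    This is the canonical solving route the generator's constructive
    promises guarantee; it is used to characterize typical solution depth.
    """
    target, env, stock = generate_problem(spec)
    state = SearchState((target,), 0)
    while True:
        open_unstocked = [m for m in state.open_molecules if not stock.contains(m)]
        if not open_unstocked:
            return state.depth
        if state.depth >= spec.d_max:
            return None
        actions = env.propose(state)
        if not actions:
            return None
        golden = None
        for action in actions:
            if all(_parse_mol(m)[1] for m in action.precursors):
                golden = action
                break
        if golden is None:
            return None
        focus = next(
            i for i, m in enumerate(state.open_molecules) if not stock.contains(m)
        )
        state = state.apply(focus, golden)


# ---------------------------------------------------------------------------
# Binary-chain thought-experiment problem


class _BinaryChainEnv:
    """Full binary problem of depth d: every state has exactly two
    equal-prior actions, exactly one of which stays on the unique solving
    path; used for the 0.5**(d - n) rollout-success law."""

    def __init__(self, d: int) -> None:
        self.d = d

    def propose(self, state: SearchState) -> list[RetroAction]:
        mol = state.open_molecules[0]
        bits = mol.split(":", 1)[1]
        if len(bits) >= self.d:
            return []
        return [
            RetroAction("a0", 0.5, (f"bc:{bits}0",)),
            RetroAction("a1", 0.5, (f"bc:{bits}1",)),
        ]


class _BinaryChainStock:
    def __init__(self, d: int) -> None:
        self.solution = "bc:" + "1" * d

    def contains(self, molecule: MoleculeRef) -> bool:
        return molecule == self.solution


def binary_chain_problem(
    d: int,
) -> tuple[MoleculeRef, _BinaryChainEnv, _BinaryChainStock]:
    """The binary-tree thought experiment: one successful and one failed
    action at each decision point down to terminal depth ``d``, so a uniform
    random rollout from depth ``n`` succeeds with probability 0.5**(d-n)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return "bc:", _BinaryChainEnv(d), _BinaryChainStock(d)
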