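"""Benchmark metrics and route sustainability scoring.

Benchmark summaries follow the usual retrosynthesis reporting: percentage of
problems solved, routes found per attempted molecule and per solved
molecule, mean search time and iterations, and the rate-correct score

    RCS = (number of solved problems) / (sum of all search times T_i)

which trades off accuracy against speed (solving the same number of
problems in half the time doubles the RCS).

Sustainability scoring works on caller-supplied per-step assessments of six
CHEM21-derived metrics — solvent, temperature, stoichiometry, element
sustainability, atom economy, safety — each flagged on an ordinal scale
from 1 (most sustainable) through 2 (problematic) and 3 (hazardous) to
4 (highly hazardous).  A reaction's overall flag is the weighted median of
its six metric flags under user-chosen slider weights (0-10 each): flags are
sorted ascending carrying their weights, and the first flag whose cumulative
weight reaches half the total weight is returned; equal weights reproduce
the ordinary (lower) median.  A route's total score sums, over the six
metrics, the mean flag across its steps — with per-step flags confined to
1-3 this ranges from 6 (best) to 18.
"""

from __future__ import annotations

from dataclasses import astuple, dataclass
from statistics import fmean
from typing import Sequence, Union

__all__ = [
    "METRIC_NAMES",
    "BenchmarkRecord",
    "BenchmarkSummary",
    "StepAssessment",
    "MetricWeights",
    "summarize",
    "rcs",
    "weighted_median",
    "route_score",
]

#: The six pre-experiment CHEM21-derived metrics, in reporting order.
METRIC_NAMES = (
    "solvent",
    "temperature",
    "stoichiometry",
    "element_sustainability",
    "atom_economy",
    "safety",
)


@dataclass(frozen=True)
class BenchmarkRecord:
    """One problem's outcome: solved flag, route count, search time T_i (in
    seconds or deterministic work units) and iterations."""

    problem_id: str
    solved: bool
    n_routes: int
    T_i: float
    iterations: int

    def __post_init__(self) -> None:
        if self.T_i < 0:
            raise ValueError("search time must be non-negative")
        if self.n_routes < 0 or self.iterations < 0:
            raise ValueError("counts must be non-negative")
        if self.solved and self.n_routes == 0:
            raise ValueError("a solved problem must have at least one route")
        if not self.solved and self.n_routes > 0:
            raise ValueError("an unsolved problem cannot have routes")


@dataclass(frozen=True)
class BenchmarkSummary:
    solve_pct: float
    total_routes: int
    routes_per_molecule: float
    routes_per_solved: float
    mean_time: float
    mean_iterations: float
    rcs: float


def summarize(records: Sequence[BenchmarkRecord]) -> BenchmarkSummary:
    """Aggregate benchmark records.

    ``routes_per_molecule`` averages over all attempted problems;
    ``routes_per_solved`` over solved ones only (0.0 when nothing solved).
    """
    if not records:
        raise ValueError("summarize requires at least one record")
    total = len(records)
    n_solved = sum(r.solved for r in records)
    total_routes = sum(r.n_routes for r in records)
    return BenchmarkSummary(
        solve_pct=100.0 * n_solved / total,
        total_routes=total_routes,
        routes_per_molecule=total_routes / total,
        routes_per_solved=(total_routes / n_solved) if n_solved else 0.0,
        mean_time=fmean(r.T_i for r in records),
        mean_iterations=fmean(r.iterations for r in records),
        rcs=rcs(records),
    )


def rcs(records: Sequence[BenchmarkRecord]) -> float:
    """Rate-correct score: solved count over the summed search times of ALL
    records (solved or not)."""
    total_time = sum(r.T_i for r in records)
    if total_time <= 0:
        raise ValueError("RCS is undefined when the summed search time is zero")
    return sum(r.solved for r in records) / total_time


# ---------------------------------------------------------------------------
# Sustainability


@dataclass(frozen=True)
class StepAssessment:
    """Six ordinal metric flags for one reaction step, each in 1..4
    (1 most sustainable, 4 highly hazardous)."""

    solvent: int
    temperature: int
    stoichiometry: int
    element_sustainability: int
    atom_economy: int
    safety: int

    def __post_init__(self) -> None:
        for name, value in zip(METRIC_NAMES, astuple(self)):
            if value not in (1, 2, 3, 4):
                raise ValueError(f"{name} flag must be in 1..4, got {value!r}")

    def flags(self) -> tuple[int, ...]:
        return astuple(self)


@dataclass(frozen=True)
class MetricWeights:
    """Per-metric slider weights, integers 0..10, not all zero."""

    solvent: int = 5
    temperature: int = 5
    stoichiometry: int = 5
    element_sustainability: int = 5
    atom_economy: int = 5
    safety: int = 5

    def __post_init__(self) -> None:
        values = astuple(self)
        for name, value in zip(METRIC_NAMES, values):
            if not isinstance(value, int) or not 0 <= value <= 10:
                raise ValueError(f"{name} weight must be an integer in 0..10")
        if not any(values):
            raise ValueError("at least one weight must be non-zero")

    def values(self) -> tuple[int, ...]:
        return astuple(self)


_FlagsLike = Union[StepAssessment, Sequence[int]]
_WeightsLike = Union[MetricWeights, Sequence[int]]


def _as_flags(flags: _FlagsLike) -> tuple[int, ...]:
    return flags.flags() if isinstance(flags, StepAssessment) else tuple(flags)


def _as_weights(weights: _WeightsLike) -> tuple[int, ...]:
    return weights.values() if isinstance(weights, MetricWeights) else tuple(weights)


def weighted_median(flags: _FlagsLike, weights: _WeightsLike) -> int:
    """Weighted median of metric flags under slider weights.

    Flags are sorted ascending carrying their weights; the first flag whose
    cumulative weight is greater than or equal to half the total weight is
    returned.  With equal weights this is the ordinary (lower) median.
    """
    values = _as_flags(flags)
    w = _as_weights(weights)
    if len(values) != len(w):
        raise ValueError("flags and weights must have the same length")
    if any(x < 0 for x in w):
        raise ValueError("weights must be non-negative")
    total = sum(w)
    if total == 0:
        raise ValueError("weights must not all be zero")
    half = total / 2.0
    cumulative = 0.0
    for value, weight in sorted(zip(values, w)):
        cumulative += weight
        if cumulative >= half:
            return value
    raise AssertionError("unreachable: cumulative weight never reached half")


def route_score(steps: Sequence[StepAssessment]) -> float:
    """Total route sustainability score: the per-metric mean flag across all
    steps, summed over the six metrics.  Monotone: raising any single flag
    never decreases the score."""
    if not steps:
        raise ValueError("route_score requires at least one step")
    matrix = [step.flags() for step in steps]
    return sum(fmean(col) for col in zip(*matrix))
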