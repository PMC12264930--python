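"""Serialization: route JSON, problem-spec YAML, benchmark CSV.

Routes serialize to the nested molecule/reaction JSON layout used by
retrosynthesis viewers: the target molecule sits at the top, molecule nodes
alternate with reaction nodes, and stock molecules are flagged so a renderer
can mark building blocks.  Key order is stable and the round trip is
lossless.  Floats in CSV output are written with 6 significant digits.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Sequence, Union

import yaml

from .core import Route, RouteNode
from .environments import SyntheticProblemSpec
from .metrics import BenchmarkSummary

__all__ = [
    "route_to_dict",
    "route_from_dict",
    "route_to_json",
    "route_from_json",
    "routes_to_json",
    "routes_from_json",
    "spec_to_yaml",
    "spec_from_yaml",
    "bench_to_csv",
    "SerializationError",
]


class SerializationError(ValueError):
    """Raised when a route payload is malformed."""


def _mol_to_dict(node: RouteNode) -> dict:
    out: dict = {"type": "mol", "id": node.molecule, "in_stock": node.in_stock}
    if node.action_id is not None:
        out["children"] = [
            {
                "type": "reaction",
                "action_id": node.action_id,
                "children": [_mol_to_dict(c) for c in node.children],
            }
        ]
    else:
        out["children"] = []
    return out


def route_to_dict(route: Route) -> dict:
    """Nested mol/reaction object with the target at the top; the route
    reward rides on the top-level molecule node."""
    out = _mol_to_dict(route.root)
    out["reward"] = route.reward
    return out


def _mol_from_dict(data: dict) -> RouteNode:
    try:
        if data["type"] != "mol":
            raise SerializationError(f"expected a mol node, got {data.get('type')!r}")
        children = data.get("children", [])
        if not children:
            return RouteNode(data["id"], bool(data["in_stock"]))
        if len(children) != 1 or children[0].get("type") != "reaction":
            raise SerializationError("a mol node must have exactly one reaction child")
        reaction = children[0]
        precursors = tuple(_mol_from_dict(c) for c in reaction["children"])
        if not precursors:
            raise SerializationError("a reaction node must have precursors")
        return RouteNode(
            data["id"], bool(data["in_stock"]), reaction["action_id"], precursors
        )
    except (KeyError, TypeError) as exc:
        raise SerializationError(f"malformed route payload: {exc}") from exc


def route_from_dict(data: dict) -> Route:
    if "reward" not in data:
        raise SerializationError("route payload is missing its reward")
    return Route(_mol_from_dict(data), float(data["reward"]))


def route_to_json(route: Route, indent: int = 2) -> str:
    return json.dumps(route_to_dict(route), indent=indent)


def route_from_json(text: str) -> Route:
    return route_from_dict(json.loads(text))


def routes_to_json(routes: Sequence[Route], indent: int = 2) -> str:
    return json.dumps([route_to_dict(r) for r in routes], indent=indent)


def routes_from_json(text: str) -> tuple[Route, ...]:
    return tuple(route_from_dict(d) for d in json.loads(text))


# ---------------------------------------------------------------------------
# Problem-spec YAML


def spec_to_yaml(spec: SyntheticProblemSpec) -> str:
    return yaml.safe_dump(spec.to_dict(), sort_keys=False)


def spec_from_yaml(text_or_path: Union[str, Path]) -> SyntheticProblemSpec:
    if isinstance(text_or_path, Path):
        text = text_or_path.read_text()
    else:
        text = text_or_path
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SerializationError("problem spec YAML must be a mapping")
    return SyntheticProblemSpec.from_dict(data)


# ---------------------------------------------------------------------------
# Benchmark CSV

BENCH_COLUMNS = (
    "method",
    "limit",
    "solve_pct",
    "routes_per_molecule",
    "routes_per_solved",
    "avg_time",
    "avg_iterations",
    "rcs",
)


def _fmt(value: float) -> str:
    return format(value, ".6g")


def bench_to_csv(rows: Sequence[tuple[str, str, BenchmarkSummary]]) -> str:
    """Render (method, limit description, summary) rows as CSV text."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(BENCH_COLUMNS)
    for method, limit, summary in rows:
        writer.writerow(
            [
                method,
                limit,
                _fmt(summary.solve_pct),
                _fmt(summary.routes_per_molecule),
                _fmt(summary.routes_per_solved),
                _fmt(summary.mean_time),
                _fmt(summary.mean_iterations),
                _fmt(summary.rcs),
            ]
        )
    return buf.getvalue()
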