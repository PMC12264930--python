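"""Shared fixtures: tiny scripted environments and tree builders."""

from __future__ import annotations

import random

import pytest

from retromcts.core import RetroAction, SearchState, TreeNode
from retromcts.environments import SetStock


class DictEnv:
    """Expansion model scripted from a {molecule: [actions]} table.

    Actions apply to the first open molecule not in stock; states whose
    focus molecule is missing from the table get no actions.
    """

    def __init__(self, table: dict[str, list[RetroAction]], stock: SetStock):
        self.table = table
        self.stock = stock

    def propose(self, state: SearchState) -> list[RetroAction]:
        for mol in state.open_molecules:
            if not self.stock.contains(mol):
                return list(self.table.get(mol, []))
        return []


@pytest.fixture
def dict_env():
    def build(table: dict[str, list[RetroAction]], stock_items=()):
        stock = SetStock(stock_items)
        return DictEnv(table, stock), stock

    return build


@pytest.fixture
def make_child():
    """Attach a child with prescribed statistics to a parent node."""

    def build(parent: TreeNode, W: float, n: int, action_id: str = "a") -> TreeNode:
        action = RetroAction(action_id, 0.5, (f"prec-{len(parent.children)}",))
        child = TreeNode(
            parent.state.apply(0, action),
            parent=parent,
            action_from_parent=action,
            in_stock_flags=(False,),
            created_index=len(parent.children) + 1,
        )
        child.W, child.n = W, n
        parent.children.append(child)
        parent.expanded = True
        parent.n += n
        parent.W += W
        return child

    return build


@pytest.fixture
def root_node():
    return TreeNode(SearchState(("target",), 0), in_stock_flags=(False,))


@pytest.fixture
def rng():
    return random.Random(20240613)
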