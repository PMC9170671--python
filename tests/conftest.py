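"""Shared fixtures and enumeration oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from fcassembly import Item, ItemPool, Block, Questionnaire


def enumerate_matchings(C: np.ndarray, J: int):
    """All ways to form exactly J blocks under pairing matrix C.

    Yields sorted tuples of (i, u) index pairs with i < u; items not in any
    pair are left out.  Exhaustive recursion — use on tiny pools only.
    """
    N = C.shape[0]

    def rec(avail: tuple, blocks_left: int):
        if blocks_left == 0:
            yield ()
            return
        if len(avail) < 2 * blocks_left:
            return
        i, rest = avail[0], avail[1:]
        if len(rest) >= 2 * blocks_left:  # leave item i unselected
            yield from rec(rest, blocks_left)
        for u in rest:
            if C[i, u]:
                rem = tuple(x for x in rest if x != u)
                for m in rec(rem, blocks_left - 1):
                    yield ((i, u),) + m

    yield from rec(tuple(range(N)), J)


def matching_to_questionnaire(pairs, pool: ItemPool) -> Questionnaire:
    return Questionnaire(blocks=[
        Block.from_items(pool.items[i], pool.items[u], pool.D)
        for i, u in pairs])


@pytest.fixture(scope="session")
def pool_n6_d2() -> ItemPool:
    """Six items on two traits (3 + 3): 6 enumerable perfect matchings."""
    rng = np.random.default_rng(42)
    items = [Item(id=k + 1, dim=1 + k // 3,
                  a=float(rng.normal(1.5, 0.5)),
                  b=float(rng.uniform(-2, 2))) for k in range(6)]
    return ItemPool(items, D=2)


@pytest.fixture(scope="session")
def pool_n60_d5() -> ItemPool:
    """Sixty items on five traits (12 each), the smallest study pool size."""
    from fcassembly import generate_item_pool

    return generate_item_pool(5, 60, "positive", np.random.default_rng(42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
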