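"""Shared fixtures and independent oracles.

The oracles deliberately re-derive the Boolean semantics and cycle
enumeration with the most naive possible code (per-gene dict arithmetic,
exhaustive DFS) so that agreement with the package's vectorized/blocked
implementations is informative.
"""

from __future__ import annotations

import numpy as np
import pytest

from stabcore import SignedNetwork


# ---------------------------------------------------------------------------
# naive Boolean semantics


def naive_step(net: SignedNetwork, values: dict[str, int], rule: str = "hold") -> dict[str, int]:
    """Dict-based synchronous step, written straight from the update rule."""
    nxt = {}
    for g in net.nodes:
        acts = [values[a] for a in net.activators(g)]
        inhs = [values[i] for i in net.inhibitors(g)]
        if not acts and not inhs:
            nxt[g] = values[g] if rule == "hold" else 0
            continue
        if acts:
            on = any(v == 1 for v in acts)
        else:
            on = True  # only inhibitors: vacuously activated
        if any(v == 1 for v in inhs):
            on = False
        nxt[g] = int(on)
    return nxt


def code_to_values(net: SignedNetwork, code: int) -> dict[str, int]:
    return {g: (code >> i) & 1 for i, g in enumerate(net.nodes)}


def values_to_code(net: SignedNetwork, values: dict[str, int]) -> int:
    return sum(values[g] << i for i, g in enumerate(net.nodes))


def naive_attractors(net: SignedNetwork, rule: str = "hold"):
    """Attractors from the explicit full transition map: walk every state to
    its cycle; returns {canonical cycle tuple: basin size}."""
    n = len(net.nodes)
    succ = {}
    for code in range(1 << n):
        succ[code] = values_to_code(net, naive_step(net, code_to_values(net, code), rule))
    basins: dict[tuple[int, ...], int] = {}
    for start in range(1 << n):
        seen: dict[int, int] = {}
        trail = []
        code = start
        while code not in seen:
            seen[code] = len(trail)
            trail.append(code)
            code = succ[code]
        cyc = trail[seen[code]:]
        k = cyc.index(min(cyc))
        canon = tuple(cyc[k:] + cyc[:k])
        basins[canon] = basins.get(canon, 0) + 1
    return basins


# ---------------------------------------------------------------------------
# naive cycle enumeration


def naive_simple_cycles(adj: dict[str, set[str]]) -> set[tuple[str, ...]]:
    """All elementary node cycles by DFS from every start, deduplicated by
    canonical rotation."""
    out: set[tuple[str, ...]] = set()

    def dfs(start: str, node: str, path: list[str]) -> None:
        for nb in adj[node]:
            if nb == start:
                k = path.index(min(path))
                out.add(tuple(path[k:] + path[:k]))
            elif nb not in path:
                dfs(start, nb, path + [nb])

    for s in adj:
        dfs(s, s, [s])
    return out


# ---------------------------------------------------------------------------
# random networks


def random_signed_network(
    rng: np.random.Generator, max_nodes: int = 12, max_edges: int = 30
) -> SignedNetwork:
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"g{i:02d}" for i in range(n)]
    m = int(rng.integers(0, max_edges + 1))
    edges = set()
    for _ in range(m):
        s = nodes[int(rng.integers(n))]
        t = nodes[int(rng.integers(n))]
        sign = 1 if rng.random() < 0.5 else -1
        edges.add((s, t, sign))
    return SignedNetwork(nodes, edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
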