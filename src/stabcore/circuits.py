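"""Elementary-circuit enumeration on signed networks.

Elementary circuits (simple directed cycles) are the feedback structures of a
regulatory network; a circuit's sign is the product of its edge signs, and
positive circuits are the topological prerequisite for multistationarity —
the property the contextualization stage tries to preserve while pruning.

Enumeration follows Johnson's algorithm, run on the unsigned support graph
(parallel +/- arcs collapsed); each node cycle is then expanded into one
circuit per combination of available edge signs, so a gene pair connected by
both an activating and an inhibiting arc contributes both a positive and a
negative 2-circuit.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

from .network import SignedNetwork

CIRCUIT_COUNT_WARN = 100_000


@dataclass(frozen=True)
class ElementaryCircuit:
    """A simple directed cycle with per-hop signs.

    ``nodes`` lists the distinct genes traversed, rotated so the first is the
    lexicographically minimal one (canonical representation); hop *i* runs
    from ``nodes[i]`` to ``nodes[(i+1) % len]`` with sign ``edge_signs[i]``.
    A length-1 circuit is a self-loop.
    """

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]

    def __post_init__(self):
        if len(self.nodes) != len(self.edge_signs):
            raise ValueError("one edge sign per hop is required")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("elementary circuit nodes must be distinct")
        if self.nodes and min(self.nodes) != self.nodes[0]:
            raise ValueError("canonical rotation must start at the minimal node")

    @classmethod
    def from_rotation(cls, nodes: Iterable[str], edge_signs: Iterable[int]) -> "ElementaryCircuit":
        """Build from any rotation of the cycle; canonicalizes."""
        nodes = list(nodes)
        signs = list(edge_signs)
        k = nodes.index(min(nodes))
        return cls(tuple(nodes[k:] + nodes[:k]), tuple(signs[k:] + signs[:k]))

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def sign(self) -> int:
        return math.prod(self.edge_signs)

    def edges(self) -> list[tuple[str, str, int]]:
        n = len(self.nodes)
        return [
            (self.nodes[i], self.nodes[(i + 1) % n], self.edge_signs[i]) for i in range(n)
        ]


# ---------------------------------------------------------------------------
# Johnson's algorithm on the unsigned support graph


def _johnson_node_cycles(adj: dict[str, set[str]]) -> Iterator[list[str]]:
    """Yield every elementary node cycle, each starting at its minimal node.

    Classic blocking/unblocking scheme: nodes are processed in lexicographic
    order; for each start s, cycles through s are searched in the strongly
    connected component of the subgraph induced on nodes >= s, with blocked
    nodes released along the B-lists when a cycle is closed.
    """
    order = sorted(adj)
    for idx, s in enumerate(order):
        allowed = set(order[idx:])
        sub = {u: {v for v in adj[u] if v in allowed} for u in allowed}
        # restrict to the SCC containing s — other components cannot close a
        # cycle through s
        g = nx.DiGraph((u, v) for u, vs in sub.items() for v in vs)
        g.add_nodes_from(sub)
        comp = next(c for c in nx.strongly_connected_components(g) if s in c)
        sub = {u: {v for v in sub[u] if v in comp} for u in comp}

        blocked: set[str] = set()
        blist: dict[str, set[str]] = {u: set() for u in comp}
        path: list[str] = []
        cycles: list[list[str]] = []

        def unblock(u: str) -> None:
            stack = [u]
            while stack:
                w = stack.pop()
                if w in blocked:
                    blocked.discard(w)
                    stack.extend(blist[w])
                    blist[w].clear()

        def circuit(v: str) -> bool:
            found = False
            path.append(v)
            blocked.add(v)
            for w in sorted(sub[v]):
                if w == s:
                    cycles.append(list(path))
                    found = True
                elif w not in blocked:
                    if circuit(w):
                        found = True
            if found:
                unblock(v)
            else:
                for w in sub[v]:
                    blist[w].add(v)
            path.pop()
            return found

        circuit(s)
        yield from cycles


def _bounded_node_cycles(adj: dict[str, set[str]], max_len: int) -> Iterator[list[str]]:
    """Plain depth-bounded DFS enumeration (used when max_len is given).

    Johnson's unblocking logic is only correct for unbounded search, so the
    length-capped variant trades its pruning for a simple bounded DFS.
    """
    order = sorted(adj)
    for idx, s in enumerate(order):
        allowed = set(order[idx:])
        stack: list[tuple[str, list[str]]] = [(s, [s])]
        while stack:
            v, path = stack.pop()
            for w in sorted(adj[v], reverse=True):
                if w == s:
                    yield path
                elif w in allowed and w not in path and len(path) < max_len:
                    stack.append((w, path + [w]))


def enumerate_elementary_circuits(
    net: SignedNetwork, max_len: int | None = None
) -> list[ElementaryCircuit]:
    """All elementary circuits of the network, canonically rotated.

    With ``max_len`` set, only circuits of at most that many nodes are
    returned.  When consecutive nodes are linked by parallel arcs of both
    signs, one circuit per sign combination is emitted.  A warning is issued
    past 100 000 circuits (counts grow combinatorially with density).
    """
    adj = net.support_adjacency()
    # self-loops first (Johnson operates on loop-free graphs)
    out: list[ElementaryCircuit] = []
    for g in net.nodes:
        for sign in net.edge_signs(g, g):
            out.append(ElementaryCircuit((g,), (sign,)))
    loopless = {u: {v for v in vs if v != u} for u, vs in adj.items()}

    if max_len is not None:
        if max_len < 1:
            return []
        node_cycles = _bounded_node_cycles(loopless, max_len)
    else:
        node_cycles = _johnson_node_cycles(loopless)

    warned = False
    for cyc in node_cycles:
        n = len(cyc)
        hop_signs = [net.edge_signs(cyc[i], cyc[(i + 1) % n]) for i in range(n)]
        for combo in itertools.product(*hop_signs):
            out.append(ElementaryCircuit.from_rotation(cyc, combo))
            if not warned and len(out) > CIRCUIT_COUNT_WARN:
                warnings.warn(
                    f"more than {CIRCUIT_COUNT_WARN} elementary circuits enumerated; "
                    "consider max_len to cap circuit length",
                    stacklevel=2,
                )
                warned = True
    out.sort(key=lambda c: (c.length, c.nodes, c.edge_signs))
    return out


def positive_circuits(circuits: Iterable[ElementaryCircuit]) -> list[ElementaryCircuit]:
    """Circuits with an even number of inhibiting edges, order preserved."""
    return [c for c in circuits if c.sign == +1]
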