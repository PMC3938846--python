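"""Signed directed regulatory networks.

A :class:`SignedNetwork` is the object every other stage consumes: the prior
interaction network to contextualize, the pruned candidates scored inside the
evolutionary loop, and the final network whose strongly connected components
form the stability core.  Edges carry a sign: ``+1`` for activation, ``-1``
for inhibition.  An activating and an inhibiting edge between the same ordered
gene pair may coexist (databases report both modes for some regulators).

Node order is lexicographic and fixed at construction so that Boolean state
encodings (bit *i* of the integer code is the value of the *i*-th node) are
reproducible across runs.
"""

from __future__ import annotations

from functools import cached_property
from typing import Iterable, Mapping

ACTIVATION = 1
INHIBITION = -1

_SIGN_WORD = {ACTIVATION: "activates", INHIBITION: "inhibits"}
_WORD_SIGN = {"activates": ACTIVATION, "inhibits": INHIBITION}

Edge = tuple[str, str, int]  # (source, target, sign)


def sign_to_word(sign: int) -> str:
    return _SIGN_WORD[sign]


def word_to_sign(word: str) -> int:
    try:
        return _WORD_SIGN[word]
    except KeyError:
        raise ValueError(
            f"unknown relation {word!r}; expected 'activates' or 'inhibits'"
        ) from None


class SignedNetwork:
    """Immutable signed digraph over gene identifiers.

    Parameters
    ----------
    nodes
        Gene identifiers; stored sorted and deduplicated.  May include
        isolated genes with no incident edge.
    edges
        Iterable of ``(source, target, sign)`` with sign in ``{+1, -1}``.
        Duplicate triples collapse to one edge.
    """

    __slots__ = ("nodes", "edges", "__dict__")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = ()):
        node_set = {str(n) for n in nodes}
        edge_set = set()
        for src, tgt, sign in edges:
            if sign not in (ACTIVATION, INHIBITION):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            if src not in node_set:
                raise ValueError(f"edge source {src!r} is not a declared node")
            if tgt not in node_set:
                raise ValueError(f"edge target {tgt!r} is not a declared node")
            edge_set.add((src, tgt, sign))
        self.nodes: tuple[str, ...] = tuple(sorted(node_set))
        self.edges: frozenset[Edge] = frozenset(edge_set)

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()) -> "SignedNetwork":
        """Build a network whose node set is the union of edge endpoints."""
        edges = list(edges)
        nodes = set(extra_nodes)
        for src, tgt, _ in edges:
            nodes.add(src)
            nodes.add(tgt)
        return cls(nodes, edges)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"SignedNetwork({len(self.nodes)} nodes, {len(self.edges)} edges)"

    # -- lookups -----------------------------------------------------------
    @cached_property
    def _index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def index(self, gene: str) -> int:
        """Position of *gene* in the lexicographic node order."""
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not a node of this network") from None

    @cached_property
    def _regulators(self) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
        acts: dict[str, list[str]] = {g: [] for g in self.nodes}
        inhs: dict[str, list[str]] = {g: [] for g in self.nodes}
        for src, tgt, sign in sorted(self.edges):
            (acts if sign == ACTIVATION else inhs)[tgt].append(src)
        return {g: (tuple(acts[g]), tuple(inhs[g])) for g in self.nodes}

    def activators(self, gene: str) -> tuple[str, ...]:
        self.index(gene)
        return self._regulators[gene][0]

    def inhibitors(self, gene: str) -> tuple[str, ...]:
        self.index(gene)
        return self._regulators[gene][1]

    def has_regulators(self, gene: str) -> bool:
        a, i = self._regulators[gene]
        return bool(a or i)

    def out_edges(self, gene: str) -> list[Edge]:
        return sorted(e for e in self.edges if e[0] == gene)

    # -- derived networks --------------------------------------------------
    def subnetwork(self, keep_edges: Iterable[Edge]) -> "SignedNetwork":
        """Same node set, restricted to *keep_edges* (must be a subset)."""
        keep = frozenset(keep_edges)
        extra = keep - self.edges
        if extra:
            raise ValueError(f"edges not present in the network: {sorted(extra)[:3]}")
        return SignedNetwork(self.nodes, keep)

    def support_adjacency(self) -> dict[str, set[str]]:
        """Unsigned adjacency (parallel +/- arcs collapse to one arc)."""
        adj: dict[str, set[str]] = {g: set() for g in self.nodes}
        for src, tgt, _ in self.edges:
            adj[src].add(tgt)
        return adj

    def edge_signs(self, src: str, tgt: str) -> tuple[int, ...]:
        """Signs present on arcs src -> tgt, sorted (inhibition first)."""
        return tuple(sorted(s for a, b, s in self.edges if a == src and b == tgt))
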