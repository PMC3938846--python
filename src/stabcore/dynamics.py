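"""Synchronous Boolean dynamics and exhaustive attractor computation.

Gene states are binary; at every time step all genes update simultaneously
under a logic rule combining each gene's activators and inhibitors.  The
default rule is inhibitor-dominant::

    next(x) = (some activator of x is ON, vacuously true when x has
               inhibitors but no activators)  AND  (no inhibitor of x is ON)

Two conventions for a gene with no regulators at all are provided as update
rules:

``"hold"`` (default)
    An unregulated gene keeps its current value (it behaves as a constant
    input).  This is the convention of the classic synchronous
    attractor-computation scheme.

``"decay"``
    An unregulated gene falls to 0 (expression requires an active
    regulator).  Under this rule deleting a gene's last activator has a
    dynamical consequence, which is what makes network pruning guided by
    stable-state consistency non-degenerate; it is the default inside the
    contextualization stage.

On networks where every gene has at least one regulator the two rules
coincide.

States are encoded as integers: bit *i* holds the value of the *i*-th node
in the network's lexicographic order, so encodings (and hence canonical
attractor representations) are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .network import SignedNetwork

UpdateRule = Literal["hold", "decay"]

UPDATE_RULES = ("hold", "decay")

DEFAULT_MAX_NODES_EXHAUSTIVE = 20


def _check_rule(rule: str) -> None:
    if rule not in UPDATE_RULES:
        raise ValueError(f"unknown update rule {rule!r}; expected one of {UPDATE_RULES}")


@dataclass(frozen=True)
class BooleanState:
    """Total 0/1 assignment over a network's genes.

    ``genes`` is the network's lexicographic node tuple and ``code`` the
    integer encoding (bit i = value of genes[i]).
    """

    genes: tuple[str, ...]
    code: int

    def __post_init__(self):
        if not 0 <= self.code < (1 << len(self.genes)):
            raise ValueError(f"code {self.code} out of range for {len(self.genes)} genes")

    @classmethod
    def from_mapping(cls, net: SignedNetwork, values: Mapping[str, int]) -> "BooleanState":
        unknown = set(values) - set(net.nodes)
        if unknown:
            raise KeyError(f"gene {sorted(unknown)[0]!r} is not a node of the network")
        missing = set(net.nodes) - set(values)
        if missing:
            raise ValueError(f"state is missing genes: {sorted(missing)}")
        code = 0
        for i, g in enumerate(net.nodes):
            v = values[g]
            if v not in (0, 1):
                raise ValueError(f"state value for {g!r} must be 0 or 1, got {v!r}")
            code |= v << i
        return cls(net.nodes, code)

    def __getitem__(self, gene: str) -> int:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} is not part of this state") from None
        return (self.code >> i) & 1

    def as_dict(self) -> dict[str, int]:
        return {g: (self.code >> i) & 1 for i, g in enumerate(self.genes)}

    def bits(self) -> np.ndarray:
        n = len(self.genes)
        return (np.asarray(self.code) >> np.arange(n)) & 1

    def __repr__(self) -> str:
        s = "".join(str((self.code >> i) & 1) for i in range(len(self.genes)))
        return f"BooleanState({s})"


@dataclass(frozen=True)
class PartialState:
    """Partial 0/1 assignment; ``None`` marks an unknown value."""

    values: Mapping[str, int | None]

    def known(self) -> dict[str, int]:
        return {g: v for g, v in self.values.items() if v is not None}

    def unknown_genes(self) -> list[str]:
        return sorted(g for g, v in self.values.items() if v is None)


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length 1) or synchronous cycle of states.

    The representation is canonical: the cycle is rotated so that its first
    state has the minimal integer encoding.  ``basin_size`` (exhaustive mode
    only) counts the states whose trajectory ends in this attractor; it does
    not take part in equality.
    """

    states: tuple[BooleanState, ...]
    basin_size: int | None = field(default=None, compare=False)

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @classmethod
    def from_cycle_codes(
        cls, genes: tuple[str, ...], codes: Iterable[int], basin_size: int | None = None
    ) -> "Attractor":
        codes = list(codes)
        k = codes.index(min(codes))
        rotated = codes[k:] + codes[:k]
        return cls(tuple(BooleanState(genes, c) for c in rotated), basin_size)

    def mean_activity(self) -> np.ndarray:
        """Per-gene time-average of the state values over the cycle."""
        return np.mean([s.bits() for s in self.states], axis=0)


# ---------------------------------------------------------------------------
# update rule


def _masks(net: SignedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Activator and inhibitor bitmasks per node, aligned with node order."""
    n = len(net.nodes)
    act = np.zeros(n, dtype=np.int64)
    inh = np.zeros(n, dtype=np.int64)
    for i, g in enumerate(net.nodes):
        for a in net.activators(g):
            act[i] |= 1 << net.index(a)
        for r in net.inhibitors(g):
            inh[i] |= 1 << net.index(r)
    return act, inh


def _step_codes(codes: np.ndarray, act: np.ndarray, inh: np.ndarray, rule: str) -> np.ndarray:
    """Vectorized synchronous step on an array of integer state codes."""
    nxt = np.zeros_like(codes)
    for i in range(len(act)):
        a, r = act[i], inh[i]
        if a == 0 and r == 0:
            bit = ((codes >> i) & 1).astype(bool) if rule == "hold" else np.zeros(len(codes), bool)
        else:
            free = (codes & r) == 0
            bit = (((codes & a) != 0) & free) if a else free
        nxt |= bit.astype(codes.dtype) << i
    return nxt


def synchronous_step(
    net: SignedNetwork, state: BooleanState, rule: UpdateRule = "hold"
) -> BooleanState:
    """Advance *state* one synchronous update of every gene."""
    _check_rule(rule)
    if state.genes != net.nodes:
        extra = set(state.genes) - set(net.nodes)
        if extra:
            raise KeyError(f"gene {sorted(extra)[0]!r} in state is not a network node")
        raise ValueError("state genes do not match network nodes")
    act, inh = _masks(net)
    code = int(_step_codes(np.array([state.code], dtype=np.int64), act, inh, rule)[0])
    return BooleanState(net.nodes, code)


def successor_table(net: SignedNetwork, rule: UpdateRule = "hold") -> np.ndarray:
    """Successor code of every state, indexed by state code (2**n entries)."""
    _check_rule(rule)
    n = len(net.nodes)
    codes = np.arange(1 << n, dtype=np.int64)
    act, inh = _masks(net)
    return _step_codes(codes, act, inh, rule)


# ---------------------------------------------------------------------------
# attractors


def find_attractors(
    net: SignedNetwork,
    mode: Literal["exhaustive", "sampled"] = "exhaustive",
    start_states: Iterable[BooleanState] | None = None,
    max_nodes_exhaustive: int = DEFAULT_MAX_NODES_EXHAUSTIVE,
    rule: UpdateRule = "hold",
) -> frozenset[Attractor]:
    """All attractors (exhaustive) or those reached from given starts (sampled).

    Exhaustive mode enumerates the full synchronous state-transition map and
    reports every attractor with its basin size; basin sizes sum to ``2**n``.
    Sampled mode follows each start state's trajectory to its attractor
    (basins are not computed) and is the only option for networks above the
    exhaustive cap.
    """
    _check_rule(rule)
    if mode == "exhaustive":
        n = len(net.nodes)
        if n > max_nodes_exhaustive:
            raise ValueError(
                f"network has {n} nodes, above the exhaustive cap "
                f"{max_nodes_exhaustive} ({1 << n} states); use mode='sampled' "
                "with explicit start states or raise max_nodes_exhaustive"
            )
        return _attractors_exhaustive(net, rule)
    if mode == "sampled":
        starts = list(start_states or [])
        if not starts:
            raise ValueError("sampled mode requires a non-empty start_states list")
        return _attractors_sampled(net, starts, rule)
    raise ValueError(f"unknown mode {mode!r}")


def _attractors_exhaustive(net: SignedNetwork, rule: str) -> frozenset[Attractor]:
    n = len(net.nodes)
    succ = successor_table(net, rule)
    size = 1 << n

    # States with in-degree 0 are transient; peel them off repeatedly.
    # What remains lies on cycles (the attractor states of a functional graph).
    indeg = np.bincount(succ, minlength=size)
    queue = [int(s) for s in np.flatnonzero(indeg == 0)]
    while queue:
        s = queue.pop()
        t = int(succ[s])
        indeg[t] -= 1
        if indeg[t] == 0:
            queue.append(t)
    on_cycle = indeg > 0

    # Group cyclic states into attractor cycles.
    attractor_id = np.full(size, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for s in np.flatnonzero(on_cycle):
        s = int(s)
        if attractor_id[s] >= 0:
            continue
        cyc = [s]
        t = int(succ[s])
        while t != s:
            cyc.append(t)
            t = int(succ[t])
        aid = len(cycles)
        cycles.append(cyc)
        for c in cyc:
            attractor_id[c] = aid

    # Basins: follow each transient state's path to a labelled state.
    for s in range(size):
        if attractor_id[s] >= 0:
            continue
        path = []
        t = s
        while attractor_id[t] < 0:
            path.append(t)
            t = int(succ[t])
        aid = attractor_id[t]
        for p in path:
            attractor_id[p] = aid

    basins = np.bincount(attractor_id, minlength=len(cycles))
    return frozenset(
        Attractor.from_cycle_codes(net.nodes, cyc, basin_size=int(basins[i]))
        for i, cyc in enumerate(cycles)
    )


def _attractors_sampled(
    net: SignedNetwork, starts: list[BooleanState], rule: str
) -> frozenset[Attractor]:
    act, inh = _masks(net)
    found: set[Attractor] = set()
    for s0 in starts:
        if s0.genes != net.nodes:
            raise ValueError("start state genes do not match network nodes")
        seen: dict[int, int] = {}
        code = s0.code
        trail: list[int] = []
        while code not in seen:
            seen[code] = len(trail)
            trail.append(code)
            code = int(_step_codes(np.array([code], dtype=np.int64), act, inh, rule)[0])
        cyc = trail[seen[code]:]
        found.add(Attractor.from_cycle_codes(net.nodes, cyc))
    return frozenset(found)


def fixed_points(
    net: SignedNetwork,
    rule: UpdateRule = "hold",
    max_nodes_exhaustive: int = DEFAULT_MAX_NODES_EXHAUSTIVE,
) -> list[BooleanState]:
    """All states mapped to themselves by the synchronous update."""
    n = len(net.nodes)
    if n > max_nodes_exhaustive:
        raise ValueError(
            f"fixed-point enumeration needs exhaustive mode; {n} nodes exceeds "
            f"the cap {max_nodes_exhaustive}"
        )
    succ = successor_table(net, rule)
    codes = np.flatnonzero(succ == np.arange(1 << n))
    return [BooleanState(net.nodes, int(c)) for c in codes]


def complete_partial_state(
    net: SignedNetwork,
    partial: PartialState,
    rule: UpdateRule = "hold",
    max_nodes_exhaustive: int = DEFAULT_MAX_NODES_EXHAUSTIVE,
) -> set[BooleanState]:
    """Predict the missing values of a partially observed stable state.

    Returns every fixed point of the network that agrees with the known
    entries of *partial* (possibly empty).
    """
    known = partial.known()
    if not known:
        raise ValueError("partial state must have at least one known value")
    if not partial.unknown_genes():
        raise ValueError("partial state must have at least one unknown value")
    unknown_genes = set(partial.values) - set(net.nodes)
    if unknown_genes:
        raise KeyError(f"gene {sorted(unknown_genes)[0]!r} is not a network node")
    out = set()
    for fp in fixed_points(net, rule, max_nodes_exhaustive):
        if all(fp[g] == v for g, v in known.items()):
            out.add(fp)
    return out
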