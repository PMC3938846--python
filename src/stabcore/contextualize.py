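"""Network contextualization: evolutionary pruning toward observed stable states.

A literature-derived signed network describes generic regulatory potential;
contextualization prunes it so that the synchronous Boolean dynamics of the
remaining edges reproduce two experimentally observed stable cell states
(e.g., the pluripotent and the differentiated expression pattern).  The
search is an estimation-of-distribution algorithm (EDA): a population of
pruned candidates is scored by attractor/observed-state consistency, the
elite fraction is used to estimate inclusion frequencies of positive
feedback circuits and of individual edges, and the next generation is
resampled from a mixture of the two distributions.  Positive circuits are
tracked explicitly because they are the structural prerequisite for the
multistationarity the two observed states demand.

The stability core of the result is the union of the non-trivial strongly
connected components of the best pruned network — the feedback structure
that maintains the two cell states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .circuits import enumerate_elementary_circuits, positive_circuits
from .dynamics import (
    DEFAULT_MAX_NODES_EXHAUSTIVE,
    Attractor,
    BooleanState,
    UpdateRule,
    find_attractors,
)
from .network import Edge, SignedNetwork


@dataclass(frozen=True)
class PruningConfig:
    """Hyperparameters of the EDA pruning loop.

    ``circuit_weight`` mixes circuit-level and edge-level elite frequencies
    when resampling; ``init_keep_prob`` sets generation-0 edge density; keep
    probabilities are clamped to ``[min_keep_prob, max_keep_prob]`` so no
    edge is ever irreversibly lost or fixed.  The sampling distribution is
    moved toward the elite estimate with ``learning_rate`` (incremental
    PBIL-style update, which damps fixation on the noisy small-elite
    frequencies), and is reset to ``init_keep_prob`` after
    ``stagnation_restart`` generations without improvement of the best
    individual (the best-ever individual is always retained).  ``update_rule`` selects the
    Boolean convention for unregulated genes; the default ``"decay"`` makes
    a gene fall to 0 when its last activator is pruned, so edge removal has
    observable dynamical consequences (under ``"hold"`` a pruned-bare gene
    freezes and nearly any deletion is consistency-neutral, which would make
    pruning degenerate).
    """

    population_size: int = 200
    elite_fraction: float = 0.2
    generations: int = 80
    circuit_weight: float = 0.5
    init_keep_prob: float = 0.5
    min_keep_prob: float = 0.02
    max_keep_prob: float = 0.98
    learning_rate: float = 0.25
    stagnation_restart: int = 12
    seed: int = 0
    stop_on_perfect: bool = True
    update_rule: UpdateRule = "decay"
    max_nodes_exhaustive: int = DEFAULT_MAX_NODES_EXHAUSTIVE

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.elite_fraction <= 1:
            raise ValueError("elite_fraction must be in (0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0 <= self.circuit_weight <= 1:
            raise ValueError("circuit_weight must be in [0, 1]")
        if not 0 <= self.min_keep_prob <= self.max_keep_prob <= 1:
            raise ValueError("require 0 <= min_keep_prob <= max_keep_prob <= 1")
        if not 0 <= self.init_keep_prob <= 1:
            raise ValueError("init_keep_prob must be in [0, 1]")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.stagnation_restart < 1:
            raise ValueError("stagnation_restart must be >= 1")


@dataclass(frozen=True)
class StabilityCore:
    """Non-trivial strongly connected components of a contextualized network."""

    components: tuple[frozenset[str], ...]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.components:
            out |= c
        return frozenset(out)


@dataclass(frozen=True)
class ContextualizationResult:
    best_network: SignedNetwork
    best_fitness: float
    attractors: frozenset[Attractor]
    fitness_trace: tuple[tuple[float, float], ...]  # per generation (best, mean)
    core: StabilityCore
    config_echo: PruningConfig


# ---------------------------------------------------------------------------
# consistency score


def _agreement(attractor: Attractor, observed: BooleanState) -> float:
    """Per-gene agreement of an attractor with an observed state, in [0,1].

    A fixed point is compared gene by gene.  A cyclic attractor is summarized
    by its per-gene time-average, rounded to the nearer Boolean value; a gene
    whose average sits exactly at 0.5 earns half credit.
    """
    obs = observed.bits()
    if attractor.is_fixed_point:
        return float(np.mean(attractor.states[0].bits() == obs))
    avg = attractor.mean_activity()
    credit = np.where(avg == 0.5, 0.5, (avg > 0.5).astype(float) == obs)
    return float(np.mean(credit))


def consistency_score(
    net: SignedNetwork,
    observed: Sequence[BooleanState],
    rule: UpdateRule = "hold",
    max_nodes_exhaustive: int = DEFAULT_MAX_NODES_EXHAUSTIVE,
) -> float:
    """Mean best agreement between the network's attractors and two observed states.

    For each observed state the attractor with the highest per-gene agreement
    is taken; the score is the mean of the two maxima and equals 1.0 when
    both observed states are fixed points of the network.
    """
    if len(observed) != 2:
        raise ValueError("exactly two observed states are required")
    for s in observed:
        if s.genes != net.nodes:
            raise ValueError("observed state genes do not match network nodes")
    attractors = find_attractors(
        net, mode="exhaustive", max_nodes_exhaustive=max_nodes_exhaustive, rule=rule
    )
    return float(
        np.mean([max(_agreement(a, s) for a in attractors) for s in observed])
    )


# ---------------------------------------------------------------------------
# stability core


def stability_core(net: SignedNetwork) -> StabilityCore:
    """SCC decomposition keeping components with >= 2 nodes or a self-loop."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((s, t) for s, t, _ in net.edges)
    comps = []
    for comp in nx.strongly_connected_components(g):
        if len(comp) >= 2 or any((v, v) in g.edges for v in comp):
            comps.append(frozenset(comp))
    comps.sort(key=lambda c: min(c))
    return StabilityCore(tuple(comps))


# ---------------------------------------------------------------------------
# EDA pruning


def prune_network(
    prior: SignedNetwork,
    observed: Sequence[BooleanState],
    cfg: PruningConfig | None = None,
) -> ContextualizationResult:
    """Prune *prior* until its attractors are consistent with the observed states.

    Estimation-of-distribution loop: generation 0 keeps each edge with
    ``init_keep_prob``; every individual is scored with
    :func:`consistency_score` (ties broken toward fewer edges — pruning
    seeks minimal consistent networks); the elite fraction's positive-circuit
    and edge inclusion frequencies define the sampling distribution of the
    next generation.  The best individual ever seen is returned with its
    attractors, stability core, and the per-generation (best, mean) fitness
    trace.  Runs with identical inputs and seed are bit-identical.
    """
    cfg = cfg or PruningConfig()
    if not prior.edges:
        raise ValueError("prior network has no edges to prune")
    if len(prior.nodes) > cfg.max_nodes_exhaustive:
        raise ValueError(
            f"prior has {len(prior.nodes)} nodes; contextualization requires "
            f"exhaustive attractor computation (cap {cfg.max_nodes_exhaustive})"
        )
    if len(observed) != 2:
        raise ValueError("exactly two observed states are required")

    edges: list[Edge] = sorted(prior.edges)
    m = len(edges)
    edge_index = {e: i for i, e in enumerate(edges)}

    # positive circuits of the prior, as edge-index sets
    pos = positive_circuits(enumerate_elementary_circuits(prior))
    circuit_edge_sets = [
        np.array(sorted(edge_index[e] for e in c.edges()), dtype=np.intp) for c in pos
    ]
    circuits_of_edge: list[list[int]] = [[] for _ in range(m)]
    for ci, es in enumerate(circuit_edge_sets):
        for ei in es:
            circuits_of_edge[ei].append(ci)

    rng = np.random.default_rng(cfg.seed)
    keep_prob = np.full(m, cfg.init_keep_prob)

    n_elite = max(1, math.ceil(cfg.elite_fraction * cfg.population_size))
    score_cache: dict[bytes, float] = {}

    def evaluate(key: bytes, mask: np.ndarray) -> float:
        hit = score_cache.get(key)
        if hit is not None:
            return hit
        sub = prior.subnetwork(e for e, keep in zip(edges, mask) if keep)
        s = consistency_score(
            sub, observed, rule=cfg.update_rule,
            max_nodes_exhaustive=cfg.max_nodes_exhaustive,
        )
        score_cache[key] = s
        return s

    best_mask: np.ndarray | None = None
    best_score = -1.0
    best_edges = m + 1
    stagnant = 0
    trace: list[tuple[float, float]] = []

    for gen in range(cfg.generations + 1):
        pop = rng.random((cfg.population_size, m)) < keep_prob
        keys = [np.packbits(ind).tobytes() for ind in pop]
        scores = np.array([evaluate(k, ind) for k, ind in zip(keys, pop)])
        n_kept = pop.sum(axis=1)
        # rank: consistency first, then parsimony (fewer edges)
        order = sorted(range(len(pop)), key=lambda i: (-scores[i], n_kept[i]))
        gen_best = order[0]
        if scores[gen_best] > best_score or (
            scores[gen_best] == best_score and n_kept[gen_best] < best_edges
        ):
            best_score = float(scores[gen_best])
            best_edges = int(n_kept[gen_best])
            best_mask = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append((best_score, float(scores.mean())))

        if gen == cfg.generations:
            break
        if cfg.stop_on_perfect and best_score >= 1.0:
            break
        if stagnant >= cfg.stagnation_restart:
            keep_prob = np.full(m, cfg.init_keep_prob)
            stagnant = 0
            continue

        # elite subpopulation, deduplicated so one genotype cannot dominate
        # the frequency estimates
        seen: set[bytes] = set()
        elite_idx: list[int] = []
        for i in order:
            if keys[i] not in seen:
                seen.add(keys[i])
                elite_idx.append(i)
            if len(elite_idx) == n_elite:
                break
        elites = pop[elite_idx]
        edge_freq = elites.mean(axis=0)
        if circuit_edge_sets:
            circ_freq = np.array(
                [elites[:, es].all(axis=1).mean() for es in circuit_edge_sets]
            )
            # an edge on no positive circuit has no circuit-level evidence;
            # its circuit term falls back to its own edge frequency so the
            # mixture does not systematically suppress it
            circ_term = np.array(
                [
                    max(
                        (circ_freq[ci] for ci in circuits_of_edge[ei]),
                        default=edge_freq[ei],
                    )
                    for ei in range(m)
                ]
            )
        else:
            circ_term = edge_freq
        target = cfg.circuit_weight * circ_term + (1 - cfg.circuit_weight) * edge_freq
        keep_prob = np.clip(
            (1 - cfg.learning_rate) * keep_prob + cfg.learning_rate * target,
            cfg.min_keep_prob,
            cfg.max_keep_prob,
        )

    assert best_mask is not None
    best_net = prior.subnetwork(e for e, keep in zip(edges, best_mask) if keep)
    attractors = find_attractors(
        best_net, mode="exhaustive",
        max_nodes_exhaustive=cfg.max_nodes_exhaustive, rule=cfg.update_rule,
    )
    return ContextualizationResult(
        best_network=best_net,
        best_fitness=best_score,
        attractors=attractors,
        fitness_trace=tuple(trace),
        core=stability_core(best_net),
        config_echo=cfg,
    )
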