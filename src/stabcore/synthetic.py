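"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study design the pipeline targets — a target
lineage vs two reference lineages, each in biological triplicate — without
any external download:

* :func:`simulate_expression` draws a log2 expression matrix with planted
  lineage-specific up/down modules on a Gaussian baseline;
* :func:`simulate_methylation` draws per-CpG methylated/total count tables
  per cell type around promoters of known methylation class (e.g.,
  structural-like genes hypermethylated in the references and demethylated
  in the target, TF-like genes low everywhere), with over-dispersed
  (negative binomial) coverage so the 10x filter is exercised;
* :func:`simulate_prior_network` builds a prior signed network containing a
  planted consistent core (disjoint positive circuits plus peripheral
  chains) and spurious edges whose removal is required for two target
  Boolean states to be fixed points; the construction is verified with the
  exhaustive attractor machinery and regenerated on failure.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import BooleanState, UpdateRule, find_attractors, synchronous_step
from .network import ACTIVATION, INHIBITION, Edge, SignedNetwork
from .omics import ExpressionMatrix

DEFAULT_CELL_TYPES = ("hESC", "hNSC", "hCM")


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class PlantedModule:
    """A block of genes shifted in one cell type."""

    n_genes: int
    log2_effect: float
    target: str
    direction: str = "up"  # "up" or "down"
    genes: tuple[str, ...] | None = None  # explicit ids; else assigned in order

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("module direction must be 'up' or 'down'")
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be >= 0")


@dataclass(frozen=True)
class ExpressionSimSpec:
    n_genes: int = 1000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_replicates: int = 3
    modules: tuple[PlantedModule, ...] = (
        PlantedModule(50, 2.0, "hCM", "up"),
        PlantedModule(50, 2.0, "hCM", "down"),
    )
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per cell type")
        for m in self.modules:
            if m.target not in self.cell_types:
                raise ValueError(f"module target {m.target!r} not a cell type")
        total = sum(m.n_genes for m in self.modules if m.genes is None)
        if total > self.n_genes:
            raise ValueError(
                f"planted modules need {total} genes but n_genes={self.n_genes}"
            )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a genes x samples log2 matrix plus a truth table of planted effects."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    # explicit module genes outside the generated universe extend the matrix
    # (e.g. regulatory-network genes planted alongside the random background)
    known = set(genes)
    for m in spec.modules:
        for g in m.genes or ():
            if g not in known:
                genes.append(g)
                known.add(g)

    # assign module gene blocks (explicit ids win; others take the next free)
    truth_dir = {g: "none" for g in genes}
    truth_tgt = {g: "" for g in genes}
    taken: set[str] = set()
    cursor = 0
    assigned: list[tuple[PlantedModule, list[str]]] = []
    for m in spec.modules:
        if m.genes is not None:
            block = list(m.genes)
            if len(block) != m.n_genes:
                raise ValueError("module gene list length differs from n_genes")
        else:
            block = []
            while len(block) < m.n_genes:
                g = genes[cursor]
                cursor += 1
                if g not in taken:
                    block.append(g)
        bad = set(block) - set(genes)
        if bad:
            raise ValueError(f"module genes not in matrix: {sorted(bad)}")
        overlap = taken & set(block)
        if overlap:
            raise ValueError(f"planted modules overlap on genes {sorted(overlap)[:5]}")
        taken |= set(block)
        assigned.append((m, block))
        for g in block:
            truth_dir[g] = m.direction
            truth_tgt[g] = m.target

    samples = [
        f"{ct}_r{r + 1}" for ct in spec.cell_types for r in range(spec.n_replicates)
    ]
    design = {s: s.rsplit("_r", 1)[0] for s in samples}

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    mat = np.tile(baseline[:, None], (1, len(samples)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for m, block in assigned:
        shift = m.log2_effect if m.direction == "up" else -m.log2_effect
        cols = [j for j, s in enumerate(samples) if design[s] == m.target]
        rows = [gene_idx[g] for g in block]
        mat[np.ix_(rows, cols)] += shift
    mat = mat + rng.normal(0.0, spec.noise_sd, size=mat.shape)

    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "direction": [truth_dir[g] for g in genes],
            "target": [truth_tgt[g] for g in genes],
        }
    ).set_index("gene")
    return ExpressionMatrix(values, design), truth


# ---------------------------------------------------------------------------
# methylation


@dataclass(frozen=True)
class PromoterClassSpec:
    """A promoter methylation class: per-cell-type level and gene fraction."""

    name: str
    levels: Mapping[str, float]
    fraction: float

    def __post_init__(self):
        for ct, lv in self.levels.items():
            if not 0 <= lv <= 1:
                raise ValueError(f"level for {ct!r} must be in [0,1], got {lv}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0,1]")


def default_promoter_classes(
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES, target: str = "hCM"
) -> tuple[PromoterClassSpec, ...]:
    """Structural-like (hypermethylated in refs, demethylated in target),
    TF-like (low everywhere), and an intermediate background class."""
    refs = [ct for ct in cell_types if ct != target]
    structural = {target: 0.1, **{r: 0.8 for r in refs}}
    tf = {ct: 0.05 for ct in cell_types}
    background = {ct: 0.5 for ct in cell_types}
    return (
        PromoterClassSpec("structural_like", structural, 0.3),
        PromoterClassSpec("tf_like", tf, 0.2),
        PromoterClassSpec("background", background, 0.5),
    )


@dataclass(frozen=True)
class MethylationSimSpec:
    n_genes: int = 60
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    classes: tuple[PromoterClassSpec, ...] = field(
        default_factory=default_promoter_classes
    )
    cpg_per_promoter_mean: float = 12.0  # Poisson mean
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0  # NB size parameter; smaller = wider
    low_coverage_fraction: float = 0.1  # sites drawn below the 10x filter
    exact_counts: bool = False  # meth_count = round(cov * level), no binomial noise
    window_bp: int = 1000
    promoter_spacing_bp: int = 4000  # >= 3 kb so promoter windows never overlap
    chrom: str = "chrS"
    gene_names: tuple[str, ...] | None = None
    class_assignments: Mapping[str, str] | None = None  # gene -> class name
    seed: int = 0

    def __post_init__(self):
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.promoter_spacing_bp < 3 * self.window_bp:
            raise ValueError("promoter spacing must keep windows disjoint")
        if not 0 <= self.low_coverage_fraction < 1:
            raise ValueError("low_coverage_fraction must be in [0,1)")


def simulate_methylation(
    spec: MethylationSimSpec, min_cov: int = 10
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-cell-type CpG count tables, a TSS BED6 frame, and a truth table.

    Promoters sit on one synthetic chromosome, spaced so their windows are
    disjoint.  Site coverage is negative binomial around ``coverage_mean``;
    a ``low_coverage_fraction`` of sites is drawn under ``min_cov`` in one
    cell type to exercise the intersection filter.  Methylated counts are
    binomial at the gene's class level.
    """
    rng = np.random.default_rng(spec.seed)
    genes = (
        list(spec.gene_names) if spec.gene_names is not None else _gene_names(spec.n_genes)
    )
    if len(genes) != spec.n_genes:
        raise ValueError("gene_names length differs from n_genes")

    class_by_name = {c.name: c for c in spec.classes}
    if spec.class_assignments is not None:
        gene_class = {g: class_by_name[spec.class_assignments[g]] for g in genes}
    else:
        fr = np.array([c.fraction for c in spec.classes], dtype=float)
        fr = fr / fr.sum()
        draws = rng.choice(len(spec.classes), size=len(genes), p=fr)
        gene_class = {g: spec.classes[k] for g, k in zip(genes, draws)}

    nb_n = spec.coverage_dispersion
    nb_p = nb_n / (nb_n + spec.coverage_mean)

    tables: dict[str, list[dict]] = {ct: [] for ct in spec.cell_types}
    bed_rows = []
    for gi, gene in enumerate(genes):
        tss = spec.promoter_spacing_bp * (gi + 1)
        strand = "+" if gi % 2 == 0 else "-"
        bed_rows.append(
            {
                "chrom": spec.chrom,
                "start": tss if strand == "+" else tss - 500,
                "end": tss + 500 if strand == "+" else tss + 1,
                "name": gene,
                "score": 0,
                "strand": strand,
            }
        )
        n_sites = rng.poisson(spec.cpg_per_promoter_mean)
        if n_sites == 0:
            continue
        offsets = rng.choice(
            np.arange(-spec.window_bp, spec.window_bp + 1),
            size=min(n_sites, 2 * spec.window_bp + 1),
            replace=False,
        )
        for off in sorted(int(o) for o in offsets):
            pos = tss + off
            low_here = rng.random() < spec.low_coverage_fraction
            low_ct = rng.choice(len(spec.cell_types)) if low_here else -1
            for k, ct in enumerate(spec.cell_types):
                if k == low_ct:
                    cov = int(rng.integers(1, min_cov))
                else:
                    cov = int(rng.negative_binomial(nb_n, nb_p)) + 1
                level = gene_class[gene].levels.get(ct, 0.0)
                if spec.exact_counts:
                    meth = round(cov * level)
                else:
                    meth = int(rng.binomial(cov, level))
                tables[ct].append(
                    {
                        "chrom": spec.chrom,
                        "pos": pos,
                        "strand": "+",
                        "meth_count": meth,
                        "total_count": cov,
                    }
                )

    out_tables = {
        ct: pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth_count", "total_count"])
        for ct, rows in tables.items()
    }
    tss_bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    truth = pd.DataFrame(
        {"gene": genes, "class": [gene_class[g].name for g in genes]}
    ).set_index("gene")
    return out_tables, tss_bed, truth


# ---------------------------------------------------------------------------
# prior network with a planted consistent core


@dataclass(frozen=True)
class NetworkSimSpec:
    circuit_sizes: tuple[int, ...] = (3, 3)  # disjoint positive activation circuits
    n_peripheral_nodes: int = 2  # chain nodes hanging off the core
    n_spurious_edges: int = 4  # consistency-breaking extra edges
    update_rule: UpdateRule = "decay"
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self):
        if any(s < 1 for s in self.circuit_sizes):
            raise ValueError("circuit sizes must be >= 1")
        if len(self.circuit_sizes) < 1:
            raise ValueError("at least one circuit is required")
        if self.n_peripheral_nodes < 0 or self.n_spurious_edges < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class PlantedNetwork:
    prior: SignedNetwork
    core_edges: frozenset[Edge]
    spurious_edges: frozenset[Edge]
    core_components: tuple[frozenset[str], ...]
    states: tuple[BooleanState, BooleanState]
    truth: pd.DataFrame  # one row per prior edge: planted vs spurious


def simulate_prior_network(spec: NetworkSimSpec) -> PlantedNetwork:
    """Prior = planted circuits + peripheral chains + verified-breaking spurious edges.

    The two target states set the circuits antiphase (circuit 0 ON / others
    OFF, and the complement) with peripheral chain values propagated from
    their source.  The generator verifies exhaustively that the planted
    network (spurious edges removed) holds both states as fixed points, that
    each spurious edge individually destroys at least one of them, and
    regenerates on failure up to ``max_retries``.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_retries):
        planted = _build_planted(spec, rng)
        if planted is not None:
            return planted
    raise RuntimeError(
        "could not construct a verified planted prior network within "
        f"{spec.max_retries} retries; relax the spec (fewer spurious edges?)"
    )


def _build_planted(spec: NetworkSimSpec, rng: np.random.Generator) -> PlantedNetwork | None:
    circuits: list[list[str]] = []
    n = 0
    for k, size in enumerate(spec.circuit_sizes):
        circuits.append([f"n{n + i:02d}" for i in range(size)])
        n += size
    core_edges: set[Edge] = set()
    for cyc in circuits:
        for i, u in enumerate(cyc):
            core_edges.add((u, cyc[(i + 1) % len(cyc)], ACTIVATION))

    core_nodes = [g for cyc in circuits for g in cyc]
    peripheral = [f"p{i:02d}" for i in range(spec.n_peripheral_nodes)]
    parent_of: dict[str, str] = {}
    for i, p in enumerate(peripheral):
        # chain off a random core node (or the previous peripheral node)
        pool = core_nodes + peripheral[:i]
        parent = pool[int(rng.integers(len(pool)))]
        parent_of[p] = parent
        core_edges.add((parent, p, ACTIVATION))

    nodes = core_nodes + peripheral
    planted_net = SignedNetwork(nodes, core_edges)

    # target states: circuit 0 ON / rest OFF, and the complement; peripheral
    # values propagate from their (unique) activator
    def state_values(on_first: bool) -> dict[str, int]:
        vals: dict[str, int] = {}
        for k, cyc in enumerate(circuits):
            v = 1 if (k == 0) == on_first else 0
            for g in cyc:
                vals[g] = v
        for p in peripheral:
            vals[p] = vals[parent_of[p]]
        return vals

    state_a = BooleanState.from_mapping(planted_net, state_values(True))
    state_b = BooleanState.from_mapping(planted_net, state_values(False))

    # spurious candidates verified to individually break a target state:
    # inhibiting chords within a circuit and activating cross-circuit edges
    candidates: list[Edge] = []
    for cyc in circuits:
        for u, v in itertools.permutations(cyc, 2):
            if (u, v, ACTIVATION) not in core_edges:
                candidates.append((u, v, INHIBITION))
    for ca, cb in itertools.permutations(range(len(circuits)), 2):
        for u in circuits[ca]:
            for v in circuits[cb]:
                candidates.append((u, v, ACTIVATION))

    def breaks(edge: Edge) -> bool:
        test = SignedNetwork(nodes, core_edges | {edge})
        for s in (state_a, state_b):
            s2 = BooleanState(test.nodes, s.code)
            if synchronous_step(test, s2, rule=spec.update_rule).code != s2.code:
                return True
        return False

    breaking = [e for e in candidates if breaks(e)]
    if len(breaking) < spec.n_spurious_edges:
        return None
    idx = rng.choice(len(breaking), size=spec.n_spurious_edges, replace=False)
    spurious = {breaking[i] for i in sorted(int(j) for j in idx)}

    prior = SignedNetwork(nodes, core_edges | spurious)

    # exhaustive verification: planted network holds both states as fixed
    # points; the full prior does not (unless no spurious edges were asked for)
    planted_attr = find_attractors(planted_net, rule=spec.update_rule)
    fp_codes = {a.states[0].code for a in planted_attr if a.is_fixed_point}
    if state_a.code not in fp_codes or state_b.code not in fp_codes:
        return None
    if spec.n_spurious_edges > 0:
        prior_attr = find_attractors(prior, rule=spec.update_rule)
        prior_fp = {a.states[0].code for a in prior_attr if a.is_fixed_point}
        if state_a.code in prior_fp and state_b.code in prior_fp:
            return None

    truth = pd.DataFrame(
        [
            {
                "source": s,
                "target": t,
                "sign": sg,
                "label": "planted" if (s, t, sg) in core_edges else "spurious",
            }
            for s, t, sg in sorted(prior.edges)
        ]
    )
    sa = BooleanState(prior.nodes, state_a.code)
    sb = BooleanState(prior.nodes, state_b.code)
    return PlantedNetwork(
        prior=prior,
        core_edges=frozenset(core_edges),
        spurious_edges=frozenset(spurious),
        core_components=tuple(frozenset(c) for c in circuits),
        states=(sa, sb),
        truth=truth,
    )
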