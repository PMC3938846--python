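"""Differential expression, promoter methylation, and their integration.

The filters here are deliberately simple and threshold-based, mirroring the
common microarray/bisulfite analysis conventions for a three-cell-type
design (one target lineage contrasted against two reference lineages, each
in replicates):

* differential expression: a gene is called up (down) when its mean log2
  expression in the target exceeds (falls below) BOTH references by at least
  log2(fold threshold), inclusive; a Welch t-test p-value accompanies each
  call;
* promoter methylation: the unweighted mean mCpG/CpG frequency over CpG
  sites with sufficient coverage in EVERY cell type, within a symmetric
  window around the TSS (inclusive boundary);
* differential methylation: promoter-level gain/loss of at least ``delta``
  (inclusive) versus both references;
* integration: promoter-demethylated AND up-regulated genes;
* binarization: a per-cell-type Boolean expression state feeding the
  network contextualization stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# tolerance for inclusive threshold comparisons on floats
_EPS = 1e-9

Direction = Literal["up", "down", "none"]
PromoterClass = Literal["hypermethylated", "low", "intermediate"]


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, genes x samples, with a sample design.

    ``design`` maps each sample id to its cell-type label.
    """

    values: pd.DataFrame
    design: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene rows: {dups[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> list[str]:
        seen = []
        for s in self.values.columns:
            ct = self.design[s]
            if ct not in seen:
                seen.append(ct)
        return seen

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == cell_type]

    def group_values(self, cell_type: str) -> pd.DataFrame:
        cols = self.samples_of(cell_type)
        if not cols:
            raise ValueError(f"no samples for cell type {cell_type!r}")
        return self.values[cols]

    def group_means(self) -> pd.DataFrame:
        """Per-gene mean log2 expression per cell type."""
        return pd.DataFrame(
            {ct: self.group_values(ct).mean(axis=1) for ct in self.cell_types}
        )


@dataclass(frozen=True)
class DECall:
    gene: str
    log2fc_vs_ref1: float
    log2fc_vs_ref2: float
    p_value: float
    direction: Direction


def call_de(
    mat: ExpressionMatrix,
    target: str,
    refs: Sequence[str],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    equal_var: bool = False,
    compare: Literal["each", "pooled"] = "each",
) -> list[DECall]:
    """Per-gene fold-change direction vs both references, with a t-test p-value.

    The direction is a pure fold-change predicate: ``up`` iff the target's
    mean exceeds both references by at least log2(fc_threshold) (inclusive),
    ``down`` symmetrically.  ``p_value`` is the larger of the two Welch
    t-test p-values against each reference (``compare="each"``, default) or
    a single test against the pooled references; use
    :func:`significant_calls` to combine direction with significance.
    """
    if len(refs) != 2:
        raise ValueError("exactly two reference cell types are required")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (a fold)")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    for ct in (target, *refs):
        k = len(mat.samples_of(ct))
        if k < 2:
            raise ValueError(f"cell type {ct!r} has {k} replicate(s); need >= 2")

    tgt = mat.group_values(target).to_numpy()
    r1 = mat.group_values(refs[0]).to_numpy()
    r2 = mat.group_values(refs[1]).to_numpy()
    lfc_thr = np.log2(fc_threshold)

    mean_t = tgt.mean(axis=1)
    lfc1 = mean_t - r1.mean(axis=1)
    lfc2 = mean_t - r2.mean(axis=1)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes (e.g. noise-free fixtures) trigger a precision
        # warning and a NaN p-value; the NaN is handled downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        if compare == "pooled":
            pooled = np.concatenate([r1, r2], axis=1)
            p = stats.ttest_ind(tgt, pooled, axis=1, equal_var=equal_var).pvalue
        else:
            p1 = stats.ttest_ind(tgt, r1, axis=1, equal_var=equal_var).pvalue
            p2 = stats.ttest_ind(tgt, r2, axis=1, equal_var=equal_var).pvalue
            p = np.maximum(p1, p2)

    up = (lfc1 >= lfc_thr - _EPS) & (lfc2 >= lfc_thr - _EPS)
    down = (lfc1 <= -lfc_thr + _EPS) & (lfc2 <= -lfc_thr + _EPS)

    calls = []
    for i, gene in enumerate(mat.genes):
        direction: Direction = "up" if up[i] else "down" if down[i] else "none"
        calls.append(
            DECall(str(gene), float(lfc1[i]), float(lfc2[i]), float(p[i]), direction)
        )
    return calls


def significant_calls(calls: Iterable[DECall], p_threshold: float = 0.05) -> list[DECall]:
    """Directional calls whose t-test p-value clears the threshold."""
    return [
        c
        for c in calls
        if c.direction != "none" and np.isfinite(c.p_value) and c.p_value < p_threshold
    ]


def binarize_expression(
    mat: ExpressionMatrix,
    method: Literal["midrange", "reference_fold"] = "midrange",
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """0/1 expression state per gene and cell type (rows genes, columns types).

    ``midrange``: ON where the cell-type mean strictly exceeds the midpoint
    of the min and max means across cell types (a constant gene is OFF
    everywhere).  ``reference_fold``: ON where the mean is at least 2-fold
    (1 log2 unit) above the lowest cell type.
    """
    means = mat.group_means()
    if genes is not None:
        missing = [g for g in genes if g not in means.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        means = means.loc[list(genes)]
    lo = means.min(axis=1)
    if method == "midrange":
        mid = (lo + means.max(axis=1)) / 2
        state = means.gt(mid, axis=0)
    elif method == "reference_fold":
        state = means.ge(lo + 1 - _EPS, axis=0) & means.gt(lo, axis=0)
        # a constant gene has no cell type above its own minimum -> all OFF
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return state.astype(int)


# ---------------------------------------------------------------------------
# methylation


def site_methylation(
    raw: Mapping[str, pd.DataFrame], min_cov: int = 10
) -> pd.DataFrame:
    """Merge per-cell-type CpG count tables and apply the coverage filter.

    Each input table needs columns ``chrom, pos, meth_count, total_count``
    (0-based point positions).  Only sites with ``total_count >= min_cov`` in
    EVERY cell type survive; the result has one row per surviving site with
    ``freq_<type>`` columns (meth_count / total_count).
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not raw:
        raise ValueError("no methylation tables given")
    merged: pd.DataFrame | None = None
    for ct, tab in raw.items():
        t = tab.copy()
        bad = t[t["meth_count"] > t["total_count"]]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"meth_count > total_count at {row['chrom']}:{int(row['pos'])} "
                f"in cell type {ct!r}"
            )
        if (t["total_count"] <= 0).any():
            row = t[t["total_count"] <= 0].iloc[0]
            raise ValueError(
                f"non-positive total_count at {row['chrom']}:{int(row['pos'])} "
                f"in cell type {ct!r}"
            )
        t = t[["chrom", "pos", "meth_count", "total_count"]].rename(
            columns={"meth_count": f"meth_{ct}", "total_count": f"total_{ct}"}
        )
        merged = t if merged is None else merged.merge(t, on=["chrom", "pos"], how="inner")
    assert merged is not None
    keep = np.ones(len(merged), dtype=bool)
    for ct in raw:
        keep &= (merged[f"total_{ct}"] >= min_cov).to_numpy()
    merged = merged.loc[keep].reset_index(drop=True)
    for ct in raw:
        merged[f"freq_{ct}"] = merged[f"meth_{ct}"] / merged[f"total_{ct}"]
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def tss_positions(tss: pd.DataFrame) -> pd.DataFrame:
    """TSS point coordinate per gene from a BED6-style frame.

    Expects columns ``chrom, start, end, name, score, strand``; the TSS is
    ``start`` on the plus strand and ``end - 1`` on the minus strand
    (0-based).
    """
    required = {"chrom", "start", "end", "name", "strand"}
    missing = required - set(tss.columns)
    if missing:
        raise ValueError(f"TSS annotation lacks columns: {sorted(missing)}")
    pos = np.where(tss["strand"] == "-", tss["end"] - 1, tss["start"])
    return pd.DataFrame(
        {"gene": tss["name"], "chrom": tss["chrom"], "tss": pos, "strand": tss["strand"]}
    )


def promoter_methylation(
    sites: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 1000,
    upstream_only: bool = False,
) -> pd.DataFrame:
    """Mean promoter mCpG/CpG level per gene and cell type.

    *sites* is the output of :func:`site_methylation`; *tss* a BED6-style
    annotation.  A site belongs to a gene's promoter when it lies within
    ``window_bp`` of the TSS, boundary inclusive (symmetric by default;
    ``upstream_only`` restricts to the strand-aware upstream side).  Genes
    with no covered promoter CpG carry NaN means and ``n_sites == 0``.
    """
    cts = sorted(c[len("freq_"):] for c in sites.columns if c.startswith("freq_"))
    anno = tss_positions(tss)
    rows = []
    by_chrom = {c: t for c, t in sites.groupby("chrom")}
    for rec in anno.itertuples(index=False):
        tab = by_chrom.get(rec.chrom)
        if tab is None:
            sel = None
        else:
            off = tab["pos"].to_numpy() - rec.tss
            if upstream_only:
                mask = (off <= 0) & (off >= -window_bp) if rec.strand != "-" else (
                    (off >= 0) & (off <= window_bp)
                )
            else:
                mask = np.abs(off) <= window_bp
            sel = tab.loc[mask] if mask.any() else None
        row = {"gene": rec.gene, "chrom": rec.chrom, "tss": rec.tss, "strand": rec.strand}
        row["n_sites"] = 0 if sel is None else len(sel)
        for ct in cts:
            row[f"mean_{ct}"] = float(sel[f"freq_{ct}"].mean()) if sel is not None else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    return out


def call_differential_methylation(
    pm: pd.DataFrame,
    target: str,
    refs: Sequence[str],
    delta: float = 0.05,
) -> tuple[list[str], list[str], list[str]]:
    """Promoter hyper-/hypo-methylation of the target vs both references.

    Returns ``(hyper, hypo, skipped)`` gene lists; a gene is hyper when its
    target promoter level exceeds each reference by at least *delta*
    (inclusive), hypo symmetrically, and skipped when its promoter level is
    undefined in any cell type.
    """
    if len(refs) != 2:
        raise ValueError("exactly two reference cell types are required")
    if not 0 <= delta <= 1:
        raise ValueError("delta must lie in [0, 1]")
    cols = [f"mean_{ct}" for ct in (target, *refs)]
    missing = [c for c in cols if c not in pm.columns]
    if missing:
        raise ValueError(f"promoter table lacks columns: {missing}")
    hyper, hypo, skipped = [], [], []
    t = pm[f"mean_{target}"]
    r1 = pm[f"mean_{refs[0]}"]
    r2 = pm[f"mean_{refs[1]}"]
    for gene in pm.index:
        vals = (t[gene], r1[gene], r2[gene])
        if any(pd.isna(v) for v in vals):
            skipped.append(str(gene))
            continue
        tv, v1, v2 = vals
        if tv - v1 >= delta - _EPS and tv - v2 >= delta - _EPS:
            hyper.append(str(gene))
        elif v1 - tv >= delta - _EPS and v2 - tv >= delta - _EPS:
            hypo.append(str(gene))
    return hyper, hypo, skipped


def classify_promoter(mean_mcpg: float) -> PromoterClass:
    """Bucket a promoter methylation level: >70% hyper, <10% low (both strict)."""
    if pd.isna(mean_mcpg):
        raise ValueError("promoter methylation level is undefined")
    if not 0 <= mean_mcpg <= 1:
        raise ValueError(f"promoter level must lie in [0, 1], got {mean_mcpg}")
    if mean_mcpg > 0.70:
        return "hypermethylated"
    if mean_mcpg < 0.10:
        return "low"
    return "intermediate"


# ---------------------------------------------------------------------------
# integration


@dataclass(frozen=True)
class IntegratedCall:
    gene: str
    meth_delta_vs_ref1: float
    meth_delta_vs_ref2: float
    de_direction: Direction
    category: Literal[
        "demethylated_upregulated",
        "hypermethylated_promoter",
        "low_methylation_promoter",
        "other",
    ]


def integrate_meth_expression(
    hypo: Sequence[str],
    de: Sequence[DECall],
    pm: pd.DataFrame | None = None,
    target: str | None = None,
    refs: Sequence[str] | None = None,
) -> list[IntegratedCall]:
    """Cross the promoter-demethylated gene list with the up-regulated genes.

    Genes both hypo-methylated and DE-up are categorized
    ``demethylated_upregulated``; with a promoter table the rest are
    classified by promoter state (hypermethylated in both references, low in
    all types) and otherwise fall to ``other``.
    """
    hypo_set = set(hypo)
    calls = []
    for c in de:
        d1 = d2 = float("nan")
        if pm is not None and target is not None and refs is not None and c.gene in pm.index:
            tv = pm.at[c.gene, f"mean_{target}"]
            d1 = float(tv - pm.at[c.gene, f"mean_{refs[0]}"])
            d2 = float(tv - pm.at[c.gene, f"mean_{refs[1]}"])
        if c.gene in hypo_set and c.direction == "up":
            cat = "demethylated_upregulated"
        else:
            cat = "other"
            if pm is not None and target is not None and refs is not None and c.gene in pm.index:
                levels = [pm.at[c.gene, f"mean_{ct}"] for ct in (target, *refs)]
                if not any(pd.isna(v) for v in levels):
                    ref_levels = levels[1:]
                    if all(classify_promoter(v) == "hypermethylated" for v in ref_levels):
                        cat = "hypermethylated_promoter"
                    elif all(classify_promoter(v) == "low" for v in levels):
                        cat = "low_methylation_promoter"
        calls.append(IntegratedCall(c.gene, d1, d2, c.direction, cat))
    return calls


def demethylated_upregulated(calls: Iterable[IntegratedCall]) -> list[str]:
    return [c.gene for c in calls if c.category == "demethylated_upregulated"]
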