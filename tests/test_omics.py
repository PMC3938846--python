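"""Threshold-based DE, promoter methylation, integration, binarization."""

import numpy as np
import pandas as pd
import pytest

from stabcore import (
    ExpressionMatrix,
    binarize_expression,
    call_de,
    call_differential_methylation,
    classify_promoter,
    integrate_meth_expression,
    promoter_methylation,
    significant_calls,
    site_methylation,
)
from stabcore.omics import DECall, demethylated_upregulated, tss_positions

CTS = ("hESC", "hNSC", "hCM")


def expr_matrix(rows: dict[str, list[float]], n_rep: int = 3) -> ExpressionMatrix:
    """rows: gene -> per-cell-type means, replicated exactly (no noise)."""
    samples = [f"{ct}_r{i+1}" for ct in CTS for i in range(n_rep)]
    values = pd.DataFrame(
        {s: [rows[g][CTS.index(s.rsplit('_r', 1)[0])] for g in rows] for s in samples},
        index=list(rows),
    )
    return ExpressionMatrix(values, {s: s.rsplit("_r", 1)[0] for s in samples})


def meth_table(sites: list[tuple[str, int, int, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        sites, columns=["chrom", "pos", "meth_count", "total_count"]
    ).assign(strand="+")


def bed(genes: list[tuple[str, str, int, str]]) -> pd.DataFrame:
    # (name, chrom, tss, strand) as a BED6 row
    return pd.DataFrame(
        [
            {
                "chrom": c,
                "start": t if s == "+" else t - 200,
                "end": t + 200 if s == "+" else t + 1,
                "name": g,
                "score": 0,
                "strand": s,
            }
            for g, c, t, s in genes
        ]
    )


class TestCallDE:
    def test_twofold_boundary_is_inclusive(self):
        mat = expr_matrix({"g1": [5.0, 4.5, 6.0], "g2": [5.0, 4.5, 5.9]})
        calls = {c.gene: c for c in call_de(mat, "hCM", ["hESC", "hNSC"])}
        assert calls["g1"].direction == "up"  # exactly 2-fold vs hESC
        assert calls["g2"].direction == "none"  # 1.9x vs hESC fails
        assert calls["g1"].log2fc_vs_ref1 == pytest.approx(1.0)

    def test_flat_gene_is_none_with_unit_fold_change(self):
        mat = expr_matrix({"g": [7.0, 7.0, 7.0]})
        (c,) = call_de(mat, "hCM", ["hESC", "hNSC"])
        assert c.direction == "none"
        assert c.log2fc_vs_ref1 == 0.0 and c.log2fc_vs_ref2 == 0.0

    def test_up_requires_both_references(self):
        mat = expr_matrix({"g": [5.0, 7.5, 8.0]})  # 8x vs hESC, 1.4x vs hNSC
        (c,) = call_de(mat, "hCM", ["hESC", "hNSC"])
        assert c.direction == "none"

    def test_planted_fixture_yields_exact_up_calls(self):
        rows = {}
        for i in range(7):  # >= 2-fold above both references
            rows[f"up{i}"] = [4.0, 4.5, 6.5]
        for i in range(5):  # up vs one reference only
            rows[f"half{i}"] = [4.0, 6.0, 6.5]
        for i in range(8):  # flat
            rows[f"flat{i}"] = [5.0, 5.0, 5.0]
        mat = expr_matrix(rows)
        up = {c.gene for c in call_de(mat, "hCM", ["hESC", "hNSC"]) if c.direction == "up"}
        assert up == {f"up{i}" for i in range(7)}

    def test_down_direction_symmetric(self):
        mat = expr_matrix({"g": [8.0, 9.0, 6.0]})
        (c,) = call_de(mat, "hCM", ["hESC", "hNSC"])
        assert c.direction == "down"

    def test_swapping_target_and_reference_negates_fold_change(self):
        mat = expr_matrix({"g": [5.0, 4.0, 8.0]})
        (fwd,) = call_de(mat, "hCM", ["hESC", "hNSC"])
        (rev,) = call_de(mat, "hESC", ["hCM", "hNSC"])
        assert fwd.log2fc_vs_ref1 == pytest.approx(-rev.log2fc_vs_ref1)

    def test_gene_order_invariance(self, rng):
        rows = {f"g{i}": list(rng.normal(7, 2, size=3)) for i in range(20)}
        mat1 = expr_matrix(rows)
        mat2 = expr_matrix(dict(reversed(list(rows.items()))))
        d1 = {c.gene: c.direction for c in call_de(mat1, "hCM", ["hESC", "hNSC"])}
        d2 = {c.gene: c.direction for c in call_de(mat2, "hCM", ["hESC", "hNSC"])}
        assert d1 == d2

    def test_single_replicate_group_rejected(self):
        samples = ["hESC_r1", "hNSC_r1", "hNSC_r2", "hCM_r1", "hCM_r2"]
        values = pd.DataFrame([[1.0] * 5], index=["g"], columns=samples)
        mat = ExpressionMatrix(values, {s: s.rsplit("_r", 1)[0] for s in samples})
        with pytest.raises(ValueError, match="hESC"):
            call_de(mat, "hCM", ["hESC", "hNSC"])

    def test_significance_filter_uses_welch_p(self, rng):
        base = rng.normal(0, 0.05, size=(1, 9))
        values = pd.DataFrame(
            base + np.array([[5, 5, 5, 5, 5, 5, 8, 8, 8]], dtype=float),
            index=["g"],
            columns=[f"{ct}_r{i+1}" for ct in CTS for i in range(3)],
        )
        mat = ExpressionMatrix(values, {c: c.rsplit("_r", 1)[0] for c in values.columns})
        calls = call_de(mat, "hCM", ["hESC", "hNSC"])
        assert [c.gene for c in significant_calls(calls)] == ["g"]


class TestBinarize:
    def test_midrange_states(self):
        mat = expr_matrix({"g": [4.0, 4.2, 9.0]})
        assert binarize_expression(mat).loc["g"].tolist() == [0, 0, 1]

    def test_constant_gene_is_off_everywhere(self):
        mat = expr_matrix({"g": [5.0, 5.0, 5.0]})
        assert binarize_expression(mat).loc["g"].tolist() == [0, 0, 0]
        assert binarize_expression(mat, method="reference_fold").loc["g"].tolist() == [0, 0, 0]

    def test_reference_fold_agrees_on_clear_case(self):
        mat = expr_matrix({"g": [10.0, 4.0, 4.0]})
        for method in ("midrange", "reference_fold"):
            assert binarize_expression(mat, method=method).loc["g"].tolist() == [1, 0, 0]

    def test_missing_gene_listed_in_error(self):
        mat = expr_matrix({"g": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError, match="nope"):
            binarize_expression(mat, genes=["g", "nope"])


class TestSiteMethylation:
    def test_coverage_filter_is_intersection_and_inclusive_at_ten(self):
        tables = {
            "hESC": meth_table([("c1", 100, 5, 12), ("c1", 200, 5, 12)]),
            "hNSC": meth_table([("c1", 100, 5, 11), ("c1", 200, 4, 9)]),
            "hCM": meth_table([("c1", 100, 5, 10), ("c1", 200, 9, 30)]),
        }
        out = site_methylation(tables, min_cov=10)
        assert out["pos"].tolist() == [100]  # site 200 fails in hNSC (9x)
        assert out.loc[0, "freq_hCM"] == pytest.approx(0.5)

    def test_filter_idempotent(self):
        tables = {
            ct: meth_table([("c1", p, p % 7, 10 + p % 13) for p in range(0, 300, 10)])
            for ct in CTS
        }
        once = site_methylation(tables, min_cov=10)
        again = site_methylation(
            {
                ct: once[["chrom", "pos", f"meth_{ct}", f"total_{ct}"]].rename(
                    columns={f"meth_{ct}": "meth_count", f"total_{ct}": "total_count"}
                )
                for ct in CTS
            },
            min_cov=10,
        )
        assert len(once) == len(again)
        assert (once["pos"].to_numpy() == again["pos"].to_numpy()).all()

    def test_count_inconsistency_reports_coordinates(self):
        tables = {"hESC": meth_table([("c1", 42, 11, 10)])}
        with pytest.raises(ValueError, match="c1:42"):
            site_methylation(tables)


class TestPromoterMethylation:
    def test_mean_over_window_sites(self):
        sites = site_methylation(
            {
                ct: meth_table([("c1", 9200, 8, 10), ("c1", 10200, 5, 10)])
                for ct in CTS
            }
        )
        pm = promoter_methylation(sites, bed([("g", "c1", 10000, "+")]))
        assert pm.loc["g", "mean_hCM"] == pytest.approx(0.65)
        assert pm.loc["g", "n_sites"] == 2

    def test_window_boundary_inclusive_at_exactly_1kb(self):
        sites = site_methylation(
            {ct: meth_table([("c1", 9000, 10, 10), ("c1", 8999, 0, 10)]) for ct in CTS}
        )
        pm = promoter_methylation(sites, bed([("g", "c1", 10000, "+")]), window_bp=1000)
        assert pm.loc["g", "n_sites"] == 1  # 8999 is 1001 bp away
        assert pm.loc["g", "mean_hESC"] == pytest.approx(1.0)

    def test_no_covered_sites_is_undefined_not_error(self):
        sites = site_methylation({ct: meth_table([("c1", 99999, 1, 10)]) for ct in CTS})
        pm = promoter_methylation(sites, bed([("g", "c1", 10000, "+"), ("h", "cX", 5000, "+")]))
        assert pm.loc["g", "n_sites"] == 0 and np.isnan(pm.loc["g", "mean_hCM"])
        assert pm.loc["h", "n_sites"] == 0  # chromosome absent entirely

    def test_minus_strand_tss_is_end_minus_one(self):
        anno = tss_positions(bed([("g", "c1", 10000, "-")]))
        assert anno.loc[0, "tss"] == 10000

    def test_adding_site_at_current_mean_preserves_mean(self):
        rows = [("c1", 9500, 3, 10), ("c1", 9700, 5, 10)]  # mean 0.4
        with_extra = rows + [("c1", 10100, 4, 10)]
        for data, expect in ((rows, 0.4), (with_extra, 0.4)):
            sites = site_methylation({ct: meth_table(data) for ct in CTS})
            pm = promoter_methylation(sites, bed([("g", "c1", 10000, "+")]))
            assert pm.loc["g", "mean_hCM"] == pytest.approx(expect)


class TestDifferentialMethylation:
    def pm_frame(self, rows: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_hCM": [v[0] for v in rows.values()],
                "mean_hESC": [v[1] for v in rows.values()],
                "mean_hNSC": [v[2] for v in rows.values()],
            },
            index=list(rows),
        )

    def test_hypo_call_and_exact_boundary(self):
        pm = self.pm_frame(
            {
                "clear": (0.10, 0.70, 0.60),
                "edge": (0.65, 0.70, 0.70),  # exactly 5% below both
                "near": (0.66, 0.70, 0.70),  # 4% below: not called
                "onesided": (0.50, 0.52, 0.90),
            }
        )
        hyper, hypo, skipped = call_differential_methylation(pm, "hCM", ["hESC", "hNSC"])
        assert hypo == ["clear", "edge"]
        assert hyper == [] and skipped == []

    def test_hyper_call_symmetric(self):
        pm = self.pm_frame({"g": (0.80, 0.60, 0.70)})
        hyper, hypo, _ = call_differential_methylation(pm, "hCM", ["hESC", "hNSC"])
        assert hyper == ["g"] and hypo == []

    def test_undefined_promoter_skipped_and_reported(self):
        pm = self.pm_frame({"g": (np.nan, 0.6, 0.6), "h": (0.1, 0.6, 0.6)})
        hyper, hypo, skipped = call_differential_methylation(pm, "hCM", ["hESC", "hNSC"])
        assert skipped == ["g"] and hypo == ["h"]


class TestClassifyAndIntegrate:
    @pytest.mark.parametrize(
        "level,expected",
        [
            (0.75, "hypermethylated"),
            (0.70, "intermediate"),  # strict >70%
            (0.05, "low"),
            (0.10, "intermediate"),  # strict <10%
            (0.40, "intermediate"),
        ],
    )
    def test_promoter_classes_strict_bounds(self, level, expected):
        assert classify_promoter(level) == expected

    def test_undefined_level_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_promoter(float("nan"))

    def de_call(self, gene, direction):
        return DECall(gene, 1.5, 1.5, 0.01, direction)

    def test_intersection_of_hypo_and_up(self):
        de = [self.de_call(g, "up") for g in ["g2", "g3", "g4"]] + [
            self.de_call("g1", "none")
        ]
        calls = integrate_meth_expression(["g1", "g2", "g3"], de)
        assert demethylated_upregulated(calls) == ["g2", "g3"]

    def test_disjoint_lists_give_no_integrated_calls(self):
        de = [self.de_call("a", "up")]
        assert demethylated_upregulated(integrate_meth_expression(["b"], de)) == []

    def test_planted_fixture_intersection_count(self):
        # 30 genes; 8 up-regulated, 8 hypo-methylated, exactly 4 in both
        genes = [f"g{i:02d}" for i in range(30)]
        up = set(genes[0:8])
        hypo = list(genes[4:12])
        de = [self.de_call(g, "up" if g in up else "none") for g in genes]
        calls = integrate_meth_expression(hypo, de)
        assert len(demethylated_upregulated(calls)) == 4
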