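import numpy as np
import pandas as pd
import pytest

from mcpgchip.intervals import GenomicInterval, Peak
from mcpgchip.io import EnhancerLink, GeneModel
from mcpgchip.targets import (
    Assignment,
    aza_reversal_stats,
    category_counts,
    classify_proximal,
    gene_set_enrichment,
    identify_direct_targets,
    link_enhancer_targets,
    naive_deg_caller,
    target_enrichment,
    upstream_window,
    wt_only_upregulated,
)

from oracles import hypergeom_upper_tail


def _peak(start, end, name, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), name=name)


def _gene(gene_id, start, end, strand, exons=None, utr5=None, chrom="chr1"):
    span = GenomicInterval(chrom, start, end, strand)
    exons = exons or [span]
    return GeneModel(gene_id, span, tuple(exons), tuple(utr5 or ()))


class TestProximal:
    def test_plus_strand_upstream_window(self):
        gene = _gene("G1", 20000, 24000, "+")
        assignments = classify_proximal([_peak(12000, 12500, "p1")], [gene])
        assert assignments == [Assignment("p1", "G1", "upstream")]

    def test_peak_outside_window_unassigned(self):
        gene = _gene("G1", 20000, 24000, "+")
        assert classify_proximal([_peak(8000, 9000, "p1")], [gene]) == []

    def test_minus_strand_window_beyond_span_end(self):
        # gene span [5000,8000) on -: upstream window is [8000,18000)
        gene = _gene("G1", 5000, 8000, "-")
        window = upstream_window(gene)
        assert (window.start, window.end) == (8000, 18000)
        assignments = classify_proximal([_peak(8500, 9000, "p1")], [gene])
        assert assignments == [Assignment("p1", "G1", "upstream")]

    def test_utr5_beats_exon_precedence(self):
        chrom_gene = _gene(
            "G1", 1000, 4000, "+",
            exons=[GenomicInterval("chr1", 1000, 2000, "+")],
            utr5=[GenomicInterval("chr1", 1000, 1200, "+")],
        )
        assignments = classify_proximal([_peak(1100, 1300, "p1")], [chrom_gene])
        assert assignments == [Assignment("p1", "G1", "utr5")]

    def test_exon_beats_upstream_and_multi_gene_hits(self):
        g1 = _gene("G1", 1000, 4000, "+", exons=[GenomicInterval("chr1", 1000, 2000, "+")])
        g2 = _gene("G2", 2500, 9000, "+")  # peak is also in G2's upstream window? no: inside span
        g3 = _gene("G3", 12000, 15000, "+")  # peak within 10 kb upstream of G3
        assignments = classify_proximal([_peak(1500, 2600, "p1")], [g1, g2, g3])
        by_gene = {a.gene_id: a.category for a in assignments}
        assert by_gene["G1"] == "exon"
        assert by_gene["G3"] == "upstream"


class TestEnhancerRoute:
    LINKS = [
        EnhancerLink(GenomicInterval("chr1", 1000, 2000), "GENE7"),
        EnhancerLink(GenomicInterval("chr1", 1800, 2600), "GENE7"),
        EnhancerLink(GenomicInterval("chr1", 5000, 6000), "GENE8"),
    ]

    def test_basic_link(self):
        assignments = link_enhancer_targets([_peak(1500, 1600, "p1")], self.LINKS)
        assert assignments == [Assignment("p1", "GENE7", "enhancer")]

    def test_two_enhancers_one_gene_deduplicated(self):
        assignments = link_enhancer_targets([_peak(1900, 1950, "p1")], self.LINKS)
        assert assignments == [Assignment("p1", "GENE7", "enhancer")]

    def test_proximal_wins_over_enhancer(self):
        proximal = [Assignment("p1", "GENE7", "upstream")]
        enhancer = [Assignment("p2", "GENE7", "enhancer")]
        (target,) = identify_direct_targets(proximal + enhancer, {"GENE7"})
        assert target.category == "upstream"
        assert target.peaks == ("p1", "p2")


class TestDirectTargets:
    def test_up_wt_only_with_peak_is_target(self):
        (target,) = identify_direct_targets([Assignment("p1", "G1", "upstream")], {"G1"})
        assert target.gene_id == "G1" and target.direction == "up"

    def test_gene_up_in_both_arms_excluded(self):
        deg_wt = pd.DataFrame({"gene_id": ["G1", "G2"], "log2fc": [2.0, 2.0], "p": [1e-9, 1e-9]})
        deg_mut = pd.DataFrame({"gene_id": ["G2"], "log2fc": [2.0], "p": [1e-9]})
        up = wt_only_upregulated(deg_wt, deg_mut)
        assert up == {"G1"}
        assignments = [Assignment("p1", "G1", "exon"), Assignment("p2", "G2", "exon")]
        targets = identify_direct_targets(assignments, up)
        assert [t.gene_id for t in targets] == ["G1"]

    def test_down_regulated_not_a_target(self):
        deg_wt = pd.DataFrame({"gene_id": ["G1"], "log2fc": [-2.0], "p": [1e-9]})
        assert wt_only_upregulated(deg_wt, deg_wt.iloc[:0]) == set()

    def test_category_counts_partition(self):
        targets = identify_direct_targets(
            [
                Assignment("p1", "G1", "upstream"),
                Assignment("p2", "G2", "enhancer"),
                Assignment("p3", "G2", "utr5"),
            ],
            {"G1", "G2"},
        )
        counts = category_counts(targets)
        assert sum(counts.values()) == len(targets) == 2
        assert counts["utr5"] == 1 and counts["upstream"] == 1


class TestEnrichment:
    def test_reported_composition_gives_fold_1_9(self):
        res = target_enrichment(116, 2518, 308, 12824)
        assert res.fold_display == 1.9
        assert res.fold_enrichment == pytest.approx((116 / 2518) / (308 / 12824))
        assert 0 < res.p < 1e-10

    def test_zero_overlap(self):
        res = target_enrichment(0, 100, 50, 1000)
        assert res.fold_enrichment == 0.0 and res.p == 1.0

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            target_enrichment(10, 5, 50, 1000)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            N = int(rng.integers(2, 50))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            res = target_enrichment(k, n, K, N)
            if k > 0:
                assert res.p == pytest.approx(float(hypergeom_upper_tail(k, N, K, n)), rel=1e-8)


class TestGeneSetEnrichment:
    def test_known_value(self):
        universe = {f"G{i}" for i in range(100)}
        sets = {"S": {f"G{i}" for i in range(10)}}
        targets = {f"G{i}" for i in range(5)}
        df = gene_set_enrichment(targets, sets, universe)
        assert df.loc[0, "p"] == pytest.approx(252 / 75_287_520, rel=1e-9)
        assert df.loc[0, "fdr"] == df.loc[0, "p"]  # single set: fdr == p

    def test_fdr_never_below_p_and_flags(self):
        rng = np.random.default_rng(8)
        universe = {f"G{i}" for i in range(200)}
        sets = {
            f"S{j}": {f"G{int(i)}" for i in rng.choice(200, size=20, replace=False)}
            for j in range(12)
        }
        targets = {f"G{i}" for i in range(30)}
        df = gene_set_enrichment(targets, sets, universe)
        assert (df["fdr"] >= df["p"] - 1e-12).all()
        assert df["p"].is_monotonic_increasing

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"G1"}, {"S": {"G1"}}, set())


class TestAzaReversal:
    def _table(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_all_targets_reduced_closed_form(self):
        rows = []
        for i in range(6):  # targets: induction lost under 5-Aza
            rows.append({"gene_id": f"T{i}", "t0": 2.0, "t48": 8.0, "t0_aza": 2.0, "t48_aza": 2.0})
        for i in range(10):  # background: half reduced, half increased
            delta = -0.5 if i < 5 else 0.5
            rows.append({"gene_id": f"B{i}", "t0": 2.0, "t48": 2.0, "t0_aza": 2.0, "t48_aza": 2.0 + delta})
        expr = self._table(rows)
        targets = {f"T{i}" for i in range(6)}
        res = aza_reversal_stats(expr, targets, set(expr.index))
        assert res.frac_targets_reduced == 1.0
        q = res.frac_universe_reduced
        assert q == pytest.approx(11 / 16)
        assert res.p == pytest.approx(q**6, rel=1e-9)

    def test_null_arm_fractions_agree(self):
        rng = np.random.default_rng(4)
        n = 400
        base = rng.lognormal(1, 1, n) + 0.6
        noise = lambda: rng.lognormal(0, 0.05, n)  # noqa: E731
        expr = pd.DataFrame(
            {
                "t0": base * noise(), "t48": base * noise(),
                "t0_aza": base * noise(), "t48_aza": base * noise(),
            },
            index=pd.Index([f"G{i}" for i in range(n)], name="gene_id"),
        )
        targets = {f"G{i}" for i in range(40)}
        res = aza_reversal_stats(expr, targets, set(expr.index))
        # no planted 5-Aza effect: both fractions are ~0.5 and agree within
        # binomial noise (3 sd for 40 targets ~ 0.24)
        assert abs(res.frac_targets_reduced - res.frac_universe_reduced) < 0.25
        assert abs(res.frac_universe_reduced - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_missing_condition_column(self):
        expr = self._table([{"gene_id": "G1", "t0": 1.0, "t48": 2.0}])
        with pytest.raises(KeyError, match="t0_aza"):
            aza_reversal_stats(expr, {"G1"}, {"G1"})

    def test_alternative_induced_level_mode(self):
        expr = self._table(
            [{"gene_id": "T0", "t0": 2.0, "t48": 8.0, "t0_aza": 2.0, "t48_aza": 3.0}]
        )
        res = aza_reversal_stats(expr, {"T0"}, {"T0"}, mode="t48_ratio")
        assert res.frac_targets_reduced == 1.0


def test_naive_deg_caller_detects_planted_fold_only():
    rng = np.random.default_rng(6)
    n = 200
    base = rng.lognormal(1.2, 0.8, n) + 0.5
    t48 = base.copy()
    t48[:10] *= 4  # planted up-regulation
    expr = pd.DataFrame(
        {"t0": base, "t48": t48},
        index=pd.Index([f"G{i}" for i in range(n)], name="gene_id"),
    )
    deg = naive_deg_caller(expr, "t0", "t48")
    called = set(deg.loc[(deg["p"] < 0.001) & (deg["log2fc"] > 0), "gene_id"])
    assert called == {f"G{i}" for i in range(10)}
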