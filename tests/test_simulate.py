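import numpy as np
import pytest

from mcpgchip.intervals import GenomicInterval
from mcpgchip.methylome import compute_beta
from mcpgchip.peaks import classify_peaks
from mcpgchip.histone import (
    build_signal_regions,
    direction_stats,
    normalize_deltas,
    region_signals,
)
from mcpgchip.simulate import (
    generate_dataset,
    generate_expression,
    generate_genome,
    generate_histone_reads,
    generate_peaks_and_methylome,
)
from mcpgchip.targets import naive_deg_caller


class TestGenome:
    def test_same_seed_identical(self):
        a = generate_genome(5, n_chroms=1, chrom_length=20_000)
        b = generate_genome(5, n_chroms=1, chrom_length=20_000)
        assert a == b
        c = generate_genome(6, n_chroms=1, chrom_length=20_000)
        assert a != c

    def test_gc_content_within_binomial_bound(self):
        genome = generate_genome(1, n_chroms=1, chrom_length=100_000, gc=0.5)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / len(seq))

    def test_gc_one_yields_only_gc(self):
        genome = generate_genome(1, n_chroms=1, chrom_length=10_000, gc=1.0)
        assert set(genome["chr1"]) <= {"C", "G"}

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            generate_genome(1, chrom_length=500)
        with pytest.raises(ValueError):
            generate_genome(1, gc=0.0)


@pytest.fixture(scope="module")
def small():
    genome = generate_genome(2, n_chroms=2, chrom_length=150_000)
    return generate_peaks_and_methylome(
        genome, 2, n_wt_specific=30, n_shared=30, n_mut_specific=8
    )


class TestPeaksAndMethylome:

    def test_classification_recovers_planted_partition(self, small):
        c = classify_peaks(small.wt_peaks, small.mut_peaks)
        assert {p.name for p in c.wt_specific} == set(small.wt_specific_names)
        assert {p.name for p in c.shared} == set(small.shared_names)
        assert {p.name for p in c.mut_specific} == set(small.mut_specific_names)

    def test_planted_beta_realized_exactly(self, small):
        by_beta = {compute_beta(s.n_meth, s.n_unmeth) for s in small.cpg_sites}
        assert by_beta <= {0.9, 0.2}

    def test_motif_spliced_into_chosen_peaks(self, small):
        peaks = {p.name: p for p in small.wt_peaks}
        for name in small.motif_peak_names:
            peak = peaks[name]
            seq = small.genome[peak.chrom][peak.start : peak.end]
            assert "CCCGCC" in seq

    def test_full_motif_fraction(self):
        genome = generate_genome(3, n_chroms=1, chrom_length=100_000)
        pm = generate_peaks_and_methylome(
            genome, 3, n_wt_specific=15, n_shared=5, n_mut_specific=2,
            frac_motif_in_specific=1.0,
        )
        for name in pm.wt_specific_names:
            peak = next(p for p in pm.wt_peaks if p.name == name)
            assert "CCCGCC" in pm.genome[peak.chrom][peak.start : peak.end]

    def test_motif_without_cg_rejected(self):
        genome = generate_genome(4, n_chroms=1, chrom_length=50_000)
        with pytest.raises(ValueError, match="CG"):
            generate_peaks_and_methylome(genome, 4, motif="AAATTT")

    def test_overcrowding_raises(self):
        genome = generate_genome(5, n_chroms=1, chrom_length=10_000)
        with pytest.raises(RuntimeError, match="place"):
            generate_peaks_and_methylome(
                genome, 5, n_wt_specific=200, n_shared=200, n_mut_specific=50
            )


class TestHistoneReads:
    SIZES = {"chr1": 400_000}

    def _regions(self, n=60):
        return [GenomicInterval("chr1", 6000 * i + 1000, 6000 * i + 3000) for i in range(n)]

    def test_determinism(self):
        regions = self._regions(10)
        a = generate_histone_reads(regions, 7, self.SIZES, n_background_reads=500)
        b = generate_histone_reads(regions, 7, self.SIZES, n_background_reads=500)
        assert a == b

    def test_planted_fold_recovered_in_counts(self):
        """With a 4x boost and no background, the mean log2 count ratio at
        effect regions approaches log2(4) = 2."""
        regions = self._regions(60)
        t0, t48 = generate_histone_reads(
            regions, 8, self.SIZES, depth=80, fold=4.0, n_background_reads=0
        )
        from mcpgchip.histone import count_overlapping_reads

        c0 = count_overlapping_reads(t0, regions)
        c48 = count_overlapping_reads(t48, regions)
        mean_delta = np.mean(np.log2((c48 + 1) / (c0 + 1)))
        assert mean_delta == pytest.approx(2.0, abs=0.15)

    def test_null_fold_gives_balanced_directions(self):
        regions = self._regions(60)
        t0, t48 = generate_histone_reads(
            regions, 9, self.SIZES, depth=60, fold=1.0, n_background_reads=5000
        )
        controls = [GenomicInterval("chr1", r.start + 3000, r.end + 3000) for r in regions[:-1]]
        signals = region_signals(t0, t48, regions)
        control_signals = region_signals(t0, t48, controls)
        normalized, _ = normalize_deltas(
            [s.delta for s in signals], [s.delta for s in control_signals]
        )
        s = direction_stats(normalized)
        assert abs(s.frac_up - 0.5) < 3 * np.sqrt(0.25 / s.n) + 0.05


class TestExpression:
    GENES = [f"G{i}" for i in range(300)]

    def test_determinism(self):
        a, _ = generate_expression(self.GENES, self.GENES[:10], 3)
        b, _ = generate_expression(self.GENES, self.GENES[:10], 3)
        assert a.equals(b)

    def test_noiseless_targets_always_reduced(self):
        expr, truth = generate_expression(
            self.GENES, self.GENES[:20], 4, noise_sd=0.0, aza_attenuation=0.0
        )
        fc_unt = expr["t48"] / expr["t0"]
        fc_aza = expr["t48_aza"] / expr["t0_aza"]
        dfc = (fc_aza - fc_unt)[self.GENES[:20]]
        assert (dfc < 0).all()
        planted_up = set(truth.loc[truth["direction"] == "up", "gene_id"])
        assert set(self.GENES[:20]) <= planted_up

    def test_no_induction_means_no_deg_calls(self):
        expr, truth = generate_expression(self.GENES, self.GENES[:20], 5, induction_fold=1.0)
        deg = naive_deg_caller(expr, "t0", "t48")
        assert (deg["p"] >= 0.001).all()
        assert (truth["direction"] == "none").all() or (
            truth.loc[truth["direction"] != "none", "gene_id"].isin(self.GENES[:20]).all()
        )

    def test_aza_attenuation_bounds(self):
        with pytest.raises(ValueError):
            generate_expression(self.GENES, [], 1, aza_attenuation=1.5)


class TestFullDataset:
    def test_truth_references_existing_entities(self, default_dataset):
        ds, _ = default_dataset
        peak_names = {p.name for p in ds.wt_peaks}
        assert set(ds.truth.motif_peak_names) <= peak_names
        assert set(ds.truth.wt_specific_names) | set(ds.truth.shared_names) == peak_names
        gene_ids = {g.gene_id for g in ds.gene_models}
        assert set(ds.truth.target_categories) <= gene_ids
        for peaks in ds.truth.target_peaks.values():
            assert set(peaks) <= peak_names
        assert set(ds.expression.index) >= gene_ids

    def test_histone_effect_structure(self, default_dataset):
        ds, _ = default_dataset
        assert set(ds.histone_reads) == {"H3K27ac", "H3K27me3", "H3K9me3"}
        regions = build_signal_regions(
            [p for p in ds.wt_peaks if p.name in {n for ns in ds.truth.target_peaks.values() for n in ns}]
        )
        spans = {(r.chrom, r.start, r.end) for r in regions}
        for mark, effects in ds.truth.histone_effect_regions.items():
            assert all((e["chrom"], e["start"], e["end"]) in spans for e in effects)

    def test_write_round_trip(self, default_dataset, tmp_path):
        from mcpgchip.io import load_cytosine_report, load_intervals

        ds, manifest = default_dataset
        assert load_intervals(manifest["wt_peaks"], kind="peak") == ds.wt_peaks
        sites = load_cytosine_report(manifest["methylome"])
        assert sites[:100] == ds.cpg_sites[:100] and len(sites) == len(ds.cpg_sites)
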