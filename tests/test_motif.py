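import numpy as np
import pytest

from mcpgchip.intervals import GenomicInterval
from mcpgchip.io import CpGSite
from mcpgchip.motif import (
    build_pwm,
    extract_methylated_kmers,
    kmer_enrichment,
    KmerStat,
    pwm_information_content,
    revcomp,
    write_meme_minimal,
)
from mcpgchip.simulate import generate_genome, generate_peaks_and_methylome

from oracles import hypergeom_upper_tail


def _site(pos1, m, u, chrom="chr1"):
    return CpGSite(chrom, pos1, "+", m, u)


class TestExtraction:
    GENOME = {"chr1": "ACCCGCCT"}
    PEAK = [GenomicInterval("chr1", 0, 8)]

    def test_windows_spanning_methylated_cg(self):
        # CG at 0-based offsets (3,4); cytosine report is 1-based -> pos 4
        (kmers,) = extract_methylated_kmers(self.PEAK, self.GENOME, [_site(4, 9, 1)])
        plus = {"ACCCGC", "CCCGCC", "CCGCCT"}
        assert plus <= kmers
        assert kmers == plus | {revcomp(s) for s in plus}

    def test_below_threshold_yields_nothing(self):
        (kmers,) = extract_methylated_kmers(self.PEAK, self.GENOME, [_site(4, 3, 7)])
        assert kmers == set()

    def test_threshold_is_strict(self):
        (kmers,) = extract_methylated_kmers(self.PEAK, self.GENOME, [_site(4, 6, 4)])
        assert kmers == set()  # beta == 0.6 exactly is not methylated

    def test_peak_beyond_chromosome_end(self):
        with pytest.raises(ValueError, match="beyond"):
            extract_methylated_kmers(
                [GenomicInterval("chr1", 0, 99)], self.GENOME, [_site(4, 9, 1)]
            )

    def test_minus_strand_site_maps_to_same_cg(self):
        minus = CpGSite("chr1", 5, "-", 9, 1)  # pairs with the CG starting at 0-based 3
        (kmers,) = extract_methylated_kmers(self.PEAK, self.GENOME, [minus])
        assert "CCCGCC" in kmers


class TestEnrichment:
    def _presence(self, n_fg, n_all, fg_with, bg_with, kmer="AACGTT"):
        """n_all peak sets where bg_with contain the k-mer, the first n_fg
        being the foreground with fg_with carriers among them."""
        sets = [set() for _ in range(n_all)]
        carriers = list(range(fg_with)) + list(range(n_fg, n_fg + (bg_with - fg_with)))
        for i in carriers:
            sets[i].add(kmer)
        return sets[:n_fg], sets

    def test_known_hypergeometric_value(self):
        fg, allp = self._presence(10, 20, 8, 8)
        stats_list, _ = kmer_enrichment(fg, allp)
        (s,) = stats_list
        assert s.fg_peaks == 8 and s.bg_peaks == 8
        assert s.p == pytest.approx(66 / 184756, rel=1e-9)

    def test_bonferroni_multiplies_by_tested_kmers(self):
        fg, allp = self._presence(10, 20, 8, 8)
        for i in range(9):  # nine further k-mers, each in one background peak
            allp[10 + i].add(f"AACG{'ACGT'[i % 4]}{'ACGT'[i // 4]}")
        stats_list, _ = kmer_enrichment(fg, allp)
        top = stats_list[0]
        assert top.kmer == "AACGTT"
        assert top.p_bonferroni == pytest.approx(top.p * 10)

    def test_foreground_not_subset_rejected(self):
        fg = [{"AACGTT"}]
        allp = [set(), set()]
        with pytest.raises(ValueError, match="subset"):
            kmer_enrichment(fg, allp)

    def test_foreground_equals_all_degenerate(self):
        fg, allp = self._presence(20, 20, 8, 8)
        stats_list, selected = kmer_enrichment(fg, allp)
        assert stats_list[0].p == pytest.approx(1.0)
        assert selected == []

    def test_monotone_in_foreground_count(self):
        ps = []
        for fg_with in range(0, 9):
            fg, allp = self._presence(10, 20, fg_with, 8)
            stats_list, _ = kmer_enrichment(fg, allp)
            ps.append(stats_list[0].p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n_all = int(rng.integers(2, 40))
            n_fg = int(rng.integers(1, n_all + 1))
            bg = int(rng.integers(1, n_all + 1))
            fg_with = int(rng.integers(max(0, bg - (n_all - n_fg)), min(bg, n_fg) + 1))
            fg, allp = self._presence(n_fg, n_all, fg_with, bg)
            stats_list, _ = kmer_enrichment(fg, allp)
            expected = hypergeom_upper_tail(fg_with, n_all, bg, n_fg)
            assert stats_list[0].p == pytest.approx(float(expected), rel=1e-8)


class TestPwm:
    def test_single_kmer_one_hot(self):
        pwm = build_pwm([KmerStat("CCCGCC", 3, 3, 1e-4, 1e-3)])
        assert pwm.consensus == "CCCGCC"
        assert np.allclose(pwm_information_content(pwm), 2.0)

    def test_weighted_column_frequencies(self):
        selected = [
            KmerStat("CCCGCC", 2, 2, 1e-4, 1e-3),
            KmerStat("ACCGCC", 1, 1, 1e-3, 1e-2),
        ]
        pwm = build_pwm(selected)
        assert pwm.width == 6  # same CG offset, no extension
        col0 = pwm.array[:, 0]
        assert col0[1] == pytest.approx(2 / 3)  # C
        assert col0[0] == pytest.approx(1 / 3)  # A

    def test_cg_offset_alignment_extends_width(self):
        selected = [
            KmerStat("CGAAAA", 1, 1, 1e-3, 1e-2),  # CG offset 0
            KmerStat("AACGAA", 1, 1, 1e-3, 1e-2),  # CG offset 2
        ]
        pwm = build_pwm(selected)
        assert pwm.width == 8

    def test_information_content_closed_forms(self):
        pwm = build_pwm([KmerStat("ACGTAC", 1, 1, 1e-3, 1e-2)])
        assert np.allclose(pwm_information_content(pwm), 2.0)
        half = ((0.5, 0.0, 0.5, 0.25), (0.5, 0.0, 0.5, 0.25),
                (0.0, 0.5, 0.0, 0.25), (0.0, 0.5, 0.0, 0.25))
        from mcpgchip.motif import PositionWeightMatrix

        ic = pwm_information_content(PositionWeightMatrix(half, support=4))
        assert ic[0] == pytest.approx(1.0)
        assert ic[3] == pytest.approx(0.0)

    def test_meme_export(self, tmp_path):
        pwm = build_pwm([KmerStat("CCCGCC", 3, 3, 1e-4, 1e-3)])
        out = tmp_path / "m.meme"
        write_meme_minimal(pwm, "test_motif", out)
        text = out.read_text()
        assert "MOTIF test_motif" in text and "w= 6" in text


def test_planted_motif_recovered_on_synthetic_peaks(small_params):
    """On generated peaks with the methylated CCCGCC planted in WT-specific
    peaks, the planted 6-mer attains the smallest enrichment p."""
    genome = generate_genome(3, n_chroms=2, chrom_length=small_params.chrom_length)
    pm = generate_peaks_and_methylome(
        genome, 3, n_wt_specific=40, n_shared=40, n_mut_specific=10
    )
    wt_specific = [p for p in pm.wt_peaks if p.name in set(pm.wt_specific_names)]
    shared = [p for p in pm.wt_peaks if p.name in set(pm.shared_names)]
    ordered = wt_specific + shared
    sets = extract_methylated_kmers(ordered, pm.genome, pm.cpg_sites)
    stats_list, selected = kmer_enrichment(sets[: len(wt_specific)], sets)
    assert stats_list[0].kmer == "CCCGCC"
    assert any(s.kmer == "CCCGCC" for s in selected)
    pwm = build_pwm(selected)
    assert "CCCGCC" in pwm.consensus or "CCGCC" in pwm.consensus


def test_logo_rendering_smoke(tmp_path):
    pwm = build_pwm(
        [KmerStat("CCCGCC", 3, 3, 1e-4, 1e-3), KmerStat("ACCGCC", 1, 2, 1e-3, 1e-2)]
    )
    from mcpgchip.plotting import plot_logo

    out = tmp_path / "logo.png"
    plot_logo(pwm, out)
    assert out.stat().st_size > 0
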