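"""Seeded generators for every input the pipeline consumes, with planted truth.

The simulated study mirrors the statistical structure the analysis
assumes: two ChIP peak sets with a controlled shared fraction; a
methylome whose high-beta CpGs concentrate in WT-specific peaks, 66% of
which carry a planted methylated CCCGCC motif (36% of shared peaks are
highly methylated without the motif); gene models laid out so that
planted direct-target genes receive a WT-specific peak in their upstream
window, 5'UTR, exon, or through an enhancer link; a four-condition
expression table (+/- induction, +/- demethylating agent) in which only
the planted targets lose induction under demethylation; and histone-mark
read sets whose 48 h coverage is boosted (or depressed) at target
regions. Every generator is a pure function of (seed, parameters); one
global seed fans out to fixed per-generator child streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, Peak
from .io import (
    CpGSite,
    EnhancerLink,
    GeneModel,
    write_cytosine_report,
    write_enhancer_map,
    write_expression,
    write_gene_models,
    write_intervals,
)
from .targets import naive_deg_caller

PLANTED_MOTIF = "CCCGCC"

# fixed offsets fanning the global seed out to per-generator streams
_STREAM = {"genome": 1, "layout": 2, "motif": 3, "methylome": 4, "expression": 6}


def child_rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM.get(stream, 90) + extra])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    gc: float = 0.41,
) -> Dict[str, str]:
    """I.i.d. random genome with P(C)=P(G)=gc/2, deterministic per seed."""
    if not (0.0 < gc <= 1.0):
        raise ValueError("gc must be in (0,1]")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    rng = child_rng(seed, "genome")
    at = (1.0 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(n_chroms):
        idx = rng.choice(4, size=chrom_length, p=probs)
        genome[f"chr{i + 1}"] = base_bytes[idx].tobytes().decode("ascii")
    return genome


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Layout engine
# ---------------------------------------------------------------------------


class _Layout:
    """Rejection-sampling placement of non-overlapping genomic entities."""

    def __init__(self, rng: np.random.Generator, sizes: Mapping[str, int], margin: int = 500):
        self.rng = rng
        self.sizes = dict(sizes)
        self.chroms = sorted(self.sizes)
        self.margin = margin
        self.trees: Dict[str, IntervalTree] = {c: IntervalTree() for c in self.chroms}

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.trees[chrom].addi(max(0, start - self.margin), end + self.margin)

    def place(self, length: int, max_tries: int = 2000) -> Tuple[str, int]:
        """A free [start, start+length) span on a random chromosome."""
        weights = np.array([self.sizes[c] for c in self.chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            chrom = self.chroms[int(self.rng.choice(len(self.chroms), p=weights))]
            limit = self.sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(self.rng.integers(0, limit))
            if not self.trees[chrom].overlap(start, start + length):
                self.reserve(chrom, start, start + length)
                return chrom, start
        raise RuntimeError(
            f"cannot place a {length} bp entity without overlap at the requested density"
        )


# ---------------------------------------------------------------------------
# Peaks + methylome
# ---------------------------------------------------------------------------


def _splice(genome_mut: Dict[str, list], chrom: str, pos: int, motif: str) -> None:
    genome_mut[chrom][pos : pos + len(motif)] = list(motif)


def _cg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def _methylome_from_genome(
    genome: Mapping[str, str],
    high_regions: Sequence[GenomicInterval],
    beta_high: float,
    beta_low: float,
    coverage: int,
) -> List[CpGSite]:
    """One plus-strand CpG row per CG dinucleotide; beta exact at the coverage.

    CpGs inside any high region get beta_high, all others beta_low; counts
    are the integer pair (round(beta * coverage), rest) so compute_beta
    reproduces the planted beta exactly.
    """
    high_by_chrom: Dict[str, IntervalTree] = {}
    for region in high_regions:
        high_by_chrom.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end)
    sites: List[CpGSite] = []
    for chrom in sorted(genome):
        tree = high_by_chrom.get(chrom)
        for cg0 in _cg_positions(genome[chrom]):
            beta = beta_high if tree is not None and tree.overlap(cg0, cg0 + 1) else beta_low
            n_meth = int(round(beta * coverage))
            sites.append(CpGSite(chrom, int(cg0) + 1, "+", n_meth, coverage - n_meth))
    return sites


@dataclass
class PeaksAndMethylome:
    genome: Dict[str, str]
    wt_peaks: List[Peak]
    mut_peaks: List[Peak]
    cpg_sites: List[CpGSite]
    motif_peak_names: List[str]
    high_shared_peak_names: List[str]
    wt_specific_names: List[str]
    shared_names: List[str]
    mut_specific_names: List[str]


def generate_peaks_and_methylome(
    genome: Mapping[str, str],
    seed: int,
    n_wt_specific: int = 120,
    n_shared: int = 120,
    n_mut_specific: int = 40,
    peak_width: int = 400,
    motif: str = PLANTED_MOTIF,
    beta_high: float = 0.9,
    beta_low: float = 0.2,
    frac_motif_in_specific: float = 0.66,
    frac_high_in_shared: float = 0.36,
    coverage: int = 10,
    layout: Optional[_Layout] = None,
    preplaced_wt_specific: Sequence[Peak] = (),
) -> PeaksAndMethylome:
    """Two peak sets with planted methylation/motif structure plus a methylome.

    Peaks are placed without mutual overlap. Shared loci appear with
    identical coordinates in both sets (distinct names), so overlap
    classification recovers the planted partition exactly. The motif is
    spliced, with high-beta CpGs, into ``frac_motif_in_specific`` of the
    WT-specific peaks; ``frac_high_in_shared`` of shared peaks are highly
    methylated without the motif. ``preplaced_wt_specific`` lets a caller
    (the full-dataset generator) contribute WT-specific peaks whose
    positions are already fixed relative to gene models.
    """
    if "CG" not in motif:
        raise ValueError("planted motif must contain CG")
    if not (0 <= frac_motif_in_specific <= 1 and 0 <= frac_high_in_shared <= 1):
        raise ValueError("fractions must be in [0,1]")
    rng = child_rng(seed, "layout", extra=17)
    sizes = {c: len(s) for c, s in genome.items()}
    if layout is None:
        layout = _Layout(rng, sizes)

    wt_peaks: List[Peak] = list(preplaced_wt_specific)
    n_free_specific = n_wt_specific - len(wt_peaks)
    if n_free_specific < 0:
        raise ValueError("more preplaced WT-specific peaks than n_wt_specific")
    for i in range(n_free_specific):
        chrom, start = layout.place(peak_width)
        wt_peaks.append(
            Peak(GenomicInterval(chrom, start, start + peak_width), name=f"WTS_{i:04d}")
        )
    shared_wt: List[Peak] = []
    mut_peaks: List[Peak] = []
    for i in range(n_shared):
        chrom, start = layout.place(peak_width)
        iv = GenomicInterval(chrom, start, start + peak_width)
        shared_wt.append(Peak(iv, name=f"SH_{i:04d}"))
        mut_peaks.append(Peak(iv, name=f"SHM_{i:04d}"))
    for i in range(n_mut_specific):
        chrom, start = layout.place(peak_width)
        mut_peaks.append(
            Peak(GenomicInterval(chrom, start, start + peak_width), name=f"MUT_{i:04d}")
        )

    motif_rng = child_rng(seed, "motif")
    n_motif = int(round(frac_motif_in_specific * len(wt_peaks)))
    motif_idx = motif_rng.choice(len(wt_peaks), size=n_motif, replace=False)
    genome_mut = {c: list(s) for c, s in genome.items()}
    motif_names = []
    for i in sorted(int(j) for j in motif_idx):
        peak = wt_peaks[i]
        pos = peak.interval.midpoint - len(motif) // 2
        _splice(genome_mut, peak.chrom, pos, motif)
        motif_names.append(peak.name)
    n_high_shared = int(round(frac_high_in_shared * n_shared))
    high_shared_idx = sorted(
        int(j) for j in motif_rng.choice(n_shared, size=n_high_shared, replace=False)
    )
    high_shared_names = [shared_wt[i].name for i in high_shared_idx]

    final_genome = {c: "".join(lst) for c, lst in genome_mut.items()}
    high_regions = [wt_peaks[i].interval for i, p in enumerate(wt_peaks) if p.name in set(motif_names)]
    high_regions += [shared_wt[i].interval for i in high_shared_idx]
    cpgs = _methylome_from_genome(final_genome, high_regions, beta_high, beta_low, coverage)

    return PeaksAndMethylome(
        genome=final_genome,
        wt_peaks=wt_peaks + shared_wt,
        mut_peaks=mut_peaks,
        cpg_sites=cpgs,
        motif_peak_names=motif_names,
        high_shared_peak_names=high_shared_names,
        wt_specific_names=[p.name for p in wt_peaks],
        shared_names=[p.name for p in shared_wt],
        mut_specific_names=[p.name for p in mut_peaks if p.name.startswith("MUT_")],
    )


# ---------------------------------------------------------------------------
# Histone reads
# ---------------------------------------------------------------------------


def generate_histone_reads(
    regions: Sequence[GenomicInterval],
    seed: int,
    genome_sizes: Mapping[str, int],
    effect_regions: Optional[Sequence[GenomicInterval]] = None,
    depth: float = 50.0,
    fold: float = 4.0,
    n_background_reads: int = 20000,
    read_len: int = 100,
    stream_offset: int = 0,
) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """BED-style read sets for two time points with planted coverage change.

    Each region draws Poisson(depth) reads at t0; at t48 effect regions
    draw Poisson(depth * fold), the rest Poisson(depth) again. Reads are
    uniform within their region. A uniform genome-wide background of
    ``n_background_reads`` is added independently at each time point.
    """
    if depth <= 0 or fold <= 0:
        raise ValueError("depth and fold must be positive")
    rng = child_rng(seed, "histone", extra=stream_offset)
    effect_keys = {(r.chrom, r.start, r.end) for r in (effect_regions if effect_regions is not None else regions)}

    def _draw_region_reads(region: GenomicInterval, lam: float) -> List[GenomicInterval]:
        n = int(rng.poisson(lam))
        out = []
        span = max(1, len(region) - read_len)
        for _ in range(n):
            start = region.start + int(rng.integers(0, span))
            out.append(GenomicInterval(region.chrom, start, start + read_len))
        return out

    def _background() -> List[GenomicInterval]:
        chroms = sorted(genome_sizes)
        weights = np.array([genome_sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        picks = rng.choice(len(chroms), size=n_background_reads, p=weights)
        out = []
        for ci in picks:
            chrom = chroms[int(ci)]
            start = int(rng.integers(0, max(1, genome_sizes[chrom] - read_len)))
            out.append(GenomicInterval(chrom, start, start + read_len))
        return out

    reads_t0: List[GenomicInterval] = []
    reads_t48: List[GenomicInterval] = []
    for region in regions:
        reads_t0.extend(_draw_region_reads(region, depth))
    for region in regions:
        lam = depth * fold if (region.chrom, region.start, region.end) in effect_keys else depth
        reads_t48.extend(_draw_region_reads(region, lam))
    reads_t0.extend(_background())
    reads_t48.extend(_background())
    return reads_t0, reads_t48


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    gene_ids: Sequence[str],
    target_ids: Sequence[str],
    seed: int,
    up_wt_only_extra: Sequence[str] = (),
    down_wt_only: Sequence[str] = (),
    up_both: Sequence[str] = (),
    lognormal_mu: float = 1.0,
    lognormal_sigma: float = 1.2,
    induction_fold: float = 4.0,
    aza_attenuation: float = 0.25,
    noise_sd: float = 0.05,
    target_min_baseline: float = 2.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Six-condition FPKM table (WT arm +/- 5-Aza, mutant arm) with planted DEGs.

    Planted direct targets are induced ``induction_fold``-fold at t48 in
    the untreated WT arm but only 1 + aza_attenuation * (fold - 1) in the
    demethylated arm (their activation needs the methyl mark); other
    planted up genes keep full induction under 5-Aza. ``up_both`` genes
    are induced in both the WT and the mutant arm. Multiplicative
    log-normal noise with sd ``noise_sd`` is applied to every measurement.
    Returns (expression table, truth table of planted directions).
    """
    if induction_fold < 1:
        raise ValueError("induction_fold must be >= 1 (1 = no planted induction)")
    if not (0.0 <= aza_attenuation <= 1.0):
        raise ValueError("aza_attenuation must be in [0,1]")
    rng = child_rng(seed, "expression")
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    baseline = rng.lognormal(lognormal_mu, lognormal_sigma, size=n)
    targets = set(target_ids)
    specials = targets | set(up_wt_only_extra) | set(down_wt_only) | set(up_both)
    for i, g in enumerate(gene_ids):
        if g in specials:
            baseline[i] = max(baseline[i], target_min_baseline)

    f = induction_fold
    aza_f = 1.0 + aza_attenuation * (f - 1.0)
    cols = {c: np.empty(n) for c in ("t0", "t48", "t0_aza", "t48_aza", "mut_t0", "mut_t48")}
    rows = []
    for i, g in enumerate(gene_ids):
        b = baseline[i]
        wt48, aza48, mut48 = b, b, b
        direction, arm = "none", "none"
        if g in targets:
            wt48, aza48 = b * f, b * aza_f
            direction, arm = "up", "wt_only_methylation_dependent"
        elif g in set(up_wt_only_extra):
            wt48, aza48 = b * f, b * f
            direction, arm = "up", "wt_only"
        elif g in set(down_wt_only):
            wt48, aza48 = b / f, b / f
            direction, arm = "down", "wt_only"
        elif g in set(up_both):
            wt48, aza48, mut48 = b * f, b * f, b * f
            direction, arm = "up", "both"
        expected = {
            "t0": b, "t48": wt48, "t0_aza": b, "t48_aza": aza48,
            "mut_t0": b, "mut_t48": mut48,
        }
        for c, v in expected.items():
            noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
            cols[c][i] = v * noise
        rows.append({"gene_id": g, "direction": direction, "arm": arm})

    expr = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(rows)
    return expr, truth


# ---------------------------------------------------------------------------
# Full dataset with gene models and enhancer links
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Default study conditions for the end-to-end simulation."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc: float = 0.41
    peak_width: int = 400
    n_wt_specific: int = 120
    n_shared: int = 120
    n_mut_specific: int = 40
    motif: str = PLANTED_MOTIF
    beta_high: float = 0.9
    beta_low: float = 0.2
    frac_motif_in_specific: float = 0.66
    frac_high_in_shared: float = 0.36
    coverage: int = 10
    n_targets: int = 30
    # planted category mix mirrors the reported 20/24/12/44 percent split
    category_fractions: Tuple[float, float, float, float] = (0.20, 0.24, 0.12, 0.44)
    gene_length: int = 3000
    upstream_gap: int = 1000
    n_decoy_up_genes: int = 10
    n_up_both_genes: int = 5
    n_expression_genes: int = 3000
    induction_fold: float = 4.0
    aza_attenuation: float = 0.25
    noise_sd: float = 0.05
    histone_depth: float = 50.0
    histone_background_reads: int = 20000
    read_len: int = 100
    # mark -> (fold at effect regions, fraction of target regions affected);
    # directions mirror the activating/repressive roles of the marks
    histone_marks: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "H3K27ac": (4.0, 0.833),
            "H3K27me3": (0.5, 0.543),
            "H3K9me3": (0.5, 0.636),
        }
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside the generated inputs."""

    planted_motif: str
    motif_peak_names: List[str]
    high_shared_peak_names: List[str]
    wt_specific_names: List[str]
    shared_names: List[str]
    mut_specific_names: List[str]
    target_categories: Dict[str, str]
    target_peaks: Dict[str, List[str]]
    deg_truth: List[dict]
    histone_effect_regions: Dict[str, List[dict]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    genome: Dict[str, str]
    wt_peaks: List[Peak]
    mut_peaks: List[Peak]
    cpg_sites: List[CpGSite]
    gene_models: List[GeneModel]
    enhancer_links: List[EnhancerLink]
    expression: pd.DataFrame
    deg_wt: pd.DataFrame
    deg_mut: pd.DataFrame
    histone_reads: Dict[str, Tuple[List[GenomicInterval], List[GenomicInterval]]]
    truth: SyntheticTruth

    def write(self, outdir) -> Dict[str, str]:
        """Write every input file the pipeline reads; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {}

        def _path(name: str) -> str:
            manifest[name.split(".")[0]] = str(outdir / name)
            return str(outdir / name)

        write_genome_fasta(self.genome, _path("genome.fa"))
        write_intervals(self.wt_peaks, _path("wt_peaks.bed"))
        write_intervals(self.mut_peaks, _path("mut_peaks.bed"))
        write_cytosine_report(self.cpg_sites, _path("methylome.cov"))
        write_gene_models(self.gene_models, _path("genes.bed12"))
        write_enhancer_map(self.enhancer_links, _path("enhancers.tsv"))
        write_expression(self.expression, _path("expression.tsv"))
        self.deg_wt.to_csv(_path("deg_wt.tsv"), sep="\t", index=False)
        self.deg_mut.to_csv(_path("deg_mut.tsv"), sep="\t", index=False)
        for mark, (t0, t48) in self.histone_reads.items():
            write_intervals(t0, _path(f"{mark}_t0.bed"))
            write_intervals(t48, _path(f"{mark}_t48.bed"))
        self.truth.to_json(_path("truth.json"))
        return manifest


def _gene_cassette(
    layout: _Layout,
    category: str,
    strand: str,
    gene_id: str,
    peak_name: Optional[str],
    params: SimulationParams,
) -> Tuple[GeneModel, Optional[Peak]]:
    """Place one gene (span + upstream window reserved) and its peak, if proximal.

    The reserved span covers the gene body plus the full 10 kb upstream
    window so that no later entity can stray into the window and create an
    unplanned proximal assignment.
    """
    glen, pw, gap = params.gene_length, params.peak_width, params.upstream_gap
    window = 10_000
    total = glen + window
    chrom, start = layout.place(total)
    if strand == "+":
        gs = start + window
    else:
        gs = start
    ge = gs + glen
    span = GenomicInterval(chrom, gs, ge, strand)
    # three exons; 5'UTR = 5'-most 200 bp of the 5' exon
    e = [
        GenomicInterval(chrom, gs, gs + 600, strand),
        GenomicInterval(chrom, gs + 1200, gs + 1800, strand),
        GenomicInterval(chrom, gs + 2400, ge, strand),
    ]
    if strand == "+":
        utr5 = (GenomicInterval(chrom, gs, gs + 200, strand),)
    else:
        utr5 = (GenomicInterval(chrom, ge - 200, ge, strand),)
    gene = GeneModel(gene_id, span, tuple(e), utr5)

    peak = None
    if category in ("upstream", "utr5", "exon"):
        if category == "upstream":
            if strand == "+":
                ps = gs - gap - pw
            else:
                ps = ge + gap
        elif category == "utr5":
            # overlap the UTR (and unavoidably the first/last exon): precedence -> utr5
            ps = gs - pw // 2 if strand == "+" else ge - pw // 2
        else:  # exon: inside the middle exon, clear of the UTR
            ps = gs + 1250
        peak = Peak(GenomicInterval(chrom, ps, ps + pw), name=peak_name)
    return gene, peak


def generate_dataset(seed: int, params: Optional[SimulationParams] = None) -> SyntheticDataset:
    """End-to-end synthetic study: genome, peaks, methylome, genes, expression, histone reads.

    The planted structure closes the loop: peak classification recovers
    the generated partition, the spliced motif is the top enriched
    methylated 6-mer, the planted targets are exactly the genes that are
    up-regulated WT-only and peak-associated, and the histone marks show
    the planted direction imbalance at target regions.
    """
    params = params or SimulationParams()
    genome = generate_genome(seed, params.n_chroms, params.chrom_length, params.gc)
    sizes = {c: len(s) for c, s in genome.items()}
    layout = _Layout(child_rng(seed, "layout"), sizes)

    # --- planted target genes and their peaks -----------------------------
    fracs = params.category_fractions
    n_t = params.n_targets
    counts = [int(round(f * n_t)) for f in fracs[:3]]
    counts.append(n_t - sum(counts))  # enhancer absorbs rounding
    categories = (
        ["upstream"] * counts[0] + ["utr5"] * counts[1] + ["exon"] * counts[2] + ["enhancer"] * counts[3]
    )
    gene_models: List[GeneModel] = []
    enhancer_links: List[EnhancerLink] = []
    preplaced: List[Peak] = []
    target_categories: Dict[str, str] = {}
    target_peaks: Dict[str, List[str]] = {}
    enhancer_genes: List[str] = []
    for i, category in enumerate(categories):
        gene_id = f"TARGET_{i:03d}"
        strand = "+" if i % 2 == 0 else "-"
        target_categories[gene_id] = category
        if category == "enhancer":
            gene, _ = _gene_cassette(layout, category, strand, gene_id, None, params)
            gene_models.append(gene)
            enhancer_genes.append(gene_id)
        else:
            peak_name = f"WTS_T{i:03d}"
            gene, peak = _gene_cassette(layout, category, strand, gene_id, peak_name, params)
            gene_models.append(gene)
            preplaced.append(peak)
            target_peaks[gene_id] = [peak_name]

    # decoy genes: up-regulated WT-only but deliberately peak-free
    decoy_up: List[str] = []
    for i in range(params.n_decoy_up_genes):
        gene_id = f"DECOY_UP_{i:03d}"
        gene, _ = _gene_cassette(layout, "enhancer", "+" if i % 2 else "-", gene_id, None, params)
        gene_models.append(gene)
        decoy_up.append(gene_id)
    # genes up in both arms, with a WT-specific peak upstream: must be excluded
    up_both: List[str] = []
    for i in range(params.n_up_both_genes):
        gene_id = f"BOTH_UP_{i:03d}"
        peak_name = f"WTS_B{i:03d}"
        gene, peak = _gene_cassette(layout, "upstream", "+", gene_id, peak_name, params)
        gene_models.append(gene)
        preplaced.append(peak)
        up_both.append(gene_id)

    # --- peaks + methylome -------------------------------------------------
    pm = generate_peaks_and_methylome(
        genome,
        seed,
        n_wt_specific=params.n_wt_specific,
        n_shared=params.n_shared,
        n_mut_specific=params.n_mut_specific,
        peak_width=params.peak_width,
        motif=params.motif,
        beta_high=params.beta_high,
        beta_low=params.beta_low,
        frac_motif_in_specific=params.frac_motif_in_specific,
        frac_high_in_shared=params.frac_high_in_shared,
        coverage=params.coverage,
        layout=layout,
        preplaced_wt_specific=preplaced,
    )

    # enhancer links: each enhancer-category target gene gets a dedicated
    # free WT-specific peak as its enhancer
    wt_by_name = {p.name: p for p in pm.wt_peaks}
    free_specific = [n for n in pm.wt_specific_names if n.startswith("WTS_") and "_T" not in n and "_B" not in n]
    if len(free_specific) < len(enhancer_genes):
        raise RuntimeError("not enough free WT-specific peaks for enhancer links")
    link_rng = child_rng(seed, "layout", extra=31)
    chosen = link_rng.choice(len(free_specific), size=len(enhancer_genes), replace=False)
    for gene_id, idx in zip(enhancer_genes, sorted(int(j) for j in chosen)):
        peak = wt_by_name[free_specific[idx]]
        enhancer_links.append(
            EnhancerLink(peak.interval.extended(200), gene_id, 1.0)
        )
        target_peaks[gene_id] = [peak.name]

    # --- expression + DEG tables ------------------------------------------
    modeled_ids = [g.gene_id for g in gene_models]
    filler = [f"G{i:05d}" for i in range(params.n_expression_genes - len(modeled_ids))]
    gene_ids = modeled_ids + filler
    n_filler_down = min(15, len(filler))
    down_wt_only = filler[:n_filler_down]  # unmodeled planted down-regulated genes
    expr, deg_truth = generate_expression(
        gene_ids,
        sorted(target_categories),
        seed,
        up_wt_only_extra=decoy_up,
        down_wt_only=down_wt_only,
        up_both=up_both,
        induction_fold=params.induction_fold,
        aza_attenuation=params.aza_attenuation,
        noise_sd=params.noise_sd,
    )
    deg_wt = naive_deg_caller(expr, "t0", "t48")
    deg_mut = naive_deg_caller(expr, "mut_t0", "mut_t48")

    # --- histone reads ------------------------------------------------------
    from .histone import build_signal_regions

    target_peak_names = sorted({n for names in target_peaks.values() for n in names})
    anchor_peaks = [wt_by_name[n] for n in target_peak_names]
    regions = build_signal_regions(anchor_peaks, half_width=1000)
    histone_reads = {}
    effect_truth: Dict[str, List[dict]] = {}
    for mi, (mark, (fold, frac)) in enumerate(sorted(params.histone_marks.items())):
        eff_rng = child_rng(seed, "histone", extra=100 + mi)
        n_eff = int(round(frac * len(regions)))
        idx = sorted(int(j) for j in eff_rng.choice(len(regions), size=n_eff, replace=False))
        effect = [regions[j] for j in idx]
        histone_reads[mark] = generate_histone_reads(
            regions,
            seed,
            sizes,
            effect_regions=effect,
            depth=params.histone_depth,
            fold=fold,
            n_background_reads=params.histone_background_reads,
            read_len=params.read_len,
            stream_offset=10 + mi,
        )
        effect_truth[mark] = [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "fold": fold} for r in effect
        ]

    truth = SyntheticTruth(
        planted_motif=params.motif,
        motif_peak_names=pm.motif_peak_names,
        high_shared_peak_names=pm.high_shared_peak_names,
        wt_specific_names=pm.wt_specific_names,
        shared_names=pm.shared_names,
        mut_specific_names=pm.mut_specific_names,
        target_categories=target_categories,
        target_peaks=target_peaks,
        deg_truth=deg_truth.to_dict("records"),
        histone_effect_regions=effect_truth,
    )
    return SyntheticDataset(
        genome=pm.genome,
        wt_peaks=pm.wt_peaks,
        mut_peaks=pm.mut_peaks,
        cpg_sites=pm.cpg_sites,
        gene_models=gene_models,
        enhancer_links=enhancer_links,
        expression=expr,
        deg_wt=deg_wt,
        deg_mut=deg_mut,
        histone_reads=histone_reads,
        truth=truth,
    )
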