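"""Methylation-aware k-mer motif enrichment and logo construction.

The procedure scans ChIP peak sequences for k-mers (k=6 by default) that
span a methylated CpG — a CG dinucleotide whose cytosine has bisulfite
beta above a threshold (0.6). Each peak contributes a presence/absence
set of such k-mers. Enrichment of each k-mer in a foreground peak set
(e.g. WT-specific peaks) against all peaks is scored with a
hypergeometric upper tail and Bonferroni-corrected over the k-mers
actually observed; selected k-mers are stacked, aligned on their CG, into
a position weight matrix for logo rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak, as_interval
from .io import CpGSite

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerStat:
    """Enrichment record for one methylated k-mer.

    fg_peaks / bg_peaks count peaks (not occurrences) containing the k-mer
    in the foreground and in all peaks; p is the hypergeometric upper tail,
    p_bonferroni the Bonferroni-adjusted p clipped at 1.
    """

    kmer: str
    fg_peaks: int
    bg_peaks: int
    p: float
    p_bonferroni: float

    def __post_init__(self) -> None:
        if self.fg_peaks > self.bg_peaks:
            raise ValueError("fg_peaks cannot exceed bg_peaks")
        if "CG" not in self.kmer:
            raise ValueError(f"methylated k-mer must contain CG: {self.kmer!r}")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Column-stochastic base-frequency matrix (rows A,C,G,T)."""

    matrix: Tuple[Tuple[float, ...], ...]  # shape (4, width), rows in BASES order
    support: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.matrix)
        if arr.shape[0] != 4:
            raise ValueError("PWM must have 4 base rows")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return len(self.matrix[0])

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.array.argmax(axis=0))


def load_genome(path) -> Dict[str, str]:
    """FASTA -> dict of upper-case chromosome sequences (via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def methylated_cg_positions(
    cpgs: Sequence[CpGSite], beta_min: float = 0.6
) -> Dict[str, Set[int]]:
    """Plus-strand CG start positions (0-based) whose cytosine has beta > beta_min.

    Sites on either strand vote for their dinucleotide: a minus-strand
    cytosine maps to the CG starting one bp earlier on the plus strand.
    Strictly greater than ``beta_min``: a site at exactly the threshold is
    not methylated.
    """
    out: Dict[str, Set[int]] = {}
    for s in cpgs:
        if s.coverage == 0:
            continue
        if s.beta > beta_min:
            out.setdefault(s.chrom, set()).add(s.cg_start0)
    return out


def extract_methylated_kmers(
    peaks: Sequence["GenomicInterval | Peak"],
    genome: Mapping[str, str],
    cpgs: Sequence[CpGSite],
    k: int = 6,
    beta_min: float = 0.6,
    both_strands: bool = True,
) -> List[Set[str]]:
    """Per-peak sets of k-mers spanning a methylated CpG.

    For every methylated CG inside a peak, all k-windows of the peak
    sequence that contain the complete CG contribute their plus-strand
    k-mer; with ``both_strands`` the reverse complement of each window is
    recorded as well (the minus-strand read of the same site). Windows
    containing N are skipped. Presence is binary per peak.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    meth = methylated_cg_positions(cpgs, beta_min)
    out: List[Set[str]] = []
    for item in peaks:
        iv = as_interval(item)
        seq = genome.get(iv.chrom)
        if seq is None:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome")
        if iv.end > len(seq):
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} extends beyond chromosome end"
            )
        kmers: Set[str] = set()
        positions = meth.get(iv.chrom, ())
        for cg0 in positions:
            if not (iv.start <= cg0 and cg0 + 2 <= iv.end):
                continue
            lo = max(iv.start, cg0 - k + 2)
            hi = min(cg0, iv.end - k)
            for w in range(lo, hi + 1):
                kmer = seq[w : w + k]
                if "N" in kmer:
                    continue
                kmers.add(kmer)
                if both_strands:
                    kmers.add(revcomp(kmer))
        out.append(kmers)
    return out


def kmer_enrichment(
    fg_presence: Sequence[Set[str]],
    all_presence: Sequence[Set[str]],
    alpha: float = 0.01,
    count_occurrences: bool = False,
) -> Tuple[List[KmerStat], List[KmerStat]]:
    """Hypergeometric enrichment of methylated k-mers in foreground peaks.

    Under the null, the ``n_fg`` foreground peaks are an unordered draw
    from the ``n_all`` peaks; for a k-mer present in K of all peaks the
    observed foreground presence count x has an upper-tail p of
    P(X >= x | N=n_all, K, n=n_fg). Bonferroni multiplies by the number of
    distinct k-mers observed in the background — only enumerated
    hypotheses are corrected for, not all 4^k strings.

    Returns (all stats sorted by ascending p, selected with
    p_bonferroni < alpha). ``count_occurrences`` is accepted for interface
    symmetry but the hypergeometric model is defined on peak presence;
    occurrence counting is not implemented for it.
    """
    if count_occurrences:
        raise NotImplementedError("hypergeometric model is defined on peak presence")
    n_fg, n_all = len(fg_presence), len(all_presence)
    if n_fg > n_all:
        raise ValueError("foreground peaks must be a subset of all peaks")
    bg_counts: Dict[str, int] = {}
    for s in all_presence:
        for kmer in s:
            bg_counts[kmer] = bg_counts.get(kmer, 0) + 1
    fg_counts: Dict[str, int] = {}
    for s in fg_presence:
        for kmer in s:
            fg_counts[kmer] = fg_counts.get(kmer, 0) + 1
    for kmer, c in fg_counts.items():
        if c > bg_counts.get(kmer, 0):
            raise ValueError(
                f"k-mer {kmer!r} seen in foreground more often than in all peaks; "
                "foreground must be a subset of the background peak set"
            )
    n_tested = len(bg_counts)
    out: List[KmerStat] = []
    for kmer, bg in bg_counts.items():
        fg = fg_counts.get(kmer, 0)
        p = float(stats.hypergeom.sf(fg - 1, n_all, bg, n_fg))
        out.append(KmerStat(kmer, fg, bg, p, min(1.0, p * n_tested)))
    out.sort(key=lambda s: (s.p, s.kmer))
    selected = [s for s in out if s.p_bonferroni < alpha]
    return out, selected


def build_pwm(selected: Sequence[KmerStat]) -> PositionWeightMatrix:
    """Stack selected k-mers, aligned on their (first) CG, into a PWM.

    Each k-mer contributes its foreground peak count as weight. Width is
    k + (max CG offset - min CG offset); columns a k-mer does not reach
    receive no contribution from it.
    """
    if not selected:
        raise ValueError("need at least one selected k-mer")
    k = len(selected[0].kmer)
    offsets = []
    for s in selected:
        off = s.kmer.find("CG")
        if off < 0:
            raise ValueError(f"selected k-mer without CG: {s.kmer!r}")
        offsets.append(off)
    max_off, min_off = max(offsets), min(offsets)
    width = k + (max_off - min_off)
    counts = np.zeros((4, width))
    support = 0
    for s, off in zip(selected, offsets):
        shift = max_off - off
        weight = max(s.fg_peaks, 1)
        support += s.fg_peaks
        for j, base in enumerate(s.kmer):
            counts[BASES.index(base), shift + j] += weight
    sums = counts.sum(axis=0)
    sums[sums == 0] = 1.0
    freqs = counts / sums
    return PositionWeightMatrix(tuple(map(tuple, freqs)), support=support)


def pwm_information_content(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-column information content in bits: 2 + sum_b f log2 f (0 log 0 = 0)."""
    arr = pwm.array
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(arr > 0, arr * np.log2(arr), 0.0)
    return 2.0 + plogp.sum(axis=0)


def kmer_stats_table(kmer_stats: Sequence[KmerStat]):
    """KmerStat list -> DataFrame (sorted by p) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "kmer": [s.kmer for s in kmer_stats],
            "fg_peaks": [s.fg_peaks for s in kmer_stats],
            "bg_peaks": [s.bg_peaks for s in kmer_stats],
            "p": [s.p for s in kmer_stats],
            "p_bonferroni": [s.p_bonferroni for s in kmer_stats],
        }
    )


def write_meme_minimal(pwm: PositionWeightMatrix, name: str, path) -> None:
    """Write the PWM in MEME minimal motif text format."""
    arr = pwm.array
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {pwm.support}\n"
        )
        for j in range(pwm.width):
            fh.write(" ".join(f"{arr[i, j]:.6f}" for i in range(4)) + "\n")
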