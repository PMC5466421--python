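"""Desk-scale peak calling and WT / mutant peak-set classification.

The caller is a deliberately simple fixed-window Poisson scan: the genome
is tiled in non-overlapping windows, each window's read count is tested
against Poisson(lambda = total_reads * window / genome_length), and
significant windows are merged into peaks. It trades MACS's local-lambda
machinery for transparency and speed on simulated data.

Classification reproduces the binding-specificity logic of a WT-vs-mutant
ChIP comparison: peaks found in both samples at the same locus are
"shared"; WT peaks with no mutant counterpart are "WT-specific"
(methyl-CpG-dependent binding events when the mutant is a
methyl-binding-deficient point mutant), and symmetrically for the mutant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak, find_overlaps, overlaps_any


@dataclass(frozen=True)
class PeakClassification:
    """Partition of two peak sets by locus overlap.

    Every WT peak lands in exactly one of {shared, wt_specific}; every
    mutant peak in exactly one of {shared_mut, mut_specific}. ``shared``
    holds the WT-side peaks of shared loci; ``shared_mut`` the mutant-side
    ones (counts may differ when overlap is not 1:1).
    """

    shared: Tuple[Peak, ...]
    wt_specific: Tuple[Peak, ...]
    mut_specific: Tuple[Peak, ...]
    shared_mut: Tuple[Peak, ...] = ()

    def summary(self) -> Dict[str, int]:
        return {
            "n_wt": len(self.shared) + len(self.wt_specific),
            "n_mut": len(self.shared_mut) + len(self.mut_specific),
            "n_shared": len(self.shared),
            "n_wt_specific": len(self.wt_specific),
            "n_mut_specific": len(self.mut_specific),
        }


def call_peaks_poisson(
    reads: Sequence[GenomicInterval],
    genome_sizes: Mapping[str, int],
    window_bp: int = 200,
    p_cutoff: float = 1e-5,
    merge_gap_windows: int = 1,
) -> List[Peak]:
    """Fixed-window Poisson peak caller.

    Each read is assigned to the window containing its midpoint. A window
    with count c is significant when the Poisson upper tail P(X >= c) under
    lambda = total_reads * window_bp / genome_length is below ``p_cutoff``.
    Significant windows separated by <= ``merge_gap_windows`` non-significant
    windows are merged into one peak (single binding events should not
    fragment); the peak score is -log10 of the best window p.
    """
    if not reads:
        raise ValueError("no reads")
    if window_bp < 50:
        raise ValueError("window_bp must be >= 50")
    genome_length = sum(genome_sizes.values())
    total_reads = len(reads)
    lam = total_reads * window_bp / genome_length

    counts: Dict[str, np.ndarray] = {
        chrom: np.zeros(max(1, -(-size // window_bp)), dtype=int)
        for chrom, size in genome_sizes.items()
    }
    for read in reads:
        arr = counts.get(read.chrom)
        if arr is None:
            continue
        w = min(read.midpoint // window_bp, len(arr) - 1)
        arr[w] += 1

    peaks: List[Peak] = []
    for chrom in sorted(genome_sizes):
        arr = counts[chrom]
        pvals = stats.poisson.sf(arr - 1, lam)
        sig = np.flatnonzero(pvals < p_cutoff)
        if sig.size == 0:
            continue
        runs: List[List[int]] = [[int(sig[0])]]
        for w in sig[1:]:
            if w - runs[-1][-1] <= merge_gap_windows + 1:
                runs[-1].append(int(w))
            else:
                runs.append([int(w)])
        for run in runs:
            start = run[0] * window_bp
            end = min((run[-1] + 1) * window_bp, genome_sizes[chrom])
            best_p = float(min(pvals[w] for w in run))
            score = 300.0 if best_p == 0.0 else -math.log10(best_p)
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    score=score,
                    name=f"{chrom}_{start}_{end}",
                )
            )
    return peaks


def classify_peaks(
    wt_peaks: Sequence[Peak],
    mut_peaks: Sequence[Peak],
    min_score_ratio: float = 0.0,
) -> PeakClassification:
    """Partition WT and mutant peak sets into shared and specific peaks.

    "Same locus" means >= 1 bp overlap. A WT peak overlapping any mutant
    peak is shared; otherwise WT-specific. Mutant peaks with no WT overlap
    are mutant-specific. With ``min_score_ratio`` > 0, a WT peak whose
    score exceeds the best overlapping mutant peak's score by at least that
    factor is reclassified WT-specific despite the overlap — a coarse
    approximation of calling peaks with the mutant sample as background.
    """
    hits = find_overlaps(wt_peaks, mut_peaks)
    shared: List[Peak] = []
    wt_specific: List[Peak] = []
    for i, peak in enumerate(wt_peaks):
        partners = hits.get(i)
        if not partners:
            wt_specific.append(peak)
            continue
        if min_score_ratio > 0:
            best_mut = max(mut_peaks[j].score for j in partners)
            if best_mut > 0 and peak.score / best_mut >= min_score_ratio:
                wt_specific.append(peak)
                continue
        shared.append(peak)
    wt_hit = overlaps_any(mut_peaks, wt_peaks)
    shared_mut = [p for p, h in zip(mut_peaks, wt_hit) if h]
    mut_specific = [p for p, h in zip(mut_peaks, wt_hit) if not h]
    return PeakClassification(
        shared=tuple(shared),
        wt_specific=tuple(wt_specific),
        mut_specific=tuple(mut_specific),
        shared_mut=tuple(shared_mut),
    )


def peak_turnover(
    peaks_t0: Sequence[Peak],
    peaks_t48: Sequence[Peak],
    anchor_peaks: Sequence[Peak] = (),
    flank_bp: int = 0,
) -> Tuple[List[Peak], List[Peak], int]:
    """Peak appearance/disappearance between two time points.

    Returns (novel, lost, novel_near_anchor): novel = t48 peaks with no t0
    overlap, lost = t0 peaks with no t48 overlap, and the count of novel
    peaks overlapping anchor peaks extended by ``flank_bp`` per side.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    novel = [p for p, h in zip(peaks_t48, overlaps_any(peaks_t48, peaks_t0)) if not h]
    lost = [p for p, h in zip(peaks_t0, overlaps_any(peaks_t0, peaks_t48)) if not h]
    if anchor_peaks:
        extended = [
            Peak(p.interval.extended(flank_bp), p.score, p.name) for p in anchor_peaks
        ]
        near = sum(overlaps_any(novel, extended))
    else:
        near = 0
    return novel, lost, near
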