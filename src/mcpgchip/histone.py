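"""Control-normalized histone-mark signal dynamics around binding peaks.

Signal regions are +/-1 kb around peak midpoints; controls sit 4-6 kb
outside peak boundaries (dropped when they run off the chromosome start
or touch any peak). Region signal is log2 RPM with a one-read pseudocount;
the 48h-vs-0h delta is centred by the control-set median so that controls
split 50% up / 50% down, and the direction imbalance of the target
regions is scored with exact Binomial(n, 1/2) statistics — both the point
mass at the observed count and the orthodox one-sided tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak, as_interval, overlaps_any


@dataclass(frozen=True)
class RegionSignal:
    """log2-RPM signal of one region at two time points.

    ``delta`` is exactly rpm_log2_t48 - rpm_log2_t0; ``delta_norm`` is
    delta minus the run's control-median shift (the same shift for every
    region of a run).
    """

    region: GenomicInterval
    rpm_log2_t0: float
    rpm_log2_t48: float
    delta: float
    delta_norm: float


@dataclass(frozen=True)
class DirectionStats:
    """Direction imbalance of normalized deltas under a fair-coin null.

    Ties (delta_norm == 0) are excluded from k_up/k_down but kept in n.
    p_up/p_down are Binomial(n, 0.5) point masses at the observed counts;
    tail_up/tail_down the corresponding one-sided upper tails.
    """

    n: int
    k_up: int
    k_down: int
    frac_up: float
    frac_down: float
    p_up: float
    p_down: float
    tail_up: float
    tail_down: float


def build_signal_regions(
    peaks: Sequence["Peak | GenomicInterval"], half_width: int = 1000
) -> List[GenomicInterval]:
    """+/-half_width windows around peak floor-midpoints, clamped at 0."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    regions = []
    for item in peaks:
        iv = as_interval(item)
        mid = iv.midpoint
        regions.append(
            GenomicInterval(iv.chrom, max(0, mid - half_width), mid + half_width)
        )
    return regions


def build_control_regions(
    peaks: Sequence["Peak | GenomicInterval"],
    near_bp: int = 4000,
    far_bp: int = 6000,
) -> List[GenomicInterval]:
    """Flanking control regions: [start-far, start-near) and [end+near, end+far).

    Controls that would extend below position 0 are dropped (not
    truncated), and controls overlapping any peak are removed so that no
    control carries bound-region signal.
    """
    if not far_bp > near_bp >= 0:
        raise ValueError("need far_bp > near_bp >= 0")
    candidates: List[GenomicInterval] = []
    for item in peaks:
        iv = as_interval(item)
        if iv.start - far_bp >= 0:
            candidates.append(GenomicInterval(iv.chrom, iv.start - far_bp, iv.start - near_bp))
        candidates.append(GenomicInterval(iv.chrom, iv.end + near_bp, iv.end + far_bp))
    hit = overlaps_any(candidates, list(peaks))
    return [c for c, h in zip(candidates, hit) if not h]


def count_overlapping_reads(
    reads: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-region count of reads overlapping it by >=1 bp (reads unstranded).

    Uses the identity #overlaps = #(read.start < region.end) -
    #(read.end <= region.start) on per-chromosome sorted endpoints.
    """
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs)
        starts[chrom] = np.sort(arr[:, 0])
        ends[chrom] = np.sort(arr[:, 1])
    out = np.zeros(len(regions), dtype=int)
    for i, region in enumerate(regions):
        s = starts.get(region.chrom)
        if s is None:
            continue
        e = ends[region.chrom]
        out[i] = np.searchsorted(s, region.end, side="left") - np.searchsorted(
            e, region.start, side="right"
        )
    return out


def region_rpm(
    count: int, total_reads: int, pseudocount: int = 1
) -> float:
    """log2 reads-per-million of a region: log2((c + pseudo)/total * 1e6)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return math.log2((count + pseudocount) / total_reads * 1_000_000)


def region_signals(
    reads_t0: Sequence[GenomicInterval],
    reads_t48: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    pseudocount: int = 1,
) -> List[RegionSignal]:
    """log2-RPM at both time points per region; deltas not yet normalized."""
    if not reads_t0 or not reads_t48:
        raise ValueError("read sets must be non-empty")
    c0 = count_overlapping_reads(reads_t0, regions)
    c48 = count_overlapping_reads(reads_t48, regions)
    t0_total, t48_total = len(reads_t0), len(reads_t48)
    out = []
    for region, a, b in zip(regions, c0, c48):
        r0 = region_rpm(int(a), t0_total, pseudocount)
        r48 = region_rpm(int(b), t48_total, pseudocount)
        out.append(RegionSignal(region, r0, r48, r48 - r0, r48 - r0))
    return out


def lower_median(values: Sequence[float]) -> float:
    """Median with the lower-median convention for even-length input."""
    s = sorted(values)
    if not s:
        raise ValueError("empty input")
    return s[(len(s) - 1) // 2]


def normalize_deltas(
    target_deltas: Sequence[float],
    control_deltas: Sequence[float],
) -> Tuple[np.ndarray, float]:
    """Centre deltas by the control median so controls split 50% up / 50% down.

    Returns (normalized target deltas, shift). The shift is the lower
    median of the control deltas; after subtraction the control up and
    down counts differ by at most the number of ties with the median.
    """
    if len(control_deltas) == 0:
        raise ValueError("control delta set must be non-empty")
    shift = lower_median(control_deltas)
    return np.asarray(target_deltas, dtype=float) - shift, shift


def apply_shift(signals: Sequence[RegionSignal], shift: float) -> List[RegionSignal]:
    """Rewrite delta_norm = delta - shift on a list of RegionSignals."""
    return [
        RegionSignal(s.region, s.rpm_log2_t0, s.rpm_log2_t48, s.delta, s.delta - shift)
        for s in signals
    ]


def binom_point_mass(k: int, n: int) -> float:
    """Binomial(n, 1/2) point probability at k, in float precision."""
    return float(stats.binom.pmf(k, n, 0.5))


def direction_stats(delta_norm: Sequence[float]) -> DirectionStats:
    """Direction imbalance of a delta set under the fair-coin null."""
    arr = np.asarray(delta_norm, dtype=float)
    n = len(arr)
    if n < 1:
        raise ValueError("need at least one region")
    k_up = int((arr > 0).sum())
    k_down = int((arr < 0).sum())
    return DirectionStats(
        n=n,
        k_up=k_up,
        k_down=k_down,
        frac_up=k_up / n,
        frac_down=k_down / n,
        p_up=binom_point_mass(k_up, n),
        p_down=binom_point_mass(k_down, n),
        tail_up=float(stats.binom.sf(k_up - 1, n, 0.5)),
        tail_down=float(stats.binom.sf(k_down - 1, n, 0.5)),
    )


def signal_table(signals: Sequence[RegionSignal]):
    """RegionSignal list -> tidy DataFrame for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [s.region.chrom for s in signals],
            "start": [s.region.start for s in signals],
            "end": [s.region.end for s in signals],
            "rpm_log2_t0": [s.rpm_log2_t0 for s in signals],
            "rpm_log2_t48": [s.rpm_log2_t48 for s in signals],
            "delta": [s.delta for s in signals],
            "delta_norm": [s.delta_norm for s in signals],
        }
    )


def heatmap_matrix(
    reads: Sequence[GenomicInterval],
    anchors: Sequence["Peak | GenomicInterval"],
    half_width: int = 3000,
    n_bins: int = 60,
) -> np.ndarray:
    """Regions x position-bins read-count matrix around anchor midpoints.

    The metaregion view behind signal heatmaps: row i, column j holds the
    read count in the j-th bin of the +/-half_width window around anchor
    i's midpoint. Export as plain TSV for rendering.
    """
    bin_w = (2 * half_width) // n_bins
    if bin_w < 1:
        raise ValueError("n_bins too large for the window")
    mat = np.zeros((len(anchors), n_bins), dtype=int)
    for i, item in enumerate(anchors):
        iv = as_interval(item)
        mid = iv.midpoint
        bins = [
            GenomicInterval(iv.chrom, max(0, mid - half_width + j * bin_w),
                            max(1, mid - half_width + (j + 1) * bin_w))
            for j in range(n_bins)
        ]
        mat[i] = count_overlapping_reads(reads, bins)
    return mat
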