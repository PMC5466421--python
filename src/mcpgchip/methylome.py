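"""Per-CpG beta values and region-level methylation summaries.

beta for one CpG site is the fraction of bisulfite reads reporting
methylation: n_meth / (n_meth + n_unmeth). Regions (ChIP peaks,
cis-regulatory elements) are summarized by the mean beta of contained
CpGs and called "highly methylated" when that mean exceeds a threshold
(0.6 by convention here). An alternative any-CpG criterion is available
because region-level "beta > 60%" admits both readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak, as_interval
from .io import CpGSite


@dataclass(frozen=True)
class RegionMethylation:
    """Methylation summary of one region.

    ``mean_beta`` is None when no eligible CpG falls in the region
    (n_cpg == 0), and ``high`` is then False.
    """

    region: GenomicInterval
    n_cpg: int
    mean_beta: Optional[float]
    high: bool

    def __post_init__(self) -> None:
        if self.n_cpg == 0 and (self.mean_beta is not None or self.high):
            raise ValueError("regions without CpGs must have mean_beta=None, high=False")
        if self.mean_beta is not None and not (0.0 <= self.mean_beta <= 1.0):
            raise ValueError(f"mean_beta out of [0,1]: {self.mean_beta}")


@dataclass
class CloneMatrix:
    """Sanger bisulfite clones: rows = clones, columns = CpG sites, entries 0/1."""

    rows: List[List[int]]
    site_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("ragged clone matrix: all clones must cover the same sites")
            if any(e not in (0, 1) for r in self.rows for e in r):
                raise ValueError("clone matrix entries must be 0 or 1")
            if self.site_labels is not None and len(self.site_labels) != width:
                raise ValueError("site_labels length mismatch")

    @property
    def n_clones(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def compute_beta(n_meth: int, n_unmeth: int) -> float:
    """Methylation level of one CpG: n_meth / (n_meth + n_unmeth).

    Raises on zero coverage — callers must filter uncovered sites.
    """
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError("read counts must be non-negative")
    total = n_meth + n_unmeth
    if total == 0:
        raise ValueError("beta undefined at zero coverage")
    return n_meth / total


def region_methylation(
    regions: Sequence["GenomicInterval | Peak"],
    cpgs: Sequence[CpGSite],
    min_coverage: int = 1,
    beta_threshold: float = 0.6,
    criterion: str = "mean",
) -> List[RegionMethylation]:
    """Summarize methylation of each region from covered CpGs inside it.

    A CpG belongs to a region when its (0-based) cytosine position lies in
    the half-open span. ``criterion='mean'`` calls a region high when the
    mean beta exceeds the threshold; ``criterion='any'`` when any single
    contained CpG does.
    """
    if not (0.0 < beta_threshold < 1.0):
        raise ValueError("beta_threshold must be in (0,1)")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if criterion not in ("mean", "any"):
        raise ValueError("criterion must be 'mean' or 'any'")

    by_chrom: dict = {}
    for s in cpgs:
        if s.coverage >= min_coverage:
            by_chrom.setdefault(s.chrom, []).append((s.pos0, s.beta))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    pos_arrays = {
        chrom: (np.array([p for p, _ in lst]), np.array([b for _, b in lst]))
        for chrom, lst in by_chrom.items()
    }

    out: List[RegionMethylation] = []
    for item in regions:
        region = as_interval(item)
        entry = pos_arrays.get(region.chrom)
        if entry is None:
            out.append(RegionMethylation(region, 0, None, False))
            continue
        pos, betas = entry
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi <= lo:
            out.append(RegionMethylation(region, 0, None, False))
            continue
        sel = betas[lo:hi]
        mean_beta = float(sel.mean())
        if criterion == "mean":
            high = mean_beta > beta_threshold
        else:
            high = bool((sel > beta_threshold).any())
        out.append(RegionMethylation(region, int(hi - lo), mean_beta, high))
    return out


def high_methylation_fraction(region_meth: Sequence[RegionMethylation]) -> float:
    """Fraction of CpG-containing regions called highly methylated.

    The denominator is regions with n_cpg > 0: regions without any covered
    CpG carry no methylation information and are excluded rather than
    counted as unmethylated.
    """
    informative = [r for r in region_meth if r.n_cpg > 0]
    if not informative:
        raise ValueError("no region contains a covered CpG")
    return sum(r.high for r in informative) / len(informative)


def compare_methylation_fractions(
    count_high_a: int, n_a: int, count_high_b: int, n_b: int
) -> Tuple[float, float, float]:
    """Two-sided Fisher exact comparison of two high-methylation fractions.

    Returns (fraction_a, fraction_b, p). The 2x2 table is
    [[high_a, low_a], [high_b, low_b]]; the two-sided p sums all tables
    with point probability <= that of the observed table.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("totals must be positive")
    if count_high_a > n_a or count_high_b > n_b:
        raise ValueError("high counts cannot exceed totals")
    table = [[count_high_a, n_a - count_high_a], [count_high_b, n_b - count_high_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return count_high_a / n_a, count_high_b / n_b, float(p)


def clone_matrix_methylation(matrix: CloneMatrix) -> List[float]:
    """Per-CpG-site percent methylation across sequenced clones.

    100 x (methylated clones) / (total clones) for each column.
    """
    if matrix.n_clones == 0:
        raise ValueError("clone matrix must contain at least one clone")
    arr = np.asarray(matrix.rows, dtype=float)
    return [float(x) for x in 100.0 * arr.mean(axis=0)]


def region_methylation_table(region_meth: Sequence[RegionMethylation]):
    """RegionMethylation list -> tidy DataFrame for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in region_meth],
            "start": [r.region.start for r in region_meth],
            "end": [r.region.end for r in region_meth],
            "n_cpg": [r.n_cpg for r in region_meth],
            "mean_beta": [r.mean_beta if r.mean_beta is not None else float("nan") for r in region_meth],
            "high": [r.high for r in region_meth],
        }
    )
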