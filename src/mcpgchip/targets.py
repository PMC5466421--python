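"""Peak-to-gene assignment and direct-target statistics.

A binding peak is tied to a gene either proximally — it overlaps the
gene's 5'UTR, an exon, or a strand-aware window up to 10 kb upstream of
the TSS — or distally through a precomputed enhancer->gene link table.
Direct targets are genes that are up-regulated only upon wild-type factor
induction and carry at least one factor-specific peak by either route.
Association strength is scored hypergeometrically against the expressed
universe; gene-set (GO-style) enrichment and the demethylating-agent
(5-Aza) reversal statistic complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, Peak, find_overlaps
from .io import EnhancerLink, GeneModel

# proximal categories outrank the enhancer route; within proximal,
# annotation specificity decides
CATEGORY_PRECEDENCE = ("utr5", "exon", "upstream", "enhancer")


@dataclass(frozen=True)
class Assignment:
    """One peak-to-gene association with its regulatory category."""

    peak_name: str
    gene_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PRECEDENCE:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class TargetGene:
    """A direct target: an up-regulated gene supported by >=1 specific peak."""

    gene_id: str
    peaks: Tuple[str, ...]
    category: str
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a target gene needs at least one supporting peak")
        if self.category not in CATEGORY_PRECEDENCE:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 association of peak-assigned genes with up-regulated genes.

    k: assigned & up; n: assigned & expressed; K: up & expressed;
    N: expressed universe. fold_enrichment = (k/n)/(K/N); p is the
    hypergeometric upper tail P(X >= k).
    """

    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p: float

    @property
    def fold_display(self) -> float:
        """Fold enrichment rounded to one decimal for reporting."""
        return round(self.fold_enrichment, 1)


def upstream_window(gene: GeneModel, upstream_bp: int = 10000) -> GenomicInterval | None:
    """Strand-aware upstream window of the TSS, 0-based half-open.

    For + genes: [tss - upstream_bp, tss); for - genes the window lies
    beyond the span end: [tss + 1, tss + 1 + upstream_bp). Clamped at 0;
    None when the clamped window is empty.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = max(0, tss - upstream_bp), tss
    else:
        start, end = tss + 1, tss + 1 + upstream_bp
    if end <= start:
        return None
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


def classify_proximal(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    upstream_bp: int = 10000,
) -> List[Assignment]:
    """Assign peaks to genes through proximal regulatory regions.

    A peak-gene pair gets one category by precedence utr5 > exon >
    upstream when several features of the same gene are hit; a peak may
    hit several genes (one assignment each).
    """
    features: List[GenomicInterval] = []
    feature_meta: List[Tuple[str, str]] = []  # (gene_id, category)
    for gene in gene_models:
        for utr in gene.utr5:
            features.append(utr)
            feature_meta.append((gene.gene_id, "utr5"))
        for exon in gene.exons:
            features.append(exon)
            feature_meta.append((gene.gene_id, "exon"))
        window = upstream_window(gene, upstream_bp)
        if window is not None:
            features.append(window)
            feature_meta.append((gene.gene_id, "upstream"))

    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    best: Dict[Tuple[str, str], str] = {}
    for i, js in find_overlaps(peaks, features).items():
        for j in js:
            gene_id, category = feature_meta[j]
            key = (peaks[i].name, gene_id)
            if key not in best or rank[category] < rank[best[key]]:
                best[key] = category
    return sorted(
        (Assignment(peak, gene, cat) for (peak, gene), cat in best.items()),
        key=lambda a: (a.gene_id, a.peak_name),
    )


def link_enhancer_targets(
    peaks: Sequence[Peak],
    enhancer_links: Sequence[EnhancerLink],
) -> List[Assignment]:
    """Assign peaks to genes through enhancer->gene links.

    A peak is linked to gene G when it overlaps any enhancer interval
    mapped to G; a peak overlapping several enhancers of one gene yields a
    single (peak, gene) assignment.
    """
    enh_intervals = [link.enhancer for link in enhancer_links]
    pairs: Set[Tuple[str, str]] = set()
    for i, js in find_overlaps(peaks, enh_intervals).items():
        for j in js:
            pairs.add((peaks[i].name, enhancer_links[j].gene_id))
    return sorted(
        (Assignment(peak, gene, "enhancer") for peak, gene in pairs),
        key=lambda a: (a.gene_id, a.peak_name),
    )


def wt_only_upregulated(
    deg_wt: pd.DataFrame,
    deg_mut: pd.DataFrame,
    p_threshold: float = 0.001,
) -> Set[str]:
    """Genes significantly up in the WT arm and not significant in the mutant arm.

    Both tables need gene_id, log2fc, p columns. Significance in the
    mutant arm in either direction removes a gene (its regulation does not
    require the methyl-binding activity).
    """
    sig_wt_up = set(
        deg_wt.loc[(deg_wt["p"] < p_threshold) & (deg_wt["log2fc"] > 0), "gene_id"]
    )
    sig_mut = set(deg_mut.loc[deg_mut["p"] < p_threshold, "gene_id"])
    return sig_wt_up - sig_mut


def identify_direct_targets(
    assignments: Iterable[Assignment],
    up_wt_only: Set[str],
) -> List[TargetGene]:
    """Intersect peak-assigned genes with WT-only up-regulated genes.

    A gene's category is the best (by precedence) over its supporting
    assignments, so a gene reached both proximally and through an enhancer
    is counted once, under the proximal category.
    """
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    by_gene: Dict[str, List[Assignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)
    targets = []
    for gene_id in sorted(by_gene):
        if gene_id not in up_wt_only:
            continue
        assigns = by_gene[gene_id]
        category = min((a.category for a in assigns), key=rank.__getitem__)
        peaks = tuple(sorted({a.peak_name for a in assigns}))
        targets.append(TargetGene(gene_id, peaks, category))
    return targets


def category_counts(targets: Sequence[TargetGene]) -> Dict[str, int]:
    counts = {c: 0 for c in CATEGORY_PRECEDENCE}
    for t in targets:
        counts[t.category] += 1
    return counts


def target_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Hypergeometric enrichment of up-regulation among peak-assigned genes."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent 2x2 composition k={k} n={n} K={K} N={N}")
    if n == 0 or K == 0:
        raise ValueError("empty margin: n and K must be positive")
    fold = (k / n) / (K / N)
    p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k=k, n=n, K=K, N=N, fold_enrichment=fold, p=p)


def gene_set_enrichment(
    targets: Set[str],
    gene_sets: Mapping[str, Set[str]],
    universe: Set[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric gene-set over-representation with BH-FDR.

    Sets are intersected with the universe; targets outside the universe
    are ignored. Returns a DataFrame (set, k, K, p, fdr, significant)
    sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    targets = targets & universe
    names, ks, Ks, ps = [], [], [], []
    N, n = len(universe), len(targets)
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        k = len(members & targets)
        K = len(members)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        ks.append(k)
        Ks.append(K)
        ps.append(p)
    if names:
        _, fdr, _, _ = multipletests(ps, method="fdr_bh")
    else:
        fdr = []
    df = pd.DataFrame(
        {"set": names, "k": ks, "K": Ks, "n": n, "N": N, "p": ps, "fdr": fdr}
    )
    df["significant"] = df["fdr"] < fdr_threshold
    return df.sort_values("p", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class AzaReversal:
    """Demethylating-agent reversal of induction among target genes.

    For each gene, induction fold change FC = fpkm(t48)/fpkm(t0) within
    the untreated and the 5-Aza arm; a gene is "reduced" when
    dFC = FC_aza - FC_untreated < 0. p is the one-sided exact binomial
    tail of seeing >= k_targets reduced among n_targets when each is
    reduced with the universe probability.
    """

    n_targets: int
    k_targets_reduced: int
    frac_targets_reduced: float
    frac_universe_reduced: float
    p: float


def aza_reversal_stats(
    expr: pd.DataFrame,
    targets: Set[str],
    expressed_universe: Set[str],
    conditions: Tuple[str, str, str, str] = ("t0", "t48", "t0_aza", "t48_aza"),
    mode: str = "delta_fc",
) -> AzaReversal:
    """5-Aza reversal statistic over a 4-condition expression table.

    ``mode='delta_fc'`` compares induction fold changes across arms
    (reduced <=> FC_aza < FC_untreated); ``mode='t48_ratio'`` compares the
    induced levels directly (reduced <=> fpkm(t48_aza) < fpkm(t48)).
    Genes with zero baseline in either arm are excluded (FC undefined).
    """
    for cond in conditions:
        if cond not in expr.columns:
            raise KeyError(f"expression table lacks condition column {cond!r}")
    if mode not in ("delta_fc", "t48_ratio"):
        raise ValueError("mode must be 'delta_fc' or 't48_ratio'")
    t0, t48, t0_aza, t48_aza = conditions
    sub = expr.loc[expr.index.isin(expressed_universe), list(conditions)]
    if mode == "delta_fc":
        sub = sub[(sub[t0] > 0) & (sub[t0_aza] > 0)]
        dfc = sub[t48_aza] / sub[t0_aza] - sub[t48] / sub[t0]
        reduced = dfc < 0
    else:
        reduced = sub[t48_aza] < sub[t48]
    if len(reduced) == 0:
        raise ValueError("no genes with defined fold changes in the universe")
    q = float(reduced.mean())
    in_targets = reduced.index.isin(targets)
    n_t = int(in_targets.sum())
    if n_t == 0:
        raise ValueError("no target genes with defined fold changes")
    k_t = int(reduced[in_targets].sum())
    p = float(stats.binom.sf(k_t - 1, n_t, q))
    return AzaReversal(
        n_targets=n_t,
        k_targets_reduced=k_t,
        frac_targets_reduced=k_t / n_t,
        frac_universe_reduced=q,
        p=p,
    )


def naive_deg_caller(
    expr: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    count_scale: float = 10.0,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Crude differential-expression plumbing: |log2FC| + Fisher on scaled counts.

    FPKMs are scaled to pseudo-counts; each gene's (a, b) counts are
    tested against the library totals with a two-sided Fisher exact test.
    Returns gene_id, log2fc, p — only a stand-in to close the loop on
    simulated tables, not a serious DE method.
    """
    ca = np.round(expr[cond_a].to_numpy() * count_scale).astype(np.int64)
    cb = np.round(expr[cond_b].to_numpy() * count_scale).astype(np.int64)
    ta, tb = int(ca.sum()), int(cb.sum())
    log2fc = np.log2((cb + 1) / (ca + 1))
    ps = np.ones(len(expr))
    big = np.abs(log2fc) >= min_abs_log2fc  # skip the exact test where FC is flat
    for i in np.flatnonzero(big):
        _, ps[i] = stats.fisher_exact([[ca[i], ta - ca[i]], [cb[i], tb - cb[i]]])
    return pd.DataFrame({"gene_id": expr.index, "log2fc": log2fc, "p": ps}).reset_index(
        drop=True
    )
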