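# Methods

`mcpgchip` re-implements, as a tested library plus CLI, the computational
chain by which genes directly transactivated through methyl-CpG-dependent
transcription-factor (TF) binding are identified: a wild-type (WT) TF that
reads methylated CpG is compared against a methyl-binding-deficient point
mutant across ChIP peak sets, a whole-genome bisulfite methylome, RNA
expression under four conditions, enhancer–gene links and histone-mark
read sets. This note records the model behind each stage, the parameters
that matter, what the synthetic data does and does not emulate, and the
numerical conventions chosen where the procedure admitted more than one
reading.

## Coordinate and data model

All internal coordinates are 0-based half-open (BED convention); 1-based
cytosine reports are converted on load. Overlap always means ≥ 1 shared
bp — intervals sharing only a boundary do not overlap. Chromosome names
are matched by exact string equality; no "chr" aliasing is performed, and
a validation pass warns about names present in only some inputs, because
silent aliasing hides real input errors.

The per-CpG methylation level is the bisulfite β value,

    β = n_meth / (n_meth + n_unmeth),

defined only at positive coverage. Sites on either strand vote for their
CG dinucleotide: a minus-strand cytosine maps to the CG starting one bp
earlier in plus coordinates.

## Peak classification

Peaks found in both the WT and mutant samples at the same locus are
*shared*; WT peaks with no mutant overlap are *WT-specific* (the
methyl-dependent binding events), and symmetrically for the mutant.
"Same locus" is implemented as ≥ 1 bp overlap — the minimal reproducible
rule — and the partition property |WT| = |shared| + |WT-specific| holds by
construction. The original analysis derived WT-specific peaks by
re-calling peaks with the mutant sample as background and subtracting
shared ones; at desk scale we classify purely by overlap, with an
optional score-ratio filter (`min_score_ratio`) as a coarse surrogate for
background-aware calling. The bundled Poisson window caller
(`call_peaks_poisson`) is plumbing, not a MACS replacement: fixed
non-overlapping windows, one global λ = reads × window / genome length,
upper-tail Poisson test, adjacent significant windows merged across gaps
of ≤ 1 window so single binding events do not fragment. It has no local
λ, duplicate handling or shift estimation.

## Region methylation

A region's methylation summary is the mean β over contained CpGs with
coverage ≥ `min_coverage` (default 1 — no coverage filter), and the
region is *highly methylated* when that mean exceeds `beta_threshold`
(default 0.6). Because a region-level "β > 60%" criterion also admits an
any-single-CpG reading, that alternative is available via
`criterion="any"`; the mean is the default as the conventional region
summary. Regions containing no covered CpG are reported with n_cpg = 0
and excluded from the high-methylation fraction's denominator — they
carry no information either way. Two high-methylation fractions are
compared with a two-sided Fisher exact test (sum of tables with point
probability ≤ observed).

## Methylated k-mer enrichment

For each peak, every k-window (k = 6) of its sequence that fully contains
a methylated CG (β > 0.6, strictly) contributes its k-mer; the reverse
complement of each window is recorded too, and k-mers are *not* collapsed
with their reverse complements, because the motif of interest (CCCGCC) is
strand-asymmetric. Presence is binary per peak: the hypergeometric null
treats the foreground as an unordered draw of peaks from all peaks, so a
k-mer present in K of N peaks and x of the n foreground peaks scores
p = P(X ≥ x | N, K, n). Bonferroni multiplies by the number of distinct
methylated k-mers observed in the background — only enumerated hypotheses
are corrected for, not all 4^k strings. An occurrence-count mode is
deliberately not implemented for this statistic because the sampling unit
of the null is the peak.

Selected k-mers (adjusted p < 0.01) are stacked into a position weight
matrix aligned on their first CG, each weighted by its foreground peak
count; column information content is 2 + Σ f log₂ f bits. The alignment
rule (CG anchoring) is our choice; no stacking rule was prescribed.

## Target assignment

A peak is tied to a gene proximally when it overlaps the gene's 5′UTR, an
exon, or a strand-aware upstream window of exactly 10,000 bp
(configurable) ending at the TSS; for minus-strand genes the window lies
beyond the span end. When several features of one gene are hit, one
category is assigned by precedence utr5 > exon > upstream (specificity
order; the source analysis reports disjoint categories without stating a
rule). The distal route consumes a precomputed enhancer→gene link table;
a gene reached both ways is counted once under its proximal category, so
enhancer-only genes are genuinely "additional".

Direct targets are genes (i) significantly up-regulated upon WT induction
but not significant in the mutant arm (p < 0.001 in the supplied DEG
tables), and (ii) supported by ≥ 1 WT-specific peak by either route.
Association strength is the hypergeometric upper tail of the 2×2
composition (targets k, assigned-and-expressed n, up-and-expressed K,
expressed universe N; FPKM > 0.5 defines "expressed"), with fold
enrichment (k/n)/(K/N) displayed to one decimal. The tail convention of
the printed significance in the source could not be pinned down, so the
one-sided upper tail is reported and no equality with the printed p is
asserted. Gene-set (GO-style) enrichment uses the same hypergeometric
tail per set with Benjamini–Hochberg FDR across sets (significant:
FDR < 0.05).

### Demethylation (5-Aza) reversal

Per gene, the induction fold change FC = FPKM(t48)/FPKM(t0) is computed
within the untreated and the 5-Aza arm; a gene is *reduced* when
ΔFC = FC_aza − FC_untreated < 0 (the histogram-of-ΔFC reading of the
source figure). An alternative reading — induced levels compared directly,
FPKM(t48_aza) < FPKM(t48) — is available via `mode="t48_ratio"`. The
reported p is the one-sided exact binomial tail of observing ≥ k reduced
targets among n when each is reduced with the universe probability q.

## Histone dynamics

Signal regions are ±1 kb around peak floor-midpoints (clamped at 0).
Controls are [start−6 kb, start−4 kb) and [end+4 kb, end+6 kb) per peak;
controls running past the chromosome start are dropped (not truncated),
and controls overlapping any peak are removed. Region signal is
log₂ RPM with a one-read pseudocount so the zero-count value is finite:
log₂((c + 1)/total × 10⁶). The 48 h − 0 h delta is centred by the control
median (lower-median convention for even counts), which realizes the
"controls split 50% up / 50% down" normalization; adding a constant to
every delta leaves normalized values unchanged.

Direction imbalance is scored two ways under Binomial(n, ½): the point
probability at the observed count — which is what the three reference
direction significances correspond to, a fact we confirmed with exact
big-integer arithmetic before adopting it — and the orthodox one-sided
tail, co-reported. Ties (delta exactly 0) are excluded from the up/down
counts but kept in n.

## Synthetic data

The generators are pure functions of (seed, parameters); one global seed
fans out to fixed per-stream child seeds, so every output file is
byte-reproducible. Default conditions (the simulated "study"):

| parameter | default | why |
|---|---|---|
| genome | 2 chromosomes × 1 Mb, GC 0.41 | mammalian-like GC; full run < 2 min on one CPU |
| peaks | 120 WT-specific, 120 shared, 40 mutant-specific, 400 bp | desk-scale mirror of a 70/30 specific/shared split |
| motif | CCCGCC spliced into 66% of WT-specific peaks | matches the 66% high-methylation fraction of specific peaks |
| methylome | β = 0.9 in high peaks (counts 9/1), 0.2 elsewhere (2/8), coverage 10 | β realized as integer count pairs so `compute_beta` reproduces it exactly |
| shared peaks | 36% highly methylated, no motif | mirrors the 36% fraction of shared peaks |
| targets | 30 genes; category mix 20/24/12/44% (upstream/5′UTR/exon/enhancer) | the reported category split |
| expression | 3000 genes, log-normal(μ=1, σ=1.2) FPKM, 4× induction, 5-Aza attenuation 0.25, 5% multiplicative noise | planted targets keep ≥ 2 FPKM baseline so the stand-in DEG caller cannot miss them |
| histone | depth 50 reads/region, 20k background reads; H3K27ac 4× up at 83.3% of target regions, H3K27me3 0.5× at 54.3%, H3K9me3 0.5× at 63.6% | direction structure of the three marks |

Layout is rejection sampling over per-chromosome interval trees with a
500 bp margin; each modeled gene reserves its body *plus its full 10 kb
upstream window* so no later entity can stray into the window and create
an unplanned proximal assignment. Planted decoys exercise the filters:
up-regulated WT-only genes with no peak (must not become targets) and
genes up-regulated in both arms with a WT-specific peak upstream (must be
excluded by the WT-only filter). Shared loci appear with identical
coordinates in both peak sets, so overlap classification recovers the
planted partition exactly.

What the simulation does **not** emulate: realistic fragment-length and
duplicate structure, bisulfite conversion error, CHG/CHH contexts,
chromatin-state spatial autocorrelation, mapping bias, or biological
correlation between methylation and expression beyond the planted
effects. Passing closed-loop tests therefore demonstrates that the
*analysis chain* is internally correct and recovers planted structure
under its own assumptions — not that it would behave identically on real
sequencing data.

## Numerical choices and degenerate inputs

- Exact tests go through scipy (`hypergeom`, `fisher_exact`, `binom`,
  `poisson`); tests verify them against brute-force support enumeration in
  exact rational arithmetic for all problem sizes up to N = 60 (and
  n = 200 for the binomial point masses).
- β at zero coverage, RPM at zero total reads, fractions over empty
  denominators, and empty control sets raise errors rather than return
  sentinels; regions without CpGs are flagged, not silently averaged.
- Peak midpoints use floor division; upstream windows clamp at 0; the
  Bonferroni product clips at 1.
- The flanking-control example geometry worth noting: with 4–6 kb flanks,
  an inner control can only collide with a neighbouring peak closer than
  6 kb + flank width; isolated peaks contribute exactly two controls.

## Known limitations

- The stand-in peak caller and DEG caller are deliberately naive; both
  are plumbing for the simulation, clearly separated from the statistics
  the package exists for.
- WT-specific classification by pure non-overlap is a simplification of
  background-aware re-calling; on real data the two differ for weak
  shared peaks.
- Enhancer–gene links are consumed, never predicted.
- The genome-scale counts of any particular study depend on its raw data
  and are not reproduced here; the package reproduces the *relationships*
  among printed quantities and demonstrates recovery on planted truth.
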