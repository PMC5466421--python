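# mcpgchip

Analysis pipeline for **methyl-CpG-dependent transcription-factor
binding**: given ChIP-seq peak sets for a wild-type (WT) TF that reads
methylated CpG and for a methyl-binding-deficient point mutant, a
whole-genome bisulfite methylome, gene models, expression tables
(± induction, ± the demethylating agent 5-Aza) and histone-mark read
sets, it identifies the genes directly transactivated through
methylation-dependent binding and quantifies the accompanying chromatin
changes.

Intended for computational epigenomics work at "desk scale": every stage
is a plain Python function over explicit data types, and a seeded
synthetic-data generator produces a complete input set with planted
ground truth, so the whole chain is testable end to end without any
sequencing data.

## What it computes

1. **Peak classification** — WT vs mutant peaks partitioned by locus
   overlap into *shared*, *WT-specific* (methyl-dependent binding) and
   *mutant-specific*; plus peak turnover between time points.
2. **Methylome integration** — per-CpG β = n_meth/(n_meth+n_unmeth) from a
   bismark-style cytosine report; per-region mean β; fraction of peaks with
   high methylation (mean β > 0.6) compared between peak classes by
   Fisher's exact test.
3. **Methylated 6-mer enrichment** — k-mers spanning a methylated CpG
   (β > 0.6) counted by peak presence; hypergeometric upper-tail
   p = P(X ≥ x | N, K, n) of foreground presence, Bonferroni-corrected over
   observed k-mers; selected k-mers stacked into a CG-anchored PWM/logo.
4. **Target assignment** — peaks tied to genes via ≤ 10 kb upstream
   windows, 5′UTRs and exons (precedence utr5 > exon > upstream) or via an
   enhancer→gene link table; direct targets = WT-only up-regulated genes
   with ≥ 1 WT-specific peak; fold enrichment (k/n)/(K/N) with
   hypergeometric p; gene-set enrichment with BH-FDR; 5-Aza reversal
   statistic (exact binomial).
5. **Histone dynamics** — log₂ RPM in ±1 kb regions around peak midpoints,
   centred by the median delta of 4–6 kb flanking controls so controls
   split 50% up / 50% down; direction imbalance scored by exact
   Binomial(n, ½) point mass and one-sided tail.

See `docs/methods.md` for the full model, parameter table and
limitations.

## Worked example

Simulate a study and run every stage (shell):

```bash
mcpgchip simulate --seed 1 --out-dir inputs
mcpgchip run-all --input-dir inputs --out-dir results --seed 1
```

or in Python:

```python
from mcpgchip import generate_dataset, run_pipeline
from mcpgchip.pipeline import config_from_manifest

dataset = generate_dataset(seed=1)
manifest = dataset.write("inputs")
report = run_pipeline(config_from_manifest(manifest, "results", seed=1))
```

The run logs one line per stage; with seed 1 it prints:

```
load: 240 WT peaks, 160 mutant peaks, 84108 CpGs, 45 genes, 3000 expression rows
classify_peaks: {'n_wt': 240, 'n_mut': 160, 'n_shared': 120, 'n_wt_specific': 120, 'n_mut_specific': 40}
methylome: high fraction 0.658 (WT-specific) vs 0.358 (shared), p=5.35e-06
motifs: top k-mer CCCGCC (p=6.76e-30), 10 selected
targets: 30 direct targets {'utr5': 7, 'exon': 4, 'upstream': 6, 'enhancer': 13}
histone H3K27ac: frac_up=0.933 (p=4.05e-07) over 30 regions
histone H3K27me3: frac_up=0.200 (p=0.000553) over 30 regions
histone H3K9me3: frac_up=0.167 (p=0.000133) over 30 regions
aza_reversal: 100.0% of targets reduced vs 51.1% of universe (p=1.78e-09)
closed_loop: {'partition_recovered': True, 'planted_motif_rank': 1, 'target_recovery': 1.0, ...}
```

Reading this: the 240 WT peaks split exactly into the 120 planted
WT-specific and 120 shared peaks; 65.8% of WT-specific peaks are highly
methylated versus 35.8% of shared peaks (the planted 66%/36% structure);
the planted methylated motif CCCGCC is the top-ranked 6-mer; all 30
planted target genes are recovered with their planted categories; the
activating mark H3K27ac rises at 93% of target regions while the
repressive marks fall; and induction of every target gene is lost under
demethylation while the expression universe splits ~50/50 — the signature
of methylation-*dependent* activation. `results/report.json` holds every
number, and `results/*.tsv`/`*.bed` the per-stage tables.

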