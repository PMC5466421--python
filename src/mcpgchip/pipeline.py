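"""End-to-end orchestration: config, staged execution, machine-readable report.

Stages run in dependency order — peak classification, methylome
summaries, methylated-motif enrichment, target assignment and enrichment
statistics, histone dynamics, 5-Aza reversal — and every count, fraction
and p-value lands in one JSON report next to per-stage TSV/BED outputs.
A stage failure aborts the run with the stage name and cause; outputs of
completed stages are kept with a failure marker in the report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import histone as hist
from . import io as mio
from . import methylome as meth
from . import motif as mot
from . import peaks as pk
from . import targets as tg
from .intervals import GenomicInterval, validate_chromosomes

logger = logging.getLogger("mcpgchip")


@dataclass
class PipelineConfig:
    """Input paths and analysis parameters; defaults are the study thresholds."""

    wt_peaks: str = ""
    mut_peaks: str = ""
    genome_fasta: str = ""
    cytosine_report: str = ""
    gene_models: str = ""
    expression: str = ""
    deg_wt: str = ""
    deg_mut: str = ""
    enhancer_map: str = ""
    gene_sets: str = ""  # optional GMT
    # mark name -> {"t0": path, "t48": path}
    histone_reads: Dict[str, Dict[str, str]] = field(default_factory=dict)
    truth: str = ""  # optional planted-truth JSON for closed-loop checks
    out_dir: str = "results"
    seed: int = 0

    k: int = 6
    beta_min: float = 0.6
    min_coverage: int = 1
    upstream_bp: int = 10000
    fpkm_min: float = 0.5
    deg_p: float = 0.001
    alpha_bonferroni: float = 0.01
    half_width: int = 1000
    near_bp: int = 4000
    far_bp: int = 6000
    fdr: float = 0.05

    def validate(self) -> None:
        required = {
            "wt_peaks": self.wt_peaks,
            "mut_peaks": self.mut_peaks,
            "genome_fasta": self.genome_fasta,
            "cytosine_report": self.cytosine_report,
            "gene_models": self.gene_models,
            "expression": self.expression,
            "deg_wt": self.deg_wt,
            "deg_mut": self.deg_mut,
            "enhancer_map": self.enhancer_map,
        }
        for key, value in required.items():
            if not value:
                raise ValueError(f"config: missing required input path {key!r}")
            if not Path(value).exists():
                raise FileNotFoundError(f"config: {key} path does not exist: {value}")
        for mark, tp in self.histone_reads.items():
            for t in ("t0", "t48"):
                if t not in tp or not Path(tp[t]).exists():
                    raise FileNotFoundError(f"config: histone {mark} missing {t} reads")
        if not (0 < self.beta_min < 1):
            raise ValueError("beta_min must be in (0,1)")
        if self.k < 2 or self.upstream_bp < 0 or self.half_width <= 0:
            raise ValueError("parameter out of bounds")
        if not self.far_bp > self.near_bp >= 0:
            raise ValueError("need far_bp > near_bp >= 0")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the report dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    if not logger.handlers:
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    report: dict = {"parameters": asdict(config), "stages": {}}
    stage = "load"
    try:
        wt_peaks = mio.load_intervals(config.wt_peaks, kind="peak")
        mut_peaks = mio.load_intervals(config.mut_peaks, kind="peak")
        cpgs = mio.load_cytosine_report(config.cytosine_report)
        genes = mio.load_gene_models(config.gene_models)
        expr = mio.load_expression(config.expression)
        deg_wt = mio.load_deg_table(config.deg_wt)
        deg_mut = mio.load_deg_table(config.deg_mut)
        links = mio.load_enhancer_map(config.enhancer_map)
        genome = mot.load_genome(config.genome_fasta)
        for warning in validate_chromosomes(
            {"wt_peaks": wt_peaks, "mut_peaks": mut_peaks, "genome": [
                GenomicInterval(c, 0, len(s)) for c, s in genome.items()
            ]}
        ):
            logger.warning(warning)
        logger.info(
            "load: %d WT peaks, %d mutant peaks, %d CpGs, %d genes, %d expression rows",
            len(wt_peaks), len(mut_peaks), len(cpgs), len(genes), len(expr),
        )

        # ------------------------------------------------------------------
        stage = "classify_peaks"
        classification = pk.classify_peaks(wt_peaks, mut_peaks)
        mio.write_intervals(classification.shared, out / "peaks_shared.bed")
        mio.write_intervals(classification.wt_specific, out / "peaks_wt_specific.bed")
        mio.write_intervals(classification.mut_specific, out / "peaks_mut_specific.bed")
        summary = classification.summary()
        pd.DataFrame([summary]).to_csv(out / "peak_classification.tsv", sep="\t", index=False)
        report["stages"]["classify_peaks"] = summary
        logger.info("classify_peaks: %s", summary)

        # ------------------------------------------------------------------
        stage = "methylome"
        rm_specific = meth.region_methylation(
            classification.wt_specific, cpgs, config.min_coverage, config.beta_min
        )
        rm_shared = meth.region_methylation(
            classification.shared, cpgs, config.min_coverage, config.beta_min
        )
        frac_specific = meth.high_methylation_fraction(rm_specific)
        frac_shared = meth.high_methylation_fraction(rm_shared)
        n_spec = sum(r.n_cpg > 0 for r in rm_specific)
        n_shar = sum(r.n_cpg > 0 for r in rm_shared)
        _, _, fisher_p = meth.compare_methylation_fractions(
            sum(r.high for r in rm_specific), n_spec, sum(r.high for r in rm_shared), n_shar
        )
        meth.region_methylation_table(rm_specific).to_csv(
            out / "methylation_wt_specific.tsv", sep="\t", index=False
        )
        meth.region_methylation_table(rm_shared).to_csv(
            out / "methylation_shared.tsv", sep="\t", index=False
        )
        report["stages"]["methylome"] = {
            "frac_high_wt_specific": frac_specific,
            "frac_high_shared": frac_shared,
            "fisher_p": fisher_p,
        }
        logger.info(
            "methylome: high fraction %.3f (WT-specific) vs %.3f (shared), p=%.3g",
            frac_specific, frac_shared, fisher_p,
        )

        # ------------------------------------------------------------------
        stage = "motifs"
        all_peaks = list(classification.wt_specific) + list(classification.shared)
        all_sets = mot.extract_methylated_kmers(
            all_peaks, genome, cpgs, k=config.k, beta_min=config.beta_min
        )
        fg_sets = all_sets[: len(classification.wt_specific)]
        stats_list, selected = mot.kmer_enrichment(
            fg_sets, all_sets, alpha=config.alpha_bonferroni
        )
        mot.kmer_stats_table(stats_list).to_csv(out / "kmer_enrichment.tsv", sep="\t", index=False)
        motif_report = {
            "n_kmers_tested": len(stats_list),
            "n_selected": len(selected),
            "top_kmer": stats_list[0].kmer if stats_list else None,
            "top_p": stats_list[0].p if stats_list else None,
        }
        if selected:
            pwm = mot.build_pwm(selected)
            mot.write_meme_minimal(pwm, "methylated_kmer_motif", out / "motif.meme")
            motif_report["pwm_consensus"] = pwm.consensus
        report["stages"]["motifs"] = motif_report
        logger.info("motifs: top k-mer %s (p=%.3g), %d selected",
                    motif_report["top_kmer"], motif_report["top_p"] or 1.0, len(selected))

        # ------------------------------------------------------------------
        stage = "targets"
        proximal = tg.classify_proximal(
            list(classification.wt_specific), genes, config.upstream_bp
        )
        enhancer = tg.link_enhancer_targets(list(classification.wt_specific), links)
        up_wt_only = tg.wt_only_upregulated(deg_wt, deg_mut, config.deg_p)
        direct = tg.identify_direct_targets(list(proximal) + list(enhancer), up_wt_only)
        expressed = set(expr.index[expr.mean(axis=1) > config.fpkm_min])
        assigned = {a.gene_id for a in proximal} | {a.gene_id for a in enhancer}
        k = len({t.gene_id for t in direct} & expressed)
        n = len(assigned & expressed)
        K = len(up_wt_only & expressed)
        N = len(expressed)
        enrichment = tg.target_enrichment(k, n, K, N) if n and K else None
        pd.DataFrame(
            [
                {"gene_id": t.gene_id, "category": t.category, "peaks": ",".join(t.peaks)}
                for t in direct
            ]
        ).to_csv(out / "direct_targets.tsv", sep="\t", index=False)
        targets_report = {
            "n_direct_targets": len(direct),
            "category_counts": tg.category_counts(direct),
            "n_up_wt_only": len(up_wt_only),
            "n_assigned_expressed": n,
            "n_expressed": N,
        }
        if enrichment:
            targets_report["fold_enrichment"] = enrichment.fold_display
            targets_report["enrichment_p"] = enrichment.p
        if config.gene_sets:
            gs = mio.load_gene_sets(config.gene_sets)
            gse = tg.gene_set_enrichment(
                {t.gene_id for t in direct}, gs, expressed, config.fdr
            )
            gse.to_csv(out / "gene_set_enrichment.tsv", sep="\t", index=False)
            targets_report["n_significant_sets"] = int(gse["significant"].sum())
        report["stages"]["targets"] = targets_report
        logger.info("targets: %d direct targets %s", len(direct), targets_report["category_counts"])

        # ------------------------------------------------------------------
        stage = "histone"
        target_peak_names = {name for t in direct for name in t.peaks}
        anchor = [p for p in classification.wt_specific if p.name in target_peak_names]
        histone_report = {}
        if anchor and config.histone_reads:
            regions = hist.build_signal_regions(anchor, config.half_width)
            controls = hist.build_control_regions(
                wt_peaks, config.near_bp, config.far_bp
            )
            for mark in sorted(config.histone_reads):
                tp = config.histone_reads[mark]
                reads_t0 = mio.load_intervals(tp["t0"])
                reads_t48 = mio.load_intervals(tp["t48"])
                signals = hist.region_signals(reads_t0, reads_t48, regions)
                control_signals = hist.region_signals(reads_t0, reads_t48, controls)
                _, shift = hist.normalize_deltas(
                    [s.delta for s in signals], [s.delta for s in control_signals]
                )
                signals = hist.apply_shift(signals, shift)
                stats = hist.direction_stats([s.delta_norm for s in signals])
                hist.signal_table(signals).to_csv(
                    out / f"histone_{mark}_signals.tsv", sep="\t", index=False
                )
                histone_report[mark] = {
                    "n_regions": stats.n,
                    "n_controls": len(controls),
                    "shift": shift,
                    "frac_up": stats.frac_up,
                    "frac_down": stats.frac_down,
                    "p_up": stats.p_up,
                    "p_down": stats.p_down,
                    "tail_up": stats.tail_up,
                    "tail_down": stats.tail_down,
                }
                logger.info(
                    "histone %s: frac_up=%.3f (p=%.3g) over %d regions",
                    mark, stats.frac_up, stats.p_up, stats.n,
                )
        report["stages"]["histone"] = histone_report

        # ------------------------------------------------------------------
        stage = "aza_reversal"
        aza_report = {}
        if {"t0", "t48", "t0_aza", "t48_aza"} <= set(expr.columns) and direct:
            aza = tg.aza_reversal_stats(
                expr, {t.gene_id for t in direct}, expressed
            )
            aza_report = {
                "n_targets": aza.n_targets,
                "frac_targets_reduced": aza.frac_targets_reduced,
                "frac_universe_reduced": aza.frac_universe_reduced,
                "p": aza.p,
            }
            logger.info(
                "aza_reversal: %.1f%% of targets reduced vs %.1f%% of universe (p=%.3g)",
                100 * aza.frac_targets_reduced, 100 * aza.frac_universe_reduced, aza.p,
            )
        report["stages"]["aza_reversal"] = aza_report

        # ------------------------------------------------------------------
        if config.truth:
            stage = "closed_loop"
            report["closed_loop"] = _closed_loop_checks(
                config.truth, classification, stats_list, direct, histone_report
            )
            logger.info("closed_loop: %s", report["closed_loop"])
    except Exception as exc:  # noqa: BLE001 - report which stage failed
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        raise StageError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _closed_loop_checks(truth_path, classification, kmer_stats, direct, histone_report) -> dict:
    """Compare pipeline output with the planted truth of a simulated run."""
    from .simulate import SyntheticTruth

    truth = SyntheticTruth.from_json(truth_path)
    found_specific = {p.name for p in classification.wt_specific}
    found_shared = {p.name for p in classification.shared}
    partition_ok = (
        found_specific == set(truth.wt_specific_names)
        and found_shared == set(truth.shared_names)
        and {p.name for p in classification.mut_specific} == set(truth.mut_specific_names)
    )
    motif_rank = next(
        (i + 1 for i, s in enumerate(kmer_stats) if s.kmer == truth.planted_motif), None
    )
    planted = set(truth.target_categories)
    recovered = {t.gene_id for t in direct}
    recovery = len(planted & recovered) / len(planted) if planted else 1.0
    categories_ok = all(
        t.category == truth.target_categories.get(t.gene_id) for t in direct
        if t.gene_id in planted
    )
    h3k27ac_up = histone_report.get("H3K27ac", {}).get("frac_up")
    return {
        "partition_recovered": partition_ok,
        "planted_motif_rank": motif_rank,
        "target_recovery": recovery,
        "n_false_targets": len(recovered - planted),
        "categories_match": categories_ok,
        "h3k27ac_frac_up": h3k27ac_up,
    }


# ---------------------------------------------------------------------------
# Flat key=value config file support (CLI)
# ---------------------------------------------------------------------------


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file into a PipelineConfig.

    Histone read paths use keys ``histone_<mark>_t0`` / ``histone_<mark>_t48``.
    """
    config = PipelineConfig()
    histone: Dict[str, Dict[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("histone_") and (key.endswith("_t0") or key.endswith("_t48")):
                mark, tp = key[len("histone_"):].rsplit("_", 1)
                histone.setdefault(mark, {})[tp] = value
            elif hasattr(config, key):
                current = getattr(config, key)
                if isinstance(current, bool):
                    setattr(config, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(config, key, int(value))
                elif isinstance(current, float):
                    setattr(config, key, float(value))
                else:
                    setattr(config, key, value)
            else:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
    config.histone_reads = histone
    return config


def config_from_manifest(manifest: Dict[str, str], out_dir: str, seed: int = 0,
                         **overrides) -> PipelineConfig:
    """Build a config straight from a SyntheticDataset.write() manifest."""
    histone = {}
    for key, path in manifest.items():
        if key.endswith("_t0") or key.endswith("_t48"):
            mark, tp = key.rsplit("_", 1)
            histone.setdefault(mark, {})[tp] = path
    config = PipelineConfig(
        wt_peaks=manifest["wt_peaks"],
        mut_peaks=manifest["mut_peaks"],
        genome_fasta=manifest["genome"],
        cytosine_report=manifest["methylome"],
        gene_models=manifest["genes"],
        expression=manifest["expression"],
        deg_wt=manifest["deg_wt"],
        deg_mut=manifest["deg_mut"],
        enhancer_map=manifest["enhancers"],
        histone_reads=histone,
        truth=manifest.get("truth", ""),
        out_dir=out_dir,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(config, key, value)
    return config
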