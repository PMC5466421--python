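"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: BED3/BED6 (intervals, peaks, reads), BED12 (gene models),
bismark-style cytosine reports (per-CpG methylated/unmethylated counts),
expression TSV (gene x condition FPKM), DEG tables, enhancer->gene link
tables, GMT gene sets, and 0/1 clone matrices from Sanger bisulfite clones.

BED is 0-based half-open; cytosine reports are 1-based and converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd

from .intervals import GenomicInterval, Peak

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message names file and line number."""


@dataclass(frozen=True)
class CpGSite:
    """One cytosine in CpG context with bisulfite read counts.

    ``pos`` is the 1-based cytosine position as in the cytosine report.
    beta (methylation level) = n_meth / (n_meth + n_unmeth), defined only
    when coverage is positive.
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"CpG strand must be + or -, got {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def beta(self) -> float:
        from .methylome import compute_beta

        return compute_beta(self.n_meth, self.n_unmeth)

    @property
    def pos0(self) -> int:
        """0-based cytosine position."""
        return self.pos - 1

    @property
    def cg_start0(self) -> int:
        """0-based plus-strand position of the C of this site's CG dinucleotide.

        A minus-strand CpG cytosine pairs with the G one bp downstream on the
        plus strand, so its CG starts one bp earlier in plus coordinates.
        """
        return self.pos0 if self.strand == "+" else self.pos0 - 1


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand, exons and 5'UTR intervals; TSS derived from strand."""

    gene_id: str
    interval: GenomicInterval
    exons: Sequence[GenomicInterval] = ()
    utr5: Sequence[GenomicInterval] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: gene models must be stranded")
        for exon in self.exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """0-based TSS position: span start for +, span end - 1 for -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class EnhancerLink:
    """A distal enhancer interval mapped to its predicted target gene."""

    enhancer: GenomicInterval
    gene_id: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


# ---------------------------------------------------------------------------
# BED intervals / peaks
# ---------------------------------------------------------------------------


def load_intervals(path: PathLike, kind: str = "interval"):
    """Load a BED3/BED6 file as GenomicIntervals or Peaks (``kind='peak'``).

    Coordinates are taken verbatim (BED is already 0-based half-open); file
    order is preserved. Score is column 5 when present, else 0; strand
    column 6 when present ('.' = unspecified).
    """
    if kind not in ("interval", "peak"):
        raise ValueError(f"kind must be 'interval' or 'peak', got {kind!r}")
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if kind == "interval":
                out.append(iv)
            else:
                name = fields[3] if len(fields) >= 4 and fields[3] != "." else f"peak_{lineno}"
                try:
                    score = float(fields[4]) if len(fields) >= 5 and fields[4] != "." else 0.0
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: non-numeric score") from exc
                out.append(Peak(iv, score=score, name=name))
    if kind == "peak":
        names = [p.name for p in out]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ParseError(f"{path}: duplicate peak names: {dupes[:5]}")
    return out


def write_intervals(items: Sequence[Union[GenomicInterval, Peak]], path: PathLike) -> None:
    """Write intervals as BED3 (strand '.'), BED6 otherwise; peaks as BED6."""
    with open(path, "w") as fh:
        for item in items:
            if isinstance(item, Peak):
                iv = item.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.name}\t{item.score:g}\t{iv.strand}\n"
                )
            elif item.strand == ".":
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")
            else:
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\t.\t0\t{item.strand}\n")


# ---------------------------------------------------------------------------
# Cytosine report
# ---------------------------------------------------------------------------


def load_cytosine_report(path: PathLike) -> List[CpGSite]:
    """Load a bismark-style cytosine report, keeping CpG-context rows only.

    Columns: chrom, position (1-based), strand, count_methylated,
    count_unmethylated, context. CHG/CHH rows are skipped: only CpG
    methylation feeds the downstream analysis.
    """
    sites: List[CpGSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 columns")
            chrom, pos_s, strand, n_meth_s, n_unmeth_s, context = fields[:6]
            if context != "CpG":
                continue
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(n_meth_s), int(n_unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field") from exc
            try:
                sites.append(CpGSite(chrom, pos, strand, n_meth, n_unmeth))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return sites


def write_cytosine_report(sites: Sequence[CpGSite], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.n_meth}\t{s.n_unmeth}\tCpG\n")


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------


def load_gene_models(path: PathLike, utr5_from_thick: bool = True) -> List[GeneModel]:
    """Load gene models from BED12.

    Exons come from blockStarts/blockSizes. The 5'UTR is derived from the
    thickStart/thickEnd (CDS) columns: exonic sequence 5' of the CDS on the
    gene's strand. Genes with thickStart == thickEnd (non-coding) get no UTR.
    """
    genes: List[GeneModel] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}: line {lineno}: BED12 requires 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}: line {lineno}: blockCount mismatch")
            if gene_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            span = GenomicInterval(chrom, start, end, strand)
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            utr5: List[GenomicInterval] = []
            if utr5_from_thick and thick_end > thick_start:
                for exon in exons:
                    if strand == "+" and exon.start < thick_start:
                        utr5.append(
                            GenomicInterval(chrom, exon.start, min(exon.end, thick_start), strand)
                        )
                    elif strand == "-" and exon.end > thick_end:
                        utr5.append(
                            GenomicInterval(chrom, max(exon.start, thick_end), exon.end, strand)
                        )
            genes.append(GeneModel(gene_id, span, tuple(exons), tuple(utr5)))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> None:
    """Write BED12; thick region spans everything 3' of the UTR (CDS proxy)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = sorted(g.exons, key=lambda e: e.start)
            if not exons:
                exons = [iv]
            if g.utr5:
                utr_edge = max(u.end for u in g.utr5) if g.strand == "+" else min(
                    u.start for u in g.utr5
                )
                thick = (utr_edge, iv.end) if g.strand == "+" else (iv.start, utr_edge)
            else:
                thick = (iv.start, iv.end)
            sizes = ",".join(str(len(e)) for e in exons)
            offsets = ",".join(str(e.start - iv.start) for e in exons)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Expression / DEG / enhancer / gene-set tables
# ---------------------------------------------------------------------------


def load_expression(path: PathLike) -> pd.DataFrame:
    """Expression TSV -> DataFrame indexed by gene_id, one FPKM column per condition.

    Requires a header row with a ``gene_id`` column; duplicate gene ids and
    negative FPKM values are errors.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'gene_id'")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene_id values: {dupes[:5]}")
    df = df.set_index("gene_id")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no condition columns")
    if (df < 0).any().any():
        raise ParseError(f"{path}: negative FPKM values")
    return df


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def load_deg_table(path: PathLike) -> pd.DataFrame:
    """DEG TSV with columns gene_id, log2fc, p (extra columns preserved)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "p"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def load_enhancer_map(path: PathLike) -> List[EnhancerLink]:
    """Enhancer link TSV: chrom, start, end, gene_id[, confidence]; no header."""
    links: List[EnhancerLink] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}: line {lineno}: expected chrom,start,end,gene_id")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            conf = float(f[4]) if len(f) >= 5 else 1.0
            links.append(EnhancerLink(iv, f[3], conf))
    return links


def write_enhancer_map(links: Sequence[EnhancerLink], path: PathLike) -> None:
    with open(path, "w") as fh:
        for link in links:
            e = link.enhancer
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{link.gene_id}\t{link.confidence:g}\n")


def load_gene_sets(path: PathLike) -> Dict[str, set]:
    """GMT file: set name, description, then member genes (tab-separated)."""
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT needs name, desc, >=1 gene")
            sets[f[0]] = set(f[2:])
    return sets


def load_clone_matrix(path: PathLike):
    """0/1 TSV grid (rows = clones, columns = CpG sites) -> CloneMatrix."""
    from .methylome import CloneMatrix

    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([int(x) for x in line.split("\t")])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer entry") from exc
    return CloneMatrix(rows=rows)
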