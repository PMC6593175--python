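"""Gene-annotation data model and gene-architecture decomposition.

All coordinates are 0-based half-open internally. GTF input (1-based closed)
is converted on read; BED12 is used natively. When a gene has several
transcript models the one with the longest genomic span is kept, so that
"gene size" means the genomic span the elongating polymerase traverses
(TSS to TES).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "GeneModel",
    "FeatureDecomposition",
    "read_gene_models",
    "read_bed12",
    "read_gtf",
    "write_bed12",
    "write_gtf",
    "decompose_architecture",
    "architecture_table",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, exon chain and optional CDS span, 0-based half-open.

    Invariants: exons are sorted, disjoint, contained in ``[start, end)``;
    the first exon starts at ``start`` and the last ends at ``end``; the CDS
    span (if any) overlaps the exon chain.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValueError(f"{self.gene_id}: exon chain must span [start, end)")
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if ce <= cs:
                raise ValueError(f"{self.gene_id}: empty CDS span")
            if not any(s < ce and cs < e for s, e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS span misses all exons")

    @property
    def length(self) -> int:
        """Genomic span length (TSS to TES), the occupancy unit."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class FeatureDecomposition:
    """Per-gene architecture: exonic/intronic totals and strand-aware UTRs.

    ``cds_length_bp``/``utr5_bp``/``utr3_bp`` are ``None`` for genes without
    an annotated CDS. Identities: gene_length = exonic + intron_total and,
    with a CDS, utr5 + cds + utr3 = exonic total.
    """

    gene_id: str
    gene_length_bp: int
    exonic_bp: int
    intron_total_bp: int
    intron_count: int
    exon_count: int
    cds_length_bp: Optional[int] = None
    utr5_bp: Optional[int] = None
    utr3_bp: Optional[int] = None


def decompose_architecture(gene: GeneModel) -> FeatureDecomposition:
    """Split a gene into exonic, intronic, CDS and UTR base counts.

    UTR labelling is strand-aware: on the + strand the 5' UTR is the exonic
    sequence upstream (left) of the CDS span; on the - strand it is the
    exonic sequence to the right.
    """
    exonic = gene.exonic_length
    introns = gene.length - exonic
    n_exons = len(gene.exons)
    if gene.cds_span is None:
        return FeatureDecomposition(
            gene_id=gene.gene_id,
            gene_length_bp=gene.length,
            exonic_bp=exonic,
            intron_total_bp=introns,
            intron_count=n_exons - 1,
            exon_count=n_exons,
        )
    cs, ce = gene.cds_span
    cds = sum(min(e, ce) - max(s, cs) for s, e in gene.exons if s < ce and cs < e)
    left = sum(min(e, cs) - s for s, e in gene.exons if s < cs)
    right = sum(e - max(s, ce) for s, e in gene.exons if e > ce)
    utr5, utr3 = (left, right) if gene.strand == "+" else (right, left)
    return FeatureDecomposition(
        gene_id=gene.gene_id,
        gene_length_bp=gene.length,
        exonic_bp=exonic,
        intron_total_bp=introns,
        intron_count=n_exons - 1,
        exon_count=n_exons,
        cds_length_bp=cds,
        utr5_bp=utr5,
        utr3_bp=utr3,
    )


def architecture_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """FeatureDecomposition for every gene as a DataFrame (gene_id index)."""
    rows = [decompose_architecture(g).__dict__ for g in genes]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _keep_longest_span(candidates: Iterable[GeneModel]) -> list[GeneModel]:
    best: dict[str, GeneModel] = {}
    for g in candidates:
        prev = best.get(g.gene_id)
        if prev is None or g.length > prev.length:
            best[g.gene_id] = g
    return [best[k] for k in sorted(best)]


def read_bed12(path: str | Path, layout: Optional[GenomeLayout] = None) -> list[GeneModel]:
    """Read BED12 records into GeneModels (longest span per name).

    thickStart == thickEnd (UCSC convention for non-coding) yields no CDS.
    Records on chromosomes absent from ``layout`` are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#", dtype={"chrom": str})
    models = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if layout is not None and row.chrom not in layout:
            logger.warning("%s line %d: unknown chromosome %r, record skipped", path, i, row.chrom)
            continue
        try:
            start = int(row.start)
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            if len(sizes) != int(row.blockCount) or len(offsets) != int(row.blockCount):
                raise ValueError("block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            thick = (int(row.thickStart), int(row.thickEnd))
            cds = thick if thick[1] > thick[0] else None
            models.append(
                GeneModel(
                    gene_id=str(row.name), chrom=row.chrom, strand=row.strand,
                    start=start, end=int(row.end), exons=exons, cds_span=cds,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: malformed BED12 record ({exc})") from exc
    return _keep_longest_span(models)


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        thick = g.cds_span if g.cds_span is not None else (g.start, g.start)
        rows.append(
            [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand, thick[0], thick[1], "0",
                len(g.exons),
                ",".join(str(e - s) for s, e in g.exons) + ",",
                ",".join(str(s - g.start) for s, _ in g.exons) + ",",
            ]
        )
    pd.DataFrame(rows, columns=_BED12_COLS).to_csv(path, sep="\t", header=False, index=False)


def read_gtf(path: str | Path, layout: Optional[GenomeLayout] = None) -> list[GeneModel]:
    """Read a GTF into GeneModels via pyranges (coordinates converted to
    0-based half-open); per gene the longest-span transcript is kept."""
    import pyranges

    df = pyranges.read_gtf(str(path)).df
    if df.empty:
        return []
    df = df[df.Feature.isin(["exon", "CDS"])]
    models = []
    for (gid, tid), sub in df.groupby(["gene_id", "transcript_id"], dropna=False):
        chrom = str(sub.Chromosome.iloc[0])
        if layout is not None and chrom not in layout:
            logger.warning("%s: unknown chromosome %r for gene %s, record skipped", path, chrom, gid)
            continue
        exon_rows = sub[sub.Feature == "exon"].sort_values("Start")
        if exon_rows.empty:
            continue
        exons = tuple(zip(exon_rows.Start.astype(int), exon_rows.End.astype(int)))
        cds_rows = sub[sub.Feature == "CDS"]
        cds = (int(cds_rows.Start.min()), int(cds_rows.End.max())) if len(cds_rows) else None
        models.append(
            GeneModel(
                gene_id=str(gid), chrom=chrom, strand=str(sub.Strand.iloc[0]),
                start=int(exons[0][0]), end=int(exons[-1][1]), exons=exons, cds_span=cds,
            )
        )
    return _keep_longest_span(models)


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "zgapipe") -> None:
    """Write GeneModels as GTF (converting to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            if g.cds_span is not None:
                cs, ce = g.cds_span
                for s, e in g.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if oe > os_:
                        fh.write(f"{g.chrom}\t{source}\tCDS\t{os_ + 1}\t{oe}\t.\t{g.strand}\t.\t{attrs}\n")


def read_gene_models(path: str | Path, layout: Optional[GenomeLayout] = None) -> list[GeneModel]:
    """Dispatch on file extension: .bed → BED12, .gtf/.gff → GTF."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed12(path, layout)
    if suffix in (".gtf", ".gff"):
        return read_gtf(path, layout)
    raise ValueError(f"unrecognised annotation format: {path}")
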