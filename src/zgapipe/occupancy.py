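"""Per-stage RNAPII gene-body occupancy calling and Hilbert genome views.

The caller operationalises "RNAPII enriched across the entire gene body":
the gene span is cut into ``n_bins`` equal-width strand-oriented bins, each
bin's ChIP/input fold is computed on counts-per-million tracks with a small
pseudo-rate, and a gene is called occupied when at least ``min_fraction`` of
bins reach ``min_fold`` with no sub-threshold run longer than ``max_gap`` of
the bins. All comparisons are inclusive and all parameters are exposed.

Only within-sample (counts-per-million) normalization is applied; spike-in
scaling across stages is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomeLayout

__all__ = [
    "StageCoverage",
    "OccupancyCall",
    "HilbertMap",
    "read_bedgraph",
    "read_bigwig",
    "write_bedgraph",
    "normalize_per_million",
    "gene_body_enrichment",
    "call_full_length",
    "call_occupancy_table",
    "hilbert_index",
    "render_hilbert",
    "PSEUDO_RATE_CPM",
]

#: pseudo-rate added to both arms of the fold ratio (cpm); stabilises folds
#: in zero-coverage bins of sparse pre-MBT samples.
PSEUDO_RATE_CPM = 0.25


@dataclass
class StageCoverage:
    """Binned ChIP and input coverage for one developmental stage.

    ``chip``/``input_`` map chromosome → per-bin value vector (fixed
    ``bin_size`` bp bins, last bin possibly ragged). Totals are the library
    sizes used for counts-per-million scaling.
    """

    stage: str
    bin_size: int
    chip: dict[str, np.ndarray]
    input_: dict[str, np.ndarray]
    chip_total: float = field(default=0.0)
    input_total: float = field(default=0.0)

    def __post_init__(self) -> None:
        if set(self.chip) != set(self.input_):
            raise ValueError("chip and input tracks cover different chromosomes")
        if self.chip_total == 0.0:
            self.chip_total = float(sum(v.sum() for v in self.chip.values()))
        if self.input_total == 0.0:
            self.input_total = float(sum(v.sum() for v in self.input_.values()))


def normalize_per_million(track: StageCoverage) -> StageCoverage:
    """Scale chip and input to counts-per-million of their own totals."""
    if track.chip_total <= 0 or track.input_total <= 0:
        raise ValueError(f"stage {track.stage}: zero library total")
    fc = 1e6 / track.chip_total
    fi = 1e6 / track.input_total
    return StageCoverage(
        stage=track.stage,
        bin_size=track.bin_size,
        chip={c: v * fc for c, v in track.chip.items()},
        input_={c: v * fi for c, v in track.input_.items()},
        chip_total=1e6,
        input_total=1e6,
    )


def _prefix(values: np.ndarray, bin_size: int) -> np.ndarray:
    """prefix[i] = integral of the piecewise-constant signal over [0, i*bin_size)."""
    return np.concatenate([[0.0], np.cumsum(values.astype(float) * bin_size)])


def _means_from_prefix(
    prefix: np.ndarray, values: np.ndarray, bin_size: int, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Mean signal over [start, end) bp intervals, fractional edge bins included."""

    def integral(pos: np.ndarray) -> np.ndarray:
        pos = np.clip(pos, 0, len(values) * bin_size)
        idx = pos // bin_size
        frac = pos - idx * bin_size
        return prefix[idx] + values[np.minimum(idx, len(values) - 1)] * frac

    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    return (integral(ends) - integral(starts)) / np.maximum(ends - starts, 1)


def _interval_means(values: np.ndarray, bin_size: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Mean of a binned per-bp signal over [start, end) intervals."""
    return _means_from_prefix(_prefix(values, bin_size), values, bin_size, starts, ends)


def gene_body_enrichment(
    track: StageCoverage,
    gene: GeneModel,
    n_bins: int = 20,
    pseudo_rate: float = PSEUDO_RATE_CPM,
) -> np.ndarray:
    """Per-bin ChIP/input fold across the gene body, TSS→TES oriented.

    ``track`` must already be counts-per-million normalised. The span is cut
    into ``n_bins`` equal-width bins; genes shorter than ``n_bins`` bp fall
    back to 1-bp bins. Fold = (chip mean + eps) / (input mean + eps).
    """
    if gene.length < n_bins:
        import warnings

        warnings.warn(
            f"gene {gene.gene_id} shorter than {n_bins} bp; using 1-bp bins",
            stacklevel=2,
        )
        n_bins = gene.length
    edges = gene.start + np.round(np.linspace(0, gene.length, n_bins + 1)).astype(np.int64)
    chip = _interval_means(track.chip[gene.chrom], track.bin_size, edges[:-1], edges[1:])
    inp = _interval_means(track.input_[gene.chrom], track.bin_size, edges[:-1], edges[1:])
    fold = (chip + pseudo_rate) / (inp + pseudo_rate)
    if gene.strand == "-":
        fold = fold[::-1]
    return fold


@dataclass(frozen=True)
class OccupancyCall:
    """Full-length occupancy decision with its diagnostics."""

    gene_id: str
    stage: str
    occupied: bool
    fraction_bins_enriched: float
    longest_gap_fraction: float
    mean_enrichment: float


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True in a boolean vector."""
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def call_full_length(
    enrichment: np.ndarray,
    gene_id: str = "",
    stage: str = "",
    min_fold: float = 2.0,
    min_fraction: float = 0.9,
    max_gap: float = 0.1,
) -> OccupancyCall:
    """Occupied iff ≥``min_fraction`` of bins reach ``min_fold`` and the
    longest sub-threshold run is ≤``max_gap`` of bins (inclusive)."""
    enrichment = np.asarray(enrichment, dtype=float)
    if enrichment.size == 0:
        raise ValueError("empty enrichment vector")
    hit = enrichment >= min_fold
    frac = float(hit.mean())
    gap = _longest_run(~hit) / hit.size
    return OccupancyCall(
        gene_id=gene_id,
        stage=stage,
        occupied=bool(frac >= min_fraction and gap <= max_gap),
        fraction_bins_enriched=frac,
        longest_gap_fraction=gap,
        mean_enrichment=float(enrichment.mean()),
    )


def call_occupancy_table(
    tracks: Mapping[str, StageCoverage],
    genes: Iterable[GeneModel],
    n_bins: int = 20,
    min_fold: float = 2.0,
    min_fraction: float = 0.9,
    max_gap: float = 0.1,
    normalized: bool = False,
) -> pd.DataFrame:
    """Occupancy calls for every gene at every stage.

    Returns a long DataFrame with one row per (gene, stage). Tracks are
    cpm-normalised here unless ``normalized`` says they already are.
    """
    genes = list(genes)
    rows = []
    for stage, track in tracks.items():
        t = track if normalized else normalize_per_million(track)
        chip_prefix = {c: _prefix(v, t.bin_size) for c, v in t.chip.items()}
        inp_prefix = {c: _prefix(v, t.bin_size) for c, v in t.input_.items()}
        for g in genes:
            nb = n_bins if g.length >= n_bins else g.length
            edges = g.start + np.round(np.linspace(0, g.length, nb + 1)).astype(np.int64)
            chip = _means_from_prefix(
                chip_prefix[g.chrom], t.chip[g.chrom], t.bin_size, edges[:-1], edges[1:]
            )
            inp = _means_from_prefix(
                inp_prefix[g.chrom], t.input_[g.chrom], t.bin_size, edges[:-1], edges[1:]
            )
            prof = (chip + PSEUDO_RATE_CPM) / (inp + PSEUDO_RATE_CPM)
            if g.strand == "-":
                prof = prof[::-1]
            call = call_full_length(
                prof, gene_id=g.gene_id, stage=stage,
                min_fold=min_fold, min_fraction=min_fraction, max_gap=max_gap,
            )
            rows.append(call.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hilbert curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HilbertMap:
    """Bijection d ↔ (x, y) over a 2^k × 2^k lattice along the Hilbert curve.

    Base-case visit order is (0,0) → (0,1) → (1,1) → (1,0); consecutive d
    are always lattice neighbours, so genomic locality is preserved in 2D.
    """

    order: int
    x: np.ndarray
    y: np.ndarray

    @property
    def side(self) -> int:
        return 1 << self.order

    def d2xy(self, d: int) -> tuple[int, int]:
        return int(self.x[d]), int(self.y[d])

    def xy2d(self, x: int, y: int) -> int:
        d = np.flatnonzero((self.x == x) & (self.y == y))
        if d.size != 1:
            raise ValueError(f"({x}, {y}) not on the lattice")
        return int(d[0])


def hilbert_index(order: int) -> HilbertMap:
    """Hilbert curve of the given order (1–12), vectorised bit-twiddling."""
    if not 1 <= order <= 12:
        raise ValueError("order must be in [1, 12]")
    n = 1 << order
    d = np.arange(n * n, dtype=np.int64)
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    t = d.copy()
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        # rotate quadrant
        flip = (ry == 0) & (rx == 1)
        x = np.where(flip, s - 1 - x, x)
        y = np.where(flip, s - 1 - y, y)
        swap = ry == 0
        x, y = np.where(swap, y, x), np.where(swap, x, y)
        x = x + s * rx
        y = y + s * ry
        t //= 4
        s *= 2
    return HilbertMap(order=order, x=x, y=y)


def render_hilbert(
    track: StageCoverage,
    layout: GenomeLayout,
    order: int,
    pseudo_rate: float = PSEUDO_RATE_CPM,
    normalized: bool = False,
) -> dict[str, np.ndarray]:
    """Fold one chromosome per matrix into a 2^k × 2^k Hilbert view.

    Each chromosome is cut into 4^k genomic bins of ceil(length / 4^k) bp;
    the curve cell holding position d gets that bin's mean ChIP/input fold.
    """
    hmap = hilbert_index(order)
    t = track if normalized else normalize_per_million(track)
    n_cells = hmap.side * hmap.side
    out: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        if chrom not in t.chip:
            continue
        length = layout.chrom_lengths[chrom]
        width = -(-length // n_cells)  # ceil
        edges = np.minimum(np.arange(n_cells + 1, dtype=np.int64) * width, length)
        chip = _interval_means(t.chip[chrom], t.bin_size, edges[:-1], edges[1:])
        inp = _interval_means(t.input_[chrom], t.bin_size, edges[:-1], edges[1:])
        fold = (chip + pseudo_rate) / (inp + pseudo_rate)
        fold[edges[:-1] >= length] = np.nan  # cells past the chromosome end
        mat = np.full((hmap.side, hmap.side), np.nan)
        mat[hmap.x, hmap.y] = fold
        out[chrom] = mat
    return out


# ---------------------------------------------------------------------------
# bedGraph I/O (fixed-width binned tracks)
# ---------------------------------------------------------------------------


def write_bedgraph(values: Mapping[str, np.ndarray], bin_size: int, path: str | Path) -> None:
    """Write a binned track as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom, vec in values.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                v = vec[s]
                v = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{s * bin_size}\t{e * bin_size}\t{v}\n")


def read_bigwig(path: str | Path, layout: GenomeLayout, bin_size: int) -> dict[str, np.ndarray]:
    """Read a bigWig into fixed-width per-bin mean-coverage vectors.

    Requires pyBigWig. Missing chromosomes yield all-zero vectors; NaN
    (uncovered) stretches read as zero.
    """
    import pyBigWig

    out: dict[str, np.ndarray] = {}
    with pyBigWig.open(str(path)) as bw:
        for chrom in layout.chrom_names:
            n = -(-layout.chrom_lengths[chrom] // bin_size)
            if chrom not in bw.chroms():
                out[chrom] = np.zeros(n)
                continue
            length = min(layout.chrom_lengths[chrom], bw.chroms()[chrom])
            vals = np.array(bw.stats(chrom, 0, length, nBins=n, type="mean"), dtype=float)
            out[chrom] = np.nan_to_num(vals, nan=0.0)
    return out


def read_bedgraph(path: str | Path, layout: GenomeLayout, bin_size: int) -> dict[str, np.ndarray]:
    """Read a bedGraph into fixed-width per-bin vectors over the layout.

    Record boundaries must fall on multiples of ``bin_size`` (the writer's
    convention); values fill every covered bin, uncovered bins are zero.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    out = {
        c: np.zeros(-(-layout.chrom_lengths[c] // bin_size)) for c in layout.chrom_names
    }
    for chrom, sub in df.groupby("chrom"):
        if chrom not in out:
            continue
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        if ((starts % bin_size) != 0).any():
            raise ValueError(f"{path}: record start not aligned to {bin_size}-bp bins")
        vec = out[chrom]
        for s, e, v in zip(starts // bin_size, -(-ends // bin_size), sub.value.to_numpy()):
            vec[s:e] = v
    return out
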