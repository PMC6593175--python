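"""Synthetic embryo with known ground truth for every pipeline stage.

The generator emulates the study design end to end: a compact genome whose
genes fall into maternal-only, maternal-zygotic, zygotic-only, silent and
promoter-decoy classes; stage-resolved RNAPII ChIP/input coverage with
full-gene-body enrichment over active genes; a 30-min transcript time
course with intronic signal leading exonic signal; replicated
loss-of-function count tables (Wnt/Nodal/BMP singles, doubles, triple,
α-amanitin, control morpholino) with planted effect sizes and a planted
Wnt/BMP synergy set; and regional expression log-ratios along the
animal-vegetal and dorsoventral axes.

Design choices that mirror the biology being emulated:

* pre-MBT activated genes are drawn short (median ~1 kb) and intron-poor,
  later and maternal genes long (median ~16 kb); a configurable fraction
  of the early genes sits in tandem genomic clusters;
* transcription onset is placed 0.25 h before the profiled stage time so
  transcripts are already detectable (≥0.1 TPM) at that stage's sample;
* maternal transcripts start well above the 0.1 TPM maternal threshold and
  decay exponentially;
* α-amanitin suppresses nascent (intronic) signal almost completely and
  exonic signal according to the maternal share of each gene's pool;
* double-LOF effects are additive on the fractional-reduction scale except
  for the planted synergy genes (singles ~90% of control, double ~40%).

Everything is deterministic given the seed (NumPy Generator streams keyed
off it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomeLayout
from .occupancy import StageCoverage
from .temporal import STAGE_TIMES_HPF, TimeCourse

__all__ = [
    "SimulationConfig",
    "SimBundle",
    "LOF_CONDITIONS",
    "SIGNAL_CONDITIONS",
    "simulate_annotation",
    "simulate_rnapii_coverage",
    "simulate_timecourse",
    "simulate_lof",
    "simulate_counts_table",
    "simulate_bundle",
]

SIGNAL_CONDITIONS = ("W", "N", "B", "W+N", "W+B", "N+B", "W+N+B")
LOF_CONDITIONS = SIGNAL_CONDITIONS + ("amanitin", "control-MO")

_PRE_MBT = ("32-cell", "128-cell", "1024-cell")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic embryo; defaults are the study conditions.

    Activation-stage fractions and the per-stage maternal shares follow the
    reported stage-resolved counts (27/117/900/1854/724/1214 newly activated
    out of a 13,042-gene analysis set; maternal shares 67–95%), scaled to
    ``n_genes``.
    """

    seed: int = 0
    n_genes: int = 2000
    stage_times: dict[str, float] = field(default_factory=lambda: dict(STAGE_TIMES_HPF))

    # class composition ----------------------------------------------------
    newly_activated_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "32-cell": 27 / 13042,
            "128-cell": 117 / 13042,
            "1024-cell": 900 / 13042,
            "MBT": 1854 / 13042,
            "mid-gastrula": 724 / 13042,
            "late-gastrula": 1214 / 13042,
        }
    )
    maternal_fraction_by_stage: dict[str, float] = field(
        default_factory=lambda: {
            "32-cell": 18 / 27,
            "128-cell": 99 / 117,
            "1024-cell": 780 / 900,
            "MBT": 1754 / 1854,
            "mid-gastrula": 644 / 724,
            "late-gastrula": 1094 / 1214,
        }
    )
    decoy_fraction: float = 0.05
    silent_fraction: float = 0.03
    deactivation_fraction: float = 0.04  # of zygotic genes

    # gene architecture ----------------------------------------------------
    early_length_median_bp: float = 1000.0
    late_length_median_bp: float = 16000.0
    length_sigma: float = 0.6
    min_gene_length_bp: int = 500
    early_cds_median_bp: float = 400.0
    late_cds_median_bp: float = 1200.0
    early_intron_mean: float = 0.3
    late_intron_mean: float = 6.0
    cluster_fraction: float = 0.5  # of pre-MBT genes placed in tandem clusters
    cluster_gap_bp: int = 2000
    intergenic_gap_mean_bp: float = 50000.0
    min_gap_bp: int = 2000
    n_chromosomes: int = 4

    # RNAPII coverage ------------------------------------------------------
    bin_size_bp: int = 50
    background_rate: float = 50.0  # expected reads per bin (~1x per bp)
    enrichment_fold: float = 4.0
    decoy_promoter_fraction: float = 0.15

    # transcript time course ----------------------------------------------
    time_step_hpf: float = 0.5
    maternal_tpm_range: tuple[float, float] = (20.0, 2000.0)
    maternal_decay_rate: float = 0.2  # per hour
    zygotic_tpm_range: tuple[float, float] = (30.0, 300.0)
    intronic_fraction: float = 0.5
    exonic_tau_h: float = 1.0
    onset_lead_h: float = 0.25  # onset precedes the stage sample by this much
    deactivation_decay_rate: float = 0.5
    noise_sd_log: float = 0.2

    # LOF design -----------------------------------------------------------
    replicates: int = 3
    nb_dispersion: float = 0.01  # NB size = 1/dispersion
    lof_assay_hpf: float = 5.0  # late blastula
    lof_single_level: float = 0.55  # relative level of a dependent gene
    lof_up_level: float = 1.8
    lof_max_delta: float = 0.95
    # residual zygotic transcription under α-amanitin: exonic component
    # retained, and the intronic (nascent) relative level
    amanitin_residual_exonic: float = 0.05
    amanitin_level_intronic: float = 0.02
    n_synergy_genes: int = 12
    synergy_single_level: float = 0.9
    synergy_double_level: float = 0.4
    base_count_scale: float = 10.0
    base_count_floor: float = 20.0

    # regional patterns ----------------------------------------------------
    region_probs_av: dict[str, float] = field(
        default_factory=lambda: {"animal": 0.20, "vegetal": 0.25, "uniform": 0.55}
    )
    region_probs_dv: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 0.15, "ventral": 0.15, "uniform": 0.70}
    )
    region_log2_magnitude: float = 2.0
    region_log2_sd: float = 0.3
    dep_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # P(pathway-dependent | region label on the relevant axis)
            "W": {"dorsal": 0.85, "vegetal": 0.45, "default": 0.10},
            "N": {"vegetal": 0.70, "dorsal": 0.50, "ventral": 0.20, "default": 0.15},
            "B": {"ventral": 0.50, "default": 0.05},
        }
    )
    up_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "W": {"ventral": 0.30, "default": 0.02},
            "N": {"default": 0.02},
            "B": {"dorsal": 0.20, "default": 0.02},
        }
    )

    def validate(self) -> None:
        times = list(self.stage_times.values())
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("stage times must be strictly increasing")
        fracs = (
            list(self.newly_activated_fractions.values())
            + list(self.maternal_fraction_by_stage.values())
            + [self.decoy_fraction, self.silent_fraction, self.deactivation_fraction]
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.background_rate, self.enrichment_fold, self.nb_dispersion) <= 0:
            raise ValueError("rates must be positive")
        if self.n_genes < len(self.stage_times) + 3:
            raise ValueError("n_genes smaller than the number of gene classes")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# annotation + ground truth
# ---------------------------------------------------------------------------


def _split_total(total: int, parts: int, min_part: int, rng: np.random.Generator) -> np.ndarray:
    """Split an integer into ``parts`` pieces, each ≥ min_part."""
    if parts == 1:
        return np.array([total])
    spare = total - parts * min_part
    if spare < 0:
        raise ValueError("total too small to split")
    cuts = rng.multinomial(spare, np.full(parts, 1.0 / parts))
    return cuts + min_part


def _make_gene(
    gid: str, chrom: str, start: int, strand: str, length: int,
    n_introns: int, cds_len: int, rng: np.random.Generator,
) -> GeneModel:
    min_exon = 30
    max_introns = max(0, (length - (cds_len + 2) - min_exon) // (min_exon + 50))
    k = int(min(n_introns, max_introns))
    if k == 0:
        exonic_total = length
        exon_sizes = np.array([length])
        intron_sizes = np.array([], dtype=int)
    else:
        lo = max(cds_len + 2, (k + 1) * min_exon)
        hi = max(lo + 1, int(length * 0.35))
        exonic_total = int(rng.integers(lo, min(hi, length - 50 * k) + 1))
        exon_sizes = _split_total(exonic_total, k + 1, min_exon, rng)
        intron_sizes = _split_total(length - exonic_total, k, 50, rng)
    exons = []
    pos = start
    for i, es in enumerate(exon_sizes):
        exons.append((pos, pos + int(es)))
        pos += int(es)
        if i < len(intron_sizes):
            pos += int(intron_sizes[i])
    cds_len = min(cds_len, exonic_total - 2)
    cds_span = None
    if cds_len >= 3:
        left_utr = int(rng.integers(1, exonic_total - cds_len))
        # map exonic offsets [left_utr, left_utr + cds_len) to genomic coords
        cs = ce = None
        off = 0
        for s, e in exons:
            if cs is None and off + (e - s) > left_utr:
                cs = s + (left_utr - off)
            if off + (e - s) >= left_utr + cds_len:
                ce = s + (left_utr + cds_len - off)
                break
            off += e - s
        cds_span = (cs, ce)
    return GeneModel(
        gene_id=gid, chrom=chrom, strand=strand,
        start=start, end=exons[-1][1], exons=tuple(exons), cds_span=cds_span,
    )


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeLayout, list[GeneModel], pd.DataFrame]:
    """Simulate the genome, gene models and the ground-truth table."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes
    stages = list(config.stage_times)

    # class assignment ------------------------------------------------------
    classes: list[dict] = []
    for s in stages:
        k = int(round(config.newly_activated_fractions[s] * n))
        n_mat = int(round(config.maternal_fraction_by_stage[s] * k))
        for i in range(k):
            classes.append({"activation_stage_true": s, "maternal_true": i < n_mat})
    n_decoy = int(round(config.decoy_fraction * n))
    n_silent = int(round(config.silent_fraction * n))
    n_maternal_only = n - len(classes) - n_decoy - n_silent
    if n_maternal_only < 0:
        raise ValueError("class fractions exceed n_genes")
    classes += [{"activation_stage_true": None, "maternal_true": True, "decoy": True}] * n_decoy
    classes += [{"activation_stage_true": None, "maternal_true": False}] * n_silent
    classes += [{"activation_stage_true": None, "maternal_true": True}] * n_maternal_only

    truth = pd.DataFrame(classes)
    if "decoy" not in truth.columns:
        truth["decoy"] = False
    truth["decoy"] = truth["decoy"].map(lambda v: bool(v) if v is True else False)
    order = rng.permutation(len(truth))
    truth = truth.iloc[order].reset_index(drop=True)
    truth["gene_id"] = [f"g{i:05d}" for i in range(len(truth))]
    truth = truth.set_index("gene_id")

    act = truth.activation_stage_true
    truth["gene_class_true"] = np.select(
        [truth.decoy, act.notna() & truth.maternal_true, act.notna(), truth.maternal_true],
        ["decoy", "maternal-zygotic", "zygotic-only", "maternal-only"],
        default="silent",
    )
    early = act.isin(_PRE_MBT)

    # deactivation: a fraction of zygotic genes losing occupancy later -----
    truth["deactivation_stage_true"] = None
    zyg = truth.index[act.notna()]
    eligible = [g for g in zyg if stages.index(act.loc[g]) < len(stages) - 1]
    n_deact = int(round(config.deactivation_fraction * len(zyg)))
    deact_genes = rng.choice(eligible, size=min(n_deact, len(eligible)), replace=False)
    for g in deact_genes:
        i0 = stages.index(act.loc[g])
        truth.loc[g, "deactivation_stage_true"] = stages[int(rng.integers(i0 + 1, len(stages)))]

    # lengths and architecture ---------------------------------------------
    med = np.where(early, config.early_length_median_bp, config.late_length_median_bp)
    lengths = np.maximum(
        config.min_gene_length_bp,
        np.round(med * np.exp(config.length_sigma * rng.standard_normal(len(truth)))).astype(int),
    )
    cds_med = np.where(early, config.early_cds_median_bp, config.late_cds_median_bp)
    cds_lens = np.round(cds_med * np.exp(0.4 * rng.standard_normal(len(truth)))).astype(int)
    intron_mean = np.where(early, config.early_intron_mean, config.late_intron_mean)
    n_introns = rng.poisson(intron_mean)
    strands = rng.choice(["+", "-"], size=len(truth))
    truth["length_bp_true"] = lengths
    truth["early_true"] = early.to_numpy()

    # placement: cluster a fraction of the pre-MBT genes --------------------
    early_ids = list(truth.index[early])
    clustered = set(
        rng.choice(early_ids, size=int(round(config.cluster_fraction * len(early_ids))), replace=False)
        if early_ids else []
    )
    units: list[list[str]] = []
    cluster_buf: list[str] = []
    for g in truth.index:
        if g in clustered:
            cluster_buf.append(g)
            if len(cluster_buf) == 3:
                units.append(cluster_buf)
                cluster_buf = []
        else:
            units.append([g])
    if cluster_buf:
        units.append(cluster_buf)
    units = [units[i] for i in rng.permutation(len(units))]

    chrom_names = tuple(f"chr{i + 1}" for i in range(config.n_chromosomes))
    cursors = dict.fromkeys(chrom_names, 0)
    genes: dict[str, GeneModel] = {}
    for u, unit in enumerate(units):
        chrom = chrom_names[u % config.n_chromosomes]
        pos = cursors[chrom]
        for j, gid in enumerate(unit):
            gap = (
                config.cluster_gap_bp
                if j > 0
                else config.min_gap_bp + int(rng.exponential(config.intergenic_gap_mean_bp))
            )
            pos += gap
            i = truth.index.get_loc(gid)
            gene = _make_gene(
                gid, chrom, pos, strands[i], int(lengths[i]),
                int(n_introns[i]), int(cds_lens[i]), rng,
            )
            genes[gid] = gene
            pos = gene.end
        cursors[chrom] = pos
    layout = GenomeLayout(
        chrom_names=chrom_names,
        chrom_lengths={c: cursors[c] + 10000 for c in chrom_names},
    )
    truth["has_introns"] = [len(genes[g].exons) > 1 for g in truth.index]

    # expression parameters --------------------------------------------------
    lo, hi = config.maternal_tpm_range
    truth["maternal_tpm0"] = np.where(
        truth.maternal_true, np.exp(rng.uniform(np.log(lo), np.log(hi), len(truth))), 0.0
    )
    lo, hi = config.zygotic_tpm_range
    truth["zygotic_amplitude"] = np.where(
        act.notna(), np.exp(rng.uniform(np.log(lo), np.log(hi), len(truth))), 0.0
    )

    _assign_regions_and_deps(config, truth, rng)
    gene_list = [genes[g] for g in truth.index]
    return layout, gene_list, truth


def _pick(prob_map: Mapping[str, float], labels: Sequence[str]) -> float:
    return max((prob_map.get(l, 0.0) for l in labels), default=0.0) or prob_map["default"]


def _assign_regions_and_deps(config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator) -> None:
    zygotic = truth.activation_stage_true.notna()
    av = np.full(len(truth), "uniform", dtype=object)
    dv = np.full(len(truth), "uniform", dtype=object)
    idx = np.flatnonzero(zygotic.to_numpy())
    av[idx] = rng.choice(
        list(config.region_probs_av), size=len(idx), p=list(config.region_probs_av.values())
    )
    dv[idx] = rng.choice(
        list(config.region_probs_dv), size=len(idx), p=list(config.region_probs_dv.values())
    )
    truth["region_av_true"] = av
    truth["region_dv_true"] = dv

    for pw in ("W", "N", "B"):
        dep = np.zeros(len(truth), bool)
        up = np.zeros(len(truth), bool)
        for i in idx:
            labels = (av[i], dv[i])
            dep[i] = rng.random() < _pick(config.dep_probs[pw], labels)
            if not dep[i]:
                up[i] = rng.random() < _pick(config.up_probs[pw], labels)
        truth[f"dep_{pw}"] = dep
        truth[f"up_{pw}"] = up

    # planted Wnt/BMP synergy genes: DV-uniform, AV-regional zygotic genes
    # already active (and nascent-detectable) by the MBT-stage LOF assay
    truth["synergy_true"] = False
    observable = truth.activation_stage_true.isin(["32-cell", "128-cell", "1024-cell", "MBT"])
    pool = truth.index[
        zygotic
        & observable
        & truth.has_introns
        & (truth.region_dv_true == "uniform")
        & (truth.region_av_true != "uniform")
    ]
    chosen = rng.choice(pool, size=min(config.n_synergy_genes, len(pool)), replace=False)
    truth.loc[chosen, "synergy_true"] = True
    truth.loc[chosen, ["dep_W", "dep_B", "up_W", "up_B"]] = False


# ---------------------------------------------------------------------------
# RNAPII coverage
# ---------------------------------------------------------------------------


def _occupied_stages(truth_row: pd.Series, stages: Sequence[str]) -> tuple[int, int]:
    """[first, last) stage-index interval of full-length occupancy."""
    act = truth_row.activation_stage_true
    if act is None or (isinstance(act, float) and np.isnan(act)):
        return (0, 0)
    i0 = stages.index(act)
    deact = truth_row.deactivation_stage_true
    i1 = stages.index(deact) if deact is not None and not pd.isna(deact) else len(stages)
    return (i0, i1)


def simulate_rnapii_coverage(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    layout: GenomeLayout,
) -> dict[str, StageCoverage]:
    """Stage → paired ChIP/input binned coverage.

    ChIP counts are Poisson(background) genome-wide, times the enrichment
    fold over the full body of genes occupied at the stage; promoter-only
    decoys get the fold over the first 15% of their body (strand-aware).
    The matched input is Poisson(background) only.
    """
    stages = list(config.stage_times)
    bs = config.bin_size_bp
    nbins = {c: -(-layout.chrom_lengths[c] // bs) for c in layout.chrom_names}
    gene_by_id = {g.gene_id: g for g in genes}
    spans = {gid: _occupied_stages(truth.loc[gid], stages) for gid in truth.index}

    out: dict[str, StageCoverage] = {}
    for si, stage in enumerate(stages):
        rng = np.random.default_rng([config.seed, 23, si])
        rate = {c: np.full(nbins[c], config.background_rate) for c in layout.chrom_names}
        for gid in truth.index:
            g = gene_by_id[gid]
            row = truth.loc[gid]
            b0, b1 = g.start // bs, -(-g.end // bs)
            if row.decoy:
                w = max(1, int(round((b1 - b0) * config.decoy_promoter_fraction)))
                if g.strand == "+":
                    rate[g.chrom][b0 : b0 + w] = config.background_rate * config.enrichment_fold
                else:
                    rate[g.chrom][b1 - w : b1] = config.background_rate * config.enrichment_fold
            else:
                i0, i1 = spans[gid]
                if i0 <= si < i1:
                    rate[g.chrom][b0:b1] = config.background_rate * config.enrichment_fold
        chip = {c: rng.poisson(rate[c]).astype(float) for c in layout.chrom_names}
        inp = {
            c: rng.poisson(np.full(nbins[c], config.background_rate)).astype(float)
            for c in layout.chrom_names
        }
        out[stage] = StageCoverage(stage=stage, bin_size=bs, chip=chip, input_=inp)
    return out


# ---------------------------------------------------------------------------
# transcript time course
# ---------------------------------------------------------------------------


def _expected_expression(
    config: SimulationConfig, truth: pd.DataFrame, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free exonic and intronic TPM matrices (genes × times)."""
    stages = list(config.stage_times)
    n, t = len(truth), len(times)
    exonic = np.zeros((n, t))
    intronic = np.zeros((n, t))

    m0 = truth.maternal_tpm0.to_numpy()
    exonic += m0[:, None] * np.exp(-config.maternal_decay_rate * times)[None, :]

    for i, (gid, row) in enumerate(truth.iterrows()):
        act = row.activation_stage_true
        if act is None or pd.isna(act):
            continue
        t_on = config.stage_times[act] - config.onset_lead_h
        a = row.zygotic_amplitude
        rising = times >= t_on
        ex = np.where(rising, a * (1.0 - np.exp(-(times - t_on) / config.exonic_tau_h)), 0.0)
        nascent = np.where(rising, config.intronic_fraction * a, 0.0) if row.has_introns else 0.0
        deact = row.deactivation_stage_true
        if deact is not None and not pd.isna(deact):
            t_off = config.stage_times[deact] - config.onset_lead_h
            off = times >= t_off
            peak = a * (1.0 - np.exp(-(t_off - t_on) / config.exonic_tau_h))
            ex = np.where(off, peak * np.exp(-config.deactivation_decay_rate * (times - t_off)), ex)
            if row.has_introns:
                nascent = np.where(off, 0.0, nascent)
        exonic[i] += ex
        intronic[i] += nascent
    return exonic, intronic


def simulate_timecourse(config: SimulationConfig, truth: pd.DataFrame) -> TimeCourse:
    """30-min exonic/intronic TPM series with multiplicative log-normal noise."""
    rng = np.random.default_rng([config.seed, 37])
    t_end = max(config.stage_times.values())
    times = np.round(np.arange(0.0, t_end + 1e-9, config.time_step_hpf), 3)
    exonic, intronic = _expected_expression(config, truth, times)
    if config.noise_sd_log > 0:
        exonic = exonic * np.exp(config.noise_sd_log * rng.standard_normal(exonic.shape))
        intronic = intronic * np.exp(config.noise_sd_log * rng.standard_normal(intronic.shape))
    return TimeCourse(
        times=times,
        exonic=pd.DataFrame(exonic, index=truth.index, columns=times),
        intronic=pd.DataFrame(intronic, index=truth.index, columns=times),
    )


# ---------------------------------------------------------------------------
# LOF count tables and regional ratios
# ---------------------------------------------------------------------------


def _true_levels(config: SimulationConfig, truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Condition → per-gene true (exonic, intronic) relative levels.

    Signal-LOF effects act on the zygotic component only: the intronic
    (nascent) signal carries the full effect, the exonic level is diluted
    by the maternal share of the gene's pool at the assay time.
    """
    t = config.lof_assay_hpf
    maternal_now = truth.maternal_tpm0.to_numpy() * np.exp(-config.maternal_decay_rate * t)
    stages = list(config.stage_times)
    zyg_now = np.zeros(len(truth))
    for i, (gid, row) in enumerate(truth.iterrows()):
        act = row.activation_stage_true
        if act is None or pd.isna(act) or config.stage_times[act] > t:
            continue
        t_on = config.stage_times[act] - config.onset_lead_h
        zyg_now[i] = row.zygotic_amplitude * (1.0 - np.exp(-(t - t_on) / config.exonic_tau_h))
    with np.errstate(invalid="ignore"):
        zyg_share = np.where(maternal_now + zyg_now > 0, zyg_now / (maternal_now + zyg_now), 0.0)

    d_single = 1.0 - config.lof_single_level
    out: dict[str, pd.DataFrame] = {}
    for cond in LOF_CONDITIONS:
        ex = np.ones(len(truth))
        intr = np.ones(len(truth))
        if cond == "control-MO":
            pass
        elif cond == "amanitin":
            # RNAPII elongation block: the zygotic component of the pool
            # collapses to its residual; maternal RNA is untouched
            ex = 1.0 - (1.0 - config.amanitin_residual_exonic) * zyg_share
            intr = np.where(zyg_share > 0, config.amanitin_level_intronic, 1.0)
        else:
            pathways = cond.split("+")
            dep = np.vstack([truth[f"dep_{p}"].to_numpy() for p in pathways])
            up = np.vstack([truth[f"up_{p}"].to_numpy() for p in pathways])
            delta_z = np.minimum(config.lof_max_delta, d_single * dep.sum(axis=0))
            syn = truth.synergy_true.to_numpy()
            if "W" in pathways and "B" in pathways:
                delta_z = np.where(syn, 1.0 - config.synergy_double_level, delta_z)
                if "N" in pathways:
                    delta_z = np.where(
                        syn & truth.dep_N.to_numpy(),
                        np.minimum(config.lof_max_delta, delta_z + d_single),
                        delta_z,
                    )
            elif ("W" in pathways) != ("B" in pathways):
                syn_single = syn & np.isin(["W", "B"], pathways).any()
                delta_z = np.where(syn_single, np.maximum(delta_z, 1.0 - config.synergy_single_level), delta_z)
            up_any = up.any(axis=0) & (dep.sum(axis=0) == 0) & ~syn
            intr_level = np.where(up_any, config.lof_up_level, 1.0 - delta_z)
            ex = 1.0 - delta_z * zyg_share
            ex = np.where(up_any, 1.0 + (config.lof_up_level - 1.0) * zyg_share, ex)
            intr = intr_level
        # genes without nascent signal have no intronic readout
        no_intron = ~truth.has_introns.to_numpy() | (zyg_now == 0)
        intr = np.where(no_intron, 1.0, intr)
        out[cond] = pd.DataFrame({"exonic": ex, "intronic": intr}, index=truth.index)
    return out


def _combined_level(levels: pd.DataFrame, has_nascent: np.ndarray) -> np.ndarray:
    """More extreme of the exonic/intronic deviations from 100% of control."""
    ex = levels.exonic.to_numpy()
    intr = np.where(has_nascent, levels.intronic.to_numpy(), np.nan)
    pick = np.abs(np.nan_to_num(intr, nan=1.0) - 1.0) > np.abs(ex - 1.0)
    return np.where(pick, intr, ex) * 100.0


def simulate_counts_table(
    control_means: pd.DataFrame,
    condition_levels: Mapping[str, pd.DataFrame],
    replicates: int,
    dispersion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tidy NB replicate counts for arbitrary condition/level designs.

    ``control_means`` has exonic/intronic mean-count columns per gene;
    ``condition_levels`` maps condition → same-shaped relative levels
    (fractions of control). Each condition gets its own paired control
    draws. Returns columns gene_id, condition, signal_type, arm,
    replicate, count.
    """
    size = 1.0 / dispersion
    blocks = []
    for cond, levels in condition_levels.items():
        for sig in ("exonic", "intronic"):
            base = control_means[sig].to_numpy()
            for arm, mean in (("condition", base * levels[sig].to_numpy()), ("control", base)):
                for rep in range(1, replicates + 1):
                    mu = np.maximum(mean, 1e-9)
                    counts = rng.negative_binomial(size, size / (size + mu))
                    counts = np.where(mean <= 0, 0, counts)
                    blocks.append(
                        pd.DataFrame(
                            {
                                "gene_id": control_means.index,
                                "condition": cond,
                                "signal_type": sig,
                                "arm": arm,
                                "replicate": rep,
                                "count": counts,
                            }
                        )
                    )
    return pd.concat(blocks, ignore_index=True)


def simulate_lof(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LOF replicate count tables plus the regional-ratio table.

    Also records per-condition true relative levels / calls in ``truth``
    (columns ``true_level_*`` and ``true_call_*``).
    """
    rng = np.random.default_rng([config.seed, 53])
    t = config.lof_assay_hpf
    maternal_now = truth.maternal_tpm0.to_numpy() * np.exp(-config.maternal_decay_rate * t)
    levels = _true_levels(config, truth)

    zyg_now = np.zeros(len(truth))
    for i, (gid, row) in enumerate(truth.iterrows()):
        act = row.activation_stage_true
        if act is None or pd.isna(act) or config.stage_times[act] > t:
            continue
        t_on = config.stage_times[act] - config.onset_lead_h
        zyg_now[i] = row.zygotic_amplitude * (1.0 - np.exp(-(t - t_on) / config.exonic_tau_h))
    exonic_mean = config.base_count_scale * (maternal_now + zyg_now) + config.base_count_floor
    has_nascent = truth.has_introns.to_numpy() & (zyg_now > 0)
    intronic_mean = np.where(
        has_nascent, config.base_count_scale * config.intronic_fraction * zyg_now, 0.0
    )
    control_means = pd.DataFrame({"exonic": exonic_mean, "intronic": intronic_mean}, index=truth.index)

    for cond in LOF_CONDITIONS:
        lv = _combined_level(levels[cond], has_nascent)
        truth[f"true_level_{cond}"] = lv
        truth[f"true_call_{cond}"] = np.where(
            lv <= 100 / 1.5, "down", np.where(lv >= 150.0, "up", "unchanged")
        )

    counts = simulate_counts_table(control_means, levels, config.replicates, config.nb_dispersion, rng)

    # regional log-ratios ---------------------------------------------------
    mag, sd = config.region_log2_magnitude, config.region_log2_sd
    sign_av = truth.region_av_true.map({"animal": 1.0, "vegetal": -1.0, "uniform": 0.0}).to_numpy()
    sign_dv = truth.region_dv_true.map({"dorsal": 1.0, "ventral": -1.0, "uniform": 0.0}).to_numpy()
    regional = pd.DataFrame(
        {
            "log2_AV": sign_av * mag + sd * rng.standard_normal(len(truth)),
            "log2_DV": sign_dv * mag + sd * rng.standard_normal(len(truth)),
        },
        index=truth.index,
    )
    return counts, regional


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    """Everything one simulated study emits, plus its ground truth."""

    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    truth: pd.DataFrame
    coverage: dict[str, StageCoverage]
    timecourse: TimeCourse
    lof_counts: pd.DataFrame
    regional: pd.DataFrame


def simulate_bundle(config: Optional[SimulationConfig] = None, seed: Optional[int] = None) -> SimBundle:
    """Run the full generator; ``seed`` overrides the config seed."""
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = seed
    layout, genes, truth = simulate_annotation(config)
    coverage = simulate_rnapii_coverage(config, genes, truth, layout)
    tc = simulate_timecourse(config, truth)
    lof_counts, regional = simulate_lof(config, truth)
    return SimBundle(
        config=config, layout=layout, genes=genes, truth=truth,
        coverage=coverage, timecourse=tc, lof_counts=lof_counts, regional=regional,
    )
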