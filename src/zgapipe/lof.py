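"""Loss-of-function differential classification and signal synergy.

Per gene and condition we estimate the transcript level relative to control
(% of control), separately for exonic and intronic signal, combine the two
as the more extreme deviation from 100% (mirroring the "exonic and/or
intronic" criterion), attach a two-sided rate-ratio p-value on pooled
replicate counts, and adjust with Benjamini-Hochberg. Down/up calls use a
1.5-fold change from control (down iff ≤ 100/1.5 %, up iff ≥ 150%).

The α-amanitin condition (global RNAPII elongation block) defines the
zygotic reference set: genes losing ≥50% of exonic and/or intronic counts
at FDR ≤ 10%, intersected with the zygotic gene list.

The synergy factor for a LOF pair is δ_double / (δ_a + δ_b) where δ is the
fractional reduction max(0, 1 − level/100); 0/0 → 1 (no effect anywhere is
additive by convention) and a double effect over zero single deltas is
capped (default 10). Factors > 1 flag super-additive (synergistic) loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LofCondition",
    "SynergyScore",
    "rate_ratio_pvalues",
    "relative_levels",
    "bh_adjust",
    "amanitin_reference_set",
    "classify_lof_effect",
    "lof_effect_table",
    "synergy_factor",
    "synergy_table",
    "hypergeometric_enrichment",
    "DOWN_LEVEL",
    "UP_LEVEL",
    "PSEUDO_CPM",
]

#: 1.5-fold change from control RNA level, expressed as % of control
DOWN_LEVEL = 100.0 / 1.5
UP_LEVEL = 150.0
#: pseudo-rate (cpm) bounding fold changes for zero-count genes
PSEUDO_CPM = 0.5


@dataclass
class LofCondition:
    """Replicate count matrices for one condition and its paired control.

    Count matrices are genes × replicates, one pair per signal type
    (exonic/intronic); intronic may be None for exon-only designs.
    """

    label: str
    exonic: pd.DataFrame
    control_exonic: pd.DataFrame
    intronic: Optional[pd.DataFrame] = None
    control_intronic: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.exonic.shape[1] < 1 or self.control_exonic.shape[1] < 1:
            raise ValueError(f"{self.label}: each arm needs ≥1 replicate")
        if not self.exonic.index.equals(self.control_exonic.index):
            raise ValueError(f"{self.label}: condition/control gene sets differ")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, label: str) -> "LofCondition":
        """Build from a tidy count table with columns gene_id, signal_type,
        arm (condition|control), replicate, count. Genes absent in one arm
        are treated as zero counts."""
        sub = df[df.condition == label] if "condition" in df.columns else df
        mats: dict[tuple[str, str], pd.DataFrame] = {}
        for (sig, arm), block in sub.groupby(["signal_type", "arm"]):
            mats[(sig, arm)] = block.pivot(index="gene_id", columns="replicate", values="count")
        genes = sorted(set().union(*(m.index for m in mats.values())))
        mats = {k: m.reindex(genes).fillna(0.0) for k, m in mats.items()}
        return cls(
            label=label,
            exonic=mats[("exonic", "condition")],
            control_exonic=mats[("exonic", "control")],
            intronic=mats.get(("intronic", "condition")),
            control_intronic=mats.get(("intronic", "control")),
        )


def rate_ratio_pvalues(x: np.ndarray, m: np.ndarray, total_x: float, total_m: float) -> np.ndarray:
    """Two-sided exact rate-ratio p-values for paired count vectors.

    Conditional binomial test: given n = x + m, X ~ Binom(n, p0) under the
    null of equal rates, p0 = total_x / (total_x + total_m). Two-sided via
    the doubling convention p = min(1, 2·min(P(X ≤ x), P(X ≥ x))), which is
    vectorisable and slightly conservative.
    """
    x = np.asarray(x, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    n = x + m
    p0 = total_x / (total_x + total_m)
    lo = stats.binom.cdf(x, n, p0)
    hi = stats.binom.sf(x - 1, n, p0)
    p = 2.0 * np.minimum(lo, hi)
    p = np.where(n == 0, 1.0, p)
    return np.minimum(p, 1.0)


def _arm_cpm(counts: pd.DataFrame, totals: pd.Series) -> tuple[pd.Series, float]:
    """Mean cpm per gene across replicates given per-replicate library totals."""
    cpm = counts / totals.replace(0, np.nan) * 1e6
    return cpm.mean(axis=1).fillna(0.0), float(totals.sum())


def _library_totals(condition: LofCondition) -> tuple[pd.Series, pd.Series]:
    """Per-replicate library sizes, shared across signal types.

    Exonic and intronic counts of one replicate come from the same
    sequencing library, so both are scaled by the combined total. This also
    anchors the intronic (purely nascent) scale to the maternally dominated
    exonic pool, which matters under global transcription loss.
    """
    cond_tot = condition.exonic.sum(axis=0)
    ctrl_tot = condition.control_exonic.sum(axis=0)
    if condition.intronic is not None:
        cond_tot = cond_tot + condition.intronic.sum(axis=0)
        ctrl_tot = ctrl_tot + condition.control_intronic.sum(axis=0)
    return cond_tot, ctrl_tot


def relative_levels(condition: LofCondition, pseudo_cpm: float = PSEUDO_CPM) -> pd.DataFrame:
    """Per-gene relative transcript level (% of control) with p-values.

    Levels are computed separately on exonic and intronic signal and
    combined as the more extreme deviation from 100%; the p-value is the
    rate-ratio test on the summed replicate counts of the signal type that
    provided the combined level.

    Returns a DataFrame indexed by gene_id with columns relative_level,
    relative_level_exonic, relative_level_intronic, p_value.
    """
    cond_totals, ctrl_totals = _library_totals(condition)
    out = {}
    for sig, cond, ctrl in [
        ("exonic", condition.exonic, condition.control_exonic),
        ("intronic", condition.intronic, condition.control_intronic),
    ]:
        if cond is None:
            continue
        cond_cpm, cond_total = _arm_cpm(cond, cond_totals)
        ctrl_cpm, ctrl_total = _arm_cpm(ctrl, ctrl_totals)
        level = 100.0 * (cond_cpm + pseudo_cpm) / (ctrl_cpm + pseudo_cpm)
        pvals = rate_ratio_pvalues(
            cond.sum(axis=1).round().to_numpy(),
            ctrl.sum(axis=1).round().to_numpy(),
            cond_total,
            ctrl_total,
        )
        out[sig] = (level, pd.Series(pvals, index=level.index))

    ex_level, ex_p = out["exonic"]
    if "intronic" in out:
        in_level, in_p = out["intronic"]
        pick_intronic = (in_level - 100.0).abs() > (ex_level - 100.0).abs()
        level = ex_level.where(~pick_intronic, in_level)
        pval = ex_p.where(~pick_intronic, in_p)
    else:
        in_level = pd.Series(np.nan, index=ex_level.index)
        level, pval = ex_level, ex_p
    return pd.DataFrame(
        {
            "relative_level": level,
            "relative_level_exonic": ex_level,
            "relative_level_intronic": in_level,
            "p_value": pval,
        }
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_lof_effect(relative_level: float | np.ndarray) -> np.ndarray:
    """down / up / unchanged against the 1.5-fold thresholds (inclusive)."""
    level = np.asarray(relative_level, dtype=float)
    return np.where(level <= DOWN_LEVEL, "down", np.where(level >= UP_LEVEL, "up", "unchanged"))


def lof_effect_table(condition: LofCondition, pseudo_cpm: float = PSEUDO_CPM) -> pd.DataFrame:
    """relative_levels + BH q-values + down/up/unchanged calls."""
    df = relative_levels(condition, pseudo_cpm=pseudo_cpm)
    df["q_value"] = bh_adjust(df.p_value.to_numpy())
    df["call"] = classify_lof_effect(df.relative_level.to_numpy())
    df.insert(0, "condition", condition.label)
    return df


def amanitin_reference_set(
    amanitin_effects: pd.DataFrame,
    zygotic_genes: Iterable[str],
    max_level: float = 50.0,
    fdr: float = 0.10,
) -> set[str]:
    """Zygotic genes with ≥50% loss of exonic and/or intronic counts at
    FDR ≤ 10% under α-amanitin — the transcription-null reference set."""
    df = amanitin_effects
    lost = (df.relative_level_exonic <= max_level) | (df.relative_level_intronic <= max_level)
    hit = df.index[lost.fillna(False) & (df.q_value <= fdr)]
    return set(hit) & set(zygotic_genes)


@dataclass(frozen=True)
class SynergyScore:
    gene_id: str
    pair_label: str
    delta_single_a: float
    delta_single_b: float
    delta_double: float
    synergy_factor: float


def _delta(relative_level: float) -> float:
    """Fractional reduction from control, clipped to [0, 1]."""
    return float(min(1.0, max(0.0, 1.0 - relative_level / 100.0)))


def synergy_factor(
    level_a: float,
    level_b: float,
    level_double: float,
    gene_id: str = "",
    pair_label: str = "",
    cap: float = 10.0,
) -> SynergyScore:
    """δ_double / (δ_a + δ_b) with 0/0 → 1 and zero-single cap."""
    da, db, dd = _delta(level_a), _delta(level_b), _delta(level_double)
    denom = da + db
    if denom == 0.0:
        factor = 1.0 if dd == 0.0 else cap
    else:
        factor = min(dd / denom, cap)
    return SynergyScore(
        gene_id=gene_id, pair_label=pair_label,
        delta_single_a=da, delta_single_b=db, delta_double=dd,
        synergy_factor=factor,
    )


def synergy_table(
    effects_a: pd.DataFrame,
    effects_b: pd.DataFrame,
    effects_double: pd.DataFrame,
    pair_label: str = "",
    genes: Optional[Iterable[str]] = None,
    cap: float = 10.0,
) -> pd.DataFrame:
    """Per-gene synergy scores for one LOF pair.

    ``genes`` restricts the table (e.g. to genes down-called in the double
    LOF, the meaningful ranking universe); default is all shared genes.
    """
    idx = effects_a.index.intersection(effects_b.index).intersection(effects_double.index)
    if genes is not None:
        idx = idx.intersection(pd.Index(list(genes)))
    rows = [
        synergy_factor(
            effects_a.relative_level.loc[g],
            effects_b.relative_level.loc[g],
            effects_double.relative_level.loc[g],
            gene_id=g, pair_label=pair_label, cap=cap,
        ).__dict__
        for g in idx
    ]
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["pair_label", "delta_single_a", "delta_single_b", "delta_double", "synergy_factor"]
    )


def hypergeometric_enrichment(
    selected: Iterable[str], annotated: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    P(overlap ≥ observed) drawing |selected| genes from a universe
    containing |annotated| annotated genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    annotated = set(annotated) & universe
    k = len(selected & annotated)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(annotated), len(selected)))
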