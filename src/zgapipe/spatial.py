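"""Regional expression assignment and per-region signal dependency.

Genes are placed along the two primary body axes from dissection-derived
log2 expression ratios: animal-over-vegetal (AV) and dorsal-over-ventral
(DV). An axis half is assigned when |log2 ratio| reaches the enrichment
threshold (default 1, i.e. 2-fold between opposite ends), otherwise the
gene is uniform on that axis; a quadrant (e.g. dorso-vegetal) exists only
when both axes are non-uniform. The left-right axis is excluded (no
regional expression differences at gastrula stages).

Regional dependency summaries report, per region and LOF condition, the
fraction of zygotic genes in that region called down- (or up-) regulated.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lof import DOWN_LEVEL, UP_LEVEL

__all__ = [
    "assign_region",
    "regional_dependency",
    "extreme_levels_across_lofs",
    "REGION_THRESHOLD_LOG2",
]

REGION_THRESHOLD_LOG2 = 1.0

_AV_LABELS = {1: "animal", -1: "vegetal", 0: "uniform"}
_DV_LABELS = {1: "dorsal", -1: "ventral", 0: "uniform"}


def assign_region(profiles: pd.DataFrame, threshold_log2: float = REGION_THRESHOLD_LOG2) -> pd.DataFrame:
    """Label axis halves and quadrants from log2 ratios.

    ``profiles`` needs columns log2_AV and log2_DV (NaN → axis unknown).
    Adds columns av_half, dv_half, quadrant (e.g. "dorso-vegetal"; None
    when either axis is uniform or unknown).
    """
    av = profiles["log2_AV"].to_numpy(dtype=float)
    dv = profiles["log2_DV"].to_numpy(dtype=float)

    def half(vals: np.ndarray, labels: Mapping[int, str]) -> np.ndarray:
        sign = np.where(np.abs(vals) >= threshold_log2, np.sign(vals), 0).astype(int)
        out = np.array([labels[s] for s in sign], dtype=object)
        out[np.isnan(vals)] = "unknown"
        return out

    out = profiles.copy()
    out["av_half"] = half(av, _AV_LABELS)
    out["dv_half"] = half(dv, _DV_LABELS)

    quad_prefix = {"dorsal": "dorso", "ventral": "ventro"}
    quads = []
    for a, d in zip(out["av_half"], out["dv_half"]):
        if a in ("uniform", "unknown") or d in ("uniform", "unknown"):
            quads.append(None)
        else:
            quads.append(f"{quad_prefix[d]}-{a}")
    out["quadrant"] = quads
    return out


def _regions_of(row: pd.Series) -> list[str]:
    regions = []
    if row.av_half not in ("uniform", "unknown"):
        regions.append(row.av_half)
    if row.dv_half not in ("uniform", "unknown"):
        regions.append(row.dv_half)
    if row.quadrant:
        regions.append(row.quadrant)
    return regions


def regional_dependency(
    effects: Mapping[str, pd.DataFrame],
    profiles: pd.DataFrame,
    zygotic_genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fraction of zygotic genes per region affected by each LOF.

    ``effects`` maps condition label → LofEffect table (indexed by gene,
    with a ``call`` column). ``profiles`` must carry the assign_region
    labels. Fractions are over zygotic genes in the region (halves count a
    gene once per axis; quadrant rows are subsets of both their halves).
    Regions without genes get NaN fractions.

    Returns a tidy DataFrame: region, condition, n_region, n_down, n_up,
    fraction_down, fraction_up.
    """
    prof = profiles
    if zygotic_genes is not None:
        prof = prof.loc[prof.index.intersection(pd.Index(list(zygotic_genes)))]
    membership: dict[str, list[str]] = {}
    for gid, row in prof.iterrows():
        for region in _regions_of(row):
            membership.setdefault(region, []).append(gid)

    rows = []
    for region, genes in sorted(membership.items()):
        idx = pd.Index(genes)
        for cond, table in effects.items():
            shared = idx.intersection(table.index)
            n = len(idx)
            n_down = int((table.loc[shared, "call"] == "down").sum())
            n_up = int((table.loc[shared, "call"] == "up").sum())
            rows.append(
                {
                    "region": region,
                    "condition": cond,
                    "n_region": n,
                    "n_down": n_down,
                    "n_up": n_up,
                    "fraction_down": n_down / n if n else np.nan,
                    "fraction_up": n_up / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def extreme_levels_across_lofs(effects: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene minimal and maximal relative level across LOF conditions.

    A gene counts as down-regulated among the LOFs iff its minimum level is
    ≤ 100/1.5 %, and up-regulated iff its maximum is ≥ 150%.
    """
    levels = pd.DataFrame({cond: t.relative_level for cond, t in effects.items()})
    out = pd.DataFrame(
        {
            "min_level": levels.min(axis=1),
            "max_level": levels.max(axis=1),
        }
    )
    out["down_any"] = out.min_level <= DOWN_LEVEL
    out["up_any"] = out.max_level >= UP_LEVEL
    return out
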