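"""End-to-end orchestration: simulate → occupancy → temporal → LOF →
spatial → architecture, with every intermediate written as TSV and a
JSON/Markdown report of the headline numbers.

The report is deterministic given the config seed (no timestamps in the
body); provenance carries the config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .genome_model import architecture_table, write_bed12
from .lof import LofCondition, amanitin_reference_set, lof_effect_table, synergy_table
from .occupancy import call_occupancy_table
from .spatial import assign_region, extreme_levels_across_lofs, regional_dependency
from .stats import ranksum_r_effect
from .synthetic_data import (
    LOF_CONDITIONS,
    SIGNAL_CONDITIONS,
    SimBundle,
    SimulationConfig,
    simulate_bundle,
)
from .temporal import call_activation, summarize_activation, zygotic_contribution

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline"]

_PAIRS = [("W", "B", "W+B"), ("W", "N", "W+N"), ("N", "B", "N+B")]


@dataclass
class PipelineReport:
    """Structured pipeline output; every section present or marked skipped."""

    provenance: dict
    activation: dict
    lof: dict | str
    spatial: dict | str
    architecture: dict | str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        body = {
            "provenance": self.provenance,
            "activation": self.activation,
            "lof": self.lof,
            "spatial": self.spatial,
            "architecture": self.architecture,
        }
        return json.dumps(body, indent=2, default=_jsonable)

    def to_markdown(self) -> str:
        lines = ["# ZGA pipeline report", ""]
        lines += [f"- config hash: `{self.provenance['config_sha256'][:12]}`",
                  f"- seed: {self.provenance['seed']}",
                  f"- zgapipe version: {self.provenance['version']}", ""]
        act = self.activation
        lines += ["## Temporal activation", ""]
        lines.append("| stage | newly activated | cumulative | maternal share |")
        lines.append("|---|---|---|---|")
        for s, n, c, m in zip(act["stages"], act["newly_activated"],
                              act["cumulative_active"], act["maternal_fraction"]):
            lines.append(f"| {s} | {n} | {c} | {m:.1%} |")
        lines += [
            "",
            f"Total zygotic genes: {act['total_zygotic']} "
            f"({act['aggregate_maternal_fraction']:.1%} with maternal contribution); "
            f"deactivated: {act['deactivated']}.",
            "",
        ]
        for name, section in [("LOF", self.lof), ("Spatial", self.spatial),
                              ("Architecture", self.architecture)]:
            lines.append(f"## {name}")
            lines.append("")
            if isinstance(section, str):
                lines.append(f"_{section}_")
            else:
                for k, v in section.items():
                    if isinstance(v, dict):
                        lines.append(f"- {k}: " + ", ".join(f"{a}={_fmt(b)}" for a, b in v.items()))
                    else:
                        lines.append(f"- {k}: {_fmt(v)}")
            lines.append("")
        return "\n".join(lines)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(
    config: Optional[SimulationConfig] = None,
    outdir: Optional[str | Path] = None,
    *,
    bundle: Optional[SimBundle] = None,
    with_lof: bool = True,
    occupancy_bins: int = 20,
) -> PipelineReport:
    """Execute every stage on a simulated (or supplied) bundle.

    ``with_lof=False`` marks the LOF and spatial sections skipped (the
    temporal section is still produced). When ``outdir`` is given all
    intermediate tables plus report.json / report.md are written there.
    """
    if bundle is None:
        bundle = simulate_bundle(config)
    config = bundle.config
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    provenance = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
        "n_genes": config.n_genes,
    }
    tables: dict[str, pd.DataFrame] = {}

    # occupancy ------------------------------------------------------------
    logger.info("calling full-length occupancy (%d genes, %d stages)",
                len(bundle.genes), len(bundle.coverage))
    occ_long = call_occupancy_table(bundle.coverage, bundle.genes, n_bins=occupancy_bins)
    tables["occupancy_calls"] = occ_long
    occupied = occ_long.pivot(index="gene_id", columns="stage", values="occupied")

    # temporal -------------------------------------------------------------
    records = call_activation(occupied, bundle.timecourse, stage_times=config.stage_times)
    tables["activation_records"] = records
    summary = summarize_activation(records, stages=list(config.stage_times))
    contribution = zygotic_contribution(summary, summary.n_maternal_detected)
    activation_section = summary.to_dict() | {
        "aggregate_maternal_fraction": summary.aggregate_maternal_fraction,
        "zygotic_contribution": contribution.tolist(),
        "zygotic_contribution_analysis_set": zygotic_contribution(
            summary, summary.n_maternal_detected_analysis
        ).tolist()
        if summary.n_maternal_detected_analysis
        else None,
    }

    # LOF ------------------------------------------------------------------
    if with_lof and bundle.lof_counts is not None:
        effects: dict[str, pd.DataFrame] = {}
        for cond in LOF_CONDITIONS:
            effects[cond] = lof_effect_table(LofCondition.from_tidy(bundle.lof_counts, cond))
        tables["lof_effects"] = pd.concat(effects.values())
        zygotic_genes = records.index[records.activation_stage.notna()]
        reference = amanitin_reference_set(effects["amanitin"], zygotic_genes)
        syn_tables = []
        for a, b, double in _PAIRS:
            down_double = effects[double].index[effects[double].call == "down"]
            syn_tables.append(
                synergy_table(
                    effects[a], effects[b], effects[double],
                    pair_label=double, genes=set(down_double) & reference,
                )
            )
        synergy = pd.concat(syn_tables)
        tables["synergy_scores"] = synergy
        lof_section = {
            "n_zygotic": int(len(zygotic_genes)),
            "n_amanitin_reference": int(len(reference)),
            "misregulated_fraction": {
                cond: float(
                    (effects[cond].loc[effects[cond].index.intersection(reference), "call"] != "unchanged").mean()
                )
                for cond in SIGNAL_CONDITIONS
            },
            "mean_synergy_factor": {
                double: float(synergy.loc[synergy.pair_label == double, "synergy_factor"].mean())
                for _, _, double in _PAIRS
                if (synergy.pair_label == double).any()
            },
        }

        # spatial ------------------------------------------------------------
        profiles = assign_region(bundle.regional)
        tables["regional_profiles"] = profiles
        signal_effects = {c: effects[c] for c in SIGNAL_CONDITIONS}
        dependency = regional_dependency(signal_effects, profiles, zygotic_genes=reference)
        tables["regional_dependency"] = dependency
        extremes = extreme_levels_across_lofs(signal_effects)
        tables["lof_extreme_levels"] = extremes
        ref_extremes = extremes.loc[extremes.index.intersection(reference)]
        spatial_section = {
            "n_regions": int(dependency.region.nunique()),
            "down_any_fraction": float(ref_extremes.down_any.mean()) if len(ref_extremes) else None,
            "up_any_fraction": float(ref_extremes.up_any.mean()) if len(ref_extremes) else None,
        }
    else:
        lof_section = "skipped: no LOF inputs"
        spatial_section = "skipped: no LOF inputs"

    # architecture ---------------------------------------------------------
    arch = architecture_table(bundle.genes)
    tables["architecture"] = arch
    pre_mbt = records.index[records.activation_stage.isin(["32-cell", "128-cell", "1024-cell"])]
    maternal_only = records.index[records.gene_class == "maternal-only"]
    if len(pre_mbt) and len(maternal_only):
        cmp_ = ranksum_r_effect(
            arch.loc[pre_mbt, "gene_length_bp"], arch.loc[maternal_only, "gene_length_bp"],
            label_a="pre-MBT activated", label_b="maternal-only",
        )
        architecture_section = {
            "pre_mbt_median_length_bp": float(arch.loc[pre_mbt, "gene_length_bp"].median()),
            "maternal_median_length_bp": float(arch.loc[maternal_only, "gene_length_bp"].median()),
            "length_comparison": {
                "p_value": cmp_.p_value,
                "r_effect": cmp_.r_effect,
                "n_a": cmp_.n_a,
                "n_b": cmp_.n_b,
            },
        }
    else:
        architecture_section = "skipped: a comparison group is empty"

    report = PipelineReport(
        provenance=provenance,
        activation=activation_section,
        lof=lof_section,
        spatial=spatial_section,
        architecture=architecture_section,
        tables=tables,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed12(bundle.genes, outdir / "annotation.bed")
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.md").write_text(report.to_markdown())
    return report
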