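"""Temporal zygotic genome activation calling.

Combines per-stage full-length RNAPII occupancy with a 30-min-resolution
transcript time course (exonic and intronic TPM) to assign each gene an
activation stage, an optional deactivation stage, a maternal flag and a
maternal/zygotic class, and to summarise activation dynamics including the
zygotic contribution to the transcriptome.

Thresholds (all inclusive):
  analysis set   — mean total TPM ≥ 3 over some 1-h window (3 samples);
  presence       — total TPM ≥ 0.1 at the sample nearest the stage time;
  maternal       — mean total TPM ≥ 0.1 over the first hour (t ≤ 1.0 hpf),
                   when the zygotic genome is still silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourse",
    "ActivationSummary",
    "STAGE_TIMES_HPF",
    "filter_analysis_set",
    "maternal_flag",
    "call_activation",
    "summarize_activation",
    "zygotic_contribution",
]

#: profiled stages and their approximate developmental times (hpf)
STAGE_TIMES_HPF: dict[str, float] = {
    "32-cell": 2.5,
    "128-cell": 3.0,
    "1024-cell": 4.0,
    "MBT": 4.5,
    "mid-gastrula": 7.5,
    "late-gastrula": 10.0,
}

ANALYSIS_TPM = 3.0
PRESENCE_TPM = 0.1
MATERNAL_TPM = 0.1
FIRST_HOUR_HPF = 1.0


@dataclass
class TimeCourse:
    """Gene × time exonic/intronic TPM matrices on a 0.5-h grid."""

    times: np.ndarray  # hpf, strictly increasing
    exonic: pd.DataFrame  # genes × times
    intronic: pd.DataFrame  # same shape/index

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.exonic.shape != self.intronic.shape:
            raise ValueError("exonic and intronic matrices differ in shape")
        if self.exonic.shape[1] != len(self.times):
            raise ValueError("matrix width does not match the time grid")

    @property
    def total(self) -> pd.DataFrame:
        return self.exonic + self.intronic

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "TimeCourse":
        """Build from a tidy table (gene_id, time_hpf, tpm_exonic, tpm_intronic)."""
        ex = df.pivot(index="gene_id", columns="time_hpf", values="tpm_exonic").sort_index(axis=1)
        intr = df.pivot(index="gene_id", columns="time_hpf", values="tpm_intronic").sort_index(axis=1)
        return cls(times=ex.columns.to_numpy(float), exonic=ex, intronic=intr)

    def to_table(self) -> pd.DataFrame:
        ex = self.exonic.stack().rename("tpm_exonic")
        intr = self.intronic.stack().rename("tpm_intronic")
        out = pd.concat([ex, intr], axis=1).reset_index()
        out.columns = ["gene_id", "time_hpf", "tpm_exonic", "tpm_intronic"]
        return out


def filter_analysis_set(tc: TimeCourse, analysis_tpm: float = ANALYSIS_TPM, window: int = 3) -> pd.Series:
    """True where some 1-h window (3 consecutive 0.5-h samples, ends
    inclusive) has mean total TPM ≥ the detection threshold."""
    total = tc.total.to_numpy()
    n = total.shape[1]
    if n < window:
        logger.warning("fewer than %d samples; evaluating the single available window", window)
        best = total.mean(axis=1)
    else:
        kernel = np.ones(window) / window
        means = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, total)
        best = means.max(axis=1)
    return pd.Series(best >= analysis_tpm, index=tc.exonic.index, name="in_analysis_set")


def maternal_flag(
    tc: TimeCourse,
    maternal_tpm: float = MATERNAL_TPM,
    first_hour_hpf: float = FIRST_HOUR_HPF,
) -> pd.Series:
    """True where mean total TPM over samples at t ≤ 1.0 hpf is ≥ 0.1."""
    mask = tc.times <= first_hour_hpf
    if not mask.any():
        raise ValueError("time course does not cover the first hour post-fertilization")
    mean0 = tc.total.to_numpy()[:, mask].mean(axis=1)
    return pd.Series(mean0 >= maternal_tpm, index=tc.exonic.index, name="maternal")


def _nearest_sample(times: np.ndarray, t: float) -> int:
    """Index of the sample nearest t; ties resolve to the earlier sample."""
    d = np.abs(times - t)
    return int(np.argmin(d))  # argmin takes the first (earlier) on ties


def call_activation(
    occupancy: pd.DataFrame,
    tc: TimeCourse,
    stage_times: Mapping[str, float] = STAGE_TIMES_HPF,
    presence_tpm: float = PRESENCE_TPM,
    analysis_tpm: float = ANALYSIS_TPM,
) -> pd.DataFrame:
    """Per-gene activation records.

    ``occupancy`` is a gene × stage boolean DataFrame of full-length calls
    (stages in profiling order; stages missing for a gene are skipped with a
    warning). A gene is active at a stage when it is occupied there and its
    total TPM at the stage-nearest sample is ≥ the presence threshold.
    Activation stage is the first active stage; the deactivation stage is
    the first later profiled stage where occupancy is lost and never
    regained. The maternal/zygotic class combines the maternal flag with
    whether the gene was ever activated.

    Returns a DataFrame indexed by gene_id with columns in_analysis_set,
    activation_stage, deactivation_stage, maternal, gene_class.
    """
    stages = [s for s in stage_times if s in occupancy.columns]
    missing = [s for s in stage_times if s not in occupancy.columns]
    if missing:
        logger.warning("stages without occupancy calls skipped: %s", missing)
    in_set = filter_analysis_set(tc, analysis_tpm=analysis_tpm)
    maternal = maternal_flag(tc)

    sample_idx = {s: _nearest_sample(tc.times, stage_times[s]) for s in stages}
    total = tc.total

    records = []
    for gid in tc.exonic.index:
        mat = bool(maternal.loc[gid])
        analysed = bool(in_set.loc[gid])
        act: Optional[str] = None
        deact: Optional[str] = None
        if analysed and gid in occupancy.index:
            occ = occupancy.loc[gid, stages].to_numpy(dtype=bool)
            present = np.array(
                [total.iat[total.index.get_loc(gid), sample_idx[s]] >= presence_tpm for s in stages]
            )
            active = occ & present
            if active.any():
                first = int(np.argmax(active))
                act = stages[first]
                # first later stage where occupancy is lost for good
                for j in range(first + 1, len(stages)):
                    if not occ[j] and not occ[j + 1 :].any():
                        deact = stages[j]
                        break
        if act is not None:
            klass = "maternal-zygotic" if mat else "zygotic-only"
        else:
            klass = "maternal-only" if mat else "silent"
        records.append(
            {
                "gene_id": gid,
                "in_analysis_set": analysed,
                "activation_stage": act,
                "deactivation_stage": deact,
                "maternal": mat,
                "gene_class": klass,
            }
        )
    return pd.DataFrame(records).set_index("gene_id")


@dataclass
class ActivationSummary:
    """Stage-resolved activation bookkeeping."""

    stages: list[str]
    newly_activated: np.ndarray  # per stage
    cumulative_active: np.ndarray
    maternal_newly_activated: np.ndarray
    maternal_fraction: np.ndarray  # maternal share of newly activated
    total_zygotic: int
    total_maternal_zygotic: int
    deactivated: int
    n_maternal_detected: int  # genes with maternal flag (full input table)
    n_maternal_detected_analysis: int = 0  # restricted to the analysis set

    @property
    def aggregate_maternal_fraction(self) -> float:
        """Share of all newly activated genes with maternal contribution."""
        return self.total_maternal_zygotic / self.total_zygotic if self.total_zygotic else 0.0

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "newly_activated": self.newly_activated.tolist(),
            "cumulative_active": self.cumulative_active.tolist(),
            "maternal_newly_activated": self.maternal_newly_activated.tolist(),
            "maternal_fraction": self.maternal_fraction.tolist(),
            "total_zygotic": self.total_zygotic,
            "total_maternal_zygotic": self.total_maternal_zygotic,
            "deactivated": self.deactivated,
            "n_maternal_detected": self.n_maternal_detected,
            "n_maternal_detected_analysis": self.n_maternal_detected_analysis,
        }


def summarize_activation(
    records: pd.DataFrame,
    stages: Sequence[str] = tuple(STAGE_TIMES_HPF),
) -> ActivationSummary:
    """Aggregate activation records into per-stage counts and totals."""
    stages = list(stages)
    newly = np.array([(records.activation_stage == s).sum() for s in stages])
    mat_newly = np.array(
        [((records.activation_stage == s) & records.maternal).sum() for s in stages]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat_frac = np.where(newly > 0, mat_newly / np.maximum(newly, 1), 0.0)
    activated = records.activation_stage.notna()
    return ActivationSummary(
        stages=stages,
        newly_activated=newly,
        cumulative_active=np.cumsum(newly),
        maternal_newly_activated=mat_newly,
        maternal_fraction=mat_frac,
        total_zygotic=int(activated.sum()),
        total_maternal_zygotic=int((activated & records.maternal).sum()),
        deactivated=int(records.deactivation_stage.notna().sum()),
        n_maternal_detected=int(records.maternal.sum()),
        n_maternal_detected_analysis=int((records.maternal & records.in_analysis_set).sum()),
    )


def zygotic_contribution(summary: ActivationSummary, n_maternal_detected: int) -> np.ndarray:
    """Per-stage cumulative zygotic gene count over the maternal-detected
    gene count — the zygotic share of the transcriptome by gene number."""
    if n_maternal_detected <= 0:
        raise ValueError("n_maternal_detected must be positive")
    return summary.cumulative_active / n_maternal_detected
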