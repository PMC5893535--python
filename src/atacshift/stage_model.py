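"""Per-peak linear regression of signal on disease stage and confounders.

For each peak the normalized signal across samples is modeled as

    C_N = a0 + a1*stage + a2*region + a3*gender + a4*age + a5*interval + eps

with stage coded 0/1/2 (normal/early/late), region and gender coded -1/+1,
age in years and procurement interval in hours. The stage coefficient a1 is
tested two-sided with a t-test and BH-adjusted across peaks; differentially
accessible regions (DARs) are the top-ranked peaks with significantly
negative a1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .intervals import PeakSet
from .matrix import NormalizedMatrix, SampleMeta

__all__ = [
    "StageFitTable",
    "DARSet",
    "design_matrix",
    "fit_stage_model",
    "select_dars",
]

COEF_NAMES = ["alpha0", "alpha1", "alpha2", "alpha3", "alpha4", "alpha5"]
_COVARIATES = ["intercept", "stage", "region", "gender", "age", "interval"]


def design_matrix(samples: list[SampleMeta]) -> np.ndarray:
    """Samples x 6 design matrix [1, stage, region, gender, age, interval]."""
    return np.column_stack(
        [
            np.ones(len(samples)),
            [s.stage_code for s in samples],
            [s.region_code for s in samples],
            [s.gender_code for s in samples],
            [s.age for s in samples],
            [s.interval for s in samples],
        ]
    ).astype(float)


@dataclass
class StageFitTable:
    """Per-peak OLS coefficients, standard errors and stage-test FDR."""

    peaks: PeakSet
    alpha: np.ndarray = field(repr=False)  # peaks x 6
    se: np.ndarray = field(repr=False)  # peaks x 6
    stage_p: np.ndarray = field(repr=False)
    stage_fdr: np.ndarray = field(repr=False)
    sigma2: np.ndarray = field(repr=False)  # residual variance per peak

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.alpha, columns=COEF_NAMES)
        df.insert(0, "peak", self.peaks.names())
        df["se1"] = self.se[:, 1]
        df["stage_p"] = self.stage_p
        df["stage_fdr"] = self.stage_fdr
        df["sigma2"] = self.sigma2
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class DARSet:
    """Ranked differentially accessible regions (most negative a1 first)."""

    peaks: PeakSet
    coefficients: np.ndarray
    fdr_cut: float
    top_n: int
    order: list[int] = field(default_factory=list)  # rank order into peaks

    def ranked_intervals(self):
        return [self.peaks.intervals[i] for i in self.order]

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rank, i in enumerate(self.order, start=1):
                iv = self.peaks.intervals[i]
                name = iv.name or iv.default_name()
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{rank}\n")


def fit_stage_model(norm: NormalizedMatrix, samples: list[SampleMeta] | None = None) -> StageFitTable:
    """Ordinary least squares per peak with the study's covariate coding.

    Requires at least 7 samples (6 parameters plus one residual degree of
    freedom) and a full-rank design. The stage p-value is the two-sided
    t-test on a1; FDR is BH across peaks.
    """
    samples = norm.samples if samples is None else samples
    x = design_matrix(samples)
    n, p = x.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples to fit {p} coefficients, got {n}")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        bad = [
            _COVARIATES[j]
            for j in range(1, p)
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    y = norm.values.T  # samples x peaks
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # 6 x peaks
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # 6 x peaks
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[1] / se[1]
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)  # zero-variance peaks: no evidence
    stage_p = 2 * stats.t.sf(np.abs(tstat), dof)
    return StageFitTable(
        peaks=norm.peaks,
        alpha=beta.T,
        se=se.T,
        stage_p=stage_p,
        stage_fdr=bh_adjust(stage_p),
        sigma2=sigma2,
    )


def select_dars(fits: StageFitTable, fdr_cut: float = 0.01, top_n: int = 5000) -> tuple[DARSet, PeakSet]:
    """Select DARs and the complementary non-DAR set.

    Candidates are peaks with stage FDR < ``fdr_cut`` and a1 < 0, ranked
    ascending by a1 (strongest decrease first); the first ``top_n`` are the
    DARs. Ties in a1 break by smaller FDR, then genomic coordinate. When
    fewer than ``top_n`` candidates pass, all of them are returned.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if len(fits.peaks) == 0:
        raise ValueError("empty fit table")
    a1 = fits.alpha[:, 1]
    candidates = [
        i
        for i in range(len(fits.peaks))
        if fits.stage_fdr[i] < fdr_cut and a1[i] < 0
    ]
    candidates.sort(
        key=lambda i: (
            a1[i],
            fits.stage_fdr[i],
            fits.peaks.intervals[i].chrom,
            fits.peaks.intervals[i].start,
            fits.peaks.intervals[i].end,
        )
    )
    chosen = candidates[:top_n]
    chosen_set = set(chosen)
    dar_peaks = PeakSet(
        [fits.peaks.intervals[i] for i in chosen],
        provenance=f"{fits.peaks.provenance}|DARs(fdr<{fdr_cut:g},top{top_n})",
    )
    # PeakSet re-sorts genomically; keep the rank order as indices into it
    name_to_pos = {iv.default_name(): j for j, iv in enumerate(dar_peaks)}
    order = [name_to_pos[fits.peaks.intervals[i].default_name()] for i in chosen]
    dars = DARSet(
        peaks=dar_peaks,
        coefficients=np.array([a1[i] for i in chosen]),
        fdr_cut=fdr_cut,
        top_n=top_n,
        order=order,
    )
    non_dars = PeakSet(
        [fits.peaks.intervals[i] for i in range(len(fits.peaks)) if i not in chosen_set],
        provenance=f"{fits.peaks.provenance}|non-DARs",
    )
    return dars, non_dars
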