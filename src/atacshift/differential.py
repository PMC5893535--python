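"""Pairwise and three-group differential accessibility tests.

The pairwise test is a negative-binomial exact test in the classic
conditional form: counts are scaled to a common library size, summed per
group, and the two-sided p-value is the probability mass of all splits of
the total whose conditional probability does not exceed that of the
observed split. A single common dispersion is estimated by the method of
moments on the scaled counts. This is the same model family as the
standard count-based packages; exact concordance with any one of them is
not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix, NormalizedMatrix, normalize_counts

__all__ = [
    "DifferentialResult",
    "GlobalShiftSummary",
    "bh_adjust",
    "estimate_common_dispersion",
    "differential_test",
    "three_group_test",
    "global_shift",
    "paired_eye_shift",
]

LOG2FC_PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    """Per-peak differential accessibility statistics (group B vs A)."""

    peak: list[str]
    mean_signal: np.ndarray
    log2fc: np.ndarray
    pvalue: np.ndarray
    fdr: np.ndarray
    fc_threshold: float = 0.8
    fdr_threshold: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return (np.abs(self.log2fc) > self.fc_threshold) & (self.fdr < self.fdr_threshold)

    @property
    def direction(self) -> np.ndarray:
        out = np.where(self.log2fc < 0, "reduced", np.where(self.log2fc > 0, "increased", "tie"))
        return out.astype(object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak": self.peak,
                "mean_signal": self.mean_signal,
                "log2fc": self.log2fc,
                "pvalue": self.pvalue,
                "fdr": self.fdr,
                "significant": self.significant,
                "direction": self.direction,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class GlobalShiftSummary:
    """Counts of reduced/increased peaks plus a binned mean fold-change curve."""

    n_peaks: int
    n_reduced: int
    n_increased: int
    n_ties: int
    mean_fc_curve: pd.DataFrame = field(repr=False)  # columns: bin_center, mean_log2fc

    @property
    def frac_reduced(self) -> float:
        return self.n_reduced / self.n_peaks


def estimate_common_dispersion(scaled: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion from within-group moments.

    For NB counts, Var = mu + phi * mu^2; pooling (s^2 - m) against m^2
    across peaks and groups (groups of size >= 2 only) gives a single phi,
    clipped below at a small positive floor.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if den <= 0:
        return MIN_DISPERSION
    return max(num / den, MIN_DISPERSION)


def _nb_exact_pvalue(s_a: float, s_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact NB test of equal means given group sums.

    Conditions on the total t = s_a + s_b. Under the null the group sums are
    NB with sizes n_a/phi and n_b/phi and means proportional to group size;
    the p-value sums the conditional probabilities of every split of t that
    is no more likely than the observed one.
    """
    s_a, s_b = int(round(s_a)), int(round(s_b))
    t = s_a + s_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    # common success probability cancels in the conditional distribution
    p_nb = r_a / (r_a + n_a * mu)
    if t > 200_000:
        # conditional split is beta-binomial(t, r_a, r_b); normal
        # approximation for very deep peaks
        mean_a = t * r_a / (r_a + r_b)
        var_a = (
            t * r_a * r_b * (r_a + r_b + t) / ((r_a + r_b) ** 2 * (r_a + r_b + 1))
        )
        z = abs(s_a - mean_a) / np.sqrt(var_a)
        return float(min(2 * stats.norm.sf(z), 1.0))
    x = np.arange(t + 1)
    logpmf = stats.nbinom.logpmf(x, r_a, p_nb) + stats.nbinom.logpmf(t - x, r_b, p_nb)
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    total = pmf.sum()
    obs = pmf[s_a]
    return float(min(pmf[pmf <= obs * (1 + 1e-12)].sum() / total, 1.0))


def differential_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = 0.8,
    fdr_threshold: float = 0.05,
) -> DifferentialResult:
    """Test each peak for differential accessibility between two groups.

    log2 fold change is of library-size-scaled group means (B over A) with a
    0.5 pseudo-count; p-values come from the NB exact test with a common
    method-of-moments dispersion; FDR is Benjamini-Hochberg. A peak is
    significant when |log2FC| > ``fc_threshold`` and FDR < ``fdr_threshold``.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    ia = np.array([counts.sample_index(s) for s in group_a])
    ib = np.array([counts.sample_index(s) for s in group_b])
    s_l = counts.library_sizes()
    ref = float(np.exp(np.mean(np.log(s_l))))  # geometric mean library size
    scaled = counts.raw * (ref / s_l)[np.newaxis, :]

    mean_a = scaled[:, ia].mean(axis=1)
    mean_b = scaled[:, ib].mean(axis=1)
    log2fc = np.log2(mean_b + LOG2FC_PSEUDOCOUNT) - np.log2(mean_a + LOG2FC_PSEUDOCOUNT)

    phi = estimate_common_dispersion(scaled, [ia, ib])
    sums_a = scaled[:, ia].sum(axis=1)
    sums_b = scaled[:, ib].sum(axis=1)
    pvals = np.array(
        [
            _nb_exact_pvalue(sa, sb, len(ia), len(ib), phi)
            for sa, sb in zip(sums_a, sums_b)
        ]
    )
    norm = normalize_counts(counts)
    mean_signal = norm.values[:, np.concatenate([ia, ib])].mean(axis=1)
    return DifferentialResult(
        peak=counts.peaks.names(),
        mean_signal=mean_signal,
        log2fc=log2fc,
        pvalue=pvals,
        fdr=bh_adjust(pvals),
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )


def three_group_test(
    counts: CountMatrix | NormalizedMatrix,
    groups: list[list[str]],
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Omnibus three-group test of normalized signal per peak.

    A one-way ANOVA F-test on C_N across the three groups (an approximation
    of a count-model omnibus test), BH-adjusted across peaks. For each
    adjacent contrast the sign of the group-mean difference is reported
    (``decreased`` / ``increased`` / ``tie``).
    """
    if len(groups) != 3:
        raise ValueError("exactly three groups required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    all_ids = [s for g in groups for s in g]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("groups must be disjoint")
    norm = normalize_counts(counts) if isinstance(counts, CountMatrix) else counts
    idx = [np.array([norm.sample_index(s) for s in g]) for g in groups]
    arrays = [norm.values[:, i] for i in idx]
    f, p = stats.f_oneway(*arrays, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero within- and between-group variance
    fdr = bh_adjust(p)
    means = [a.mean(axis=1) for a in arrays]

    def _sign(d: np.ndarray) -> np.ndarray:
        return np.where(d < 0, "decreased", np.where(d > 0, "increased", "tie")).astype(object)

    return pd.DataFrame(
        {
            "peak": norm.peaks.names(),
            "fstat": f,
            "pvalue": p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
            "contrast_1_vs_0": _sign(means[1] - means[0]),
            "contrast_2_vs_1": _sign(means[2] - means[1]),
        }
    )


def _shift_summary(mean_signal: np.ndarray, log2fc: np.ndarray, n_bins: int) -> GlobalShiftSummary:
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if log2fc.size == 0:
        raise ValueError("empty result")
    n_reduced = int(np.sum(log2fc < 0))
    n_increased = int(np.sum(log2fc > 0))
    n_ties = int(np.sum(log2fc == 0))
    edges = np.linspace(mean_signal.min(), mean_signal.max(), n_bins + 1)
    which = np.clip(np.digitize(mean_signal, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            rows.append((centers[b], float(log2fc[mask].mean())))
    curve = pd.DataFrame(rows, columns=["bin_center", "mean_log2fc"])
    return GlobalShiftSummary(
        n_peaks=int(log2fc.size),
        n_reduced=n_reduced,
        n_increased=n_increased,
        n_ties=n_ties,
        mean_fc_curve=curve,
    )


def global_shift(result: DifferentialResult, n_bins: int = 50) -> GlobalShiftSummary:
    """Summarize the genome-wide direction of accessibility change.

    Peaks with negative log2FC count as reduced, positive as increased and
    exact zeros as ties; ties stay in the denominator of ``frac_reduced``
    but not its numerator. The curve is the mean log2FC per mean-intensity
    bin (the MA-plot trend line).
    """
    return _shift_summary(np.asarray(result.mean_signal), np.asarray(result.log2fc), n_bins)


def paired_eye_shift(
    norm: NormalizedMatrix, left: str, right: str, n_bins: int = 50
) -> GlobalShiftSummary:
    """Per-peak signal shift between two samples of one donor.

    log2FC is simply C_N(left) - C_N(right) since C_N is already
    library-size normalized; used for the asymmetric-disease eye-pair
    comparison and its symmetric-pair control.
    """
    il = norm.sample_index(left)
    ir = norm.sample_index(right)
    log2fc = norm.values[:, il] - norm.values[:, ir]
    mean_signal = 0.5 * (norm.values[:, il] + norm.values[:, ir])
    return _shift_summary(mean_signal, log2fc, n_bins)
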