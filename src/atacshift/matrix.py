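"""Peak x sample signal matrices: normalization, filtering and MDS.

The raw matrix holds fragment counts C_R per peak and sample. Normalized
signal is

    C_N = log2(C_R / S_L * 1e8 + 1)

where S_L is the per-sample library size (count of qualified fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "NormalizedMatrix",
    "normalize_counts",
    "filter_by_mean_signal",
    "classical_mds",
    "read_sample_table",
    "write_sample_table",
]

NORMALIZATION_SCALE = 100_000_000

_META_COLUMNS = [
    "sample_id",
    "tissue",
    "region_code",
    "stage_code",
    "gender_code",
    "age",
    "interval",
    "library_size",
]


@dataclass
class SampleMeta:
    """Per-sample covariates and library size.

    Codings follow the study design: ``stage_code`` 0/1/2 for normal, early
    and late disease; ``region_code`` -1 periphery / +1 macula;
    ``gender_code`` -1 female / +1 male; ``age`` in years; ``interval`` the
    death-to-procurement time in hours; ``library_size`` the count of
    qualified fragments.
    """

    sample_id: str
    tissue: str = "retina"
    region_code: int = -1
    stage_code: int = 0
    gender_code: int = -1
    age: float = 85.0
    interval: float = 8.0
    library_size: float = 30_000_000.0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"{self.sample_id}: library_size must be > 0")
        if self.stage_code not in (0, 1, 2):
            raise ValueError(f"{self.sample_id}: stage_code must be 0, 1 or 2")
        if self.region_code not in (-1, 1):
            raise ValueError(f"{self.sample_id}: region_code must be -1 or +1")
        if self.gender_code not in (-1, 1):
            raise ValueError(f"{self.sample_id}: gender_code must be -1 or +1")


def write_sample_table(samples: list[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(s, c) for c in _META_COLUMNS} for s in samples])
    df.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            region_code=int(r.region_code),
            stage_code=int(r.stage_code),
            gender_code=int(r.gender_code),
            age=float(r.age),
            interval=float(r.interval),
            library_size=float(r.library_size),
        )
        for r in df.itertuples()
    ]


def _check_dims(peaks: PeakSet, samples: list[SampleMeta], values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != (len(peaks), len(samples)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(peaks)} peaks x {len(samples)} samples"
        )
    return values


@dataclass
class CountMatrix:
    """Raw fragment counts C_R over a peak universe for a sample cohort."""

    peaks: PeakSet
    samples: list[SampleMeta]
    raw: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.raw = _check_dims(self.peaks, self.samples, self.raw)
        if np.any(self.raw < 0) or not np.issubdtype(self.raw.dtype, np.integer):
            if not np.allclose(self.raw, np.round(self.raw)) or np.any(self.raw < 0):
                raise ValueError("raw counts must be non-negative integers")
            self.raw = self.raw.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.peaks.names(), columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("peak").to_csv(path, sep="\t")


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log2-scale signal C_N."""

    peaks: PeakSet
    samples: list[SampleMeta]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = _check_dims(self.peaks, self.samples, self.values).astype(float)
        if np.any(self.values < 0):
            raise ValueError("normalized signal must be >= 0")

    sample_ids = CountMatrix.sample_ids
    sample_index = CountMatrix.sample_index
    library_sizes = CountMatrix.library_sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.peaks.names(), columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("peak").to_csv(path, sep="\t", float_format="%.6g")


def normalize_counts(counts: CountMatrix, library_sizes: np.ndarray | None = None) -> NormalizedMatrix:
    """Apply C_N = log2(C_R / S_L * 1e8 + 1) element-wise.

    ``library_sizes`` overrides the metadata column, which supports the
    alternative properly-paired-fragment library size without a second code
    path.
    """
    s_l = counts.library_sizes() if library_sizes is None else np.asarray(library_sizes, dtype=float)
    if s_l.shape != (len(counts.samples),):
        raise ValueError("library_sizes length must match sample count")
    if np.any(s_l <= 0):
        raise ValueError("library sizes must be > 0")
    values = np.log2(counts.raw / s_l[np.newaxis, :] * NORMALIZATION_SCALE + 1.0)
    return NormalizedMatrix(counts.peaks, counts.samples, values)


def invert_normalization(norm: NormalizedMatrix) -> np.ndarray:
    """Recover C_R from C_N (floating point; exact up to rounding)."""
    s_l = norm.library_sizes()
    return (np.exp2(norm.values) - 1.0) * s_l[np.newaxis, :] / NORMALIZATION_SCALE


def filter_by_mean_signal(
    norm: NormalizedMatrix,
    threshold: float | str = 6.5,
    scope: list[str] | None = None,
) -> NormalizedMatrix:
    """Keep peaks whose mean C_N over ``scope`` samples is >= threshold.

    ``threshold`` may be a constant (default 6.5) or the string
    ``"quantile:q"`` for the q-quantile of the per-peak means (the study's
    75%-quantile heuristic is ``"quantile:0.75"``). The sample set is
    unchanged; only peaks are dropped.
    """
    if scope is None:
        idx = np.arange(len(norm.samples))
    else:
        if len(scope) == 0:
            raise ValueError("scope must be non-empty")
        idx = np.array([norm.sample_index(s) for s in scope])
    means = norm.values[:, idx].mean(axis=1)
    if isinstance(threshold, str):
        if not threshold.startswith("quantile:"):
            raise ValueError(f"threshold string must be 'quantile:q', got {threshold!r}")
        q = float(threshold.split(":", 1)[1])
        cut = float(np.quantile(means, q))
    else:
        cut = float(threshold)
    keep = means >= cut
    kept_peaks = PeakSet(
        [iv for iv, k in zip(norm.peaks, keep) if k],
        provenance=f"{norm.peaks.provenance}|mean_signal>={cut:g}",
    )
    return NormalizedMatrix(kept_peaks, norm.samples, norm.values[keep, :])


def classical_mds(norm: NormalizedMatrix | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of samples from Euclidean C_N distances.

    Double-centers the squared sample-sample Euclidean distance matrix and
    eigendecomposes it; coordinates are eigenvectors scaled by the square
    root of the (clipped non-negative) eigenvalues. Deterministic up to sign
    of each axis. Returns an ``n_samples x dims`` array.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm, float)
    n = values.shape[1]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for {dims}-D MDS, got {n}")
    x = values.T  # samples x peaks
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)[np.newaxis, :]


def demo_peaks(n_peaks: int, width: int = 500, spacing: int = 2000, chrom: str = "chr1") -> PeakSet:
    """Evenly spaced synthetic peak coordinates for simulated matrices."""
    return PeakSet(
        [
            GenomicInterval(chrom, i * spacing, i * spacing + width)
            for i in range(n_peaks)
        ],
        provenance="synthetic",
    )
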