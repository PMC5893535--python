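"""Synthetic cohorts, fragment files and footprint insertions with ground truth.

The cohort generator emulates the statistical structure of a postmortem
eye-tissue ATAC-seq study: a peak x sample count matrix whose log2 expected
signal follows the stage-plus-confounders linear model, negative-binomial
count noise, per-sample library sizes in the tens of millions, and a
majority of peaks carrying a negative disease-stage effect. Planted
parameters are returned alongside the data so parameter-recovery tests can
compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval, PeakSet
from .matrix import CountMatrix, SampleMeta, demo_peaks
from .footprints import Insertions, MotifOccurrence

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "default_cohort_meta",
    "simulate_cohort",
    "simulate_fragments",
    "simulate_footprint_insertions",
]

NORMALIZATION_SCALE = 100_000_000


def default_cohort_meta(
    n_normal: int = 11,
    n_early: int = 5,
    n_late: int = 9,
    tissue: str = "retina",
    seed: int = 0,
    age_range: tuple[float, float] = (79.0, 94.0),
    interval_range: tuple[float, float] = (4.0, 13.0),
    library_range: tuple[float, float] = (2e7, 5e7),
) -> list[SampleMeta]:
    """Sample templates mirroring a retina-style cohort design.

    Defaults follow the retina arm of the study design (11 normal, 5
    early-stage, 9 late-stage donors/eyes) with alternating region and
    gender codes, donor ages around the mid-80s, procurement intervals of a
    few hours, and library sizes of 20-50 million qualified fragments.
    """
    rng = np.random.default_rng(seed)
    metas = []
    i = 0
    for stage, n in ((0, n_normal), (1, n_early), (2, n_late)):
        for j in range(n):
            metas.append(
                SampleMeta(
                    sample_id=f"{tissue}_s{stage}_{j}",
                    tissue=tissue,
                    region_code=(-1) ** (i % 2),
                    stage_code=stage,
                    gender_code=(-1) ** ((i // 2) % 2),
                    age=float(rng.uniform(*age_range)),
                    interval=float(rng.uniform(*interval_range)),
                    library_size=float(rng.uniform(*library_range)),
                )
            )
            i += 1
    return metas


def paired_eye_meta(
    stage_left: int,
    stage_right: int,
    tissue: str = "retina",
    region_code: int = 1,
    seed: int = 0,
    library_range: tuple[float, float] = (2e7, 5e7),
) -> list[SampleMeta]:
    """Two samples from one donor's left and right eyes.

    Eyes of one donor share gender, age and procurement interval and are
    sampled from the same region (macula by default); only disease stage
    and library size may differ. Returns [left, right].
    """
    rng = np.random.default_rng(seed)
    gender = int(rng.choice([-1, 1]))
    age = float(rng.uniform(79.0, 94.0))
    interval = float(rng.uniform(4.0, 13.0))
    return [
        SampleMeta(
            sample_id=f"{tissue}_{eye}_stage{stage}",
            tissue=tissue,
            region_code=region_code,
            stage_code=stage,
            gender_code=gender,
            age=age,
            interval=interval,
            library_size=float(rng.uniform(*library_range)),
        )
        for eye, stage in (("left", stage_left), ("right", stage_right))
    ]


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic peak x sample cohort.

    ``baseline_mean``/``baseline_sd`` set the per-peak intercept of the
    log2 signal (units of C_N); ``stage_effect_mean`` (< 0) and
    ``stage_effect_sd`` describe the planted per-stage log2 change in the
    affected fraction of peaks. The default spread (0.25 around -0.4) lets
    the effect distribution cross zero, mirroring the broad stage-coefficient
    density seen in degenerating tissue, and makes the expected fraction of
    reduced peaks equal the planted affected fraction:
    f * Phi(0.4 / 0.25) + (1 - f) / 2 = f for f = 0.9. Confounder
    coefficients are log2-per-unit
    effects (region/gender per code unit, age per year, interval per
    hour). ``dispersion`` is the NB overdispersion (variance = mu +
    dispersion * mu^2); ``noise`` may be set to ``"lognormal-poisson"``
    for a robustness alternative with matched variance.
    """

    n_peaks: int = 2000
    samples: list[SampleMeta] = field(default_factory=default_cohort_meta)
    baseline_mean: float = 7.5
    baseline_sd: float = 0.8
    stage_effect_mean: float = -0.4
    stage_effect_sd: float = 0.25
    fraction_affected: float = 0.9
    region_coef: float = 0.1
    gender_coef: float = 0.05
    age_coef: float = -0.005
    interval_coef: float = -0.02
    dispersion: float = 0.05
    noise: str = "nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if not (0 <= self.fraction_affected <= 1):
            raise ValueError("fraction_affected must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.noise not in ("nb", "lognormal-poisson"):
            raise ValueError("noise must be 'nb' or 'lognormal-poisson'")


@dataclass
class SyntheticTruth:
    """Planted parameters backing a simulated cohort."""

    alpha1: np.ndarray  # per-peak true stage effect
    alpha0: np.ndarray  # per-peak baseline
    confounders: dict[str, float]
    library_sizes: np.ndarray
    affected: np.ndarray  # boolean mask of peaks with nonzero alpha1


def simulate_cohort(config: CohortConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix from the stage-plus-confounders NB model.

    Expected counts are mu = S_L / 1e8 * 2^(a0 + a1*stage + a2*region +
    a3*gender + a4*age + a5*interval); a planted ``fraction_affected`` of
    peaks receive a nonzero (typically negative) stage effect and the rest
    have a1 = 0. Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_peaks = config.n_peaks
    samples = config.samples
    peaks = demo_peaks(n_peaks)
    alpha0 = rng.normal(config.baseline_mean, config.baseline_sd, size=n_peaks)
    affected = rng.random(n_peaks) < config.fraction_affected
    alpha1 = np.where(
        affected,
        rng.normal(config.stage_effect_mean, config.stage_effect_sd, size=n_peaks),
        0.0,
    )
    stage = np.array([s.stage_code for s in samples], dtype=float)
    region = np.array([s.region_code for s in samples], dtype=float)
    gender = np.array([s.gender_code for s in samples], dtype=float)
    age = np.array([s.age for s in samples], dtype=float)
    interval = np.array([s.interval for s in samples], dtype=float)
    s_l = np.array([s.library_size for s in samples], dtype=float)
    log2_signal = (
        alpha0[:, None]
        + alpha1[:, None] * stage[None, :]
        + config.region_coef * region[None, :]
        + config.gender_coef * gender[None, :]
        + config.age_coef * age[None, :]
        + config.interval_coef * interval[None, :]
    )
    mu = s_l[None, :] / NORMALIZATION_SCALE * np.exp2(log2_signal)
    if config.noise == "nb":
        # NB(mean mu, var mu + phi mu^2): size r = 1/phi, p = r/(r+mu)
        r = 1.0 / config.dispersion
        raw = rng.negative_binomial(r, r / (r + mu))
    else:
        # lognormal multiplicative noise with matched variance, then Poisson
        sigma2 = np.log1p(config.dispersion)
        lam = mu * rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=mu.shape)
        raw = rng.poisson(lam)
    truth = SyntheticTruth(
        alpha1=alpha1,
        alpha0=alpha0,
        confounders={
            "region": config.region_coef,
            "gender": config.gender_coef,
            "age": config.age_coef,
            "interval": config.interval_coef,
        },
        library_sizes=s_l,
        affected=affected,
    )
    return CountMatrix(peaks, samples, raw.astype(np.int64)), truth


def null_config(**overrides) -> CohortConfig:
    """A cohort with no stage effect anywhere (for type-I / FDR checks)."""
    cfg = CohortConfig(fraction_affected=0.0, stage_effect_mean=0.0, stage_effect_sd=0.0)
    return replace(cfg, **overrides)


def _draw_fragment_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Two-component length mixture: sub- and mono-nucleosomal fragments."""
    sub = rng.integers(60, 121, size=n)
    mono = rng.integers(180, 251, size=n)
    return np.where(rng.random(n) < 0.7, sub, mono)


def simulate_fragments(
    peaks: PeakSet,
    rates: np.ndarray | list[float],
    background_rate: float = 0.0,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> list[GenomicInterval]:
    """Place fragments in peaks (Poisson per-peak rates) plus background.

    Peak fragments have their midpoint uniform within the peak; background
    fragments are uniform over each chromosome span outside no particular
    structure. Lengths follow a sub-nucleosomal (60-120 bp) /
    mono-nucleosomal (180-250 bp) mixture. Writes BED3 when ``out_path``
    is given; byte-identical output for identical inputs and seed.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (len(peaks),):
        raise ValueError("one rate per peak required")
    if np.any(rates < 0) or background_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    frags: list[GenomicInterval] = []
    for iv, rate in zip(peaks, rates):
        n = rng.poisson(rate)
        if n == 0:
            continue
        mids = rng.integers(iv.start, iv.end, size=n)
        lengths = _draw_fragment_lengths(rng, n)
        for mid, length in zip(mids, lengths):
            start = max(int(mid) - int(length) // 2, 0)
            frags.append(GenomicInterval(iv.chrom, start, start + int(length)))
    if background_rate > 0 and len(peaks) > 0:
        spans: dict[str, int] = {}
        for iv in peaks:
            spans[iv.chrom] = max(spans.get(iv.chrom, 0), iv.end + 10_000)
        for chrom in sorted(spans):
            n = rng.poisson(background_rate * spans[chrom] / 1000.0)
            starts = rng.integers(0, spans[chrom], size=n)
            lengths = _draw_fragment_lengths(rng, n)
            for start, length in zip(starts, lengths):
                frags.append(GenomicInterval(chrom, int(start), int(start) + int(length)))
    frags.sort(key=lambda f: (f.chrom, f.start, f.end))
    if out_path is not None:
        with open(out_path, "w") as fh:
            for f in frags:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
    return frags


def simulate_footprint_insertions(
    site: MotifOccurrence,
    flank_rate: float,
    occupancy: float,
    seed: int = 0,
) -> tuple[Insertions, float]:
    """Poisson insertions around one motif with a planted central depletion.

    Flanks (3 motif lengths each side) get ``flank_rate`` insertions per
    bp; the central motif span gets ``flank_rate * (1 - occupancy)``.
    Returns the insertion multiset and the closed-form expected FOS,
    -log2((rate_c*L + 1) / (flank_rate*L + 1)) for motif length L.
    """
    if not (0 <= occupancy <= 1):
        raise ValueError("occupancy must lie in [0, 1]")
    if flank_rate < 0:
        raise ValueError("flank_rate must be >= 0")
    rng = np.random.default_rng(seed)
    iv = site.interval
    length = site.motif_length
    lo = iv.start - 3 * length
    hi = iv.end + 3 * length
    rate_c = flank_rate * (1.0 - occupancy)
    positions = []
    for base in range(lo, hi):
        rate = rate_c if iv.start <= base < iv.end else flank_rate
        k = rng.poisson(rate)
        positions.extend([base] * k)
    expected_fos = -np.log2((rate_c * length + 1.0) / (flank_rate * length + 1.0))
    return {iv.chrom: np.asarray(sorted(positions), dtype=np.int64)}, float(expected_fos)
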