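"""Tn5 insertion profiles, footprint occupancy scores and DAR enrichment.

A bound transcription factor protects its motif from Tn5 transposition,
leaving a local dip ("footprint") in the per-base insertion frequency
inside an otherwise accessible region. The footprint occupancy score (FOS)
quantifies the depth of that dip:

    FOS = min(-log2((N_C + 1) / (N_L + 1)), -log2((N_C + 1) / (N_R + 1)))

where N_C is the insertion count in the central region (the motif span) and
N_L, N_R are one third of the counts in the left/right flanking regions,
each flank being three motif lengths wide. Deeper protection gives a larger
positive FOS; uniform insertion density gives 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .intervals import FragmentFile, GenomicInterval, PeakSet, iter_fragments

__all__ = [
    "MotifOccurrence",
    "InsertionProfile",
    "FosResult",
    "insertions_from_fragments",
    "profile_at_motifs",
    "compute_fos",
    "footprint_enrichment",
    "read_motif_bed",
]

TN5_SHIFT_PLUS = 4
TN5_SHIFT_MINUS = -5


@dataclass(frozen=True)
class MotifOccurrence:
    """A motif match interval with its motif identity."""

    interval: GenomicInterval
    motif_id: str

    @property
    def motif_length(self) -> int:
        return self.interval.width

    @property
    def center(self) -> int:
        return self.interval.midpoint


def read_motif_bed(path: str | Path) -> list[MotifOccurrence]:
    """Read motif occurrences from BED6 with the motif id in the name field."""
    return [
        MotifOccurrence(interval=iv, motif_id=iv.name or "motif")
        for iv in iter_fragments(path)
    ]


Insertions = dict[str, np.ndarray]  # chrom -> sorted 0-based positions


def insertions_from_fragments(
    fragments: FragmentFile | str | Path | Iterable[GenomicInterval],
    shift_plus: int = TN5_SHIFT_PLUS,
    shift_minus: int = TN5_SHIFT_MINUS,
) -> Insertions:
    """Convert fragments to per-chromosome Tn5 insertion positions.

    Each fragment contributes its two boundary insertions: ``start +
    shift_plus`` and ``end + shift_minus`` (the half-open end coordinate
    shifted back into the fragment). The +4/-5 defaults are the standard
    Tn5 dimer correction; offsets (0, 0) give the naive fragment
    boundaries.
    """
    if isinstance(fragments, (str, Path)):
        fragments = FragmentFile(fragments)
    acc: dict[str, list[int]] = {}
    for frag in fragments:
        bucket = acc.setdefault(frag.chrom, [])
        bucket.append(frag.start + shift_plus)
        bucket.append(frag.end + shift_minus)
    return {
        chrom: np.sort(np.asarray(pos, dtype=np.int64)) for chrom, pos in acc.items()
    }


def _count_in(insertions: Insertions, chrom: str, lo: int, hi: int) -> int:
    """Insertions in [lo, hi) on chrom."""
    pos = insertions.get(chrom)
    if pos is None or hi <= lo:
        return 0
    return int(np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="left"))


def _per_base(insertions: Insertions, chrom: str, lo: int, hi: int) -> np.ndarray:
    pos = insertions.get(chrom)
    width = hi - lo
    if pos is None:
        return np.zeros(width, dtype=np.int64)
    a = np.searchsorted(pos, lo, side="left")
    b = np.searchsorted(pos, hi, side="left")
    return np.bincount(pos[a:b] - lo, minlength=width)


@dataclass
class InsertionProfile:
    """Aggregate per-base insertion counts around motif centers.

    ``positions`` are offsets relative to the motif center over the window;
    ``counts`` sums raw insertions over sites; ``normalized`` is the
    across-site average of each site's window counts divided by its
    flanking-window insertion total (None when no site has flank signal,
    flagged by ``null_normalization``).
    """

    positions: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray | None
    n_sites: int
    null_normalization: bool = False


def profile_at_motifs(
    insertions: Insertions,
    sites: list[MotifOccurrence],
    window: int = 200,
    flank_norm: int = 300,
) -> InsertionProfile:
    """Per-base insertion profile in a centered window, flank-normalized.

    The window is centered on each motif midpoint; minus-strand sites are
    positionally flipped so profiles aggregate in motif orientation. Each
    site's window counts are divided by the total insertions in the
    flanking normalization window (``flank_norm`` bp split evenly
    immediately outside the window edges) and then averaged across sites.
    """
    if not sites:
        raise ValueError("at least one site required")
    half = window // 2
    flank_half = flank_norm // 2
    positions = np.arange(-half, window - half)
    counts = np.zeros(window, dtype=np.int64)
    norm_sum = np.zeros(window, dtype=float)
    n_normalized = 0
    for site in sites:
        chrom = site.interval.chrom
        center = site.center
        lo = center - half
        vec = _per_base(insertions, chrom, lo, lo + window)
        flank_total = _count_in(insertions, chrom, lo - flank_half, lo) + _count_in(
            insertions, chrom, lo + window, lo + window + flank_half
        )
        if site.interval.strand == "-":
            vec = vec[::-1]
        counts += vec
        if flank_total > 0:
            norm_sum += vec / flank_total
            n_normalized += 1
    if n_normalized == 0:
        return InsertionProfile(positions, counts, None, len(sites), null_normalization=True)
    return InsertionProfile(positions, counts, norm_sum / n_normalized, len(sites))


@dataclass
class FosResult:
    """Footprint occupancy score for one motif occurrence."""

    site: MotifOccurrence
    n_c: int
    n_l: float
    n_r: float
    fos: float


def compute_fos(insertions: Insertions, site: MotifOccurrence) -> FosResult:
    """Footprint occupancy score at one motif occurrence.

    Central region is the motif span; each flank is the 3x-motif-length
    interval immediately adjacent. N_L and N_R are the flank counts divided
    by 3 (kept real-valued); the +1 pseudo-counts apply after the division.
    """
    iv = site.interval
    length = site.motif_length
    n_c = _count_in(insertions, iv.chrom, iv.start, iv.end)
    left = _count_in(insertions, iv.chrom, iv.start - 3 * length, iv.start)
    right = _count_in(insertions, iv.chrom, iv.end, iv.end + 3 * length)
    n_l = left / 3.0
    n_r = right / 3.0
    fos = min(
        -np.log2((n_c + 1) / (n_l + 1)),
        -np.log2((n_c + 1) / (n_r + 1)),
    )
    return FosResult(site=site, n_c=n_c, n_l=n_l, n_r=n_r, fos=float(fos))


def fos_table(insertions: Insertions, sites: list[MotifOccurrence]) -> pd.DataFrame:
    rows = [compute_fos(insertions, s) for s in sites]
    return pd.DataFrame(
        {
            "site": [r.site.interval.default_name() for r in rows],
            "motif": [r.site.motif_id for r in rows],
            "N_C": [r.n_c for r in rows],
            "N_L": [r.n_l for r in rows],
            "N_R": [r.n_r for r in rows],
            "fos": [r.fos for r in rows],
        }
    )


def _overlaps_any(site: MotifOccurrence, regions: dict) -> bool:
    iv = site.interval
    entry = regions.get(iv.chrom)
    if entry is None:
        return False
    starts, ends, _ = entry
    lo = np.searchsorted(ends, iv.start, side="right")
    return bool(lo < len(starts) and starts[lo] < iv.end)


def footprint_enrichment(
    sites_by_motif: dict[str, list[MotifOccurrence]],
    dars: PeakSet,
    non_dars: PeakSet,
) -> pd.DataFrame:
    """Hypergeometric enrichment of footprinted sites in DARs, per motif.

    Each footprinted site is classified as in-DAR or in-non-DAR by
    any-overlap (sites in neither are dropped; a site overlapping both sets
    is an error since DARs and non-DARs must be disjoint). With n DARs out
    of N regions and K classified sites of which k fall in DARs, the
    p-value is the upper tail of Hypergeom(N, n, K); FDR is BH across
    motifs.
    """
    dar_idx = dars.by_chrom()
    non_idx = non_dars.by_chrom()
    n = len(dars)
    big_n = n + len(non_dars)
    rows = []
    for motif_id in sorted(sites_by_motif):
        k = 0
        big_k = 0
        for site in sites_by_motif[motif_id]:
            in_dar = _overlaps_any(site, dar_idx)
            in_non = _overlaps_any(site, non_idx)
            if in_dar and in_non:
                raise ValueError(
                    f"site {site.interval.default_name()} overlaps both DARs and "
                    "non-DARs; the two sets must be disjoint"
                )
            if in_dar:
                k += 1
                big_k += 1
            elif in_non:
                big_k += 1
        p = float(stats.hypergeom.sf(k - 1, big_n, n, big_k)) if big_k > 0 else 1.0
        rows.append((motif_id, k, big_k, n, big_n, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["motif", "k", "K", "n", "N", "pvalue"])
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    return df
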