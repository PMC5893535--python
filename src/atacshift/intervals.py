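"""Genomic interval model, BED I/O, peak merging and fragment counting.

Coordinates are 0-based half-open throughout, following the BED convention.
Chromosome names are compared by exact string match (no ``chr`` aliasing).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "FragmentFile",
    "read_intervals",
    "merge_proximal",
    "subtract_blacklist",
    "count_fragments",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap test: true when the intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def default_name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakSet:
    """A sorted, de-duplicated collection of genomic intervals.

    Sorting is by ``(chrom, start, end)`` with chromosomes in lexicographic
    order; duplicate ``(chrom, start, end)`` records collapse to one.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        out: list[GenomicInterval] = []
        for iv in sorted(self.intervals, key=lambda i: (i.chrom, i.start, i.end)):
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                out.append(iv)
        self.intervals = out

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def names(self) -> list[str]:
        return [iv.name or iv.default_name() for iv in self.intervals]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends, global_indices)`` arrays."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            chroms.setdefault(iv.chrom, []).append(i)
        for chrom, idx in chroms.items():
            idx_arr = np.asarray(idx, dtype=np.int64)
            starts = np.array([self.intervals[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.intervals[i].end for i in idx], dtype=np.int64)
            out[chrom] = (starts, ends, idx_arr)
        return out

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                name = iv.name or iv.default_name()
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


@dataclass
class FragmentFile:
    """Pointer to a BED3+ file with one record per sequenced fragment."""

    path: str | Path
    sample_id: str = ""

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter_fragments(self.path)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval | None:
    line = line.rstrip("\n")
    if not line or line.startswith(("#", "track", "browser")):
        return None
    fields = line.split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
    name = fields[3] if len(fields) > 3 else ""
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(chrom, start, end, name, strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def iter_fragments(path: str | Path) -> Iterator[GenomicInterval]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            iv = _parse_bed_line(line, lineno)
            if iv is not None:
                yield iv


def read_intervals(path: str | Path, provenance: str = "") -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a sorted :class:`PeakSet`.

    Extra narrowPeak columns beyond the name are tolerated and ignored.
    Input need not be sorted; the returned set is.
    """
    intervals = list(iter_fragments(path))
    return PeakSet(intervals, provenance=provenance or str(path))


def merge_proximal(peaks: PeakSet, gap_lt: int = 10) -> PeakSet:
    """Merge same-chromosome peaks whose inter-peak gap is ``< gap_lt`` bp.

    The merge is transitive: a chain of proximal peaks collapses into one
    interval spanning the chain. Overlapping peaks (negative gap) always
    merge. Ties at exactly ``gap_lt`` are kept separate.
    """
    if gap_lt < 0:
        raise ValueError(f"gap_lt must be >= 0, got {gap_lt}")
    merged: list[GenomicInterval] = []
    current: GenomicInterval | None = None
    for iv in peaks:
        if current is not None and iv.chrom == current.chrom and iv.start - current.end < gap_lt:
            current = replace(current, end=max(current.end, iv.end), name="")
        else:
            if current is not None:
                merged.append(current)
            current = iv
    if current is not None:
        merged.append(current)
    return PeakSet(merged, provenance=f"{peaks.provenance}|merged(gap<{gap_lt})")


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop every peak that overlaps a blacklist interval by >= 1 bp.

    Removal is whole-peak: a peak touching a blacklisted region is excluded
    entirely rather than trimmed.
    """
    black = blacklist.by_chrom()
    kept: list[GenomicInterval] = []
    for iv in peaks:
        if iv.chrom in black:
            starts, ends, _ = black[iv.chrom]
            # overlap iff some blacklist interval has start < iv.end and end > iv.start
            lo = np.searchsorted(ends, iv.start, side="right")
            if lo < len(starts) and starts[lo] < iv.end:
                continue
        kept.append(iv)
    return PeakSet(kept, provenance=f"{peaks.provenance}|blacklist-filtered")


def count_fragments(
    fragments: FragmentFile | str | Path | Iterable[GenomicInterval],
    peaks: PeakSet,
) -> np.ndarray:
    """Count fragments over peaks under the any-overlap rule.

    A fragment contributes 1 to every peak it overlaps by at least one base;
    a fragment spanning two peaks is counted once in each. Requires a sorted,
    non-overlapping peak set (i.e. post-merge).

    Returns an integer vector of raw counts, one per peak.
    """
    if isinstance(fragments, (str, Path)):
        fragments = FragmentFile(fragments)
    by_chrom = peaks.by_chrom()
    for chrom, (starts, ends, _) in by_chrom.items():
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"peaks overlap on {chrom}; merge before counting")
    counts = np.zeros(len(peaks), dtype=np.int64)
    # difference-array accumulation: fragment hits the contiguous run of
    # peaks with end > frag.start and start < frag.end
    diffs = {chrom: np.zeros(len(idx) + 1, dtype=np.int64) for chrom, (_, _, idx) in by_chrom.items()}
    for frag in fragments:
        entry = by_chrom.get(frag.chrom)
        if entry is None:
            continue
        starts, ends, _ = entry
        lo = int(np.searchsorted(ends, frag.start, side="right"))
        hi = int(np.searchsorted(starts, frag.end, side="left"))
        if hi > lo:
            diffs[frag.chrom][lo] += 1
            diffs[frag.chrom][hi] -= 1
    for chrom, (_, _, idx) in by_chrom.items():
        counts[idx] = np.cumsum(diffs[chrom][:-1])
    return counts
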