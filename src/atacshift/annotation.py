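"""Peak-to-gene annotation, gene ranking and GWAS SNP overlap.

Peaks are assigned to their nearest gene (peak midpoint to gene body
distance, 0 on overlap) and categorized with a fixed precedence:
promoter-proximal (within 2 kb of the TSS or overlapping the 5'UTR), then
3'UTR (overlapping the 3'UTR or within 2 kb of the TES), then exonic,
intronic and intergenic. Gene-proximal peaks are those within 2 kb of the
gene body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet
from .stage_model import StageFitTable

__all__ = [
    "GeneModel",
    "PeakAnnotation",
    "SnpRecord",
    "read_gene_table",
    "read_bed12_genes",
    "read_snp_table",
    "annotate_peaks",
    "rank_genes_by_coefficient",
    "snp_overlap",
    "make_nonpeaks",
]

PROXIMAL_BP = 2000
CATEGORIES = ["promoter_proximal", "utr3", "exonic", "intronic", "intergenic"]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.body_end <= self.body_start:
            raise ValueError(f"{self.gene_id}: empty gene body")

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end - 1

    @property
    def tes(self) -> int:
        return self.body_end - 1 if self.strand == "+" else self.body_start


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read genes from a 6-column TSV: gene_id, chrom, strand, tss, tes, body.

    ``body`` is ``start-end`` in 0-based half-open coordinates. TSS/TES are
    implied by strand and body and are accepted for readability only.
    """
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        start, end = (int(x) for x in str(r.body).split("-"))
        genes.append(
            GeneModel(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                strand=str(r.strand),
                body_start=start,
                body_end=end,
            )
        )
    return genes


def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks = exons, thick = CDS)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"line {lineno}: BED12 requires 12 fields")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]

            def _clip(lo: int, hi: int) -> list[tuple[int, int]]:
                return [
                    (max(es, lo), min(ee, hi))
                    for es, ee in exons
                    if max(es, lo) < min(ee, hi)
                ]

            left_utr = _clip(start, thick_start)
            right_utr = _clip(thick_end, end)
            utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    body_start=start,
                    body_end=end,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    return genes


@dataclass
class PeakAnnotation:
    peak: GenomicInterval
    gene_id: str
    category: str
    distance: int
    proximal: bool


def _point_distance(iv: GenomicInterval, lo: int, hi: int) -> int:
    """Distance from the interval midpoint to [lo, hi); 0 inside."""
    mid = iv.midpoint
    if mid < lo:
        return lo - mid
    if mid >= hi:
        return mid - (hi - 1)
    return 0


def _interval_distance(iv: GenomicInterval, lo: int, hi: int) -> int:
    """Gap between the peak interval and [lo, hi); 0 on overlap."""
    if iv.end <= lo:
        return lo - iv.end + 1
    if iv.start >= hi:
        return iv.start - hi + 1
    return 0


def _overlaps_blocks(iv: GenomicInterval, blocks: list[tuple[int, int]]) -> bool:
    return any(iv.start < e and s < iv.end for s, e in blocks)


def annotate_peaks(peaks: PeakSet, genes: list[GeneModel]) -> list[PeakAnnotation]:
    """Assign each peak its nearest gene and a genomic category.

    Nearest gene minimizes the midpoint-to-gene-body distance (ties break
    to the lexicographically first gene_id). The category follows the
    precedence promoter_proximal > 3'UTR > exonic > intronic > intergenic,
    evaluated against the assigned gene; ``proximal`` flags peaks within
    2 kb of the gene body.
    """
    if not genes:
        raise ValueError("gene models must be non-empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for peak in peaks:
        cands = by_chrom.get(peak.chrom, genes)
        best = min(
            cands,
            key=lambda g: (_point_distance(peak, g.body_start, g.body_end), g.gene_id),
        )
        distance = _point_distance(peak, best.body_start, best.body_end)
        tss_lo, tss_hi = best.tss - PROXIMAL_BP, best.tss + PROXIMAL_BP + 1
        tes_lo, tes_hi = best.tes - PROXIMAL_BP, best.tes + PROXIMAL_BP + 1
        body_overlap = peak.start < best.body_end and best.body_start < peak.end
        if _interval_distance(peak, tss_lo, tss_hi) == 0 or _overlaps_blocks(peak, best.utr5):
            category = "promoter_proximal"
        elif _overlaps_blocks(peak, best.utr3) or _interval_distance(peak, tes_lo, tes_hi) == 0:
            category = "utr3"
        elif _overlaps_blocks(peak, best.exons):
            category = "exonic"
        elif body_overlap:
            category = "intronic"
        else:
            category = "intergenic"
        proximal = _interval_distance(peak, best.body_start, best.body_end) <= PROXIMAL_BP
        out.append(
            PeakAnnotation(
                peak=peak,
                gene_id=best.gene_id,
                category=category,
                distance=distance,
                proximal=proximal,
            )
        )
    return out


def rank_genes_by_coefficient(
    fits: StageFitTable, annotations: list[PeakAnnotation]
) -> pd.DataFrame:
    """Rank genes by the minimum stage coefficient of their proximal peaks.

    When several peaks map to one gene the most negative coefficient wins;
    genes with no proximal peak are omitted. The output is sorted ascending
    (strongest accessibility decrease first), suitable as a ranked list for
    gene-set enrichment.
    """
    a1_by_peak = {
        iv.default_name(): fits.alpha[i, 1] for i, iv in enumerate(fits.peaks)
    }
    scores: dict[str, float] = {}
    for ann in annotations:
        if not ann.proximal:
            continue
        key = ann.peak.default_name()
        if key not in a1_by_peak:
            raise ValueError(f"annotated peak {key} not present in the fit table")
        coef = a1_by_peak[key]
        if ann.gene_id not in scores or coef < scores[ann.gene_id]:
            scores[ann.gene_id] = coef
    df = pd.DataFrame(
        {"gene_id": list(scores), "coefficient": list(scores.values())}
    ).sort_values(["coefficient", "gene_id"], kind="mergesort")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS SNP; ``pos`` is 0-based (converted from 1-based at the reader)."""

    chrom: str
    pos: int
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"SNP p-value must be in (0, 1], got {self.pvalue}")


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read SNPs from TSV (chrom, pos, P) with 1-based positions."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    chrom_c = cols.get("chrom", df.columns[0])
    pos_c = cols.get("pos", df.columns[1])
    p_c = cols.get("p", cols.get("pvalue", df.columns[2]))
    return [
        SnpRecord(str(r[chrom_c]), int(r[pos_c]) - 1, float(r[p_c]))
        for _, r in df.iterrows()
    ]


def snp_overlap(
    regions: PeakSet,
    snps: list[SnpRecord],
    extension: int = 0,
    p_threshold: float = 5e-8,
) -> tuple[float, pd.DataFrame]:
    """Minimum GWAS P per region and the proportion below a threshold.

    Each region is optionally extended by ``extension`` bp on both sides;
    its P is the minimum over contained SNPs, defaulting to 1 when no SNP
    falls inside. Returns ``(proportion with P < p_threshold, per-region
    table)``.
    """
    if extension < 0:
        raise ValueError(f"extension must be >= 0, got {extension}")
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in snps}:
        sub = sorted((s.pos, s.pvalue) for s in snps if s.chrom == chrom)
        by_chrom[chrom] = (
            np.array([p for p, _ in sub], dtype=np.int64),
            np.array([v for _, v in sub], dtype=float),
        )
    rows = []
    for iv in regions:
        min_p = 1.0
        entry = by_chrom.get(iv.chrom)
        if entry is not None:
            pos, pv = entry
            lo = np.searchsorted(pos, max(iv.start - extension, 0), side="left")
            hi = np.searchsorted(pos, iv.end + extension, side="left")
            if hi > lo:
                min_p = float(pv[lo:hi].min())
        rows.append((iv.name or iv.default_name(), min_p))
    df = pd.DataFrame(rows, columns=["region", "min_p"])
    proportion = float((df["min_p"] < p_threshold).mean())
    return proportion, df


def make_nonpeaks(peaks: PeakSet, side: str = "downstream") -> PeakSet:
    """Flanking same-width control intervals adjacent to each peak.

    Each peak contributes the immediately adjacent interval of equal width
    on the chosen side (downstream by default, i.e. just past the peak
    end); flanks that would overlap any input peak are skipped, and
    upstream flanks that would cross position 0 are skipped too.
    """
    if side not in ("downstream", "upstream"):
        raise ValueError("side must be 'downstream' or 'upstream'")
    idx = peaks.by_chrom()
    flanks = []
    for iv in peaks:
        w = iv.width
        if side == "downstream":
            lo, hi = iv.end, iv.end + w
        else:
            lo, hi = iv.start - w, iv.start
            if lo < 0:
                continue
        starts, ends, _ = idx[iv.chrom]
        pos = np.searchsorted(ends, lo, side="right")
        if pos < len(starts) and starts[pos] < hi:
            continue  # flank collides with a peak
        flanks.append(GenomicInterval(iv.chrom, lo, hi))
    return PeakSet(flanks, provenance=f"{peaks.provenance}|nonpeaks({side})")
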