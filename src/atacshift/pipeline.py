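"""End-to-end pipeline: counts -> normalization -> tests -> DARs -> annotation.

The pipeline is a pure function of (inputs, config): given fragment files,
peak sets and sample metadata it produces TSV/BED artifacts plus a manifest
recording the configuration hash and per-artifact row counts, so reruns on
identical inputs are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    annotate_peaks,
    make_nonpeaks,
    rank_genes_by_coefficient,
    read_gene_table,
    read_snp_table,
    snp_overlap,
)
from .differential import differential_test, global_shift
from .footprints import fos_table, footprint_enrichment, insertions_from_fragments, read_motif_bed
from .intervals import PeakSet, count_fragments, merge_proximal, read_intervals, subtract_blacklist
from .matrix import (
    CountMatrix,
    classical_mds,
    filter_by_mean_signal,
    normalize_counts,
    read_sample_table,
)
from .stage_model import fit_stage_model, select_dars

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("atacshift")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    metadata: str
    peaks: list[str]
    fragments: dict[str, str] = field(default_factory=dict)  # sample_id -> BED path
    counts: str | None = None  # precomputed count matrix TSV (alternative to fragments)
    blacklist: str | None = None
    genes: str | None = None
    snps: str | None = None
    motifs: str | None = None
    merge_gap: int = 10
    signal_threshold: float | str = 6.5
    fc_threshold: float = 0.8
    fdr_threshold: float = 0.05
    dar_fdr: float = 0.01
    top_n: int = 5000
    snp_extension: int = 5000
    snp_p_threshold: float = 5e-8
    seed: int = 0
    outdir: str = "atacshift_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        missing = []
        for p in [self.metadata, *self.peaks, self.blacklist, self.genes, self.snps,
                  self.motifs, self.counts, *self.fragments.values()]:
            if p is not None and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not self.fragments and not self.counts:
            raise ValueError("either fragment files or a precomputed count matrix is required")
        if self.merge_gap < 0 or self.top_n < 1:
            raise ValueError("merge_gap must be >= 0 and top_n >= 1")

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                logger.error("stage %s: FAILED", name)
                raise RuntimeError(f"pipeline stage '{name}' failed") from sys.exc_info()[1]
            logger.info("stage %s: done in %.2fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write artifacts under ``config.outdir``.

    Stages: peak consolidation -> fragment counting -> normalization and
    filtering -> MDS -> pairwise differential test (normal vs disease) ->
    stage regression -> DAR selection -> annotation and SNP overlap ->
    footprint scoring/enrichment when motifs are provided. Returns the
    manifest dictionary (also written as ``manifest.json``).
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_hash": config.content_hash(), "artifacts": {}}

    def _emit(name: str, n_rows: int) -> None:
        manifest["artifacts"][name] = {"rows": int(n_rows)}

    samples = _stage("metadata")(read_sample_table)(config.metadata)

    @_stage("peaks")
    def _peaks() -> PeakSet:
        merged_input = PeakSet(
            [iv for p in config.peaks for iv in read_intervals(p)], provenance="input"
        )
        peaks = merge_proximal(merged_input, config.merge_gap)
        if config.blacklist:
            peaks = subtract_blacklist(peaks, read_intervals(config.blacklist))
        peaks.write_bed(outdir / "peaks.bed")
        return peaks

    peaks = _peaks()
    _emit("peaks.bed", len(peaks))

    @_stage("count")
    def _count() -> CountMatrix:
        if config.counts:
            df = pd.read_csv(config.counts, sep="\t", index_col=0)
            order = [s.sample_id for s in samples]
            raw = df[order].to_numpy()
            counts = CountMatrix(peaks, samples, raw)
        else:
            cols = []
            for s in samples:
                if s.sample_id not in config.fragments:
                    raise ValueError(f"no fragment file for sample {s.sample_id}")
                cols.append(count_fragments(config.fragments[s.sample_id], peaks))
            counts = CountMatrix(peaks, samples, np.column_stack(cols))
        counts.write_tsv(outdir / "counts.tsv")
        return counts

    counts = _count()
    _emit("counts.tsv", len(peaks))

    @_stage("normalize")
    def _normalize():
        norm = normalize_counts(counts)
        filtered = filter_by_mean_signal(norm, config.signal_threshold)
        filtered.write_tsv(outdir / "normalized_filtered.tsv")
        keep = set(filtered.peaks.names())
        mask = np.array([name in keep for name in counts.peaks.names()])
        filtered_counts = CountMatrix(filtered.peaks, samples, counts.raw[mask, :])
        return filtered, filtered_counts

    norm, filtered_counts = _normalize()
    _emit("normalized_filtered.tsv", len(norm.peaks))

    @_stage("mds")
    def _mds():
        coords = classical_mds(norm, dims=2)
        df = pd.DataFrame(coords, columns=["dim1", "dim2"])
        df.insert(0, "sample_id", [s.sample_id for s in samples])
        df.to_csv(outdir / "mds.tsv", sep="\t", index=False, float_format="%.6g")
        return df

    _emit("mds.tsv", len(_mds()))

    @_stage("differential")
    def _diff():
        group_a = [s.sample_id for s in samples if s.stage_code == 0]
        group_b = [s.sample_id for s in samples if s.stage_code > 0]
        result = differential_test(
            filtered_counts, group_a, group_b,
            fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold,
        )
        result.write_tsv(outdir / "differential.tsv")
        shift = global_shift(result)
        with open(outdir / "global_shift.json", "w") as fh:
            json.dump(
                {
                    "n_peaks": shift.n_peaks,
                    "n_reduced": shift.n_reduced,
                    "frac_reduced": shift.frac_reduced,
                },
                fh,
                indent=2,
            )
        return result

    _emit("differential.tsv", len(_diff().peak))

    @_stage("stage_model")
    def _fit():
        fits = fit_stage_model(norm)
        fits.write_tsv(outdir / "stage_fits.tsv")
        dars, non_dars = select_dars(fits, fdr_cut=config.dar_fdr, top_n=config.top_n)
        dars.write_bed(outdir / "dars.bed")
        non_dars.write_bed(outdir / "non_dars.bed")
        return fits, dars, non_dars

    fits, dars, non_dars = _fit()
    _emit("dars.bed", len(dars.peaks))
    _emit("non_dars.bed", len(non_dars))

    if config.genes:
        @_stage("annotation")
        def _annotate():
            genes = read_gene_table(config.genes)
            anns = annotate_peaks(norm.peaks, genes)
            df = pd.DataFrame(
                {
                    "peak": [a.peak.name or a.peak.default_name() for a in anns],
                    "gene_id": [a.gene_id for a in anns],
                    "category": [a.category for a in anns],
                    "distance": [a.distance for a in anns],
                    "proximal": [a.proximal for a in anns],
                }
            )
            df.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
            ranks = rank_genes_by_coefficient(fits, anns)
            ranks.to_csv(outdir / "gene_ranks.tsv", sep="\t", index=False, float_format="%.6g")
            return df

        _emit("annotations.tsv", len(_annotate()))

    if config.snps:
        @_stage("snp_overlap")
        def _snps():
            snps = read_snp_table(config.snps)
            rows = []
            for label, regions in (
                ("DARs", dars.peaks),
                ("non_DARs", non_dars),
                ("non_peaks", make_nonpeaks(norm.peaks)),
            ):
                for ext in (0, config.snp_extension):
                    prop, _ = snp_overlap(regions, snps, extension=ext,
                                          p_threshold=config.snp_p_threshold)
                    rows.append((label, ext, prop))
            df = pd.DataFrame(rows, columns=["regions", "extension", "proportion_significant"])
            df.to_csv(outdir / "snp_overlap.tsv", sep="\t", index=False, float_format="%.6g")
            return df

        _emit("snp_overlap.tsv", len(_snps()))

    if config.motifs and config.fragments:
        @_stage("footprints")
        def _footprints():
            sites = read_motif_bed(config.motifs)
            pooled: dict[str, list[np.ndarray]] = {}
            for path in config.fragments.values():
                for chrom, pos in insertions_from_fragments(path).items():
                    pooled.setdefault(chrom, []).append(pos)
            insertions = {c: np.sort(np.concatenate(v)) for c, v in pooled.items()}
            fos = fos_table(insertions, sites)
            fos.to_csv(outdir / "fos.tsv", sep="\t", index=False, float_format="%.6g")
            by_motif: dict[str, list] = {}
            for s in sites:
                by_motif.setdefault(s.motif_id, []).append(s)
            enrich = footprint_enrichment(by_motif, dars.peaks, non_dars)
            enrich.to_csv(outdir / "footprint_enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")
            return fos

        _emit("fos.tsv", len(_footprints()))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
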