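import numpy as np
import pytest

from atacshift import normalize_counts
from atacshift.simulate import (
    CohortConfig,
    default_cohort_meta,
    null_config,
    simulate_cohort,
)


def write_bed(path, rows):
    """rows: iterable of (chrom, start, end[, name[, score, strand]])."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def bed_writer(tmp_path):
    def _write(rows, name="test.bed"):
        return write_bed(tmp_path / name, rows)

    return _write


@pytest.fixture(scope="session")
def small_cohort():
    """500-peak, 24-sample cohort with planted effects (fixed seed)."""
    meta = default_cohort_meta(n_normal=10, n_early=5, n_late=9, seed=11)
    counts, truth = simulate_cohort(CohortConfig(n_peaks=500, samples=meta, seed=11))
    return counts, truth


@pytest.fixture(scope="session")
def null_cohort():
    """1000-peak cohort with no stage effect and no confounder effects."""
    cfg = null_config(
        n_peaks=1000, seed=12, region_coef=0.0, gender_coef=0.0,
        age_coef=0.0, interval_coef=0.0,
    )
    counts, truth = simulate_cohort(cfg)
    return counts, truth


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    counts, _ = small_cohort
    return normalize_counts(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
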