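import itertools
import math

import numpy as np
import pytest

from atacshift.footprints import (
    MotifOccurrence,
    compute_fos,
    footprint_enrichment,
    insertions_from_fragments,
    profile_at_motifs,
)
from atacshift.intervals import GenomicInterval, PeakSet


def site(chrom="chr1", start=1000, end=1010, strand=".", motif="M1"):
    return MotifOccurrence(GenomicInterval(chrom, start, end, strand=strand), motif)


def insertions_at(positions, chrom="chr1"):
    return {chrom: np.sort(np.asarray(positions, dtype=np.int64))}


class TestInsertions:
    def test_standard_tn5_offsets(self):
        ins = insertions_from_fragments([GenomicInterval("chr1", 100, 200)])
        assert ins["chr1"].tolist() == [104, 195]

    def test_zero_offsets_give_fragment_boundaries(self):
        ins = insertions_from_fragments(
            [GenomicInterval("chr1", 100, 200)], shift_plus=0, shift_minus=0
        )
        assert ins["chr1"].tolist() == [100, 200]

    def test_empty_input(self):
        assert insertions_from_fragments([]) == {}

    def test_two_insertions_per_fragment(self, bed_writer):
        path = bed_writer([("chr1", 0, 100), ("chr1", 50, 300), ("chr2", 0, 60)], "f.bed")
        ins = insertions_from_fragments(path)
        assert sum(len(v) for v in ins.values()) == 6


class TestProfileAtMotifs:
    def test_uniform_insertions_give_flat_normalized_profile(self):
        ins = insertions_at(range(0, 3000))  # one insertion per base
        prof = profile_at_motifs(ins, [site(start=1495, end=1505)])
        assert prof.normalized is not None
        assert np.allclose(prof.normalized, prof.normalized[0])
        # window total / flank total = 200 / 300
        assert prof.normalized.sum() == pytest.approx(200 / 300)

    def test_center_spike(self):
        s = site(start=1495, end=1505)
        ins = insertions_at([s.center] * 7 + list(range(0, 3000, 10)))
        prof = profile_at_motifs(ins, [s])
        assert prof.counts.argmax() == 100  # window position of the center

    def test_minus_strand_site_is_flipped(self):
        # a spike downstream of a plus-strand motif must aggregate at the
        # same window position as its mirror upstream of a minus-strand one
        plus = site(start=1000, end=1010, strand="+")
        minus = site(start=5000, end=5010, strand="-")
        ins = insertions_at([plus.center + 30] * 5 + [minus.center - 31] * 5)
        p_plus = profile_at_motifs(ins, [plus])
        p_minus = profile_at_motifs(ins, [minus])
        np.testing.assert_array_equal(p_plus.counts, p_minus.counts)

    def test_site_order_invariance(self, rng):
        sites = [site(start=s, end=s + 10) for s in (1000, 3000, 5000)]
        ins = insertions_at(rng.integers(0, 6000, size=2000))
        a = profile_at_motifs(ins, sites)
        b = profile_at_motifs(ins, sites[::-1])
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_allclose(a.normalized, b.normalized)

    def test_zero_flank_insertions_flagged(self):
        s = site(start=1495, end=1505)
        ins = insertions_at([s.center])  # nothing in the flanks
        prof = profile_at_motifs(ins, [s])
        assert prof.null_normalization
        assert prof.normalized is None
        assert prof.counts.sum() == 1

    def test_requires_sites(self):
        with pytest.raises(ValueError):
            profile_at_motifs(insertions_at([]), [])


def brute_force_fos(positions, s):
    length = s.motif_length
    iv = s.interval
    n_c = sum(1 for p in positions if iv.start <= p < iv.end)
    n_l = sum(1 for p in positions if iv.start - 3 * length <= p < iv.start) / 3
    n_r = sum(1 for p in positions if iv.end <= p < iv.end + 3 * length) / 3
    return min(-math.log2((n_c + 1) / (n_l + 1)), -math.log2((n_c + 1) / (n_r + 1)))


class TestComputeFos:
    def test_uniform_density_gives_zero(self):
        s = site(start=1000, end=1010)
        ins = insertions_at(range(970, 1040))  # one per base across all regions
        res = compute_fos(ins, s)
        assert res.n_c == 10
        assert res.n_l == res.n_r == 10.0
        assert res.fos == 0.0

    def test_hand_worked_example(self):
        # central 0, left flank 21, right flank 45 -> N_L=7, N_R=15, FOS=3
        s = site(start=1000, end=1010)
        positions = (
            list(range(970, 991))  # 21 insertions in the 30-bp left flank
            + list(range(1010, 1040))  # 45 in the right flank (some bases twice)
            + list(range(1010, 1025))
        )
        res = compute_fos(insertions_at(positions), s)
        assert res.n_c == 0
        assert res.n_l == 7.0
        assert res.n_r == 15.0
        assert res.fos == 3.0

    def test_enriched_center_gives_negative_score(self):
        s = site(start=1000, end=1010)
        res = compute_fos(insertions_at([1005] * 50), s)
        assert res.fos < 0

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            length = int(rng.integers(5, 25))
            start = int(rng.integers(100, 5000))
            s = site(start=start, end=start + length)
            n = int(rng.integers(0, 10_000))
            positions = rng.integers(start - 4 * length, start + 5 * length, size=n)
            res = compute_fos(insertions_at(positions), s)
            assert res.fos == pytest.approx(brute_force_fos(positions.tolist(), s))


def enumerate_hypergeom_upper(k, big_n, n, big_k):
    """P(X >= k) by exhaustive enumeration of C(n,x)C(N-n,K-x)/C(N,K)."""
    total = math.comb(big_n, big_k)
    return sum(
        math.comb(n, x) * math.comb(big_n - n, big_k - x)
        for x in range(k, min(n, big_k) + 1)
    ) / total


class TestFootprintEnrichment:
    def make_universe(self, n_dar, n_non):
        dars = PeakSet([GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(n_dar)])
        non = PeakSet(
            [GenomicInterval("chr2", i * 1000, i * 1000 + 500) for i in range(n_non)]
        )
        return dars, non

    def sites_in(self, regions, count, motif="M1"):
        return [
            MotifOccurrence(
                GenomicInterval(ivl.chrom, ivl.start + 10, ivl.start + 20), motif
            )
            for ivl in list(regions)[:count]
        ]

    def test_all_sites_in_dars_closed_form(self):
        dars, non = self.make_universe(5, 45)
        sites = {"M1": self.sites_in(dars, 5)}
        df = footprint_enrichment(sites, dars, non)
        expected = math.comb(5, 5) / math.comb(50, 5)
        assert df.loc[0, "pvalue"] == pytest.approx(expected)
        assert df.loc[0, ["k", "K", "n", "N"]].tolist() == [5, 5, 5, 50]

    def test_no_classified_sites_gives_p_one(self):
        dars, non = self.make_universe(5, 10)
        far = [MotifOccurrence(GenomicInterval("chr9", 0, 10), "M1")]
        df = footprint_enrichment({"M1": far}, dars, non)
        assert df.loc[0, "pvalue"] == 1.0
        assert df.loc[0, "K"] == 0

    def test_proportional_sites_not_significant(self):
        dars, non = self.make_universe(5, 45)
        sites = {"M1": self.sites_in(dars, 1) + self.sites_in(non, 9)}
        df = footprint_enrichment(sites, dars, non)
        assert df.loc[0, "pvalue"] > 0.05

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(25):
            n_dar = int(rng.integers(1, 20))
            n_non = int(rng.integers(1, 30))
            dars, non = self.make_universe(n_dar, n_non)
            k = int(rng.integers(0, n_dar + 1))
            j = int(rng.integers(0, n_non + 1))
            sites = {"M1": self.sites_in(dars, k) + self.sites_in(non, j)}
            df = footprint_enrichment(sites, dars, non)
            if k + j == 0:
                assert df.loc[0, "pvalue"] == 1.0
            else:
                expected = enumerate_hypergeom_upper(k, n_dar + n_non, n_dar, k + j)
                assert df.loc[0, "pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_site_in_both_sets_rejected(self):
        dars = PeakSet([GenomicInterval("chr1", 0, 500)])
        non = PeakSet([GenomicInterval("chr1", 400, 900)])
        sites = {"M1": [MotifOccurrence(GenomicInterval("chr1", 450, 460), "M1")]}
        with pytest.raises(ValueError, match="both"):
            footprint_enrichment(sites, dars, non)

    def test_fdr_adjusts_across_motifs(self):
        dars, non = self.make_universe(5, 45)
        sites = {
            "M1": self.sites_in(dars, 5, "M1"),
            "M2": self.sites_in(non, 5, "M2"),
        }
        df = footprint_enrichment(sites, dars, non)
        assert set(df["motif"]) == {"M1", "M2"}
        assert (df["fdr"] >= df["pvalue"] - 1e-15).all()
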