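"""Pigeonhole seed mapper: exactness against the brute-force Hamming
oracle, strand handling, random multi-mapper assignment."""

import numpy as np
import pytest

from centrochip import _seq
from centrochip.genome import ChromosomeSpec, GenomeBuild, GenomeTruth, RepeatFamilySpec, build_genome
from centrochip.mapping import (
    AlignmentSet,
    GenomeIndex,
    assign_read,
    brute_force_best_hits,
    find_best_hits,
    map_library,
    partition_scheme,
)
from centrochip.reads import LibraryConfig, OccupancyProfile, simulate_library


class TestPartitions:
    def test_49bp_two_mismatch_partitions(self):
        assert partition_scheme(49, 2) == [(0, 17), (17, 16), (33, 16)]

    def test_partitions_cover_read(self):
        for R in (20, 36, 49, 75, 100):
            for m in (0, 1, 2, 3):
                parts = partition_scheme(R, m)
                assert len(parts) == m + 1
                assert sum(k for _, k in parts) == R

    def test_read_too_short(self):
        with pytest.raises(ValueError):
            partition_scheme(2, 2)


class TestIndex:
    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeIndex(GenomeBuild({}, GenomeTruth()), 49)

    def test_short_chromosome_excluded_with_warning(self):
        build = GenomeBuild({"tiny": "ACGT" * 5, "ok": "ACGT" * 5_000}, GenomeTruth())
        with pytest.warns(UserWarning, match="tiny"):
            index = GenomeIndex(build, 49)
        assert index.chrom_names == ["ok"]

    def test_planted_exact_kmer_found(self, small_build, small_index):
        g = small_build.codes("chr1")
        read = g[1_234:1_283]
        hits = find_best_hits(read, small_index)
        assert any(h.start == 1_234 and h.strand == "+" and h.mismatches == 0
                   for h in hits)


class TestBestHits:
    def test_unique_locus_single_hit(self, small_build, small_index):
        # arm sequence (outside the repeat array) is unique w.h.p.
        g = small_build.codes("chr1")
        read = g[2_000:2_049]
        hits = find_best_hits(read, small_index)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand, hits[0].mismatches) == (2_000, "+", 0)

    def test_unmappable_read_empty(self, small_build, small_index, rng):
        # random 49-mer: expected distance to any locus is ~36, far above 2
        read = rng.integers(0, 4, 49).astype(np.uint8)
        assert find_best_hits(read, small_index) == []
        assert brute_force_best_hits(read, small_build) == []

    def test_strand_mirror(self, small_build, small_index):
        g = small_build.codes("chr1")
        read = g[3_000:3_049]
        fwd = find_best_hits(read, small_index)
        rev = find_best_hits(_seq.revcomp_codes(read), small_index)
        assert sorted((h.start, h.mismatches) for h in fwd) == \
            sorted((h.start, h.mismatches) for h in rev)
        assert {h.strand for h in fwd} == {"+"} and {h.strand for h in rev} == {"-"}

    def test_oracle_equivalence_sampled(self, small_build, small_index, rng):
        """Strata equal the brute-force Hamming scan for sampled reads with
        injected errors (deep version runs in the acceptance suite)."""
        g = small_build.codes("chr1")
        for _ in range(60):
            s = int(rng.integers(0, 30_000 - 49))
            read = g[s:s + 49].copy()
            n_err = int(rng.integers(0, 3))
            pos = rng.choice(49, n_err, replace=False)
            read[pos] = (read[pos] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
            if rng.random() < 0.5:
                read = _seq.revcomp_codes(read)
            got = sorted((h.start, h.strand, h.mismatches)
                         for h in find_best_hits(read, small_index))
            want = sorted((h.start, h.strand, h.mismatches)
                          for h in brute_force_best_hits(read, small_build))
            assert got == want

    def test_n_bases_count_as_mismatches(self, small_build, small_index):
        g = small_build.codes("chr1")
        read = g[2_100:2_149].copy()
        read[[5, 20]] = _seq.N
        hits = find_best_hits(read, small_index)
        assert any(h.start == 2_100 and h.mismatches == 2 for h in hits)
        read[40] = _seq.N  # three Ns: beyond the mismatch budget
        assert all(h.start != 2_100 for h in find_best_hits(read, small_index))

    def test_best_stratum_suppresses_worse_hits(self, small_index, small_build):
        g = small_build.codes("chr1")
        read = g[2_200:2_249]
        hits = find_best_hits(read, small_index)
        assert {h.mismatches for h in hits} == {0}


class TestAssignment:
    def test_single_hit_kept(self, small_build, small_index, rng):
        g = small_build.codes("chr1")
        hits = find_best_hits(g[2_300:2_349], small_index)
        assert assign_read(hits, rng) == hits[0]

    def test_empty_unmapped(self, rng):
        assert assign_read([], rng) is None

    def test_two_identical_loci_split_evenly(self):
        """Binomial oracle: 1,000 reads from two identical loci split
        500 +/- 3*sqrt(250) between them."""
        arm = ChromosomeSpec("c", 40_000, RepeatFamilySpec(100, 0.6, 5, 0.0), 10_000)
        build = build_genome([arm], None, rng_seed=3)
        seq = build.sequences["c"]
        # plant an exact copy of a 1 kb arm block
        dup_src, dup_dst = 20_000, 30_000
        seq = seq[:dup_dst] + seq[dup_src:dup_src + 1_000] + seq[dup_dst + 1_000:]
        build2 = GenomeBuild({"c": seq}, GenomeTruth())
        index = GenomeIndex(build2, 49)
        g = build2.codes("c")
        rng = np.random.default_rng(0)
        at_src = 0
        n = 1_000
        for i in range(n):
            s = dup_src + int(rng.integers(0, 1_000 - 49))
            hits = find_best_hits(g[s:s + 49], index)
            assert len(hits) == 2
            chosen = assign_read(hits, rng)
            at_src += chosen.start < 25_000
        assert abs(at_src - 500) <= 3 * np.sqrt(250)


class TestMapLibrary:
    def test_empty_readset(self, small_build, small_index):
        from centrochip.reads import ReadSet

        empty = ReadSet(np.zeros((0, 49), np.uint8), np.zeros((0, 49), np.uint8))
        aln, stats = map_library(empty, small_index, 0)
        assert len(aln) == 0 and stats.total == 0

    def test_error_free_arm_reads_map_uniquely_to_origin(self, small_build, small_index):
        """Reads simulated from unique arms: >= 99% unique hits at the
        truth coordinate."""
        lib = LibraryConfig(n_fragments=2_000, error_rate=0.0)
        # restrict occupancy to the left arm (unique sequence)
        profile = OccupancyProfile([("chr1", 0, 9_500, 1.0)], baseline=0.0)
        reads = simulate_library(small_build, profile, lib, 21)
        aln, stats = map_library(reads, small_index, 22)
        assert stats.mapped == stats.total
        correct_unique = (
            (aln.multiplicity == 1)
            & (aln.start == reads.truth_start[aln.read_idx])
            & (aln.strand == reads.truth_strand[aln.read_idx])
        )
        assert correct_unique.mean() >= 0.99

    def test_seeded_determinism(self, small_build, small_index):
        lib = LibraryConfig(n_fragments=1_000, error_rate=0.005)
        reads = simulate_library(small_build, OccupancyProfile.uniform(), lib, 23)
        a1, s1 = map_library(reads, small_index, 77)
        a2, s2 = map_library(reads, small_index, 77)
        assert (a1.start == a2.start).all() and (a1.strand == a2.strand).all()
        assert s1 == s2

    def test_stats_invariants(self, small_build, small_index):
        lib = LibraryConfig(n_fragments=3_000, error_rate=0.01)
        reads = simulate_library(small_build, OccupancyProfile.uniform(), lib, 24)
        _, stats = map_library(reads, small_index, 25)
        assert stats.mapped + stats.unmapped == stats.total == len(reads)
        assert stats.unique + stats.multi == stats.mapped


class TestSamOutput:
    def test_sam_round_trip_via_pysam(self, small_build, small_index, tmp_path):
        lib = LibraryConfig(n_fragments=300, error_rate=0.005)
        reads = simulate_library(small_build, OccupancyProfile.uniform(), lib, 26)
        aln, _ = map_library(reads, small_index, 27)
        sam = tmp_path / "out.sam"
        aln.to_sam(sam, small_build, reads)

        import pysam

        with pysam.AlignmentFile(str(sam), "r") as fh:
            recs = list(fh)
        assert len(recs) == len(aln)
        for i, rec in enumerate(recs):
            assert rec.reference_start == aln.start[i]
            assert rec.is_reverse == bool(aln.strand[i])
            assert rec.get_tag("NM") == aln.mismatches[i]
            assert rec.get_tag("XH") == aln.multiplicity[i]

        back = AlignmentSet.from_sam(sam)
        assert (back.start == aln.start).all()
        assert (back.mismatches == aln.mismatches).all()

    def test_bed_output(self, small_build, small_index, tmp_path):
        lib = LibraryConfig(n_fragments=50, error_rate=0.0)
        reads = simulate_library(small_build, OccupancyProfile.uniform(), lib, 28)
        aln, _ = map_library(reads, small_index, 29)
        bed = tmp_path / "out.bed"
        aln.to_bed(bed)
        lines = bed.read_text().splitlines()
        assert len(lines) == len(aln)
        chrom, start, end, _name, _score, strand = lines[0].split("\t")
        assert int(end) - int(start) == 49 and strand in "+-"
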