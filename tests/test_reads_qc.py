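"""Read simulator (fragment sampling, sequencing errors, artifacts) and
the three-rule QC filter."""

import numpy as np
import pytest
from scipy import stats

from centrochip import _seq
from centrochip.genome import ChromosomeSpec, RepeatFamilySpec, build_genome
from centrochip.reads import (
    LibraryConfig,
    OccupancyProfile,
    QCReport,
    ReadSet,
    fragments_to_reads,
    inject_artifacts,
    qc_filter,
    sample_fragments,
    simulate_library,
)


@pytest.fixture(scope="module")
def flat_build():
    """400 kb chromosome with a 40 kb centromere (for fold-fraction math)."""
    cen = RepeatFamilySpec(unit_length=177, unit_at_fraction=0.7,
                           copy_count=226, per_copy_divergence=0.02)
    chrom = ChromosomeSpec("chr1", 400_000, cen, 180_000)
    return build_genome([chrom], None, rng_seed=5)


class TestFragmentSampling:
    def test_uniform_starts_chi_square(self, flat_build):
        """Uniform profile: fragment starts pass a 10-bin chi-square test
        at alpha=0.01 in at least 18 of 20 seeds."""
        lib = LibraryConfig(n_fragments=5_000)
        profile = OccupancyProfile.uniform()
        passes = 0
        for seed in range(20):
            frags = sample_fragments(flat_build, profile, lib, seed)
            counts, _ = np.histogram(frags.start, bins=10, range=(0, 400_000))
            _, p = stats.chisquare(counts)
            passes += p > 0.01
        assert passes >= 18

    def test_fold_weighted_fraction(self, flat_build):
        """Fold 10 on a 40 kb centromere of 400 kb: expected centromeric
        fraction is (10*40)/(10*40 + 360) ~ 0.526."""
        cen = flat_build.truth.features[0]
        profile = OccupancyProfile([(cen.chrom, cen.start, cen.end, 10.0)])
        lib = LibraryConfig(n_fragments=20_000)
        frags = sample_fragments(flat_build, profile, lib, 1)
        frac = ((frags.start >= cen.start) & (frags.start < cen.end)).mean()
        expected = (10 * 40_000) / (10 * 40_000 + 360_000)
        assert abs(frac - expected) < 0.02

    def test_zero_fragments(self, flat_build):
        frags = sample_fragments(flat_build, OccupancyProfile.uniform(),
                                 LibraryConfig(n_fragments=0), 0)
        assert len(frags) == 0

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError):
            OccupancyProfile([("c", 0, 10, -1.0)])


class TestReads:
    def test_error_free_reads_match_genome(self, flat_build):
        lib = LibraryConfig(n_fragments=500, error_rate=0.0)
        frags = sample_fragments(flat_build, OccupancyProfile.uniform(), lib, 2)
        reads, skipped = fragments_to_reads(frags, flat_build, lib, 3)
        assert reads.read_length == 49
        g = flat_build.codes("chr1")
        for i in range(len(reads)):
            s = reads.truth_start[i]
            window = g[s:s + 49]
            if reads.truth_strand[i]:
                window = _seq.revcomp_codes(window)
            assert (reads.seq[i] == window).all()

    def test_error_rate_calibration(self, flat_build):
        """Binomial oracle: observed mismatch fraction vs the truth origin
        within 0.01 +/- 0.002 for 10,000 reads at rate 0.01."""
        lib = LibraryConfig(n_fragments=10_000, error_rate=0.01)
        frags = sample_fragments(flat_build, OccupancyProfile.uniform(), lib, 4)
        reads, _ = fragments_to_reads(frags, flat_build, lib, 5)
        g = flat_build.codes("chr1")
        mism = 0
        for i in range(len(reads)):
            s = reads.truth_start[i]
            window = g[s:s + 49]
            if reads.truth_strand[i]:
                window = _seq.revcomp_codes(window)
            mism += int((reads.seq[i] != window).sum())
        frac = mism / (len(reads) * 49)
        assert abs(frac - 0.01) < 0.002

    def test_short_fragments_skipped(self, flat_build):
        lib = LibraryConfig(n_fragments=200, fragment_length_mean=50.0,
                            fragment_length_sd=10.0)
        frags = sample_fragments(flat_build, OccupancyProfile.uniform(), lib, 6)
        # clip some fragments below the read length artificially
        frags.end = frags.start + 10
        reads, skipped = fragments_to_reads(frags, flat_build, lib, 7)
        assert len(reads) == 0 and skipped == 200


class TestArtifacts:
    def _reads(self, flat_build, n=1_000, **kwargs):
        lib = LibraryConfig(n_fragments=n, error_rate=0.0, **kwargs)
        frags = sample_fragments(flat_build, OccupancyProfile.uniform(), lib, 8)
        reads, _ = fragments_to_reads(frags, flat_build, lib, 9)
        return reads, lib

    def test_zero_rates_identity(self, flat_build):
        reads, lib = self._reads(flat_build)
        out = inject_artifacts(reads, lib, 10)
        assert out is reads

    def test_n_injection_trips_rule(self, flat_build):
        reads, _ = self._reads(flat_build)
        lib = LibraryConfig(n_fragments=1, n_fraction=1.0)
        out = inject_artifacts(reads, lib, 11)
        n_counts = (out.seq == _seq.N).sum(axis=1)
        assert (n_counts >= 3).all()  # 3/49 = 6.1% > 5%

    def test_lowq_injection_trips_rule(self, flat_build):
        reads, _ = self._reads(flat_build)
        lib = LibraryConfig(n_fragments=1, lowq_fraction=1.0)
        out = inject_artifacts(reads, lib, 12)
        lowq = (out.qual < 10).sum(axis=1)
        assert (lowq >= 10).all()  # 10/49 = 20.4% > 20%


def _make_reads(seq_rows, qual_rows):
    seq = np.vstack([_seq.encode(s) for s in seq_rows])
    qual = np.vstack([np.asarray(q, dtype=np.uint8) for q in qual_rows])
    return ReadSet(seq, qual)


class TestQCFilter:
    GOOD = "ACGT" * 12 + "A"  # 49 bp

    def test_boundary_n_content(self):
        """2 Ns (4.1%) kept; 3 Ns (6.1%) removed: strict 5% rule."""
        two_n = "NN" + self.GOOD[2:]
        three_n = "NNN" + self.GOOD[3:]
        reads = _make_reads([two_n, three_n], [[40] * 49] * 2)
        clean, rep = qc_filter(reads)
        assert rep == QCReport(2, 0, 1, 0, 1)
        assert _seq.decode(clean.seq[0]) == two_n

    def test_boundary_low_quality(self):
        """9 bases < Q10 (18.4%) kept; 10 (20.4%) removed: strict 20% rule."""
        q9 = [2] * 9 + [40] * 40
        q10 = [2] * 10 + [40] * 39
        reads = _make_reads([self.GOOD, self.GOOD], [q9, q10])
        clean, rep = qc_filter(reads)
        assert rep == QCReport(2, 0, 0, 1, 1)

    def test_boundary_quality_score_is_strict(self):
        """Bases at exactly Q10 are not low-quality."""
        q_all10 = [10] * 49
        reads = _make_reads([self.GOOD], [q_all10])
        _, rep = qc_filter(reads)
        assert rep.clean == 1

    def test_adapter_prefix_removed(self):
        from centrochip.reads import DEFAULT_ADAPTER

        bad = DEFAULT_ADAPTER + self.GOOD[len(DEFAULT_ADAPTER):]
        reads = _make_reads([bad, self.GOOD], [[40] * 49] * 2)
        clean, rep = qc_filter(reads)
        assert rep == QCReport(2, 1, 0, 0, 1)

    def test_constructed_fixture_counts(self, flat_build):
        """100 reads with disjoint 10 adapter / 5 N / 7 low-quality
        failures: per-rule counts forced by construction."""
        lib = LibraryConfig(n_fragments=100, error_rate=0.0,
                            adapter_fraction=0.10, n_fraction=0.05,
                            lowq_fraction=0.07)
        frags = sample_fragments(flat_build, OccupancyProfile.uniform(), lib, 13)
        reads, _ = fragments_to_reads(frags, flat_build, lib, 14)
        degraded = inject_artifacts(reads, lib, 15)
        clean, rep = qc_filter(degraded)
        assert (rep.adapter_removed, rep.n_removed, rep.lowq_removed) == (10, 5, 7)
        assert rep.clean == 78

    def test_report_invariant_and_identity(self, flat_build):
        lib = LibraryConfig(n_fragments=2_000, error_rate=0.0)
        reads = simulate_library(flat_build, OccupancyProfile.uniform(), lib, 16)
        clean, rep = qc_filter(reads)
        assert rep.adapter_removed + rep.n_removed + rep.lowq_removed + rep.clean == rep.total
        assert rep.clean == rep.total == len(reads)  # all artifact rates 0
        assert (clean.seq == reads.seq).all()


class TestFastqIO:
    def test_round_trip(self, flat_build, tmp_path):
        lib = LibraryConfig(n_fragments=50, error_rate=0.01)
        reads = simulate_library(flat_build, OccupancyProfile.uniform(), lib, 17)
        p = tmp_path / "r.fastq"
        reads.to_fastq(p)
        back = ReadSet.from_fastq(p)
        assert (back.seq == reads.seq).all()
        assert (back.qual == reads.qual).all()
        assert list(back.ids) == list(reads.ids)

    def test_simulation_determinism(self, flat_build, tmp_path):
        lib = LibraryConfig(n_fragments=200, error_rate=0.01,
                            adapter_fraction=0.05, n_fraction=0.05, lowq_fraction=0.05)
        files = []
        for tag in ("a", "b"):
            reads = simulate_library(flat_build, OccupancyProfile.uniform(), lib, 123)
            p = tmp_path / f"{tag}.fastq"
            reads.to_fastq(p)
            files.append(p.read_bytes())
        assert files[0] == files[1]

    def test_malformed_record_names_read(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\nXXXX\nIIII\n")
        with pytest.raises(ValueError, match="r1"):
            ReadSet.from_fastq(p)
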