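"""Reference experiments at the package's standard study conditions.

Each function runs one self-contained, seeded experiment used to
characterise the pipeline: mapper-vs-oracle agreement, pigeonhole
completeness, no-enrichment ratio calibration, planted-centromere
recovery, and the repeat cross-mapping (false-positive peak) mechanism.
The same functions back the test suite and the reproduction script, so
the conditions are defined exactly once.

Standard conditions: 400 kb chromosomes carrying one 20 kb centromeric
array (113 copies of a 177 bp AT-rich unit at 2% per-copy divergence),
49 bp single-end reads, up to 2 mismatches, 150 bp windows, <10-input-read
masking, 3x-background peak threshold. Coverage is 20x per library for the
calibration experiment and 5x (demo genome) or 10x (single-chromosome
duplicate screen) for the peak-level experiments.
"""

from __future__ import annotations

import numpy as np

from . import reads as rm
from .ambiguity import cross_map_rate
from .enrichment import EnrichmentModel
from .genome import (
    CENTROMERE,
    ChromosomeSpec,
    GenomeBuild,
    PlantedDuplicate,
    RepeatFamilySpec,
    build_genome,
)
from .mapping import (
    GenomeIndex,
    brute_force_best_hits,
    find_best_hits,
    map_library,
    partition_scheme,
)
from .pipeline import demo_config, run_pipeline
from .reads import LibraryConfig, OccupancyProfile, qc_filter, simulate_library

STANDARD_CENTROMERE = RepeatFamilySpec(
    unit_length=177, unit_at_fraction=0.70, copy_count=113, per_copy_divergence=0.02
)


def _sub_seed(seed: int, tag: str) -> int:
    """Stable small sub-seed from (seed, tag)."""
    import zlib

    return int(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# mapper correctness


def oracle_agreement(n_genomes: int = 20, reads_per_genome: int = 200,
                     seed: int = 0, genome_length: int = 40_000) -> dict:
    """Compare the seeded mapper's best-hit strata against a brute-force
    Hamming scan on small repeat-bearing genomes.

    Reads are sampled from the genome with 0-2 injected substitutions on a
    random strand. Returns the fraction of reads whose strata agree
    exactly and the total read count.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    total = 0
    for gi in range(n_genomes):
        length = int(genome_length * (0.25 + 0.75 * rng.random()))  # <= 50 kb
        cen = RepeatFamilySpec(100, 0.6, 30, 0.03)
        chrom = ChromosomeSpec("c", length, cen, length // 3)
        build = build_genome([chrom], None, rng_seed=int(rng.integers(2**31)))
        index = GenomeIndex(build, 49)
        g = build.codes("c")
        for _ in range(reads_per_genome):
            s = int(rng.integers(0, length - 49))
            read = g[s:s + 49].copy()
            n_err = int(rng.integers(0, 3))
            pos = rng.choice(49, n_err, replace=False)
            read[pos] = (read[pos] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
            if rng.random() < 0.5:
                from . import _seq

                read = _seq.revcomp_codes(read)
            got = sorted((h.chrom, h.start, h.strand, h.mismatches)
                         for h in find_best_hits(read, index))
            want = sorted((h.chrom, h.start, h.strand, h.mismatches)
                          for h in brute_force_best_hits(read, build))
            agree += got == want
            total += 1
    return {"agreement": agree / total, "n": total}


def pigeonhole_check(seed: int = 0, n_loci: int = 30) -> dict:
    """Adversarial completeness check of the partition seed index.

    For planted loci, place 2 substitutions in every one- or two-partition
    combination of the 3-partition scheme and confirm the planted locus is
    never missed. Returns the number of missed placements (0 expected).
    """
    rng = np.random.default_rng(seed)
    chrom = ChromosomeSpec("c", 20_000, RepeatFamilySpec(100, 0.6, 5, 0.0), 8_000)
    build = build_genome([chrom], None, rng_seed=seed)
    index = GenomeIndex(build, 49)
    parts = partition_scheme(49, 2)
    g = build.codes("c")
    missed = 0
    cases = 0
    for _ in range(n_loci):
        s = int(rng.integers(0, 20_000 - 49))
        base = g[s:s + 49].copy()
        for i, (oi, ki) in enumerate(parts):
            for j, (oj, kj) in enumerate(parts):
                read = base.copy()
                if i == j:  # both errors inside one partition
                    p1, p2 = rng.choice(ki, 2, replace=False) + oi
                else:
                    p1 = int(rng.integers(0, ki)) + oi
                    p2 = int(rng.integers(0, kj)) + oj
                for p in (p1, p2):
                    read[p] = (read[p] + int(rng.integers(1, 4))) % 4
                hits = find_best_hits(read, index)
                found = any(h.chrom == "c" and h.start == s and h.strand == "+"
                            for h in hits)
                missed += not found
                cases += 1
    return {"missed": missed, "n": cases}


# ---------------------------------------------------------------------------
# enrichment-statistic calibration and recovery


def flat_calibration(seed: int, chrom_length: int = 400_000,
                     coverage: float = 20.0) -> dict:
    """No-enrichment ChIP vs input on one standard chromosome.

    Both libraries are simulated at uniform occupancy and the given
    coverage; returns the genome-wide mean unmasked ratio, the fraction of
    unmasked windows inside [0.5, 2.0], the masked-window count, and the
    number of peaks at the default threshold (expected 0).
    """
    chrom = ChromosomeSpec("chr1", chrom_length, STANDARD_CENTROMERE,
                           chrom_length // 2 - STANDARD_CENTROMERE.array_length // 2)
    build = build_genome([chrom], None, rng_seed=_sub_seed(seed, "genome"))
    index = GenomeIndex(build, 49)
    n = int(coverage * chrom_length / 49)
    lib = LibraryConfig(n_fragments=n, error_rate=0.005)
    uniform = OccupancyProfile.uniform()

    def _library(tag):
        reads = simulate_library(build, uniform, lib, _sub_seed(seed, f"sim_{tag}"))
        clean, _ = qc_filter(reads)
        aln, _ = map_library(clean, index, _sub_seed(seed, f"map_{tag}"))
        return aln

    model = EnrichmentModel(_library("chip"), _library("input"), build)
    res = model.fit(background_interval=("chr1", 50_000, 150_000))
    t = res.window_table
    unmasked = t.loc[~t["masked"], "ratio"]
    return {
        "mean_ratio": float(unmasked.mean()),
        "fraction_in_band": float(unmasked.between(0.5, 2.0).mean()),
        "n_masked": int(t["masked"].sum()),
        "n_windows": len(t),
        "n_peaks": len(res.peaks),
        "background": res.background.mean_ratio,
    }


def centromere_recovery(seed: int, coverage: float = 5.0) -> dict:
    """Full demo-genome pipeline run scored against the planted truth.

    Returns per-chromosome flags for 'top peak overlaps the truth
    centromere' plus the minichromosome contig summary.
    """
    cfg = demo_config(seed=seed, coverage=coverage)
    report = run_pipeline(cfg)
    per_chrom = {}
    for c in cfg.chromosomes:
        tops = [p for p in report.peaks
                if p["chrom"] == c.name and p["is_top_per_chromosome"]]
        per_chrom[c.name] = bool(tops) and bool(tops[0]["overlaps_truth_centromere"])
    mini = report.contig_summaries[0] if report.contig_summaries else None
    return {
        "top_peak_recovered": per_chrom,
        "background": report.background,
        "mini_mean_ratio": mini["mean_ratio"] if mini else float("nan"),
        "mini_above_background": (mini["mean_ratio"] > report.background) if mini else None,
    }


# ---------------------------------------------------------------------------
# repeat cross-mapping mechanism


def duplicate_screen(identity: float, seed: int, chrom_length: int = 400_000,
                     dup_length: int = 2_000, coverage: float = 10.0) -> dict:
    """Plant an arm copy of centromeric sequence at the given percent
    identity and test whether it attracts a spurious enrichment peak.

    The chromosome carries the standard centromere (10-fold ChIP
    occupancy); the duplicate itself has baseline occupancy, so any peak
    over it is pure cross-mapping artifact. Returns the peak verdicts and
    the duplicate's observed cross-map rate into the centromere.
    """
    cen_start = chrom_length // 2 - STANDARD_CENTROMERE.array_length // 2
    dup = PlantedDuplicate(
        source_start=cen_start + 5_000, source_end=cen_start + 5_000 + dup_length,
        dest_start=300_000, target_identity=identity,
    )
    chrom = ChromosomeSpec("chr1", chrom_length, STANDARD_CENTROMERE, cen_start,
                           planted_duplicates=(dup,))
    build = build_genome([chrom], None, rng_seed=_sub_seed(seed, "genome"))
    index = GenomeIndex(build, 49)
    n = int(coverage * chrom_length / 49)
    lib = LibraryConfig(n_fragments=n, error_rate=0.005)
    chip_prof = OccupancyProfile.from_truth(build.truth, {CENTROMERE: 10.0})

    def _library(profile, tag):
        reads = simulate_library(build, profile, lib, _sub_seed(seed, f"sim_{tag}"))
        clean, _ = qc_filter(reads)
        aln, _ = map_library(clean, index, _sub_seed(seed, f"map_{tag}"))
        return aln

    model = EnrichmentModel(
        _library(chip_prof, "chip"), _library(OccupancyProfile.uniform(), "input"), build)
    res = model.fit(background_interval=("chr1", 50_000, 150_000), truth=build.truth)
    dup_peaks = [p for p in res.peaks
                 if p.start < dup.dest_end and p.end > dup.dest_start]
    rate = cross_map_rate(
        ("chr1", dup.dest_start, dup.dest_end),
        ("chr1", cen_start, cen_start + STANDARD_CENTROMERE.array_length),
        build, index,
    )
    return {
        "spurious_peak": bool(dup_peaks),
        "dup_peak_mean_ratio": dup_peaks[0].mean_ratio if dup_peaks else float("nan"),
        "cross_map_rate": rate,
        "background": res.background.mean_ratio,
        "n_peaks": len(res.peaks),
        "peaks": res.peaks,
        "build": build,
        "index": index,
    }


def identity_sweep(seed: int = 0, identities=(100, 98, 96, 94, 92, 90),
                   feature_length: int = 2_000, genome_length: int = 60_000) -> dict:
    """Cross-map rate of one planted duplicate as it is progressively
    diverged from its centromeric source.

    The same element is mutated cumulatively: each identity step adds
    substitutions (at positions drawn once) on top of the previous step,
    the way a single diverging copy accumulates changes over time. The
    rate at every step is computed by exhaustive k-mer enumeration; under
    cumulative divergence the rate is non-increasing by construction,
    which is the property the sweep demonstrates.
    """
    from . import _seq
    from .genome import GenomeTruth

    cen = RepeatFamilySpec(177, 0.7, 20, 0.02)
    cen_start = 20_000
    dup_start = 45_000
    dup = PlantedDuplicate(cen_start, cen_start + feature_length, dup_start,
                           target_identity=100.0)
    chrom = ChromosomeSpec("c", genome_length, cen, cen_start,
                           planted_duplicates=(dup,))
    base = build_genome([chrom], None, rng_seed=_sub_seed(seed, "sweep"))
    codes0 = base.codes("c").copy()

    rng = np.random.default_rng(_sub_seed(seed, "sweep_mut"))
    positions = rng.permutation(feature_length)
    shifts = rng.integers(1, 4, feature_length, dtype=np.uint8)

    rates = []
    for ident in identities:
        n_sub = int(round((1.0 - ident / 100.0) * feature_length))
        codes = codes0.copy()
        p = dup_start + positions[:n_sub]
        codes[p] = (codes[p] + shifts[:n_sub]) % 4
        build = GenomeBuild({"c": _seq.decode(codes)}, GenomeTruth())
        index = GenomeIndex(build, 49)
        rates.append(cross_map_rate(
            ("c", dup_start, dup_start + feature_length),
            ("c", cen_start, cen_start + cen.array_length),
            build, index,
        ))
    return {"identities": list(identities), "rates": rates}
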