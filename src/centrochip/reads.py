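"""Single-end short-read simulation and read quality control.

The simulator stands in for the wet-lab side of a ChIP experiment: fragment
start positions are drawn with probability proportional to a per-base fold
occupancy (the immunoprecipitation enrichment), fragments get truncated-
normal lengths, and one 49 bp single-end read is taken from the 5' end of a
uniformly chosen strand. Artifact injection and the QC filter implement the
standard cleaning rules for such libraries: reads carrying the sequencing
adapter, reads with more than 5% unknown (N) bases, and reads in which more
than 20% of bases fall below quality 10 are removed (strict inequalities;
rules applied in that order, first match wins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .genome import GenomeBuild, as_rng

DEFAULT_ADAPTER = "AGATCGGAAGAGC"
DEFAULT_READ_LENGTH = 49

#: QC rule constants: N-fraction bound, low-quality fraction bound, and the
#: Phred score below which a base counts as low quality.
MAX_N_FRACTION = 0.05
MAX_LOWQ_FRACTION = 0.20
LOWQ_PHRED = 10


@dataclass
class OccupancyProfile:
    """Fold occupancy over the genome: ``baseline`` everywhere except the
    listed intervals. Fragment starts are sampled proportional to fold."""

    intervals: list[tuple[str, int, int, float]] = field(default_factory=list)
    baseline: float = 1.0

    def __post_init__(self) -> None:
        for chrom, start, end, fold in self.intervals:
            if not (math.isfinite(fold) and fold >= 0):
                raise ValueError(f"fold for {chrom}:{start}-{end} must be finite and >= 0")
        if not (math.isfinite(self.baseline) and self.baseline >= 0):
            raise ValueError("baseline fold must be finite and >= 0")

    @classmethod
    def uniform(cls) -> "OccupancyProfile":
        return cls([])

    @classmethod
    def from_truth(cls, truth, fold_by_label: dict[str, float]) -> "OccupancyProfile":
        """Assign a fold to every truth feature whose label appears in
        ``fold_by_label``; everything else stays at baseline."""
        ivals = [
            (f.chrom, f.start, f.end, fold_by_label[f.label])
            for f in truth.features
            if f.label in fold_by_label
        ]
        return cls(ivals)

    def weights(self, chrom: str, length: int) -> np.ndarray:
        w = np.full(length, self.baseline, dtype=np.float64)
        for c, start, end, fold in self.intervals:
            if c == chrom:
                w[start:end] = fold
        return w


@dataclass(frozen=True)
class LibraryConfig:
    """Sequencing-library simulation parameters.

    ``error_rate`` is the per-base substitution probability; qualities are
    written as the Phred score implied by that rate (capped at Q40).
    Artifact rates are the fractions of reads receiving, respectively, an
    adapter read-through prefix, N injections pushing N-content above 5%,
    and quality downgrades pushing >20% of bases below Q10.
    """

    n_fragments: int
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 50.0
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = 0.005
    adapter_fraction: float = 0.0
    n_fraction: float = 0.0
    lowq_fraction: float = 0.0
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for name in ("error_rate", "adapter_fraction", "n_fraction", "lowq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FragmentSet:
    """Sampled fragments as parallel arrays (chromosome index into names)."""

    chrom_names: list[str]
    chrom_idx: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __len__(self) -> int:
        return len(self.start)


class ReadSet:
    """Fixed-length single-end reads as code/quality matrices.

    ``truth_chrom_idx``/``truth_start``/``truth_strand`` record the genomic
    origin of each simulated read (the leftmost coordinate of the read
    interval on the forward strand); they are carried for testing and are
    not written to FASTQ. ``artifact`` labels injected artifacts.
    """

    def __init__(self, seq, qual, ids=None, truth_chrom_idx=None,
                 truth_start=None, truth_strand=None, chrom_names=None,
                 artifact=None):
        self.seq = np.asarray(seq, dtype=np.uint8)
        self.qual = np.asarray(qual, dtype=np.uint8)
        if self.seq.shape != self.qual.shape:
            raise ValueError("sequence and quality matrices must have the same shape")
        n = self.seq.shape[0]
        self.ids = np.asarray(ids, dtype=object) if ids is not None else np.array(
            [f"read{i}" for i in range(n)], dtype=object)
        self.truth_chrom_idx = truth_chrom_idx
        self.truth_start = truth_start
        self.truth_strand = truth_strand
        self.chrom_names = chrom_names
        self.artifact = artifact

    def __len__(self) -> int:
        return self.seq.shape[0]

    @property
    def read_length(self) -> int:
        return self.seq.shape[1]

    def subset(self, mask_or_idx) -> "ReadSet":
        def take(a):
            return None if a is None else a[mask_or_idx]

        return ReadSet(
            self.seq[mask_or_idx], self.qual[mask_or_idx], take(self.ids),
            take(self.truth_chrom_idx), take(self.truth_start),
            take(self.truth_strand), self.chrom_names, take(self.artifact),
        )

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@{self.ids[i]}\n")
                fh.write(_seq.decode(self.seq[i]) + "\n+\n")
                fh.write((self.qual[i] + 33).tobytes().decode("ascii") + "\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        """Parse 4-line FASTQ records (Phred+33). All reads must share one
        length; a malformed record raises naming the offending read."""
        ids, seqs, quals = [], [], []
        with open(path) as fh:
            lines = fh.read().splitlines()
        if len(lines) % 4 != 0:
            raise ValueError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
        length = None
        for i in range(0, len(lines), 4):
            head, seq, plus, qual = lines[i:i + 4]
            name = head[1:].split()[0] if len(head) > 1 else f"record {i // 4}"
            if not head.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record '{name}'")
            if len(seq) != len(qual):
                raise ValueError(f"{path}: sequence/quality length mismatch in '{name}'")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(f"{path}: variable read length at '{name}' (expected {length})")
            ids.append(name)
            seqs.append(_seq.encode(seq))
            quals.append(np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33)
        if not seqs:
            return cls(np.zeros((0, 0), np.uint8), np.zeros((0, 0), np.uint8), [])
        return cls(np.vstack(seqs), np.vstack(quals), ids)


@dataclass
class QCReport:
    total: int
    adapter_removed: int
    n_removed: int
    lowq_removed: int
    clean: int

    def __post_init__(self) -> None:
        assert self.adapter_removed + self.n_removed + self.lowq_removed + self.clean == self.total

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# simulation


def sample_fragments(
    genome: GenomeBuild,
    profile: OccupancyProfile,
    config: LibraryConfig,
    rng_seed: int | np.random.Generator,
) -> FragmentSet:
    """Draw fragment start positions proportional to the occupancy fold and
    lengths from a truncated normal, clipping at chromosome ends."""
    if not genome.sequences:
        raise ValueError("cannot sample fragments from an empty genome")
    rng = as_rng(rng_seed)
    names = genome.names
    lengths = [len(genome.sequences[n]) for n in names]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    w = np.concatenate([profile.weights(n, L) for n, L in zip(names, lengths)])
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("occupancy profile has zero total weight")

    n = config.n_fragments
    if n == 0:
        empty = np.zeros(0, dtype=np.int64)
        return FragmentSet(names, empty, empty.copy(), empty.copy())
    cum = np.cumsum(w)
    starts_global = np.searchsorted(cum, rng.random(n) * total_w, side="right")
    chrom_idx = np.searchsorted(offsets, starts_global, side="right") - 1
    starts = starts_global - offsets[chrom_idx]

    frag_len = rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    frag_len = np.maximum(np.round(frag_len), config.read_length).astype(np.int64)
    chrom_ends = np.asarray(lengths)[chrom_idx]
    ends = np.minimum(starts + frag_len, chrom_ends)
    return FragmentSet(names, chrom_idx.astype(np.int64), starts.astype(np.int64), ends)


def fragments_to_reads(
    fragments: FragmentSet,
    genome: GenomeBuild,
    config: LibraryConfig,
    rng_seed: int | np.random.Generator,
) -> tuple[ReadSet, int]:
    """Sequence one read per fragment from the 5' end of a random strand.

    Fragments shorter than the read length are skipped; the skip count is
    returned alongside the reads. Substitution errors occur independently
    per base at ``config.error_rate``.
    """
    rng = as_rng(rng_seed)
    R = config.read_length
    keep = (fragments.end - fragments.start) >= R
    n_skipped = int((~keep).sum())
    cidx = fragments.chrom_idx[keep]
    fstart = fragments.start[keep]
    fend = fragments.end[keep]
    n = len(fstart)

    names = fragments.chrom_names
    lengths = [len(genome.sequences[c]) for c in names]
    offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
    G = np.concatenate([genome.codes(c) for c in names]) if names else np.zeros(0, np.uint8)

    strand = rng.integers(0, 2, n)  # 0 = forward, 1 = reverse
    left = np.where(strand == 0, fstart, fend - R)
    gidx = (offsets[cidx] + left)[:, None] + np.arange(R)
    codes = G[gidx] if n else np.zeros((0, R), np.uint8)
    rev = strand == 1
    codes[rev] = _seq.revcomp_codes(codes[rev])

    if config.error_rate > 0 and n:
        err = rng.random((n, R)) < config.error_rate
        shift = rng.integers(1, 4, (n, R), dtype=np.uint8)
        mut = err & (codes < 4)
        codes[mut] = (codes[mut] + shift[mut]) % 4

    q = min(40, int(round(-10 * math.log10(max(config.error_rate, 1e-4)))))
    qual = np.full((n, R), q, dtype=np.uint8)
    ids = np.array([f"read{i}" for i in range(n)], dtype=object)
    reads = ReadSet(
        codes, qual, ids,
        truth_chrom_idx=cidx.copy(), truth_start=left.copy(),
        truth_strand=strand.astype(np.int8), chrom_names=list(names),
        artifact=np.full(n, "", dtype=object),
    )
    return reads, n_skipped


def simulate_library(
    genome: GenomeBuild,
    profile: OccupancyProfile,
    config: LibraryConfig,
    rng_seed: int | np.random.Generator,
) -> ReadSet:
    """Fragment sampling + read sequencing + artifact injection in one call."""
    rng = as_rng(rng_seed)
    frags = sample_fragments(genome, profile, config, rng)
    reads, _ = fragments_to_reads(frags, genome, config, rng)
    return inject_artifacts(reads, config, rng)


def inject_artifacts(
    reads: ReadSet, config: LibraryConfig, rng_seed: int | np.random.Generator
) -> ReadSet:
    """Degrade disjoint read subsets with adapter read-through, N bases, or
    quality downgrades, each sized to trip its QC rule."""
    n = len(reads)
    n_ad = int(round(config.adapter_fraction * n))
    n_n = int(round(config.n_fraction * n))
    n_q = int(round(config.lowq_fraction * n))
    if n_ad + n_n + n_q == 0 or n == 0:
        return reads
    if n_ad + n_n + n_q > n:
        raise ValueError("artifact fractions sum to more than 1")
    rng = as_rng(rng_seed)
    out = reads.subset(slice(None))
    out.seq = out.seq.copy()
    out.qual = out.qual.copy()
    out.artifact = out.artifact.copy() if out.artifact is not None else np.full(n, "", dtype=object)
    perm = rng.permutation(n)
    ad_idx = perm[:n_ad]
    n_idx = perm[n_ad:n_ad + n_n]
    q_idx = perm[n_ad + n_n:n_ad + n_n + n_q]
    R = reads.read_length

    adapter_codes = _seq.encode(config.adapter)[:R]
    out.seq[ad_idx, :len(adapter_codes)] = adapter_codes
    out.artifact[ad_idx] = "adapter"

    k_n = int(np.floor(MAX_N_FRACTION * R)) + 1  # smallest count exceeding the rule
    for i in n_idx:
        pos = rng.choice(R, size=k_n, replace=False)
        out.seq[i, pos] = _seq.N
        out.qual[i, pos] = 2
    out.artifact[n_idx] = "n_content"

    k_q = int(np.floor(MAX_LOWQ_FRACTION * R)) + 1
    for i in q_idx:
        pos = rng.choice(R, size=k_q, replace=False)
        out.qual[i, pos] = 2
    out.artifact[q_idx] = "low_quality"
    return out


# ---------------------------------------------------------------------------
# quality control


def qc_filter(reads: ReadSet, adapter: str = DEFAULT_ADAPTER) -> tuple[ReadSet, QCReport]:
    """Apply the cleaning rules in order (adapter, N content, low quality)
    with first-match attribution; returns survivors and per-rule counts.

    Rules use strict inequalities: a read is removed when its N fraction
    exceeds 5% or when more than 20% of its bases have quality < 10.
    """
    n = len(reads)
    if n == 0:
        return reads, QCReport(0, 0, 0, 0, 0)
    R = reads.read_length
    ad = _seq.encode(adapter)[:R]
    has_adapter = (reads.seq[:, :len(ad)] == ad).all(axis=1)
    n_bad = (reads.seq == _seq.N).sum(axis=1) / R > MAX_N_FRACTION
    q_bad = (reads.qual < LOWQ_PHRED).sum(axis=1) / R > MAX_LOWQ_FRACTION

    rm_ad = has_adapter
    rm_n = n_bad & ~rm_ad
    rm_q = q_bad & ~rm_ad & ~rm_n
    keep = ~(rm_ad | rm_n | rm_q)
    report = QCReport(
        total=n,
        adapter_removed=int(rm_ad.sum()),
        n_removed=int(rm_n.sum()),
        lowq_removed=int(rm_q.sum()),
        clean=int(keep.sum()),
    )
    return reads.subset(keep), report


def write_qc_report(report: QCReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for k, v in report.to_dict().items():
            fh.write(f"{k}\t{v}\n")
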