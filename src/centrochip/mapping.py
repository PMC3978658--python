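"""Ungapped short-read placement with bounded mismatches.

Reads are placed on both strands allowing up to ``max_mismatches``
substitutions (default 2), and only the best stratum — all placements at
the minimum achievable mismatch count — is reported. A read with several
equally good placements (a multi-mapping read, typical inside centromeric
tandem repeats) is assigned to exactly one of them uniformly at random,
with the number of tied placements recorded as its multiplicity. This is
the behaviour that turns near-identical repeat copies into shared,
randomly split read counts, the mechanism this package exists to analyse.

Completeness comes from a pigeonhole seed index: a read of length R is cut
into ``max_mismatches + 1`` contiguous partitions; any placement with at
most ``max_mismatches`` mismatches must match at least one partition
exactly, so exact lookups of every partition on both strands enumerate a
candidate superset which is then verified by vectorised Hamming counting.
N bases (in read or genome) count as mismatches against everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _seq
from .genome import GenomeBuild, as_rng
from .reads import ReadSet

_PAD = 64  # N padding between concatenated chromosomes


@dataclass(frozen=True)
class MappingConfig:
    max_mismatches: int = 2
    batch_size: int = 32768

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def n_partitions(self) -> int:
        return self.max_mismatches + 1


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int  # 0-based leftmost base on the forward strand
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class MappingStats:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    unique: int = 0
    multi: int = 0

    def __post_init__(self) -> None:
        assert self.mapped + self.unmapped == self.total
        assert self.unique + self.multi == self.mapped

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class AlignmentSet:
    """One chosen placement per mapped read, as parallel arrays."""

    def __init__(self, chrom_names, read_idx, read_ids, chrom_idx, start,
                 strand, mismatches, multiplicity, n_reads, read_length):
        self.chrom_names = list(chrom_names)
        self.read_idx = read_idx          # index into the input ReadSet
        self.read_ids = read_ids
        self.chrom_idx = chrom_idx
        self.start = start
        self.strand = strand              # 0 forward, 1 reverse
        self.mismatches = mismatches
        self.multiplicity = multiplicity
        self.n_reads = n_reads
        self.read_length = read_length

    def __len__(self) -> int:
        return len(self.start)

    def for_chrom(self, name: str) -> np.ndarray:
        """Start positions of alignments on one chromosome."""
        return self.start[self.chrom_idx == self.chrom_names.index(name)]

    def to_sam(self, path, genome: GenomeBuild, reads: ReadSet | None = None) -> None:
        """Minimal SAM: mandatory columns plus NM (mismatches) and XH
        (number of equally best placements)."""
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for name in self.chrom_names:
                fh.write(f"@SQ\tSN:{name}\tLN:{len(genome.sequences[name])}\n")
            for i in range(len(self)):
                flag = 16 if self.strand[i] else 0
                chrom = self.chrom_names[self.chrom_idx[i]]
                if reads is not None:
                    ridx = self.read_idx[i]
                    seq_codes = reads.seq[ridx]
                    if self.strand[i]:
                        seq_codes = _seq.revcomp_codes(seq_codes)
                        qual = (reads.qual[ridx][::-1] + 33).tobytes().decode()
                    else:
                        qual = (reads.qual[ridx] + 33).tobytes().decode()
                    seq = _seq.decode(seq_codes)
                else:
                    seq, qual = "*", "*"
                fh.write(
                    f"{self.read_ids[i]}\t{flag}\t{chrom}\t{self.start[i] + 1}\t255\t"
                    f"{self.read_length}M\t*\t0\t0\t{seq}\t{qual}\t"
                    f"NM:i:{self.mismatches[i]}\tXH:i:{self.multiplicity[i]}\n"
                )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                chrom = self.chrom_names[self.chrom_idx[i]]
                strand = "-" if self.strand[i] else "+"
                fh.write(
                    f"{chrom}\t{self.start[i]}\t{self.start[i] + self.read_length}\t"
                    f"{self.read_ids[i]}\t{self.mismatches[i]}\t{strand}\n"
                )

    @classmethod
    def from_sam(cls, path, chrom_names=None) -> "AlignmentSet":
        """Read a SAM file (e.g. one written by :meth:`to_sam`) via pysam."""
        import pysam

        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            names = chrom_names or list(sam.references)
            rid, cid, st, strd, nm, mult = [], [], [], [], [], []
            read_len = 0
            n_reads = 0
            for rec in sam:
                n_reads += 1
                if rec.is_unmapped:
                    continue
                rid.append(rec.query_name)
                cid.append(names.index(rec.reference_name))
                st.append(rec.reference_start)
                strd.append(1 if rec.is_reverse else 0)
                nm.append(rec.get_tag("NM") if rec.has_tag("NM") else 0)
                mult.append(rec.get_tag("XH") if rec.has_tag("XH") else 1)
                read_len = rec.query_length or rec.infer_read_length() or read_len
        k = len(st)
        return cls(
            names, np.arange(k), np.array(rid, dtype=object),
            np.array(cid, dtype=np.int64), np.array(st, dtype=np.int64),
            np.array(strd, dtype=np.int8), np.array(nm, dtype=np.int64),
            np.array(mult, dtype=np.int64), n_reads, read_len,
        )


def partition_scheme(read_length: int, max_mismatches: int) -> list[tuple[int, int]]:
    """(offset, length) of the max_mismatches+1 contiguous read partitions;
    lengths differ by at most one (e.g. 17/16/16 for 49 bp, 2 mismatches)."""
    m = max_mismatches + 1
    base, rem = divmod(read_length, m)
    if base == 0:
        raise ValueError("read too short for the partition scheme")
    parts = []
    off = 0
    for i in range(m):
        k = base + (1 if i < rem else 0)
        parts.append((off, k))
        off += k
    return parts


class GenomeIndex:
    """Exact-match index of every genome window for each read partition."""

    def __init__(self, genome: GenomeBuild, read_length: int,
                 config: MappingConfig | None = None):
        self.config = config or MappingConfig()
        self.read_length = read_length
        names, codes = [], []
        for name in genome.names:
            if len(genome.sequences[name]) < read_length:
                warnings.warn(
                    f"chromosome {name} shorter than the read length; excluded from mapping"
                )
                continue
            names.append(name)
            codes.append(genome.codes(name))
        if not names:
            raise ValueError("no chromosome is long enough to map reads onto")
        self.chrom_names = names
        pad = np.full(_PAD, _seq.N, dtype=np.uint8)
        pieces, offsets, off = [], [], 0
        for c in codes:
            offsets.append(off)
            pieces.append(c)
            pieces.append(pad)
            off += len(c) + _PAD
        self.G = np.concatenate(pieces)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.chrom_lengths = np.asarray([len(c) for c in codes], dtype=np.int64)
        self.partitions = partition_scheme(read_length, self.config.max_mismatches)
        self._index = [self._build_partition(off, k) for off, k in self.partitions]

    def _build_partition(self, off: int, k: int):
        G = self.G
        L = len(G)
        n_win = L - k + 1
        code = np.zeros(n_win, dtype=np.uint64)
        for t in range(k):
            code = code * np.uint64(4) + G[t:t + n_win]
        n_cum = np.concatenate([[0], np.cumsum(G == _seq.N)])
        valid = (n_cum[k:] - n_cum[:-k]) == 0
        pos = np.nonzero(valid)[0].astype(np.int64)
        codes = code[pos]
        order = np.argsort(codes, kind="stable")
        return codes[order], pos[order]

    # -- candidate generation -------------------------------------------------

    def _candidates(self, S: np.ndarray):
        """All (read, global start) candidate pairs for a batch of encoded
        reads (one strand orientation)."""
        n, R = S.shape
        out_reads, out_starts = [], []
        for (off, k), (sorted_codes, sorted_pos) in zip(self.partitions, self._index):
            sub = S[:, off:off + k]
            has_n = (sub == _seq.N).any(axis=1)
            code = np.zeros(n, dtype=np.uint64)
            for t in range(k):
                code = code * np.uint64(4) + sub[:, t]
            lo = np.searchsorted(sorted_codes, code, side="left")
            hi = np.searchsorted(sorted_codes, code, side="right")
            counts = hi - lo
            counts[has_n] = 0
            total = int(counts.sum())
            if total == 0:
                continue
            read_idx = np.repeat(np.arange(n), counts)
            cum = np.concatenate([[0], np.cumsum(counts)])
            within = np.arange(total) - cum[read_idx]
            gpos = sorted_pos[np.repeat(lo, counts) + within]
            starts = gpos - off
            ok = starts >= 0  # upper bound enforced by per-chromosome check later
            out_reads.append(read_idx[ok])
            out_starts.append(starts[ok])
        if not out_reads:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        return np.concatenate(out_reads), np.concatenate(out_starts)

    def best_hits_batch(self, seqs: np.ndarray):
        """Best-stratum hits for a batch of reads.

        Returns ``(read_idx, start, strand, mm, best_count)`` where the
        first four are parallel arrays over all best-stratum hits (start is
        the global concatenated-genome coordinate) and ``best_count[r]`` is
        the number of tied hits of read r (0 if unmapped).
        """
        n, R = seqs.shape
        max_mm = self.config.max_mismatches
        S0 = seqs
        S1 = _seq.revcomp_codes(seqs)

        Lg = len(self.G)
        all_r, all_s, all_st = [], [], []
        for strand, S in ((0, S0), (1, S1)):
            ridx, starts = self._candidates(S)
            if len(ridx):
                all_r.append(ridx)
                all_s.append(starts)
                all_st.append(np.full(len(ridx), strand, dtype=np.int64))
        if not all_r:
            empty = np.zeros(0, np.int64)
            return empty, empty, empty, empty, np.zeros(n, np.int64)
        ridx = np.concatenate(all_r)
        start = np.concatenate(all_s)
        strand = np.concatenate(all_st)

        # verify every candidate (duplicates from several partitions are
        # cheap to verify and deduplicated afterwards); read N recoded to 5
        # so a single comparison against the genome (N=4) counts every N
        # as a mismatch
        SS = np.concatenate([
            np.where(S0 == _seq.N, np.uint8(5), S0),
            np.where(S1 == _seq.N, np.uint8(5), S1),
        ])
        windows = np.lib.stride_tricks.sliding_window_view(self.G, R)
        start_clip = np.minimum(start, Lg - R)  # pad windows: all-N, filtered by mm
        row_of = strand * n + ridx
        mm = np.empty(len(start), dtype=np.int64)
        chunk = 4_000_000
        for i in range(0, len(start), chunk):
            sl = slice(i, i + chunk)
            mm[sl] = np.count_nonzero(windows[start_clip[sl]] != SS[row_of[sl]], axis=1)

        good = mm <= max_mm
        ridx, strand, start, mm = ridx[good], strand[good], start[good], mm[good]
        if len(ridx) == 0:
            empty = np.zeros(0, np.int64)
            return empty, empty, empty, empty, np.zeros(n, np.int64)

        # deduplicate (read, strand, start) triples via one radix sort
        key = ridx * (2 * Lg) + strand * Lg + start
        order = np.argsort(key, kind="stable")
        key = key[order]
        keep = np.concatenate([[True], key[1:] != key[:-1]])
        order = order[keep]
        ridx, strand, start, mm = ridx[order], strand[order], start[order], mm[order]

        # bound check: alignment must lie fully inside one chromosome
        ci = np.searchsorted(self.offsets, start, side="right") - 1
        inside = (start - self.offsets[ci] + R) <= self.chrom_lengths[ci]
        ridx, strand, start, mm = ridx[inside], strand[inside], start[inside], mm[inside]
        if len(ridx) == 0:
            empty = np.zeros(0, np.int64)
            return empty, empty, empty, empty, np.zeros(n, np.int64)

        # group by read with mm ascending; within ties the (strand, start)
        # order from the dedup sort is preserved by the stable sort
        order2 = np.argsort(ridx * (R + 1) + mm, kind="stable")
        ridx, strand, start, mm = ridx[order2], strand[order2], start[order2], mm[order2]
        first = np.concatenate([[True], ridx[1:] != ridx[:-1]])
        group_of = np.cumsum(first) - 1
        min_mm = mm[first]  # first entry per read is its minimum
        best = mm == min_mm[group_of]
        ridx, strand, start, mm = ridx[best], strand[best], start[best], mm[best]
        best_count = np.bincount(ridx, minlength=n).astype(np.int64)
        return ridx, start, strand, mm, best_count

    def split_global(self, start: np.ndarray):
        """Global concatenated coordinates -> (chrom_idx, local start)."""
        ci = np.searchsorted(self.offsets, start, side="right") - 1
        return ci, start - self.offsets[ci]


def index_genome(genome: GenomeBuild, read_length: int,
                 config: MappingConfig | None = None) -> GenomeIndex:
    return GenomeIndex(genome, read_length, config)


def find_best_hits(read: str | np.ndarray, index: GenomeIndex) -> list[Hit]:
    """All placements of one read at its minimum achievable mismatch count
    (empty if nothing is within ``max_mismatches``)."""
    codes = _seq.encode(read) if isinstance(read, str) else np.asarray(read, np.uint8)
    if len(codes) != index.read_length:
        raise ValueError("read length does not match the index")
    ridx, start, strand, mm, _ = index.best_hits_batch(codes[None, :])
    ci, local = index.split_global(start)
    return [
        Hit(index.chrom_names[c], int(s), "-" if st else "+", int(m))
        for c, s, st, m in zip(ci, local, strand, mm)
    ]


def assign_read(hits: list[Hit], rng: int | np.random.Generator) -> Hit | None:
    """Pick one hit uniformly at random from the best stratum (hits as
    produced by :func:`find_best_hits`); None if unmapped."""
    if not hits:
        return None
    rng = as_rng(rng)
    return hits[int(rng.integers(0, len(hits)))]


def map_library(
    reads: ReadSet,
    index: GenomeIndex,
    rng_seed: int | np.random.Generator,
    config: MappingConfig | None = None,
) -> tuple[AlignmentSet, MappingStats]:
    """Map a ReadSet: best-stratum search + uniform random assignment of
    multi-mapping reads. Deterministic given the seed."""
    config = config or index.config
    rng = as_rng(rng_seed)
    n = len(reads)
    R = reads.read_length if n else index.read_length
    if n and R != index.read_length:
        raise ValueError("read length does not match the index")

    sel_ridx, sel_start, sel_strand, sel_mm, sel_mult = [], [], [], [], []
    bs = config.batch_size
    for b0 in range(0, n, bs):
        batch = reads.seq[b0:b0 + bs]
        ridx, start, strand, mm, best_count = index.best_hits_batch(batch)
        mapped = np.nonzero(best_count > 0)[0]
        if len(mapped) == 0:
            continue
        # hits are grouped by read (sorted); pick a uniform index per read
        cum = np.concatenate([[0], np.cumsum(best_count)])
        pick_within = np.floor(rng.random(len(mapped)) * best_count[mapped]).astype(np.int64)
        pick = cum[mapped] + pick_within
        sel_ridx.append(mapped + b0)
        sel_start.append(start[pick])
        sel_strand.append(strand[pick])
        sel_mm.append(mm[pick])
        sel_mult.append(best_count[mapped])

    if sel_ridx:
        read_idx = np.concatenate(sel_ridx)
        gstart = np.concatenate(sel_start)
        strand = np.concatenate(sel_strand).astype(np.int8)
        mm = np.concatenate(sel_mm)
        mult = np.concatenate(sel_mult)
    else:
        read_idx = np.zeros(0, np.int64)
        gstart = np.zeros(0, np.int64)
        strand = np.zeros(0, np.int8)
        mm = np.zeros(0, np.int64)
        mult = np.zeros(0, np.int64)

    ci, local = index.split_global(gstart)
    aln = AlignmentSet(
        index.chrom_names, read_idx, reads.ids[read_idx], ci.astype(np.int64),
        local.astype(np.int64), strand, mm, mult, n_reads=n, read_length=R,
    )
    mapped = len(aln)
    unique = int((mult == 1).sum())
    stats = MappingStats(
        total=n, mapped=mapped, unmapped=n - mapped,
        unique=unique, multi=mapped - unique,
    )
    return aln, stats


def brute_force_best_hits(read: str | np.ndarray, genome: GenomeBuild,
                          max_mismatches: int = 2) -> list[Hit]:
    """Independent oracle: full Hamming scan of every position on both
    strands, returning the minimum-mismatch stratum (<= max_mismatches)."""
    codes = _seq.encode(read) if isinstance(read, str) else np.asarray(read, np.uint8)
    R = len(codes)
    rc = _seq.revcomp_codes(codes)
    hits: list[Hit] = []
    best = max_mismatches
    for name in genome.names:
        g = genome.codes(name)
        if len(g) < R:
            continue
        W = np.lib.stride_tricks.sliding_window_view(g, R)
        for strand, q in (("+", codes), ("-", rc)):
            mm = ((W != q) | (W == _seq.N) | (q == _seq.N)).sum(axis=1)
            for s in np.nonzero(mm <= max_mismatches)[0]:
                hits.append(Hit(name, int(s), strand, int(mm[s])))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]
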