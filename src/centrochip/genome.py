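"""Seeded synthetic genomes with kinetoplastid-like repeat architecture.

The generator emulates the genome features the enrichment analysis has to
cope with: megabase-scale chromosomes carrying one AT-rich centromeric
tandem-repeat array each, optional near-identical copies of centromeric
sequence planted in the chromosome arms (the mechanism behind false-positive
enrichment peaks), and a palindromic minichromosome contig built almost
entirely from 177 bp repeat units. Every build carries ground-truth feature
annotations so downstream peak calls can be scored.

Coordinates are 0-based half-open throughout, matching the BED output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import _seq

CENTROMERE = "centromere"
DUPLICATE_COPY = "duplicate_copy"
MINICHROMOSOME_REPEAT = "minichromosome_repeat"

#: Repeat unit length of the minichromosome core.
MINI_UNIT_LENGTH = 177
#: Default length of the model minichromosome contig.
MINI_TOTAL_LENGTH = 42_529


def as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class SpecificationError(ValueError):
    """Raised when a genome spec violates its invariants."""


@dataclass(frozen=True)
class RepeatFamilySpec:
    """A tandem-repeat family: ``copy_count`` mutated copies of one unit.

    Parameters
    ----------
    unit_length : int
        Length of the master repeat unit in bp (177 for the minichromosome
        core repeat).
    unit_at_fraction : float
        Expected A+T fraction of the unit; centromeric repeat units are
        relatively AT rich.
    copy_count : int
        Number of tandem copies in the array.
    per_copy_divergence : float
        Expected substitutions per base applied independently to each copy,
        in [0, 0.25]. Identity of a copy to the master unit is therefore
        ~(1 - per_copy_divergence).
    """

    unit_length: int
    unit_at_fraction: float
    copy_count: int
    per_copy_divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise SpecificationError("unit_length must be >= 1")
        if not 0.0 <= self.unit_at_fraction <= 1.0:
            raise SpecificationError("unit_at_fraction must be in [0, 1]")
        if self.copy_count < 1:
            raise SpecificationError("copy_count must be >= 1")
        if not 0.0 <= self.per_copy_divergence <= 0.25:
            raise SpecificationError("per_copy_divergence must be in [0, 0.25]")

    @property
    def array_length(self) -> int:
        return self.unit_length * self.copy_count


@dataclass(frozen=True)
class PlantedDuplicate:
    """A copy of ``[source_start, source_end)`` pasted at ``dest_start``,
    mutated to ``target_identity`` percent identity (substitutions only)."""

    source_start: int
    source_end: int
    dest_start: int
    target_identity: float = 100.0

    def __post_init__(self) -> None:
        if self.source_end <= self.source_start:
            raise SpecificationError("duplicate source interval is empty")
        if not 0.0 < self.target_identity <= 100.0:
            raise SpecificationError("target_identity must be in (0, 100]")

    @property
    def length(self) -> int:
        return self.source_end - self.source_start

    @property
    def dest_end(self) -> int:
        return self.dest_start + self.length


@dataclass(frozen=True)
class ChromosomeSpec:
    """One synthetic chromosome: i.i.d. arms + centromeric array + duplicates."""

    name: str
    length: int
    centromere: RepeatFamilySpec
    centromere_start: int
    arm_gc_fraction: float = 0.46
    planted_duplicates: tuple[PlantedDuplicate, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_duplicates", tuple(self.planted_duplicates))
        if self.length < 1:
            raise SpecificationError(f"{self.name}: length must be positive")
        if not 0.0 <= self.arm_gc_fraction <= 1.0:
            raise SpecificationError(f"{self.name}: arm_gc_fraction must be in [0, 1]")
        cen = (self.centromere_start, self.centromere_end)
        if cen[0] < 0 or cen[1] > self.length:
            raise SpecificationError(f"{self.name}: centromere outside chromosome")
        intervals = [cen]
        for dup in self.planted_duplicates:
            if dup.dest_start < 0 or dup.dest_end > self.length:
                raise SpecificationError(f"{self.name}: duplicate destination outside chromosome")
            intervals.append((dup.dest_start, dup.dest_end))
        intervals.sort()
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise SpecificationError(
                    f"{self.name}: planted features overlap ([{a0},{a1}) vs [{b0},{b1}))"
                )

    @property
    def centromere_end(self) -> int:
        return self.centromere_start + self.centromere.array_length


@dataclass(frozen=True)
class MinichromosomeSpec:
    """Palindromic minichromosome contig built from tandem repeat units.

    The sequence left of ``inversion_point`` is the reverse complement of
    the sequence right of it (truncated at the shorter side), i.e. the two
    halves read outward from the centre as the same repeat array.
    """

    name: str = "minichromosome"
    unit_length: int = MINI_UNIT_LENGTH
    total_length: int = MINI_TOTAL_LENGTH
    inversion_point: int | None = None
    unit_at_fraction: float = 0.60
    per_copy_divergence: float = 0.01

    def __post_init__(self) -> None:
        if self.total_length < 2 * self.unit_length:
            raise SpecificationError("total_length must be >= 2 * unit_length")
        if self.inversion_point is None:
            object.__setattr__(self, "inversion_point", self.total_length // 2)
        if not 0 < self.inversion_point < self.total_length:
            raise SpecificationError("inversion_point must lie inside the contig")


@dataclass(frozen=True)
class Feature:
    """A ground-truth interval on the build (0-based half-open)."""

    chrom: str
    start: int
    end: int
    label: str

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and start < self.end and end > self.start


@dataclass
class GenomeTruth:
    features: list[Feature] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def by_label(self, label: str) -> list[Feature]:
        return [f for f in self.features if f.label == label]


class GenomeBuild:
    """Sequences plus truth annotations for one synthetic genome."""

    def __init__(self, sequences: dict[str, str], truth: GenomeTruth):
        self.sequences = dict(sequences)
        self.truth = truth
        self._codes: dict[str, np.ndarray] = {}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def codes(self, name: str) -> np.ndarray:
        """uint8 code array for one chromosome (cached)."""
        if name not in self._codes:
            self._codes[name] = _seq.encode(self.sequences[name])
        return self._codes[name]

    def write(self, fasta_path, bed_path=None) -> None:
        write_genome(self, fasta_path, bed_path)

    @classmethod
    def from_fasta(cls, fasta_path, bed_path=None) -> "GenomeBuild":
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        truth = GenomeTruth()
        if bed_path is not None:
            with open(bed_path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    chrom, start, end, label = line.rstrip("\n").split("\t")[:4]
                    truth.features.append(Feature(chrom, int(start), int(end), label))
        return cls(sequences, truth)


def _spec_hash(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# sequence generation primitives


def random_background(length: int, gc_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-base background at the given GC fraction (code array)."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return rng.choice(
        np.arange(4, dtype=np.uint8), size=length, p=[p_at, p_gc, p_gc, p_at]
    ).astype(np.uint8)


def make_repeat_unit(spec: RepeatFamilySpec, rng_seed: int | np.random.Generator) -> str:
    """Draw the master repeat unit at the requested A+T fraction.

    Exactly ``round(unit_at_fraction * unit_length)`` positions carry an
    A/T (chosen uniformly between the two), the rest G/C, at random
    positions. The exact count matters because the whole tandem array
    inherits the master unit's composition, so per-base sampling noise in
    the unit would dominate the array-level AT fraction.
    """
    rng = as_rng(rng_seed)
    L = spec.unit_length
    n_at = int(round(spec.unit_at_fraction * L))
    codes = np.empty(L, dtype=np.uint8)
    codes[:n_at] = rng.choice(np.array([_seq.A, _seq.T], np.uint8), size=n_at)
    codes[n_at:] = rng.choice(np.array([_seq.C, _seq.G], np.uint8), size=L - n_at)
    rng.shuffle(codes)
    return _seq.decode(codes)


def _mutate_bernoulli(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``; a
    substitution always changes the base (uniform among the other three)."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _mutate_to_identity(codes: np.ndarray, identity_pct: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly round((1 - identity/100) * len) distinct positions."""
    n_sub = int(round((1.0 - identity_pct / 100.0) * codes.size))
    out = codes.copy()
    if n_sub == 0:
        return out
    pos = rng.choice(codes.size, size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out


def build_repeat_array(
    unit: str,
    copy_count: int,
    per_copy_divergence: float,
    rng_seed: int | np.random.Generator,
) -> tuple[str, list[float]]:
    """Concatenate ``copy_count`` independently mutated copies of ``unit``.

    Returns the array sequence and, per copy, its percent identity to the
    master unit (substitution-only Hamming identity).
    """
    if copy_count < 1:
        raise SpecificationError("copy_count must be >= 1")
    rng = as_rng(rng_seed)
    unit_codes = _seq.encode(unit)
    copies = []
    identities = []
    for _ in range(copy_count):
        cp = _mutate_bernoulli(unit_codes, per_copy_divergence, rng)
        copies.append(cp)
        identities.append(100.0 * float((cp == unit_codes).mean()))
    return _seq.decode(np.concatenate(copies)), identities


def build_chromosome(
    spec: ChromosomeSpec, rng_seed: int | np.random.Generator
) -> tuple[str, list[Feature]]:
    """Assemble one chromosome: background arms, centromeric array, planted
    duplicates; returns the sequence and its truth features."""
    rng = as_rng(rng_seed)
    codes = random_background(spec.length, spec.arm_gc_fraction, rng)

    unit = make_repeat_unit(spec.centromere, rng)
    array, _ = build_repeat_array(
        unit, spec.centromere.copy_count, spec.centromere.per_copy_divergence, rng
    )
    cen0, cen1 = spec.centromere_start, spec.centromere_end
    codes[cen0:cen1] = _seq.encode(array)
    features = [Feature(spec.name, cen0, cen1, CENTROMERE)]

    for dup in spec.planted_duplicates:
        src = codes[dup.source_start:dup.source_end].copy()
        codes[dup.dest_start:dup.dest_end] = _mutate_to_identity(src, dup.target_identity, rng)
        features.append(Feature(spec.name, dup.dest_start, dup.dest_end, DUPLICATE_COPY))

    return _seq.decode(codes), features


def build_minichromosome(
    spec: MinichromosomeSpec, rng_seed: int | np.random.Generator
) -> tuple[str, list[Feature]]:
    """Build the palindromic repeat contig.

    The longer half is generated as a tandem array of the repeat unit; the
    other half mirrors it as a reverse complement around the inversion
    point, so ``seq[:p]`` ends with the reverse complement of ``seq[p:]``
    (truncation at the shorter side).
    """
    rng = as_rng(rng_seed)
    h = spec.inversion_point
    m = spec.total_length - h
    unit = make_repeat_unit(
        RepeatFamilySpec(spec.unit_length, spec.unit_at_fraction, 1), rng
    )
    n_copies = int(np.ceil(max(h, m) / spec.unit_length))
    array, _ = build_repeat_array(unit, n_copies, spec.per_copy_divergence, rng)
    tile = _seq.encode(array)

    if m >= h:
        generator = tile[:m]
        left = generator[m - h:]
        right = _seq.revcomp_codes(generator)
    else:
        generator = tile[:h]
        left = generator
        right = _seq.revcomp_codes(generator[h - m:])
    seq = _seq.decode(np.concatenate([left, right]))
    assert len(seq) == spec.total_length
    features = [Feature(spec.name, 0, spec.total_length, MINICHROMOSOME_REPEAT)]
    return seq, features


def build_genome(
    chromosomes: list[ChromosomeSpec],
    minichromosome: MinichromosomeSpec | None = None,
    rng_seed: int = 0,
) -> GenomeBuild:
    """Build a full genome from chromosome specs plus an optional
    minichromosome, with deterministic per-chromosome sub-seeding."""
    if not chromosomes and minichromosome is None:
        raise SpecificationError("empty genome build")
    names = [c.name for c in chromosomes]
    if minichromosome is not None:
        names.append(minichromosome.name)
    if len(set(names)) != len(names):
        raise SpecificationError("duplicate chromosome names")

    root = np.random.SeedSequence(rng_seed)
    children = root.spawn(len(chromosomes) + 1)
    sequences: dict[str, str] = {}
    truth = GenomeTruth(
        provenance={
            "rng_seed": rng_seed,
            "spec_hash": _spec_hash({"chromosomes": chromosomes, "minichromosome": minichromosome}),
        }
    )
    for cspec, ss in zip(chromosomes, children):
        seq, feats = build_chromosome(cspec, np.random.default_rng(ss))
        sequences[cspec.name] = seq
        truth.features.extend(feats)
    if minichromosome is not None:
        seq, feats = build_minichromosome(minichromosome, np.random.default_rng(children[-1]))
        sequences[minichromosome.name] = seq
        truth.features.extend(feats)
    return GenomeBuild(sequences, truth)


def write_genome(build: GenomeBuild, fasta_path, bed_path=None) -> None:
    """Write the build as FASTA (one record per chromosome) and optionally
    the truth features as 4-column BED."""
    if not build.sequences:
        raise SpecificationError("refusing to write an empty build")
    try:
        with open(fasta_path, "w") as fh:
            for name, seq in build.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        if bed_path is not None:
            with open(bed_path, "w") as fh:
                for f in build.truth.features:
                    fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.label}\n")
    except OSError as exc:
        raise OSError(f"failed writing genome output to {exc.filename}: {exc}") from exc


def palindrome_check(seq: str, inversion_point: int) -> bool:
    """True iff the halves mirror as reverse complements around the point."""
    left, right = seq[:inversion_point], seq[inversion_point:]
    t = min(len(left), len(right))
    return left[-t:] == _seq.revcomp(right[:t])
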