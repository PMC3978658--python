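"""End-to-end seeded pipeline: genome synthesis -> library simulation ->
QC -> mapping -> window enrichment -> peak calling -> artifact diagnosis.

One global seed governs every stochastic stage through documented sub-seed
derivation (stage name hashed into a SeedSequence together with the global
seed), so a single stage can be re-run reproducibly and two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ambiguity, enrichment, genome as genome_mod, mapping, reads as reads_mod
from .genome import (
    CENTROMERE,
    MINICHROMOSOME_REPEAT,
    ChromosomeSpec,
    MinichromosomeSpec,
    PlantedDuplicate,
    RepeatFamilySpec,
)

logger = logging.getLogger("centrochip")


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: seeded by (global seed, crc32 of
    the stage name), so stages are independent and individually re-runnable."""
    return np.random.default_rng(np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())]))


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    chromosomes: list[ChromosomeSpec]
    minichromosome: MinichromosomeSpec | None
    chip_library: reads_mod.LibraryConfig
    input_library: reads_mod.LibraryConfig
    fold_by_label: dict[str, float]
    background_interval: tuple[str, int, int]
    mapping: mapping.MappingConfig = field(default_factory=mapping.MappingConfig)
    window_size: int = enrichment.DEFAULT_WINDOW_SIZE
    min_input_reads: int = enrichment.MIN_INPUT_READS
    fold_threshold: float = 3.0
    merge_gap: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_interval"] = list(self.background_interval)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        chroms = []
        for c in d["chromosomes"]:
            c = dict(c)
            c["centromere"] = RepeatFamilySpec(**c["centromere"])
            c["planted_duplicates"] = tuple(
                PlantedDuplicate(**p) for p in c.get("planted_duplicates", ())
            )
            chroms.append(ChromosomeSpec(**c))
        mini = d.get("minichromosome")
        return cls(
            chromosomes=chroms,
            minichromosome=MinichromosomeSpec(**mini) if mini else None,
            chip_library=reads_mod.LibraryConfig(**d["chip_library"]),
            input_library=reads_mod.LibraryConfig(**d["input_library"]),
            fold_by_label=dict(d["fold_by_label"]),
            background_interval=tuple(d["background_interval"]),
            mapping=mapping.MappingConfig(**d.get("mapping", {})),
            window_size=d.get("window_size", enrichment.DEFAULT_WINDOW_SIZE),
            min_input_reads=d.get("min_input_reads", enrichment.MIN_INPUT_READS),
            fold_threshold=d.get("fold_threshold", 3.0),
            merge_gap=d.get("merge_gap", 1),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def demo_config(seed: int = 0, n_chromosomes: int = 4, chrom_length: int = 400_000,
                coverage: float = 5.0, centromere_fold: float = 10.0,
                mini_fold: float = 3.0, with_minichromosome: bool = True,
                duplicates: dict[str, PlantedDuplicate] | None = None) -> RunConfig:
    """The default demonstration setup: megabase-like chromosomes with one
    AT-rich centromeric array each (20 kb of 177 bp units), an optional
    palindromic minichromosome, ten-fold ChIP occupancy on centromeres and
    three-fold on the minichromosome repeats."""
    cen_spec = RepeatFamilySpec(
        unit_length=177, unit_at_fraction=0.70, copy_count=113, per_copy_divergence=0.02
    )
    chroms = []
    for i in range(n_chromosomes):
        name = f"chr{i + 1}"
        dup = (duplicates or {}).get(name)
        chroms.append(ChromosomeSpec(
            name=name,
            length=chrom_length,
            centromere=cen_spec,
            centromere_start=chrom_length // 2 - cen_spec.array_length // 2,
            arm_gc_fraction=0.46,
            planted_duplicates=(dup,) if dup else (),
        ))
    mini = MinichromosomeSpec() if with_minichromosome else None
    total = n_chromosomes * chrom_length + (mini.total_length if mini else 0)
    n_frag = int(coverage * total / reads_mod.DEFAULT_READ_LENGTH)
    lib = dict(n_fragments=n_frag, error_rate=0.005,
               adapter_fraction=0.01, n_fraction=0.005, lowq_fraction=0.01)
    fold = {CENTROMERE: centromere_fold}
    if mini:
        fold[MINICHROMOSOME_REPEAT] = mini_fold
    return RunConfig(
        chromosomes=chroms,
        minichromosome=mini,
        chip_library=reads_mod.LibraryConfig(**lib),
        input_library=reads_mod.LibraryConfig(**lib),
        fold_by_label=fold,
        background_interval=(chroms[-1].name, 50_000, 150_000),
        seed=seed,
    )


@dataclass
class RunReport:
    config_seed: int
    genome_lengths: dict[str, int]
    n_truth_features: int
    chip_qc: dict
    input_qc: dict
    chip_mapping: dict
    input_mapping: dict
    background: float
    n_masked_windows: int
    n_windows: int
    peaks: list[dict]
    contig_summaries: list[dict]
    annotations: list[dict]

    def to_json(self, path=None) -> str:
        blob = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(blob + "\n")
        return blob


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field checks; returns a list of error strings (empty if ok)."""
    errors: list[str] = []
    if config.seed < 0:
        errors.append("seed: must be non-negative")
    lengths = {c.name: c.length for c in config.chromosomes}
    if config.minichromosome is not None:
        lengths[config.minichromosome.name] = config.minichromosome.total_length
    chrom, start, end = config.background_interval
    if chrom not in lengths:
        errors.append(f"background_interval: chromosome {chrom} not in the genome")
    elif not (0 <= start < end <= lengths[chrom]):
        errors.append("background_interval: interval outside the chromosome")
    for label, lib in (("chip_library", config.chip_library),
                       ("input_library", config.input_library)):
        if lib.read_length != config.chip_library.read_length:
            errors.append("chip and input libraries must share a read length")
        if lib.fragment_length_mean < lib.read_length:
            errors.append(f"{label}.fragment_length_mean: shorter than the read length")
    if config.window_size < 1:
        errors.append("window_size: must be >= 1")
    if config.fold_threshold <= 0:
        errors.append("fold_threshold: must be positive")
    for label, fold in config.fold_by_label.items():
        if fold < 0:
            errors.append(f"fold_by_label[{label}]: must be >= 0")
    return errors


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Run all stages; write stage outputs under ``outdir`` when given."""
    errs = validate_config(config)
    if errs:
        raise ValueError("invalid config:\n  " + "\n  ".join(errs))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done", name)
        return result

    seed = config.seed
    build = _stage("genome", lambda: genome_mod.build_genome(
        config.chromosomes, config.minichromosome,
        rng_seed=int(stage_rng(seed, "genome").integers(2**31)),
    ))
    if out is not None:
        build.write(out / "genome.fasta", out / "truth.bed")

    profile_chip = reads_mod.OccupancyProfile.from_truth(build.truth, config.fold_by_label)
    profile_input = reads_mod.OccupancyProfile.uniform()

    libs = {}
    for name, profile, lib_conf in (
        ("chip", profile_chip, config.chip_library),
        ("input", profile_input, config.input_library),
    ):
        raw = _stage(f"simulate_{name}", lambda p=profile, c=lib_conf, n=name:
                     reads_mod.simulate_library(build, p, c, stage_rng(seed, f"simulate_{n}")))
        clean, qc = _stage(f"qc_{name}", lambda r=raw, c=lib_conf:
                           reads_mod.qc_filter(r, adapter=c.adapter))
        if out is not None:
            clean.to_fastq(out / f"{name}.clean.fastq")
            reads_mod.write_qc_report(qc, out / f"{name}.qc.tsv")
        libs[name] = (raw, clean, qc)

    index = _stage("index", lambda: mapping.GenomeIndex(
        build, config.chip_library.read_length, config.mapping))
    alns, stats = {}, {}
    for name in ("chip", "input"):
        clean = libs[name][1]
        a, s = _stage(f"map_{name}", lambda r=clean, n=name:
                      mapping.map_library(r, index, stage_rng(seed, f"map_{n}")))
        assert s.total == len(clean), "stage count conservation violated"
        alns[name], stats[name] = a, s
        if out is not None:
            a.to_sam(out / f"{name}.sam", build, clean)

    model = enrichment.EnrichmentModel(
        alns["chip"], alns["input"], build,
        window_size=config.window_size, min_input_reads=config.min_input_reads,
    )
    results = _stage("enrichment", lambda: model.fit(
        background_interval=config.background_interval,
        fold_threshold=config.fold_threshold, merge_gap=config.merge_gap,
        truth=build.truth,
    ))
    if out is not None:
        enrichment.write_window_table(results.window_table, out / "windows.tsv")
        enrichment.write_peaks_bed(results.peaks, out / "peaks.bed")

    annotations = _stage("diagnose", lambda: ambiguity.annotate_false_positive_peaks(
        results.peaks, build.truth, build))
    if out is not None:
        ambiguity.write_annotations(annotations, out / "peak_annotations.tsv")

    contig_summaries = []
    if config.minichromosome is not None:
        try:
            cs = results.contig_summary(config.minichromosome.name)
            contig_summaries.append(dataclasses.asdict(cs))
        except ValueError:
            pass

    table = results.window_table
    report = RunReport(
        config_seed=seed,
        genome_lengths=build.lengths,
        n_truth_features=len(build.truth.features),
        chip_qc=libs["chip"][2].to_dict(),
        input_qc=libs["input"][2].to_dict(),
        chip_mapping=stats["chip"].to_dict(),
        input_mapping=stats["input"].to_dict(),
        background=results.background.mean_ratio,
        n_masked_windows=int(table["masked"].sum()),
        n_windows=len(table),
        peaks=[dataclasses.asdict(p) for p in results.peaks],
        contig_summaries=contig_summaries,
        annotations=[
            {
                "chrom": a.peak.chrom, "start": a.peak.start, "end": a.peak.end,
                "verdict": a.verdict, "identity": a.identity,
            }
            for a in annotations
        ],
    )
    if out is not None:
        report.to_json(out / "report.json")
    return report
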