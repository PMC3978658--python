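"""Window-level ChIP/input enrichment: the core statistic of the package.

For nonoverlapping genomic windows (150 bp by default) the enrichment
ratio is

    ratio_w = (chip_count_w / chip_total) / (input_count_w / input_total)

i.e. per-window library proportions, which normalises for sequencing depth.
A read contributes to every window its interval overlaps by at least one
base. Windows with fewer than 10 raw input reads are masked (no ratio) to
suppress noise from unreliable denominators. The background level is the
mean unmasked ratio over a designated non-centromeric reference interval,
and peaks are merged runs of windows at or above a fold threshold times
that background; the top peak per chromosome is the centromere call.

The user-facing surface follows the statsmodels convention: build an
:class:`EnrichmentModel` from two alignment sets, call :meth:`fit`, and
read estimates off the returned :class:`EnrichmentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CENTROMERE, GenomeBuild, GenomeTruth
from .mapping import AlignmentSet

DEFAULT_WINDOW_SIZE = 150
MIN_INPUT_READS = 10


@dataclass(frozen=True)
class BackgroundEstimate:
    chrom: str
    start: int
    end: int
    mean_ratio: float
    n_windows: int

    def __float__(self) -> float:
        return self.mean_ratio


@dataclass
class PeakCall:
    chrom: str
    start: int
    end: int
    max_ratio: float
    mean_ratio: float
    n_windows: int
    is_top_per_chromosome: bool = False
    overlaps_truth_centromere: bool | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ContigSummary:
    contig: str
    mean_ratio: float
    background: float
    fraction_above_background: float
    n_windows: int


def window_grid(genome: GenomeBuild, window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """The window partition: consecutive nonoverlapping windows covering
    each chromosome exactly once; the final window may be partial."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    frames = []
    for name, length in genome.lengths.items():
        n_win = -(-length // window_size)
        starts = np.arange(n_win, dtype=np.int64) * window_size
        ends = np.minimum(starts + window_size, length)
        frames.append(pd.DataFrame({
            "chrom": name, "window": np.arange(n_win), "start": starts, "end": ends,
        }))
    return pd.concat(frames, ignore_index=True)


def count_windows(
    alignments: AlignmentSet,
    genome: GenomeBuild,
    window_size: int = DEFAULT_WINDOW_SIZE,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Per-window read counts for one library.

    ``mode='overlap'`` (default): a read increments every window its
    [start, start+read_length) interval overlaps by >= 1 bp, so a read
    spanning a window boundary counts in both windows. ``mode='start'``
    assigns each read to the window containing its leftmost base only.
    """
    if mode not in ("overlap", "start"):
        raise ValueError("mode must be 'overlap' or 'start'")
    grid = window_grid(genome, window_size)
    counts = np.zeros(len(grid), dtype=np.int64)
    # first row index of each chromosome block in the grid
    first_row = grid.groupby("chrom", sort=False)["window"].apply(lambda s: s.index[0]).to_dict()
    n_win_by_chrom = grid.groupby("chrom", sort=False)["window"].size().to_dict()
    R = alignments.read_length
    for ci, name in enumerate(alignments.chrom_names):
        if name not in first_row:
            raise ValueError(f"alignment chromosome {name} absent from genome")
        starts = alignments.start[alignments.chrom_idx == ci]
        if len(starts) == 0:
            continue
        L = len(genome.sequences[name])
        if (starts < 0).any() or (starts + R > L).any():
            raise ValueError(f"alignment beyond bounds of {name}")
        base = first_row[name]
        n_win = n_win_by_chrom[name]
        w_first = starts // window_size
        counts[base:base + n_win] += np.bincount(w_first, minlength=n_win)
        if mode == "overlap":
            w_last = (starts + R - 1) // window_size
            # intermediate windows (reads longer than a window) plus the last
            span = w_last - w_first
            for d in range(1, int(span.max()) + 1 if len(span) else 0):
                extra = w_first[span >= d] + d
                counts[base:base + n_win] += np.bincount(extra, minlength=n_win)
    out = grid.copy()
    out["count"] = counts
    return out


def compute_ratios(
    chip_table: pd.DataFrame,
    input_table: pd.DataFrame,
    chip_total: int,
    input_total: int,
    min_input_reads: int = MIN_INPUT_READS,
) -> pd.DataFrame:
    """Combine per-library window counts into the normalised ratio table.

    Rows with ``input_count < min_input_reads`` are masked and carry NaN
    ratios. Totals are the mapped-read totals of each library.
    """
    key = ["chrom", "window", "start", "end"]
    if not chip_table[key].equals(input_table[key]):
        raise ValueError("chip and input tables are on different window grids")
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    table = chip_table[key].copy()
    table["chip_count"] = chip_table["count"].to_numpy()
    table["input_count"] = input_table["count"].to_numpy()
    table["masked"] = table["input_count"] < min_input_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (table["chip_count"] / chip_total) / (table["input_count"] / input_total)
    table["ratio"] = np.where(table["masked"], np.nan, ratio)
    return table


def estimate_background(
    table: pd.DataFrame, reference_interval: tuple[str, int, int]
) -> BackgroundEstimate:
    """Mean unmasked ratio over windows overlapping the reference interval."""
    chrom, start, end = reference_interval
    sel = table[
        (table["chrom"] == chrom) & (table["start"] < end) & (table["end"] > start)
        & ~table["masked"]
    ]
    if len(sel) == 0:
        raise ValueError(
            f"no unmasked windows in {chrom}:{start}-{end}; choose a better-covered interval"
        )
    return BackgroundEstimate(chrom, start, end, float(sel["ratio"].mean()), len(sel))


def call_peaks(
    table: pd.DataFrame,
    background: float | BackgroundEstimate,
    fold_threshold: float = 3.0,
    merge_gap: int = 1,
    truth: GenomeTruth | None = None,
) -> list[PeakCall]:
    """Merged runs of unmasked windows with ratio >= fold_threshold x
    background; runs separated by <= merge_gap windows are joined. The
    call with the largest mean ratio on each chromosome is flagged top."""
    bg = float(background)
    if bg <= 0:
        raise ValueError("background must be positive")
    threshold = fold_threshold * bg
    peaks: list[PeakCall] = []
    for chrom, sub in table.groupby("chrom", sort=False):
        qual = sub[~sub["masked"] & (sub["ratio"] >= threshold)]
        if len(qual) == 0:
            continue
        wins = qual["window"].to_numpy()
        breaks = np.nonzero(np.diff(wins) > merge_gap + 1)[0]
        segments = np.split(np.arange(len(wins)), breaks + 1)
        chrom_peaks = []
        for seg in segments:
            rows = qual.iloc[seg]
            chrom_peaks.append(PeakCall(
                chrom=chrom,
                start=int(rows["start"].iloc[0]),
                end=int(rows["end"].iloc[-1]),
                max_ratio=float(rows["ratio"].max()),
                mean_ratio=float(rows["ratio"].mean()),
                n_windows=len(rows),
            ))
        top = max(chrom_peaks, key=lambda p: p.mean_ratio)
        top.is_top_per_chromosome = True
        peaks.extend(chrom_peaks)
    if truth is not None:
        cens = truth.by_label(CENTROMERE)
        for p in peaks:
            p.overlaps_truth_centromere = any(
                f.overlaps(p.chrom, p.start, p.end) for f in cens
            )
    return peaks


def contig_enrichment(
    table: pd.DataFrame, contig_name: str, background: float | BackgroundEstimate
) -> ContigSummary:
    """Aggregate enrichment over one contig (e.g. the minichromosome)."""
    if contig_name not in set(table["chrom"]):
        raise ValueError(f"contig {contig_name} not in the window table")
    bg = float(background)
    sub = table[(table["chrom"] == contig_name) & ~table["masked"]]
    if len(sub) == 0:
        raise ValueError(f"no unmasked windows on {contig_name}")
    ratios = sub["ratio"].to_numpy()
    return ContigSummary(
        contig=contig_name,
        mean_ratio=float(ratios.mean()),
        background=bg,
        fraction_above_background=float((ratios > bg).mean()),
        n_windows=len(sub),
    )


def write_window_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_peaks_bed(peaks: list[PeakCall], path) -> None:
    """BED6+: score column holds the mean ratio; extra columns flag the
    per-chromosome top call and truth overlap when known."""
    with open(path, "w") as fh:
        for p in peaks:
            truth_col = "." if p.overlaps_truth_centromere is None else str(
                int(p.overlaps_truth_centromere))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.mean_ratio:.4f}\t.\t"
                f"{int(p.is_top_per_chromosome)}\t{truth_col}\n"
            )


class EnrichmentModel:
    """ChIP vs input enrichment over a fixed window grid.

    Parameters
    ----------
    chip, input_ : AlignmentSet
        Mapped ChIP and input libraries (same genome).
    genome : GenomeBuild
        The reference the libraries were mapped to.
    window_size : int
        Nonoverlapping window width in bp.
    min_input_reads : int
        Mask threshold on raw input counts.
    count_mode : str
        'overlap' (default) or 'start'; see :func:`count_windows`.
    """

    def __init__(self, chip: AlignmentSet, input_: AlignmentSet, genome: GenomeBuild,
                 window_size: int = DEFAULT_WINDOW_SIZE,
                 min_input_reads: int = MIN_INPUT_READS,
                 count_mode: str = "overlap"):
        self.chip = chip
        self.input_ = input_
        self.genome = genome
        self.window_size = window_size
        self.min_input_reads = min_input_reads
        self.count_mode = count_mode

    @classmethod
    def from_sam(cls, chip_sam, input_sam, genome: GenomeBuild, **kwargs) -> "EnrichmentModel":
        return cls(AlignmentSet.from_sam(chip_sam), AlignmentSet.from_sam(input_sam),
                   genome, **kwargs)

    def fit(self, background_interval: tuple[str, int, int],
            fold_threshold: float = 3.0, merge_gap: int = 1,
            truth: GenomeTruth | None = None) -> "EnrichmentResults":
        chip_counts = count_windows(self.chip, self.genome, self.window_size, self.count_mode)
        input_counts = count_windows(self.input_, self.genome, self.window_size, self.count_mode)
        table = compute_ratios(
            chip_counts, input_counts, len(self.chip), len(self.input_),
            self.min_input_reads,
        )
        background = estimate_background(table, background_interval)
        peaks = call_peaks(table, background, fold_threshold, merge_gap, truth)
        return EnrichmentResults(self, table, background, peaks,
                                 fold_threshold=fold_threshold, merge_gap=merge_gap)


class EnrichmentResults:
    """Fitted window table, background estimate and peak calls."""

    def __init__(self, model: EnrichmentModel, window_table: pd.DataFrame,
                 background: BackgroundEstimate, peaks: list[PeakCall],
                 fold_threshold: float, merge_gap: int):
        self.model = model
        self.window_table = window_table
        self.background = background
        self.peaks = peaks
        self.fold_threshold = fold_threshold
        self.merge_gap = merge_gap

    @property
    def top_peaks(self) -> list[PeakCall]:
        return [p for p in self.peaks if p.is_top_per_chromosome]

    def contig_summary(self, contig_name: str) -> ContigSummary:
        return contig_enrichment(self.window_table, contig_name, self.background)

    def summary(self) -> str:
        t = self.window_table
        unmasked = t[~t["masked"]]
        lines = [
            "ChIP/input window enrichment",
            "=" * 60,
            f"windows: {len(t)} ({t['masked'].sum()} masked, "
            f"input < {self.model.min_input_reads} reads)",
            f"window size: {self.model.window_size} bp; counting: {self.model.count_mode}",
            f"chip reads mapped: {len(self.model.chip)}; "
            f"input reads mapped: {len(self.model.input_)}",
            f"mean unmasked ratio: {unmasked['ratio'].mean():.3f}",
            f"background ({self.background.chrom}:{self.background.start}-"
            f"{self.background.end}, {self.background.n_windows} windows): "
            f"{self.background.mean_ratio:.3f}",
            f"peak threshold: {self.fold_threshold:g} x background = "
            f"{self.fold_threshold * self.background.mean_ratio:.3f}",
            f"peaks: {len(self.peaks)}",
        ]
        for p in self.peaks:
            flags = []
            if p.is_top_per_chromosome:
                flags.append("top")
            if p.overlaps_truth_centromere:
                flags.append("truth-centromere")
            lines.append(
                f"  {p.chrom}:{p.start}-{p.end}  mean {p.mean_ratio:.2f}  "
                f"max {p.max_ratio:.2f}  [{', '.join(flags) or '-'}]"
            )
        return "\n".join(lines)

    def plot_track(self, chrom: str, ax=None):
        """Per-window ratio track for one chromosome (matplotlib)."""
        import matplotlib.pyplot as plt

        sub = self.window_table[self.window_table["chrom"] == chrom]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ax.plot(sub["start"], sub["ratio"], lw=0.5, color="steelblue")
        ax.axhline(self.background.mean_ratio, ls=":", color="grey", label="background")
        ax.axhline(self.fold_threshold * self.background.mean_ratio, ls=":",
                   color="firebrick", label="peak threshold")
        ax.set_xlabel(f"{chrom} position (bp)")
        ax.set_ylabel("ChIP/input ratio")
        ax.legend(loc="upper right", fontsize=8)
        return ax
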