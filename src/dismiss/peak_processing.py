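"""Peak input, strand-split counting, classification and stranded output.

The unit of analysis is a peak region emitted by an upstream caller
(e.g. MACS2).  For each peak the filtered first-mate alignments
overlapping it by ≥1 bp are counted per strand, the Poisson
likelihood-set rule assigns a strand class, and the results are written
as a BED6 track, per-strand BedGraph coverage and a TSV report.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency

from .alignment_io import FirstMateAlignment, filter_reason, _to_first_mate
from .genomic_features import GenomicInterval, Strand
from .strand_model import (
    LikelihoodSetResult,
    StrandClass,
    StrandedPeakCount,
    classify_peak,
)

logger = logging.getLogger(__name__)

AlignmentSource = Union[str, Path, Iterable[FirstMateAlignment]]


@dataclass(frozen=True)
class PeakRegion:
    """A caller-emitted peak; unstranded on input."""

    interval: GenomicInterval
    name: str
    score: Optional[float] = None


@dataclass(frozen=True)
class ClassifiedPeak:
    peak: PeakRegion
    counts: StrandedPeakCount
    result: LikelihoodSetResult


@dataclass
class ClassificationSummary:
    """Classified peaks plus the class tally and single-stranded fraction."""

    peaks: list[ClassifiedPeak]
    n_plus: int
    n_minus: int
    n_both: int
    n_unclassified: int

    @property
    def n_total(self) -> int:
        return len(self.peaks)

    @property
    def single_stranded_fraction(self) -> float:
        """Fraction of classified (non-UNCLASSIFIED) peaks called single-stranded."""
        classified = self.n_plus + self.n_minus + self.n_both
        if classified == 0:
            return float("nan")
        return (self.n_plus + self.n_minus) / classified


# ---------------------------------------------------------------------------
# Peak input
# ---------------------------------------------------------------------------

def read_peaks(peak_file: str | Path) -> list[PeakRegion]:
    """Read BED3+/BED6/narrowPeak peaks (0-based half-open, dialect by column count).

    Names are generated as ``peak_<i>`` when the file has none; the
    narrowPeak signal columns are not retained beyond the BED score.
    Lines with ``start >= end`` raise with their line number.
    """
    peaks: list[PeakRegion] = []
    with open(peak_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected ≥3 BED columns")
            seqname, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"line {lineno}: empty or inverted interval {start}..{end}"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            peaks.append(
                PeakRegion(
                    interval=GenomicInterval(seqname, start, end, Strand.BOTH),
                    name=name if name is not None else f"peak_{len(peaks) + 1}",
                    score=score,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# Strand-split counting
# ---------------------------------------------------------------------------

def _count_from_bam(
    peaks: Sequence[PeakRegion],
    bam_path: str | Path,
    count_mode: str,
    min_mapq: int,
    drop_duplicates: bool,
    proper_pairs_only: bool,
    missing_seqname: str,
) -> list[StrandedPeakCount]:
    out: list[StrandedPeakCount] = []
    with pysam.AlignmentFile(str(bam_path)) as af:
        refs = set(af.references)
        warned: set[str] = set()
        for peak in peaks:
            iv = peak.interval
            if iv.seqname not in refs:
                if missing_seqname == "error":
                    raise ValueError(
                        f"peak seqname {iv.seqname!r} absent from alignment header"
                    )
                if iv.seqname not in warned:
                    warned.add(iv.seqname)
                    warnings.warn(
                        f"seqname {iv.seqname!r} absent from alignment header; "
                        "reporting zero counts"
                    )
                out.append(StrandedPeakCount(peak.name, 0, 0, interval=iv))
                continue
            y_plus = y_minus = 0
            for rec in af.fetch(iv.seqname, iv.start, iv.end):
                if filter_reason(rec, min_mapq, drop_duplicates, proper_pairs_only):
                    continue
                if count_mode == "fiveprime":
                    five = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
                    if not (iv.start <= five < iv.end):
                        continue
                if rec.is_reverse:
                    y_minus += 1
                else:
                    y_plus += 1
            out.append(StrandedPeakCount(peak.name, y_plus, y_minus, interval=iv))
    return out


def _count_from_records(
    peaks: Sequence[PeakRegion],
    records: Iterable[FirstMateAlignment],
    count_mode: str,
) -> list[StrandedPeakCount]:
    # data carries the record index so duplicate spans are not collapsed
    # by the tree's set semantics
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(records):
        if count_mode == "fiveprime":
            five = rec.end - 1 if rec.strand is Strand.MINUS else rec.start
            start, end = five, five + 1
        else:
            start, end = rec.start, rec.end
        trees.setdefault(rec.seqname, IntervalTree()).addi(
            start, end, (i, rec.strand)
        )
    out = []
    for peak in peaks:
        iv = peak.interval
        tree = trees.get(iv.seqname)
        y_plus = y_minus = 0
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                if hit.data[1] is Strand.MINUS:
                    y_minus += 1
                else:
                    y_plus += 1
        out.append(StrandedPeakCount(peak.name, y_plus, y_minus, interval=iv))
    return out


def count_strands(
    peaks: Sequence[PeakRegion],
    alignments: AlignmentSource,
    count_mode: str = "overlap",
    min_mapq: int = 10,
    drop_duplicates: bool = True,
    proper_pairs_only: bool = False,
    missing_seqname: str = "warn",
) -> list[StrandedPeakCount]:
    """Count filtered first-mate reads per peak, split by strand.

    ``alignments`` is either an indexed SAM/BAM path (region queries, with
    the standard filters applied on the fly) or an iterable of
    already-filtered :class:`FirstMateAlignment` records.  In ``overlap``
    mode a read is assigned to every peak its span overlaps by ≥1 bp; in
    ``fiveprime`` mode only when its 5' end lies inside the peak.
    """
    if count_mode not in ("overlap", "fiveprime"):
        raise ValueError(f"unknown count_mode: {count_mode!r}")
    if isinstance(alignments, (str, Path)):
        return _count_from_bam(
            peaks,
            alignments,
            count_mode,
            min_mapq,
            drop_duplicates,
            proper_pairs_only,
            missing_seqname,
        )
    return _count_from_records(peaks, alignments, count_mode)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_all(
    counts: Sequence[StrandedPeakCount],
    alpha: float = 0.1,
    min_depth: int = 0,
    peaks: Optional[Sequence[PeakRegion]] = None,
) -> ClassificationSummary:
    """Classify every peak and tally the classes.

    When ``peaks`` is omitted, minimal :class:`PeakRegion` records are
    reconstructed from the count intervals.
    """
    if peaks is not None and len(peaks) != len(counts):
        raise ValueError("peaks and counts length mismatch")
    classified: list[ClassifiedPeak] = []
    tally = {c: 0 for c in StrandClass}
    for i, c in enumerate(counts):
        result = classify_peak(c, alpha=alpha, min_depth=min_depth)
        peak = (
            peaks[i]
            if peaks is not None
            else PeakRegion(interval=c.interval, name=c.peak_id)
        )
        classified.append(ClassifiedPeak(peak=peak, counts=c, result=result))
        tally[result.strand_class] += 1
    return ClassificationSummary(
        peaks=classified,
        n_plus=tally[StrandClass.PLUS],
        n_minus=tally[StrandClass.MINUS],
        n_both=tally[StrandClass.BOTH],
        n_unclassified=tally[StrandClass.UNCLASSIFIED],
    )


# ---------------------------------------------------------------------------
# Width-bias independence test
# ---------------------------------------------------------------------------

@dataclass
class WidthBiasResult:
    table: pd.DataFrame
    statistic: float
    p_value: float
    dof: int
    boundaries: list[float]
    low_expected_warning: bool = False


def width_bias_test(
    peaks: Sequence[ClassifiedPeak],
    n_groups: int = 3,
    quantile_bounds: Sequence[float] = (0.50, 0.95),
) -> WidthBiasResult:
    """Chi-squared test of independence between peak width and strand class.

    Peaks are split into ``n_groups`` width groups at the given width
    quantiles (defaults: 50/45/5 % of peaks) and cross-tabulated against
    the PLUS/MINUS/BOTH classes.  A warning flag is attached when any
    expected cell falls below 1.
    """
    if len(quantile_bounds) + 1 != n_groups:
        raise ValueError("need n_groups - 1 quantile bounds")
    rows = [
        (p.peak.interval.width, p.result.strand_class.name)
        for p in peaks
        if p.result.strand_class is not StrandClass.UNCLASSIFIED
    ]
    if not rows:
        raise ValueError("no classified peaks to test")
    widths = np.array([r[0] for r in rows], dtype=float)
    if len(np.unique(widths)) < n_groups:
        raise ValueError("fewer distinct widths than groups")
    cuts = np.quantile(widths, quantile_bounds)
    group = np.searchsorted(cuts, widths, side="right")
    classes = pd.Categorical(
        [r[1] for r in rows], categories=["PLUS", "MINUS", "BOTH"]
    )
    table = pd.crosstab(
        pd.Series(group, name="width_group"), pd.Series(classes, name="class")
    )
    # drop all-zero rows/columns so the chi-squared test is well defined
    trimmed = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        return WidthBiasResult(table, 0.0, 1.0, 0, list(cuts))
    stat, p, dof, expected = chi2_contingency(trimmed.to_numpy(), correction=False)
    low = bool((expected < 1).any())
    if low:
        warnings.warn("chi-squared expected cell count below 1")
    return WidthBiasResult(table, float(stat), float(p), int(dof), list(cuts), low)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_STRAND_CHAR = {
    StrandClass.PLUS: "+",
    StrandClass.MINUS: "-",
    StrandClass.BOTH: ".",
    StrandClass.UNCLASSIFIED: ".",
}


def report_table(classified: Sequence[ClassifiedPeak]) -> pd.DataFrame:
    """Per-peak TSV-ready report with counts, θ, class and set bounds."""
    rows = []
    for cp in classified:
        iv = cp.peak.interval
        res = cp.result
        rows.append(
            {
                "peak_id": cp.peak.name,
                "seqname": iv.seqname,
                "start": iv.start,
                "end": iv.end,
                "y_plus": cp.counts.y_plus,
                "y_minus": cp.counts.y_minus,
                "y_total": cp.counts.y_total,
                "theta": cp.counts.theta if cp.counts.theta is not None else np.nan,
                "strand_class": res.strand_class.name,
                "ls_plus_min": min(res.ls_plus) if res.ls_plus else np.nan,
                "ls_plus_max": max(res.ls_plus) if res.ls_plus else np.nan,
                "ls_minus_min": min(res.ls_minus) if res.ls_minus else np.nan,
                "ls_minus_max": max(res.ls_minus) if res.ls_minus else np.nan,
                "low_depth": res.low_depth_flag,
            }
        )
    return pd.DataFrame(rows)


def _coverage_runs(
    records: Sequence[FirstMateAlignment], strand: Strand
) -> dict[str, list[tuple[int, int, int]]]:
    """Per-seqname (start, end, depth) runs of first-mate coverage."""
    events: dict[str, dict[int, int]] = {}
    for rec in records:
        if rec.strand is not strand:
            continue
        ev = events.setdefault(rec.seqname, {})
        ev[rec.start] = ev.get(rec.start, 0) + 1
        ev[rec.end] = ev.get(rec.end, 0) - 1
    runs: dict[str, list[tuple[int, int, int]]] = {}
    for seq, ev in events.items():
        positions = sorted(ev)
        depth = 0
        out = []
        for pos, nxt in zip(positions, positions[1:] + [None]):
            depth += ev[pos]
            if nxt is not None and depth > 0:
                out.append((pos, nxt, depth))
        runs[seq] = out
    return runs


def write_stranded_tracks(
    classified: Sequence[ClassifiedPeak],
    out_prefix: str | Path,
    alignments: Optional[Iterable[FirstMateAlignment] | str | Path] = None,
) -> dict[str, Path]:
    """Write the stranded peak BED6, the TSV report and BedGraph coverage.

    Outputs ``<prefix>.peaks.bed`` (strand column +/−/., score =
    ``y_total``), ``<prefix>.report.tsv`` and — when ``alignments`` is
    given — ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``
    holding per-base first-mate coverage of each strand.
    """
    if not classified:
        raise ValueError("no classified peaks to write")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bed_path = prefix.with_name(prefix.name + ".peaks.bed")
    with open(bed_path, "w") as fh:
        for cp in classified:
            iv = cp.peak.interval
            fh.write(
                f"{iv.seqname}\t{iv.start}\t{iv.end}\t{cp.peak.name}\t"
                f"{cp.counts.y_total}\t{_STRAND_CHAR[cp.result.strand_class]}\n"
            )
    paths["peaks_bed"] = bed_path

    tsv_path = prefix.with_name(prefix.name + ".report.tsv")
    report_table(classified).to_csv(tsv_path, sep="\t", index=False)
    paths["report_tsv"] = tsv_path

    if alignments is not None:
        if isinstance(alignments, (str, Path)):
            from .alignment_io import load_first_mates

            records = list(load_first_mates(alignments))
        else:
            records = list(alignments)
        for strand, label in ((Strand.PLUS, "plus"), (Strand.MINUS, "minus")):
            bg_path = prefix.with_name(f"{prefix.name}.{label}.bedgraph")
            runs = _coverage_runs(records, strand)
            with open(bg_path, "w") as fh:
                for seq in sorted(runs):
                    for start, end, depth in runs[seq]:
                        fh.write(f"{seq}\t{start}\t{end}\t{depth}\n")
            paths[f"{label}_bedgraph"] = bg_path
    return paths
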