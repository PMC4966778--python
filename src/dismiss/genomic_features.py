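"""Strand-aware genomic intervals, overlap counting and feature derivation.

All coordinates are 0-based half-open internally.  GFF3 input (1-based,
closed) is converted at the boundary; BED-style output keeps the internal
convention.  Strand compatibility follows the GenomicRanges convention:
``both`` (written ``.``) is compatible with everything, ``+`` and ``-``
only with themselves or ``both``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from intervaltree import IntervalTree
from scipy.stats import norm


class Strand(str, Enum):
    """Strand of a genomic interval: plus, minus, or both (unstranded)."""

    PLUS = "+"
    MINUS = "-"
    BOTH = "."

    @classmethod
    def from_symbol(cls, symbol: str) -> "Strand":
        try:
            return cls(symbol)
        except ValueError:
            if symbol in ("*",):
                return cls.BOTH
            raise ValueError(f"unrecognised strand symbol: {symbol!r}")

    @property
    def opposite(self) -> "Strand":
        if self is Strand.PLUS:
            return Strand.MINUS
        if self is Strand.MINUS:
            return Strand.PLUS
        return Strand.BOTH


def strands_compatible(a: Strand, b: Strand) -> bool:
    """True when two strands can overlap: ``both`` matches anything."""
    return a is Strand.BOTH or b is Strand.BOTH or a is b


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic location with a strand.

    Parameters
    ----------
    seqname
        Chromosome or scaffold name.
    start, end
        0-based half-open coordinates, ``start < end``.
    strand
        One of :class:`Strand`; defaults to ``both``.
    """

    seqname: str
    start: int
    end: int
    strand: Strand = Strand.BOTH

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", respect_strand: bool = True) -> bool:
        """≥1 bp coordinate overlap on the same seqname, optionally strand-aware."""
        if self.seqname != other.seqname:
            return False
        if respect_strand and not strands_compatible(self.strand, other.strand):
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class FeatureSet:
    """A named collection of genomic intervals (e.g. exons, splice donors)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return len(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# Overlap counting
# ---------------------------------------------------------------------------

def _build_trees(
    intervals: Sequence[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.seqname, IntervalTree()).addi(iv.start, iv.end, iv.strand)
    return trees


def count_overlaps(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    respect_strand: bool = True,
) -> np.ndarray:
    """Count, for each query interval, the subject intervals overlapping it.

    Two intervals overlap when they share a seqname, have ≥1 bp of
    coordinate overlap and (if ``respect_strand``) compatible strands.
    Returns an integer array of length ``len(query)``.
    """
    trees = _build_trees(subject)
    counts = np.zeros(len(query), dtype=np.int64)
    for i, q in enumerate(query):
        tree = trees.get(q.seqname)
        if tree is None:
            continue
        hits = tree.overlap(q.start, q.end)
        if respect_strand:
            counts[i] = sum(1 for h in hits if strands_compatible(q.strand, h.data))
        else:
            counts[i] = len(hits)
    return counts


# ---------------------------------------------------------------------------
# GFF3-derived features
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _open_gff(annotation: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(annotation),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _sequence_lengths(db: gffutils.FeatureDB) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            lengths[parts[1]] = int(parts[3])
    return lengths


def _transcript_introns(
    db: gffutils.FeatureDB, transcript: gffutils.Feature
) -> list[tuple[int, int]]:
    """0-based half-open intron coordinates of one transcript, sorted."""
    exons = sorted(
        db.children(transcript, featuretype="exon"), key=lambda e: e.start
    )
    introns = []
    for left, right in zip(exons, exons[1:]):
        istart, iend = left.end, right.start - 1  # convert to 0-based half-open
        if istart < iend:
            introns.append((istart, iend))
    return introns


def derive_gene_features(
    annotation: str | Path, flank: int = 2000
) -> dict[str, FeatureSet]:
    """Derive gene-anatomy feature sets from a GFF3 annotation.

    Returns a map with keys ``upstream2kb``, ``exon``, ``intron`` and
    ``downstream2kb``.  Up/downstream flanks extend ``flank`` bp from the
    gene's 5'/3' end on the gene's strand (arithmetic reversed for
    minus-strand genes) and are clipped at sequence boundaries when the
    GFF declares ``##sequence-region`` lengths.  Introns are the gaps
    between consecutive exons of each transcript; identical intervals from
    different isoforms are deduplicated.
    """
    db = _open_gff(annotation)
    seq_lengths = _sequence_lengths(db)

    upstream = FeatureSet("upstream2kb")
    downstream = FeatureSet("downstream2kb")
    exon_keys: set[tuple] = set()
    intron_keys: set[tuple] = set()
    exons = FeatureSet("exon")
    introns = FeatureSet("intron")

    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            warnings.warn(
                f"gene {gene.id} has no strand; skipped from feature derivation"
            )
            continue
        strand = Strand.from_symbol(gene.strand)
        gstart, gend = gene.start - 1, gene.end
        seqlen = seq_lengths.get(gene.seqid)
        if strand is Strand.PLUS:
            up = (max(0, gstart - flank), gstart)
            down = (gend, gend + flank if seqlen is None else min(seqlen, gend + flank))
        else:
            up = (gend, gend + flank if seqlen is None else min(seqlen, gend + flank))
            down = (max(0, gstart - flank), gstart)
        if up[0] < up[1]:
            upstream.intervals.append(GenomicInterval(gene.seqid, *up, strand))
        if down[0] < down[1]:
            downstream.intervals.append(GenomicInterval(gene.seqid, *down, strand))

    for ttype in _TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ttype):
            strand = Strand.from_symbol(tx.strand) if tx.strand in ("+", "-") else None
            if strand is None:
                continue
            for exon in db.children(tx, featuretype="exon"):
                key = (exon.seqid, exon.start - 1, exon.end, strand)
                if key not in exon_keys:
                    exon_keys.add(key)
                    exons.intervals.append(GenomicInterval(*key))
            for istart, iend in _transcript_introns(db, tx):
                key = (tx.seqid, istart, iend, strand)
                if key not in intron_keys:
                    intron_keys.add(key)
                    introns.intervals.append(GenomicInterval(*key))

    return {
        "upstream2kb": upstream,
        "exon": exons,
        "intron": introns,
        "downstream2kb": downstream,
    }


def derive_splice_sites(
    annotation: str | Path, half_width: int = 100
) -> tuple[FeatureSet, FeatureSet]:
    """Windows around splice donor and acceptor sites.

    The donor is the exon→intron boundary (the intron's 5' end in
    transcription orientation), the acceptor the intron→exon boundary (the
    intron's 3' end).  For minus-strand transcripts the donor sits at the
    intron's higher genomic coordinate.  Each window spans
    ``±half_width`` bp around the boundary, carries the transcript's
    strand, and junctions shared between isoforms are deduplicated by
    (seqname, position, strand).
    """
    db = _open_gff(annotation)
    donor = FeatureSet("splice_donor")
    acceptor = FeatureSet("splice_acceptor")
    seen: set[tuple] = set()

    def add(fs: FeatureSet, seqid: str, pos: int, strand: Strand, kind: str) -> None:
        key = (kind, seqid, pos, strand)
        if key in seen:
            return
        seen.add(key)
        start = max(0, pos - half_width)
        fs.intervals.append(GenomicInterval(seqid, start, pos + half_width, strand))

    for ttype in _TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ttype):
            if tx.strand not in ("+", "-"):
                continue
            strand = Strand.from_symbol(tx.strand)
            for istart, iend in _transcript_introns(db, tx):
                if strand is Strand.PLUS:
                    add(donor, tx.seqid, istart, strand, "donor")
                    add(acceptor, tx.seqid, iend, strand, "acceptor")
                else:
                    add(donor, tx.seqid, iend, strand, "donor")
                    add(acceptor, tx.seqid, istart, strand, "acceptor")

    return donor, acceptor


# ---------------------------------------------------------------------------
# Splice-site sense/antisense asymmetry
# ---------------------------------------------------------------------------

def two_tailed_proportion_test(
    successes: int, n: int, p: float = 0.5, continuity: bool = True
) -> float:
    """Two-tailed one-sample proportion test (normal approximation).

    Matches R's ``prop.test`` with Yates continuity correction: the test
    statistic is ``z = (|x − np| − c) / sqrt(np(1−p))`` with
    ``c = min(0.5, |x − np|)``.  Returns ``nan`` when ``n == 0``.
    """
    if n == 0:
        return math.nan
    diff = abs(successes - n * p)
    if continuity:
        diff -= min(0.5, diff)
    z = diff / math.sqrt(n * p * (1.0 - p))
    return float(2.0 * norm.sf(z))


@dataclass
class SpliceSideCounts:
    """Sense/antisense tally of single-stranded peaks at one splice-site type."""

    site_type: str
    sense: int
    antisense: int
    p_value: float

    @property
    def n(self) -> int:
        return self.sense + self.antisense

    @property
    def antisense_fraction(self) -> float:
        return self.antisense / self.n if self.n else math.nan


@dataclass
class SpliceAsymmetryResult:
    donor: SpliceSideCounts
    acceptor: SpliceSideCounts


def _single_stranded_intervals(classified_peaks: Iterable) -> list[GenomicInterval]:
    """Extract stranded intervals of PLUS/MINUS peaks.

    Accepts either :class:`GenomicInterval` objects carrying a +/− strand,
    or classified-peak records exposing ``.result.strand_class`` and
    ``.peak.interval`` (duck-typed to avoid a circular dependency on the
    peak-processing layer).
    """
    out: list[GenomicInterval] = []
    for item in classified_peaks:
        if isinstance(item, GenomicInterval):
            if item.strand in (Strand.PLUS, Strand.MINUS):
                out.append(item)
            continue
        cls = item.result.strand_class
        if cls.name not in ("PLUS", "MINUS"):
            continue
        iv = item.peak.interval
        strand = Strand.PLUS if cls.name == "PLUS" else Strand.MINUS
        out.append(GenomicInterval(iv.seqname, iv.start, iv.end, strand))
    return out


def _side_counts(
    windows: FeatureSet,
    plus_peaks: list[GenomicInterval],
    minus_peaks: list[GenomicInterval],
) -> tuple[int, int]:
    w_plus = [w for w in windows if w.strand is Strand.PLUS]
    w_minus = [w for w in windows if w.strand is Strand.MINUS]
    sense = int(
        count_overlaps(w_plus, plus_peaks, respect_strand=False).sum()
        + count_overlaps(w_minus, minus_peaks, respect_strand=False).sum()
    )
    antisense = int(
        count_overlaps(w_plus, minus_peaks, respect_strand=False).sum()
        + count_overlaps(w_minus, plus_peaks, respect_strand=False).sum()
    )
    return sense, antisense


def splice_asymmetry(
    classified_peaks: Iterable,
    donor: FeatureSet,
    acceptor: FeatureSet,
) -> SpliceAsymmetryResult:
    """Test whether single-stranded methylation favours the antisense side.

    Only PLUS/MINUS peaks participate.  For each site type, ``sense``
    counts overlaps between peaks and windows of the same strand,
    ``antisense`` overlaps with the opposite strand; the two-tailed
    proportion test evaluates the null that both sides carry half of the
    single-stranded overlaps.  With zero overlaps the p-value is ``nan``.
    """
    peaks = _single_stranded_intervals(classified_peaks)
    plus_peaks = [p for p in peaks if p.strand is Strand.PLUS]
    minus_peaks = [p for p in peaks if p.strand is Strand.MINUS]

    results = []
    for windows, label in ((donor, "donor"), (acceptor, "acceptor")):
        sense, antisense = _side_counts(windows, plus_peaks, minus_peaks)
        p = two_tailed_proportion_test(sense, sense + antisense)
        results.append(SpliceSideCounts(label, sense, antisense, p))
    return SpliceAsymmetryResult(donor=results[0], acceptor=results[1])
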