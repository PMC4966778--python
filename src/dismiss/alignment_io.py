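"""Reading paired-end alignments and the per-cycle base-frequency QC.

Strand-preserving MeDIP libraries sequence the immuno-captured strand
first: the FIRST mate of each pair carries the strand identity of the
methylated fragment.  A forward first-mate alignment indicates plus-strand
methylation, a reverse-complement alignment minus-strand methylation.
Only primary, mapped, first-in-pair records passing the mapping-quality
and duplicate filters contribute to strand counting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from .genomic_features import Strand

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T", "N")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class FirstMateAlignment:
    """A filtered first-in-pair alignment reduced to its strand signal."""

    seqname: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: Strand
    mapq: int
    duplicate_flag: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("alignment span must be non-empty")


@dataclass
class FilterSummary:
    """Bookkeeping of records read, kept and discarded by reason."""

    read: int = 0
    kept: int = 0
    discarded: dict[str, int] = field(default_factory=dict)

    def discard(self, reason: str) -> None:
        self.discarded[reason] = self.discarded.get(reason, 0) + 1

    @property
    def total_discarded(self) -> int:
        return sum(self.discarded.values())


def filter_reason(
    rec: pysam.AlignedSegment,
    min_mapq: int = 10,
    drop_duplicates: bool = True,
    proper_pairs_only: bool = False,
) -> Optional[str]:
    """Reason a record is excluded from strand counting, or None if kept."""
    if rec.is_unmapped:
        return "unmapped"
    if rec.is_secondary:
        return "secondary"
    if rec.is_supplementary:
        return "supplementary"
    if not rec.is_paired:
        return "unpaired"
    if not rec.is_read1:
        return "second_mate"
    if rec.mapping_quality < min_mapq:
        return "low_mapq"
    if drop_duplicates and rec.is_duplicate:
        return "duplicate"
    if proper_pairs_only and not rec.is_proper_pair:
        return "improper_pair"
    return None


def _to_first_mate(rec: pysam.AlignedSegment) -> FirstMateAlignment:
    return FirstMateAlignment(
        seqname=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand=Strand.MINUS if rec.is_reverse else Strand.PLUS,
        mapq=rec.mapping_quality,
        duplicate_flag=rec.is_duplicate,
    )


def load_first_mates(
    alignment_file: str | Path,
    min_mapq: int = 10,
    drop_duplicates: bool = True,
    proper_pairs_only: bool = False,
    summary: Optional[FilterSummary] = None,
) -> Iterator[FirstMateAlignment]:
    """Stream filtered first-mate alignments from a SAM/BAM file.

    Yields primary, mapped, first-in-pair records with
    ``mapq ≥ min_mapq`` and (when ``drop_duplicates``) an unset duplicate
    flag; strand is taken from the reverse-complement flag.  A
    ``FilterSummary`` passed via ``summary`` is filled in place and the
    tally is logged when the stream is exhausted.  A file containing
    mapped reads but no paired records raises, since single-end data
    carries no first-mate strand signal.
    """
    stats = summary if summary is not None else FilterSummary()
    paired_seen = 0
    with pysam.AlignmentFile(str(alignment_file), check_sq=False) as af:
        for rec in af:
            stats.read += 1
            if rec.is_paired:
                paired_seen += 1
            reason = filter_reason(rec, min_mapq, drop_duplicates, proper_pairs_only)
            if reason is not None:
                stats.discard(reason)
                continue
            stats.kept += 1
            yield _to_first_mate(rec)
    if stats.read > 0 and paired_seen == 0:
        raise ValueError(
            "no paired-end records found: first-in-pair flags are required "
            "to recover the MeDIP-captured strand"
        )
    logger.info(
        "alignments read=%d kept=%d discarded=%s",
        stats.read,
        stats.kept,
        stats.discarded,
    )


# ---------------------------------------------------------------------------
# FASTQ QC: base frequency per cycle
# ---------------------------------------------------------------------------

@dataclass
class BaseFrequencyMatrix:
    """Per-cycle nucleobase counts of a FASTQ file.

    ``counts`` has one row per sequencing cycle and one column per base in
    ``A, C, G, T, N`` order; at every cycle the row sum equals the number
    of reads long enough to reach that cycle.  In a MeDIP-enriched library
    the C and G columns diverge because the captured strand carries the
    methylated cytosines.
    """

    counts: np.ndarray  # shape (n_cycles, 5)
    n_reads: int

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[0]

    def cg_ratio(self) -> np.ndarray:
        """Per-cycle C/G count ratio (nan where G count is zero)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.counts[:, 1] / self.counts[:, 2]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "cycle", np.arange(1, self.n_cycles + 1))
        df["cg_ratio"] = self.cg_ratio()
        return df


def base_frequency_per_cycle(fastq_file: str | Path) -> BaseFrequencyMatrix:
    """Tally each nucleobase at each read position of a FASTQ file.

    Accepts plain or gzip-compressed FASTQ.  Characters outside ACGT are
    counted as N.  Raises with the record index when a record is
    malformed.
    """
    rows: list[np.ndarray] = []
    n_reads = 0
    try:
        with pysam.FastxFile(str(fastq_file)) as fh:
            for n_reads, read in enumerate(fh, start=1):
                seq = read.sequence or ""
                if len(seq) > len(rows):
                    for _ in range(len(seq) - len(rows)):
                        rows.append(np.zeros(5, dtype=np.int64))
                for cycle, base in enumerate(seq.upper()):
                    rows[cycle][_BASE_INDEX.get(base, 4)] += 1
    except OSError as exc:
        raise ValueError(
            f"malformed FASTQ near record {n_reads + 1}: {exc}"
        ) from exc
    counts = np.vstack(rows) if rows else np.zeros((0, 5), dtype=np.int64)
    return BaseFrequencyMatrix(counts=counts, n_reads=n_reads)
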