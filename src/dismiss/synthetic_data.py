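"""Seeded generator of strand-preserving MeDIP-style test data.

Produces a small genome, gene annotation, caller-style peak list,
aligned first-mate reads (BAM) and a per-base stranded 5mC call table,
together with a truth table of each peak's planted strand class.  The
generator emulates the three methylation scenarios a strand-preserving
MeDIP library distinguishes: 5mC on both strands (symmetric), on the
plus strand only, or on the minus strand only.

Key realism choices:

* a peak whose methylation sits on one strand receives
  ``Poisson(depth_mean)`` first mates on that strand and
  ``Poisson(cross_contamination × depth_mean)`` on the other, modelling
  imperfect antibody selection; a symmetric peak receives
  ``Poisson(depth_mean)`` on each strand;
* single-stranded peaks are hosted at splice junctions of simulated
  genes where possible, antisense to the host gene with probability
  ``antisense_bias``, so strand-aware splice-site analyses have planted
  structure to recover;
* the genome sequence under each peak is enriched for cytosine on the
  methylated strand, so the per-cycle C:G imbalance of the first-mate
  FASTQ is reproduced;
* background reads are scattered uniformly at ``background_rate`` reads
  per kb.

All randomness flows through one ``numpy`` generator seeded from
``config.seed``; the same seed yields byte-identical text outputs and an
identical read set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# plus-strand base probabilities (A, C, G, T) planted under each peak class
_PEAK_COMPOSITION = {
    "plus": (0.20, 0.40, 0.15, 0.25),  # methylated strand is the plus strand: C-rich
    "minus": (0.20, 0.15, 0.40, 0.25),  # plus strand G-rich, minus strand C-rich
    "both": (0.20, 0.30, 0.30, 0.20),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated MeDIP-Seq experiment.

    ``depth_mean`` is the Poisson mean of first-mate reads on each
    methylated strand of a peak; ``cross_contamination`` scales the mean
    on the unmethylated strand of single-stranded peaks (0 gives the
    idealised library).  ``antisense_bias`` is the probability that a
    single-stranded peak lies antisense to its host gene.
    """

    seed: int
    n_sequences: int = 2
    sequence_length: int = 250_000
    n_genes: int = 16
    exons_per_gene: tuple[int, int] = (3, 6)
    n_peaks: int = 200
    class_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    depth_mean: float = 50.0
    cross_contamination: float = 0.02
    background_rate: float = 0.3  # reads per kb, both strands combined
    read_length: int = 50
    antisense_bias: float = 0.5
    peak_width: tuple[int, int] = (250, 350)
    calls_per_peak: int = 8

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if min(self.n_sequences, self.sequence_length, self.n_genes, self.n_peaks) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.antisense_bias <= 1.0:
            raise ValueError("antisense_bias must lie in [0, 1]")
        if self.peak_width[0] < self.read_length + 10:
            raise ValueError("peaks must be wider than the read length")


@dataclass
class SimulationBundle:
    """Paths of the files written by :func:`simulate`."""

    out_dir: Path
    genome_fasta: Path
    annotation_gff: Path
    peaks_bed: Path
    alignments_bam: Path
    reads_fastq: Path
    truth_tsv: Path
    calls_tsv: Path

    @property
    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_tsv, sep="\t")


@dataclass
class _Gene:
    gene_id: str
    seqname: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        ]


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Gene]:
    genes: list[_Gene] = []
    cursors = {i: 3000 for i in range(cfg.n_sequences)}
    for g in range(cfg.n_genes):
        seq_i = g % cfg.n_sequences
        seqname = f"chr{seq_i + 1}"
        k = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(150, 401, size=k)
        intron_lens = rng.integers(800, 2001, size=max(k - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(1500, 4001))
        start = cursors[seq_i] + gap
        exons = []
        pos = start
        for j in range(k):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < k - 1:
                pos += int(intron_lens[j])
        end = exons[-1][1]
        if end > cfg.sequence_length - 3000:
            raise ValueError(
                "genes do not fit in the genome; increase sequence_length"
            )
        cursors[seq_i] = end
        genes.append(_Gene(f"gene{g + 1}", seqname, start, end, strand, exons))
    return genes


def _write_fasta(path: Path, genome: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name, idx in genome.items():
            fh.write(f">{name}\n")
            seq = "".join(_BASES[idx])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gff(path: Path, cfg: SimulationConfig, genes: list[_Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(cfg.n_sequences):
            fh.write(f"##sequence-region chr{i + 1} 1 {cfg.sequence_length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.seqname}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            tx_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.seqname}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tx_id};Parent={g.gene_id}\n"
            )
            for j, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.seqname}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={tx_id}.e{j};Parent={tx_id}\n"
                )


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulationBundle:
    """Generate the full fixture bundle into ``out_dir``.

    Draw order from the single seeded generator: genome bases, gene
    layout, peak classes, peak placement (with junction hosting and
    orientation), per-peak strand depths, read positions, background
    reads, 5mC call positions.  Raises when peaks cannot be placed
    without overlap.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seqnames = [f"chr{i + 1}" for i in range(cfg.n_sequences)]
    genome = {
        name: rng.integers(0, 4, cfg.sequence_length).astype(np.int8)
        for name in seqnames
    }
    genes = _place_genes(cfg, rng)

    # junction pool by host-gene strand: (seqname, gene_id, gene_strand, pos, site)
    pools: dict[str, list[tuple]] = {"+": [], "-": []}
    for g in genes:
        for istart, iend in g.introns:
            donor, acceptor = (istart, iend) if g.strand == "+" else (iend, istart)
            pools[g.strand].append((g.seqname, g.gene_id, g.strand, donor, "donor"))
            pools[g.strand].append(
                (g.seqname, g.gene_id, g.strand, acceptor, "acceptor")
            )

    labels = np.array(["plus", "minus", "both"])
    classes = rng.choice(labels, size=cfg.n_peaks, p=list(cfg.class_fractions))

    used = {name: IntervalTree() for name in seqnames}

    def try_place(seqname: str, start: int, width: int) -> Optional[tuple[int, int]]:
        start = max(0, min(start, cfg.sequence_length - width))
        end = start + width
        if used[seqname].overlap(start, end):
            return None
        used[seqname].addi(start, end)
        return start, end

    truth_rows = []
    reads: list[tuple[str, int, str]] = []  # (seqname, start, strand)
    call_rows = []

    def random_place(width: int) -> tuple[str, int, int]:
        for _ in range(500):
            seqname = seqnames[int(rng.integers(cfg.n_sequences))]
            start = int(rng.integers(0, cfg.sequence_length - width))
            placed = try_place(seqname, start, width)
            if placed is not None:
                return seqname, placed[0], placed[1]
        raise ValueError("could not place peaks without overlap; use a larger genome")

    for i, cls in enumerate(classes):
        peak_id = f"peak_{i + 1}"
        width = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
        host_gene = orientation = None
        seqname = start = end = None
        if cls in ("plus", "minus"):
            peak_strand = "+" if cls == "plus" else "-"
            antisense = rng.random() < cfg.antisense_bias
            wanted = (
                {"+": "-", "-": "+"}[peak_strand] if antisense else peak_strand
            )
            for gene_strand in (wanted, {"+": "-", "-": "+"}[wanted]):
                pool = pools[gene_strand]
                while pool:
                    j = int(rng.integers(len(pool)))
                    seq_j, gid, gstrand, pos, _site = pool.pop(j)
                    jitter = int(rng.integers(-50, 51))
                    placed = try_place(seq_j, pos + jitter - width // 2, width)
                    if placed is not None:
                        seqname, (start, end) = seq_j, placed
                        host_gene = gid
                        orientation = (
                            "antisense" if gstrand != peak_strand else "sense"
                        )
                        break
                if seqname is not None:
                    break
        if seqname is None:
            seqname, start, end = random_place(width)

        # plant strand-specific C enrichment under the peak
        probs = _PEAK_COMPOSITION[cls]
        genome[seqname][start:end] = rng.choice(4, size=end - start, p=probs).astype(
            np.int8
        )

        if cls == "both":
            y_plus = int(rng.poisson(cfg.depth_mean))
            y_minus = int(rng.poisson(cfg.depth_mean))
        elif cls == "plus":
            y_plus = int(rng.poisson(cfg.depth_mean))
            y_minus = int(rng.poisson(cfg.cross_contamination * cfg.depth_mean))
        else:
            y_plus = int(rng.poisson(cfg.cross_contamination * cfg.depth_mean))
            y_minus = int(rng.poisson(cfg.depth_mean))

        hi = end - cfg.read_length
        for strand_sym, n in (("+", y_plus), ("-", y_minus)):
            if n > 0:
                starts = rng.integers(start, hi + 1, size=n)
                reads.extend((seqname, int(s), strand_sym) for s in starts)

        truth_rows.append(
            {
                "peak_id": peak_id,
                "seqname": seqname,
                "start": start,
                "end": end,
                "true_class": cls,
                "y_plus": y_plus,
                "y_minus": y_minus,
                "host_gene": host_gene if host_gene else "NA",
                "orientation": orientation if orientation else "NA",
            }
        )

        # per-base 5mC calls consistent with the planted class; the count
        # varies across peaks so paired per-peak comparisons are non-degenerate
        m = int(min(end - start, max(2, rng.poisson(cfg.calls_per_peak))))
        positions = rng.choice(np.arange(start, end), size=m, replace=False)
        for j, pos in enumerate(sorted(int(p) for p in positions)):
            if cls == "both":
                strand_sym = "+" if rng.random() < 0.5 else "-"
                context = "CG"
            else:
                strand_sym = "+" if cls == "plus" else "-"
                context = "CHH" if rng.random() < 0.8 else "CHG"
            call_rows.append(
                {
                    "seqname": seqname,
                    "position": pos,
                    "strand": strand_sym,
                    "context": context,
                    "supporting_reads": 3 + int(rng.poisson(5)),
                }
            )

    # background reads, uniform over the genome
    total_kb = cfg.n_sequences * cfg.sequence_length / 1000.0
    n_background = int(rng.poisson(cfg.background_rate * total_kb))
    for _ in range(n_background):
        seqname = seqnames[int(rng.integers(cfg.n_sequences))]
        pos = int(rng.integers(0, cfg.sequence_length - cfg.read_length))
        strand_sym = "+" if rng.random() < 0.5 else "-"
        reads.append((seqname, pos, strand_sym))

    # ---------------------------------------------------------------- outputs
    fasta_path = out / "genome.fa"
    _write_fasta(fasta_path, genome)

    gff_path = out / "annotation.gff3"
    _write_gff(gff_path, cfg, genes)

    bed_path = out / "peaks.bed"
    with open(bed_path, "w") as fh:
        for row in truth_rows:
            fh.write(
                f"{row['seqname']}\t{row['start']}\t{row['end']}\t{row['peak_id']}\t0\t.\n"
            )

    truth_path = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    calls_path = out / "calls.tsv"
    pd.DataFrame(
        call_rows,
        columns=["seqname", "position", "strand", "context", "supporting_reads"],
    ).to_csv(calls_path, sep="\t", index=False)

    bam_path = out / "alignments.bam"
    fastq_path = out / "reads.fastq"
    _write_reads(cfg, genome, seqnames, reads, bam_path, fastq_path)

    return SimulationBundle(
        out_dir=out,
        genome_fasta=fasta_path,
        annotation_gff=gff_path,
        peaks_bed=bed_path,
        alignments_bam=bam_path,
        reads_fastq=fastq_path,
        truth_tsv=truth_path,
        calls_tsv=calls_path,
    )


def _write_reads(
    cfg: SimulationConfig,
    genome: dict[str, np.ndarray],
    seqnames: list[str],
    reads: list[tuple[str, int, str]],
    bam_path: Path,
    fastq_path: Path,
) -> None:
    """Emit reads as coordinate-sorted, indexed BAM plus as-sequenced FASTQ.

    Each read is written as a mapped, paired, first-in-pair primary
    alignment; the mate is not emitted (only first mates carry the
    MeDIP strand signal).  The FASTQ holds the sequence as the machine
    would read it: the reference slice for forward reads, its reverse
    complement for reverse reads — i.e. always the captured strand.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": cfg.sequence_length} for n in seqnames],
    }
    tid = {n: i for i, n in enumerate(seqnames)}
    unsorted = bam_path.with_suffix(".unsorted.bam")
    qual = "I" * cfg.read_length
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam, open(
        fastq_path, "w"
    ) as fq:
        for i, (seqname, pos, strand) in enumerate(reads):
            ref_slice = "".join(_BASES[genome[seqname][pos : pos + cfg.read_length]])
            rec = pysam.AlignedSegment()
            rec.query_name = f"r{i + 1:06d}"
            rec.flag = 0x1 | 0x2 | 0x40 | (0x10 if strand == "-" else 0) | (
                0x20 if strand == "+" else 0
            )
            rec.reference_id = tid[seqname]
            rec.reference_start = pos
            rec.mapping_quality = 60
            rec.cigarstring = f"{cfg.read_length}M"
            rec.next_reference_id = tid[seqname]
            rec.next_reference_start = pos
            rec.template_length = 0
            rec.query_sequence = ref_slice
            rec.query_qualities = pysam.qualitystring_to_array(qual)
            bam.write(rec)
            sequenced = (
                ref_slice
                if strand == "+"
                else ref_slice.translate(_COMPLEMENT)[::-1]
            )
            fq.write(f"@r{i + 1:06d}/1\n{sequenced}\n+\n{qual}\n")
    pysam.sort("-o", str(bam_path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam_path))
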