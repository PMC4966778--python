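from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from dismiss import SimulationConfig, simulate

GFF_TEXT = """\
##gff-version 3
##sequence-region chr1 1 20000
chr1\ttest\tgene\t5001\t8000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t5001\t8000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t5001\t5600\t.\t+\t.\tID=geneA.t1.e1;Parent=geneA.t1
chr1\ttest\texon\t7001\t8000\t.\t+\t.\tID=geneA.t1.e2;Parent=geneA.t1
chr1\ttest\tgene\t12001\t16000\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t12001\t16000\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\ttest\texon\t12001\t12800\t.\t-\t.\tID=geneB.t1.e1;Parent=geneB.t1
chr1\ttest\texon\t14001\t16000\t.\t-\t.\tID=geneB.t1.e2;Parent=geneB.t1
chr1\ttest\tmRNA\t12001\t16000\t.\t-\t.\tID=geneB.t2;Parent=geneB
chr1\ttest\texon\t12001\t12800\t.\t-\t.\tID=geneB.t2.e1;Parent=geneB.t2
chr1\ttest\texon\t14001\t16000\t.\t-\t.\tID=geneB.t2.e2;Parent=geneB.t2
"""


@pytest.fixture
def small_gff(tmp_path: Path) -> Path:
    path = tmp_path / "small.gff3"
    path.write_text(GFF_TEXT)
    return path


def make_sam(
    path: Path,
    records: list[dict],
    seqs: dict[str, int] | None = None,
) -> Path:
    """Write a SAM file from record dicts (defaults: mapped first mates)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in (seqs or {"chr1": 100000}).items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, spec in enumerate(records):
            rec = pysam.AlignedSegment()
            rec.query_name = spec.get("name", f"r{i}")
            length = spec.get("length", 50)
            flag = 0x1 | 0x40  # paired, first in pair
            if spec.get("read2"):
                flag = 0x1 | 0x80
            if spec.get("reverse"):
                flag |= 0x10
            if spec.get("duplicate"):
                flag |= 0x400
            if spec.get("secondary"):
                flag |= 0x100
            if spec.get("unpaired"):
                flag &= ~(0x1 | 0x40 | 0x80)
            rec.flag = flag
            rec.reference_id = spec.get("tid", 0)
            rec.reference_start = spec["pos"]
            rec.mapping_quality = spec.get("mapq", 60)
            rec.cigarstring = f"{length}M"
            rec.query_sequence = "A" * length
            rec.query_qualities = pysam.qualitystring_to_array("I" * length)
            rec.next_reference_id = rec.reference_id
            rec.next_reference_start = rec.reference_start
            out.write(rec)
    return path


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A modest simulated dataset shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=7, n_peaks=100, depth_mean=50.0)
    return cfg, simulate(cfg, out)
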