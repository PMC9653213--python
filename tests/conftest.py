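"""Shared fixtures: toy transcripts, hand-built BAMs and randomized BAMs."""
from __future__ import annotations

import random
from pathlib import Path

import numpy as np
import pysam
import pytest

from clipmeta import GenomicInterval, TranscriptModel, derive_features


def make_transcript(
    tid="t1",
    chrom="chr1",
    strand="+",
    exons=((100, 200),),
    cds=(),
    gene_id="g1",
):
    """Build and derive a TranscriptModel from genomic exon tuples."""
    exon_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons)]
    cds_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(cds)]
    if strand == "-":
        exon_ivs, cds_ivs = exon_ivs[::-1], cds_ivs[::-1]
    span = GenomicInterval(chrom, min(s for s, _ in exons), max(e for _, e in exons), strand)
    return derive_features(
        TranscriptModel(tid, gene_id, span, exon_ivs, cds=cds_ivs)
    )


def write_bam(path, reads, chrom="chr1", chrom_len=100_000):
    """Write records to a sorted, indexed BAM; reads are dicts of fields."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
    }
    h = pysam.AlignmentHeader.from_dict(header)
    segs = []
    for i, r in enumerate(reads):
        a = pysam.AlignedSegment(h)
        a.query_name = r.get("name", f"r{i}")
        a.reference_id = 0
        a.reference_start = r["start"]
        a.cigartuples = r["cigar"]
        qlen = sum(ln for op, ln in r["cigar"] if op in (0, 1, 4, 7, 8))
        a.query_sequence = r.get("seq", "A" * qlen)
        a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
        a.mapping_quality = r.get("mapq", 30)
        a.flag = r.get("flag", 0)
        for tag, val in r.get("tags", {}).items():
            a.set_tag(tag, val)
        segs.append(a)
    segs.sort(key=lambda s: s.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for s in segs:
            fh.write(s)
    pysam.index(str(path))
    return path


def random_bam_with_md(path, rng, n_reads=100, chrom="chr1", chrom_len=5000):
    """Random reads with mixed CIGARs and mismatches; MD tags via samtools calmd.

    Returns (bam_path, reference dict). Reads start/end in matches and may
    contain soft clips, insertions, deletions and N gaps.
    """
    ref = "".join(rng.choice(list("ACGT")) for _ in range(chrom_len))
    fa = Path(path).with_suffix(".fa")
    with open(fa, "w") as fh:
        fh.write(f">{chrom}\n{ref}\n")
    pysam.faidx(str(fa))

    reads = []
    for i in range(n_reads):
        start = rng.randrange(50, chrom_len - 400)
        cigar = []
        if rng.random() < 0.2:
            cigar.append((4, rng.randrange(1, 6)))  # leading soft clip
        cigar.append((0, rng.randrange(8, 25)))
        for _ in range(rng.randrange(0, 3)):
            op = rng.choice([1, 2, 3])  # I / D / N
            cigar.append((op, rng.randrange(1, 5) if op != 3 else rng.randrange(10, 40)))
            cigar.append((0, rng.randrange(8, 25)))
        if rng.random() < 0.2:
            cigar.append((4, rng.randrange(1, 6)))
        # read sequence from reference, with random mismatches
        seq, pos = [], start
        for op, ln in cigar:
            if op in (0, 7, 8):
                for _ in range(ln):
                    base = ref[pos]
                    if rng.random() < 0.05:
                        base = rng.choice([b for b in "ACGT" if b != base])
                    seq.append(base)
                    pos += 1
            elif op in (2, 3):
                pos += ln
            else:  # I or S: bases not from the reference
                seq.extend(rng.choice(list("ACGT")) for _ in range(ln))
        reads.append(
            {
                "name": f"rnd{i}",
                "start": start,
                "cigar": cigar,
                "seq": "".join(seq),
                "flag": 16 if rng.random() < 0.5 else 0,
            }
        )
    raw = Path(str(path) + ".raw.bam")
    write_bam(raw, reads, chrom=chrom, chrom_len=chrom_len)
    pysam.calmd("-b", str(raw), str(fa), save_stdout=str(path))
    pysam.index(str(path))
    return Path(path), {chrom: ref}


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240901)
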