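"""Deterministic synthetic fixtures: toy genome, annotation and eCLIP reads.

The generator emulates the background structure of an eCLIP experiment:
each transcript gets an expression level, the size-matched input (SMInput)
library is uniform background coverage proportional to that expression,
and the IP library is a mixture of the same background plus crosslink
reads whose 5' ends sit at planted sites. With enrichment fold ``f`` a
planted-site class contributes crosslink reads at odds ``(f-1):1``
against background, so ``f = 1`` makes IP and SMInput draws from the same
generator and planted signal grows monotonically with ``f``.

Crosslink reads are *truncated* with probability ``truncation_rate`` —
the read starts one base 3' of the crosslink, so the default truncation
extractor (offset -1) recovers the planted site exactly — and otherwise
read through the crosslink, in which case a transition mutation is
injected at the crosslinked base with probability ``mutation_rate``.
All output is byte-deterministic given the seed.
"""
from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .annotation import (
    GenomicInterval,
    TranscriptModel,
    derive_features,
    write_gtf,
)

__all__ = ["FixtureConfig", "FixturePaths", "make_genome_and_annotation", "make_reads", "simulate_fixture"]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic fixture.

    ``planted_sites`` entries are ``(feature_class, offset_nt, fold)``:
    the crosslink site sits ``offset_nt`` (negative = upstream/5') from
    each anchor of that class, with IP enrichment fold >= 1.
    """

    seed: int = 0
    n_transcripts: int = 50
    n_exons: int = 3
    exon_length: tuple[int, int] = (80, 150)
    intron_length: tuple[int, int] = (60, 120)
    intergenic_gap: int = 300
    chrom: str = "chrSim"
    read_length: int = 30
    read_depth: int = 100  # background reads per transcript per library
    planted_sites: tuple[tuple[str, int, float], ...] = (("three_prime_ss", -30, 10.0),)
    truncation_rate: float = 1.0
    mutation_rate: float = 0.1
    branchpoint_offset: int = -25  # nt relative to each 3'ss anchor
    expression_range: tuple[float, float] = (0.5, 2.0)
    paired: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.exon_length, self.intron_length):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must satisfy 0 < min <= max")
        for _, _, fold in self.planted_sites:
            if fold < 1:
                raise ValueError(f"enrichment fold must be >= 1, got {fold}")
        for rate in (self.truncation_rate, self.mutation_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        if self.read_length < 10:
            raise ValueError("read_length must be >= 10")
        if self.exon_length[0] * self.n_exons < self.read_length:
            raise ValueError("transcripts shorter than the read length are infeasible")


@dataclass
class FixturePaths:
    fasta: Path
    gtf: Path
    branchpoint_bed: Path
    models: list[TranscriptModel]
    genome_sizes: dict[str, int]
    bams: dict[str, Path] = field(default_factory=dict)


def make_genome_and_annotation(cfg: FixtureConfig, out_dir: Path) -> FixturePaths:
    """Write a toy genome FASTA (+fai), GTF annotation and branchpoint BED.

    Transcripts are multi-exon, alternate between strands, and are
    genomically disjoint. One branchpoint is planted per intron at a fixed
    offset upstream of its 3' splice site.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    models: list[TranscriptModel] = []
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_transcripts):
        strand = "+" if i % 2 == 0 else "-"
        tid = f"tx{i:04d}"
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, cfg.n_exons)
        intron_lens = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, max(cfg.n_exons - 1, 0)
        )
        exons = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            exons.append(GenomicInterval(cfg.chrom, pos, pos + int(el), strand))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        span = GenomicInterval(cfg.chrom, cursor, pos, strand)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"gene{i:04d}",
            span=span,
            exons=exons if strand == "+" else exons[::-1],
        )
        models.append(derive_features(model))
        cursor = pos + cfg.intergenic_gap

    chrom_len = cursor + cfg.intergenic_gap
    genome_sizes = {cfg.chrom: chrom_len}
    seq = "".join(rng.choice(_BASES, chrom_len))

    fasta = out_dir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")
    pysam.faidx(str(fasta))

    gtf = out_dir / "annotation.gtf"
    write_gtf(models, gtf)

    bed = out_dir / "branchpoints.bed"
    with open(bed, "w") as fh:
        for t in models:
            for ss in t.features("three_prime_ss"):
                anchor_t, _ = t.transcript_extent(ss)
                site_t = anchor_t + cfg.branchpoint_offset
                if not 0 <= site_t < t.span_length:
                    continue
                g = t.to_genomic_coord(site_t)
                fh.write(
                    f"{t.chrom}\t{g}\t{g + 1}\t{t.transcript_id}\t0\t{t.strand}\n"
                )
    return FixturePaths(fasta, gtf, bed, models, genome_sizes)


def _planted_positions(
    cfg: FixtureConfig, t: TranscriptModel
) -> tuple[list[int], list[float]]:
    """Genomic crosslink positions and their mixture weights for one transcript."""
    sites: list[int] = []
    weights: list[float] = []
    for feature_class, offset, fold in cfg.planted_sites:
        anchors = t.features(feature_class)
        valid = []
        for anchor in anchors:
            anchor_t, _ = t.transcript_extent(anchor)
            site_t = anchor_t + offset
            if 0 <= site_t < t.span_length:
                valid.append(t.to_genomic_coord(site_t))
        for g in valid:
            sites.append(g)
            weights.append((fold - 1.0) / max(len(valid), 1))
    return sites, weights


def _md_tag(read_seq: str, ref_seq: str) -> tuple[str, int]:
    """MD tag and NM for an all-match-CIGAR read."""
    md, run, nm = [], 0, 0
    for rb, qb in zip(ref_seq, read_seq):
        if rb == qb:
            run += 1
        else:
            md.append(f"{run}{rb}")
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def make_reads(
    cfg: FixtureConfig,
    fixture: FixturePaths,
    out_dir: Optional[Path] = None,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Generate sorted+indexed IP and SMInput BAMs over the fixture genome.

    SMInput reads are uniform over each transcript span at a depth
    proportional to its expression level; IP reads are the same background
    mixed with crosslink reads at the planted sites. Reads are sense-strand
    and single-end unless ``cfg.paired``, in which case the signal-bearing
    read is written as read 2 with a non-signal mate as read 1.
    """
    out_dir = Path(out_dir) if out_dir is not None else fixture.fasta.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_base = (cfg.seed + 987654321 if seed is None else seed) % 2**31
    with pysam.FastaFile(str(fixture.fasta)) as fa:
        genome = {c: fa.fetch(c) for c in fa.references}

    # expression is a per-transcript property shared by both libraries
    rng_expr = np.random.default_rng(seed_base)
    expression = {
        t.transcript_id: rng_expr.uniform(*cfg.expression_range)
        for t in fixture.models
    }

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(fixture.genome_sizes.items())],
    }
    rl = cfg.read_length
    bams: dict[str, Path] = {}

    for lib_index, library in enumerate(("SMInput", "IP")):
        rng = np.random.default_rng(seed_base + 1 + lib_index)
        reads = []
        for t in fixture.models:
            n_reads = int(round(cfg.read_depth * expression[t.transcript_id]))
            span = t.span
            if span.length <= rl:
                continue
            sites, weights = _planted_positions(cfg, t) if library == "IP" else ([], [])
            total_w = 1.0 + sum(weights)
            for k in range(n_reads):
                mutate_at: Optional[int] = None
                u = rng.uniform(0, total_w)
                site = None
                if sites and u > 1.0:
                    u -= 1.0
                    for g, w in zip(sites, weights):
                        if u <= w:
                            site = g
                            break
                        u -= w
                    if site is None:
                        site = sites[-1]
                if site is None:
                    start = int(rng.integers(span.start, span.end - rl + 1))
                else:
                    truncated = rng.uniform() < cfg.truncation_rate
                    if truncated:
                        # read begins one base 3' of the crosslink
                        start = site + 1 if t.strand == "+" else site - rl
                    else:
                        shift = int(rng.integers(5, 16))
                        start = site - shift if t.strand == "+" else site + shift - rl + 1
                        if rng.uniform() < cfg.mutation_rate:
                            mutate_at = site
                    start = max(0, min(start, fixture.genome_sizes[t.chrom] - rl))
                seq = list(genome[t.chrom][start : start + rl])
                if mutate_at is not None and start <= mutate_at < start + rl:
                    seq[mutate_at - start] = _TRANSITION[seq[mutate_at - start]]
                seq = "".join(seq)
                md, nm = _md_tag(seq, genome[t.chrom][start : start + rl])
                name = f"{library}_{t.transcript_id}_{k}"
                reads.extend(
                    _records(header, name, t, start, seq, md, nm, cfg.paired, genome, rl)
                )
        reads.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
        final = out_dir / f"{library}.bam"
        with pysam.AlignmentFile(str(final), "wb", header=header) as fh:
            for r in reads:
                fh.write(r)
        pysam.index(str(final))
        bams[library] = final
    fixture.bams = bams
    return bams


def _records(header, name, t, start, seq, md, nm, paired, genome, rl):
    """Build the aligned-segment record(s) for one sense-strand fragment."""
    h = pysam.AlignmentHeader.from_dict(header)
    r2 = pysam.AlignedSegment(h)
    r2.query_name = name
    r2.reference_id = 0
    r2.reference_start = start
    r2.cigartuples = [(0, rl)]
    r2.query_sequence = seq
    r2.query_qualities = pysam.qualitystring_to_array("I" * rl)
    r2.mapping_quality = 30
    r2.flag = 16 if t.strand == "-" else 0
    r2.set_tag("MD", md)
    r2.set_tag("NM", nm)
    if not paired:
        return [r2]
    # signal read becomes read 2; mate (read 1) on the opposite strand,
    # shifted within the fragment, carries no planted signal
    chrom_len = len(genome[t.chrom])
    m_start = min(max(0, start + 15), chrom_len - rl)
    r1 = pysam.AlignedSegment(h)
    r1.query_name = name
    r1.reference_id = 0
    r1.reference_start = m_start
    r1.cigartuples = [(0, rl)]
    r1.query_sequence = genome[t.chrom][m_start : m_start + rl]
    r1.query_qualities = pysam.qualitystring_to_array("I" * rl)
    r1.mapping_quality = 30
    r1_md, r1_nm = _md_tag(r1.query_sequence, r1.query_sequence)
    r1.set_tag("MD", r1_md)
    r1.set_tag("NM", r1_nm)
    PAIRED, PROPER, REV, MREV, READ1, READ2 = 0x1, 0x2, 0x10, 0x20, 0x40, 0x80
    r2_rev = t.strand == "-"
    r2.flag = PAIRED | PROPER | READ2 | (REV if r2_rev else 0) | (0 if r2_rev else MREV)
    r1.flag = PAIRED | PROPER | READ1 | (0 if r2_rev else REV) | (MREV if r2_rev else 0)
    for a, b in ((r1, r2), (r2, r1)):
        a.next_reference_id = 0
        a.next_reference_start = b.reference_start
    return [r1, r2]


def simulate_fixture(cfg: FixtureConfig, out_dir: Path) -> FixturePaths:
    """Genome + annotation + branchpoints + IP/SMInput BAMs in one call."""
    fixture = make_genome_and_annotation(cfg, Path(out_dir))
    make_reads(cfg, fixture)
    return fixture
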