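"""Strand-aware transcript feature models parsed from annotation files.

All internal coordinates are 0-based half-open genomic intervals. GTF input
(1-based, inclusive) is converted at the file boundary; BED input is already
0-based half-open. A transcript's *span* is its full pre-mRNA extent (TSS to
TES) and transcript coordinates run 5'->3' along the unspliced span, with
position 0 at the 5' end — intronic positions are therefore addressable,
which is what makes branchpoints and splice sites first-class anchors.

Splice-site point convention: the 5'ss point is the first intronic base (in
transcript orientation) of each intron; the 3'ss point is the first exonic
base of the downstream exon. Both are single-base anchors from which fixed
windows extend.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "CustomFeature",
    "point",
    "parse_gtf",
    "derive_features",
    "write_gtf",
    "load_custom_features",
    "read_whitelist",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def point(chrom: str, pos: int, strand: str) -> GenomicInterval:
    """A single-base feature encoded as a half-open interval of length 1."""
    return GenomicInterval(chrom, pos, pos + 1, strand)


# Feature classes resolvable by name on a TranscriptModel.
POINT_FEATURES = ("five_prime_ss", "three_prime_ss", "tss", "tes")
INTERVAL_FEATURES = ("exons", "introns", "cds", "five_prime_utr", "three_prime_utr")


@dataclass
class TranscriptModel:
    """One transcript's pre-mRNA extent plus derived features.

    ``exons`` and ``cds`` are ordered 5'->3' in transcript orientation
    (for minus-strand transcripts index 0 is the genomically rightmost
    exon). Derived lists follow the same orientation.
    """

    transcript_id: str
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    five_prime_utr: list[GenomicInterval] = field(default_factory=list)
    three_prime_utr: list[GenomicInterval] = field(default_factory=list)
    five_prime_ss: list[GenomicInterval] = field(default_factory=list)
    three_prime_ss: list[GenomicInterval] = field(default_factory=list)
    tss: Optional[GenomicInterval] = None
    tes: Optional[GenomicInterval] = None

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def span_length(self) -> int:
        return self.span.length

    def to_transcript_coord(self, gpos: int) -> int:
        """Genomic base position -> transcript coordinate (0 = span 5' end)."""
        if self.strand == "+":
            return gpos - self.span.start
        return self.span.end - 1 - gpos

    def to_genomic_coord(self, tpos: int) -> int:
        if self.strand == "+":
            return self.span.start + tpos
        return self.span.end - 1 - tpos

    def transcript_extent(self, iv: GenomicInterval) -> tuple[int, int]:
        """(transcript coord of 5'-most base, length) of a genomic interval."""
        if self.strand == "+":
            return iv.start - self.span.start, iv.length
        return self.span.end - iv.end, iv.length

    def features(self, name: str) -> list[GenomicInterval]:
        """Feature instances of a named class, 5'->3' in transcript order."""
        if name in POINT_FEATURES:
            val = getattr(self, name)
            if name in ("tss", "tes"):
                return [val] if val is not None else []
            return list(val)
        if name in INTERVAL_FEATURES:
            return list(getattr(self, name))
        raise KeyError(
            f"unknown feature class {name!r}; known: "
            f"{', '.join(POINT_FEATURES + INTERVAL_FEATURES)}"
        )


@dataclass(frozen=True)
class CustomFeature:
    """A user-supplied feature (e.g. a branchpoint) assigned to a transcript."""

    name: str
    transcript_id: str
    site: GenomicInterval


def _oriented(ivs: Sequence[GenomicInterval], strand: str) -> list[GenomicInterval]:
    ivs = sorted(ivs, key=lambda iv: iv.start)
    return ivs[::-1] if strand == "-" else ivs


def derive_features(t: TranscriptModel) -> TranscriptModel:
    """Populate introns, splice-site points, UTRs, TSS and TES.

    Introns are the complement of the exons within the span. UTRs are the
    exonic pieces outside the CDS hull and are only present when a CDS is
    annotated. Raises ``ValueError`` if a CDS piece falls outside the exon
    union.
    """
    strand = t.strand
    chrom = t.chrom
    exons_g = sorted(t.exons, key=lambda iv: iv.start)

    introns_g = []
    for left, right in zip(exons_g, exons_g[1:]):
        if right.start > left.end:
            introns_g.append(GenomicInterval(chrom, left.end, right.start, strand))

    five_ss, three_ss = [], []
    for intron in _oriented(introns_g, strand):
        if strand == "+":
            five_ss.append(point(chrom, intron.start, strand))
            three_ss.append(point(chrom, intron.end, strand))
        else:
            five_ss.append(point(chrom, intron.end - 1, strand))
            three_ss.append(point(chrom, intron.start - 1, strand))

    if strand == "+":
        tss = point(chrom, t.span.start, strand)
        tes = point(chrom, t.span.end - 1, strand)
    else:
        tss = point(chrom, t.span.end - 1, strand)
        tes = point(chrom, t.span.start, strand)

    futr: list[GenomicInterval] = []
    tutr: list[GenomicInterval] = []
    if t.cds:
        for piece in t.cds:
            if not any(exon.contains(piece) for exon in exons_g):
                raise ValueError(
                    f"CDS {piece.start}-{piece.end} outside exon union for "
                    f"transcript {t.transcript_id}"
                )
        cs = min(p.start for p in t.cds)
        ce = max(p.end for p in t.cds)

        def exon_clip(a: int, b: int) -> list[GenomicInterval]:
            out = []
            for exon in exons_g:
                lo, hi = max(exon.start, a), min(exon.end, b)
                if lo < hi:
                    out.append(GenomicInterval(chrom, lo, hi, strand))
            return out

        if strand == "+":
            futr = exon_clip(t.span.start, cs)
            tutr = exon_clip(ce, t.span.end)
        else:
            futr = _oriented(exon_clip(ce, t.span.end), strand)
            tutr = _oriented(exon_clip(t.span.start, cs), strand)

    return replace(
        t,
        exons=_oriented(exons_g, strand),
        cds=_oriented(t.cds, strand),
        introns=_oriented(introns_g, strand),
        five_prime_utr=futr,
        three_prime_utr=tutr,
        five_prime_ss=five_ss,
        three_prime_ss=three_ss,
        tss=tss,
        tes=tes,
    )


def parse_gtf(
    path: Union[str, Path],
    transcript_whitelist: Optional[Iterable[str]] = None,
    report: Optional[dict] = None,
) -> list[TranscriptModel]:
    """Parse a GTF/GFF annotation into :class:`TranscriptModel` objects.

    Reads ``transcript``, ``exon`` and ``CDS`` records; tolerates both the
    GENCODE GTF attribute dialect (``key "value";``) and GFF3 ``key=value``.
    Malformed records are skipped with a warning and counted; transcripts
    with zero exons are excluded. If ``transcript_whitelist`` is given, only
    those transcript IDs are returned. ``report``, if supplied, receives
    counts of skipped records.
    """
    whitelist = set(transcript_whitelist) if transcript_whitelist is not None else None
    counts = {"malformed": 0, "no_exons": 0, "parsed": 0}
    wanted = {"transcript", "exon", "CDS"}
    acc: dict[str, dict] = {}

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                if feat.featuretype not in wanted:
                    continue
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes.get("gene_id", ["NA"])[0]
            except Exception:
                counts["malformed"] += 1
                logger.warning("skipping malformed annotation record: %s", line[:120])
                continue
            if whitelist is not None and tid not in whitelist:
                continue
            rec = acc.setdefault(
                tid,
                {
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "gene_id": gid,
                    "exons": [],
                    "cds": [],
                    "extent": None,
                },
            )
            start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
            if feat.featuretype == "transcript":
                rec["extent"] = (start0, end0)
            elif feat.featuretype == "exon":
                rec["exons"].append((start0, end0))
            else:
                rec["cds"].append((start0, end0))

    models = []
    for tid in sorted(acc):
        rec = acc[tid]
        if not rec["exons"]:
            counts["no_exons"] += 1
            logger.warning("transcript %s has no exon records; excluded", tid)
            continue
        chrom, strand = rec["chrom"], rec["strand"]
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(rec["exons"])]
        cds = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(rec["cds"])]
        if rec["extent"] is not None:
            span = GenomicInterval(chrom, rec["extent"][0], rec["extent"][1], strand)
        else:
            span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            span=span,
            exons=_oriented(exons, strand),
            cds=_oriented(cds, strand),
        )
        models.append(derive_features(model))
        counts["parsed"] += 1

    if report is not None:
        report.update(counts)
    if counts["malformed"]:
        logger.warning("%d malformed annotation records skipped", counts["malformed"])
    return models


def write_gtf(models: Sequence[TranscriptModel], path: Union[str, Path]) -> None:
    """Write transcript/exon/CDS records back out as GENCODE-dialect GTF."""
    with open(path, "w") as fh:
        for t in sorted(models, key=lambda m: (m.chrom, m.span.start, m.transcript_id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'

            def row(ftype: str, iv: GenomicInterval) -> str:
                return (
                    f"{iv.chrom}\tclipmeta\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )

            fh.write(row("transcript", t.span))
            for exon in sorted(t.exons, key=lambda iv: iv.start):
                fh.write(row("exon", exon))
            for piece in sorted(t.cds, key=lambda iv: iv.start):
                fh.write(row("CDS", piece))


def load_custom_features(
    path: Union[str, Path],
    transcripts: Sequence[TranscriptModel],
    assign_by: str = "overlap",
    feature_name: str = "custom",
    report: Optional[dict] = None,
) -> list[CustomFeature]:
    """Load BED6 features and assign them to transcripts.

    ``assign_by="overlap"`` assigns each feature to every transcript whose
    span overlaps it on the same strand (a feature shared by two transcripts
    yields two records); ``assign_by="name_column"`` uses BED column 4 as a
    transcript ID. Features on chromosomes absent from the annotation are
    skipped with a warning; unassignable features are counted and reported.
    """
    if assign_by not in ("overlap", "name_column"):
        raise ValueError(f"assign_by must be 'overlap' or 'name_column', got {assign_by!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"BED file {path} has {df.shape[1]} columns; need at least 6")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)

    known_chroms = {t.chrom for t in transcripts}
    by_id = {t.transcript_id: t for t in transcripts}
    out: list[CustomFeature] = []
    counts = {"assigned": 0, "unassignable": 0, "skipped_chrom": 0}

    for rec in df.itertuples(index=False):
        if rec.chrom not in known_chroms:
            counts["skipped_chrom"] += 1
            logger.warning("feature on unknown chromosome %s skipped", rec.chrom)
            continue
        site = GenomicInterval(rec.chrom, rec.start, rec.end, rec.strand)
        if assign_by == "name_column":
            t = by_id.get(rec.name)
            hits = [t] if t is not None and t.span.overlaps(site) and t.strand == site.strand else []
        else:
            hits = [
                t
                for t in transcripts
                if t.strand == site.strand and t.span.overlaps(site)
            ]
        if not hits:
            counts["unassignable"] += 1
            continue
        for t in hits:
            out.append(CustomFeature(feature_name, t.transcript_id, site))
            counts["assigned"] += 1

    if counts["unassignable"]:
        logger.warning("%d custom features could not be assigned", counts["unassignable"])
    if report is not None:
        report.update(counts)
    return out


def read_whitelist(path: Union[str, Path]) -> set[str]:
    """Read a transcript whitelist: one ID per line, ``#`` comments allowed."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return ids
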