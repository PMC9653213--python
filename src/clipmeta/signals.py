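"""Per-transcript diagnostic signal extraction from alignments and tracks.

Three diagnostic signals are supported, each yielding one count per
nucleotide of a transcript's pre-mRNA span, oriented 5'->3':

* **coverage** — number of reads whose aligned reference bases include the
  position (deletions within a read count as covered, skipped introns do
  not);
* **truncation** — crosslink-induced truncation (CIT) sites: reverse
  transcription stops adjacent to the crosslinked base, so each read's
  5'-most aligned base, shifted by a configurable offset in read
  orientation, marks one putative crosslink per read;
* **mutation** — crosslink-induced mutations (CIMs): mismatches (from the
  MD tag or a supplied reference), deletions and/or insertions.

Arbitrary pre-computed coverage tracks (BigWig) can be substituted for
alignment-derived signal, which also accommodates non-CLIP assays.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pysam

from .annotation import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTrack",
    "ReadFilterConfig",
    "GenomeTrack",
    "coverage_from_alignments",
    "truncations_from_alignments",
    "mutations_from_alignments",
    "signal_from_track",
    "export_track",
]

# CIGAR operations that consume reference, and the subset that leaves the
# reference base covered by the read (D yes, N no).
_REF_CONSUME = {0, 2, 3, 7, 8}
_REF_COVERED = {0, 2, 7, 8}


@dataclass(frozen=True)
class SignalTrack:
    """Per-nucleotide signal for one transcript, one library, one signal type.

    ``values[0]`` is the transcript's 5' end regardless of genomic strand.
    """

    transcript_id: str
    library: str  # "IP" or "SMInput"
    signal_type: str  # coverage | truncation | mutation | track_value
    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ReadFilterConfig:
    """Alignment filters applied before any signal is counted.

    Defaults are conservative standards: unmapped, secondary, supplementary
    and QC-fail reads are dropped; duplicates only if flagged; MAPQ >= 1.
    ``mate`` selects which mate of a paired library carries the signal
    ("read2" is the eCLIP convention, where read 2's 5' end abuts the
    crosslink); single-end reads always pass the mate test.
    """

    min_mapq: int = 1
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True
    exclude_duplicates: bool = True
    mate: str = "read2"  # read1 | read2 | both

    def __post_init__(self) -> None:
        if self.mate not in ("read1", "read2", "both"):
            raise ValueError(f"mate must be read1|read2|both, got {self.mate!r}")

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if read.is_paired and self.mate != "both":
            if self.mate == "read1" and not read.is_read1:
                return False
            if self.mate == "read2" and not read.is_read2:
                return False
        return True


def _open_bam(bam: Union[str, Path, pysam.AlignmentFile]) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(bam, pysam.AlignmentFile):
        return bam, False
    handle = pysam.AlignmentFile(str(bam))
    if not handle.has_index():
        handle.close()
        raise ValueError(f"alignment file {bam} has no index; run samtools index")
    return handle, True


def _fetch_passing(
    bam: pysam.AlignmentFile,
    t: TranscriptModel,
    filters: ReadFilterConfig,
    pad: int = 0,
) -> Iterable[pysam.AlignedSegment]:
    chrom = t.chrom
    chrom_len = bam.get_reference_length(chrom)
    start = max(0, t.span.start - pad)
    end = min(chrom_len, t.span.end + pad)
    for read in bam.fetch(chrom, start, end):
        if filters.passes(read):
            yield read


def _orient(values: np.ndarray, strand: str) -> np.ndarray:
    return values[::-1].copy() if strand == "-" else values


def coverage_from_alignments(
    bam: Union[str, Path, pysam.AlignmentFile],
    t: TranscriptModel,
    filters: Optional[ReadFilterConfig] = None,
) -> SignalTrack:
    """Per-base read coverage over the transcript span.

    A position is covered by a read if it lies under an aligned (M/=/X) or
    deleted (D) reference segment of that read; N gaps are not covered.
    """
    filters = filters or ReadFilterConfig()
    handle, owned = _open_bam(bam)
    span = t.span
    vals = np.zeros(span.length, dtype=np.int64)
    try:
        if span.chrom not in handle.references:
            logger.warning(
                "chromosome %s absent from alignment header; zero coverage for %s",
                span.chrom,
                t.transcript_id,
            )
        else:
            for read in _fetch_passing(handle, t, filters):
                pos = read.reference_start
                for op, ln in read.cigartuples:
                    if op in _REF_COVERED:
                        a = max(pos, span.start)
                        b = min(pos + ln, span.end)
                        if a < b:
                            vals[a - span.start : b - span.start] += 1
                    if op in _REF_CONSUME:
                        pos += ln
    finally:
        if owned:
            handle.close()
    return SignalTrack(t.transcript_id, "", "coverage", _orient(vals, span.strand))


def truncations_from_alignments(
    bam: Union[str, Path, pysam.AlignmentFile],
    t: TranscriptModel,
    filters: Optional[ReadFilterConfig] = None,
    offset: int = -1,
) -> SignalTrack:
    """Crosslink-induced truncation sites over the transcript span.

    For each passing read the crosslink site is placed ``offset``
    nucleotides from the read's 5'-most aligned base, measured in *read*
    orientation (negative = 5' of the read start; the default -1 puts the
    crosslink on the base immediately preceding the read, matching reverse
    transcription stopping one base short of the crosslink). Sites falling
    outside the span are dropped and counted.
    """
    filters = filters or ReadFilterConfig()
    handle, owned = _open_bam(bam)
    span = t.span
    vals = np.zeros(span.length, dtype=np.int64)
    dropped = 0
    try:
        if span.chrom not in handle.references:
            logger.warning(
                "chromosome %s absent from alignment header; zero truncations for %s",
                span.chrom,
                t.transcript_id,
            )
        else:
            seen: set[tuple] = set()
            for read in _fetch_passing(handle, t, filters, pad=abs(offset) + 1):
                key = (read.query_name, read.flag, read.reference_start)
                if key in seen:  # padding can re-yield boundary reads
                    continue
                seen.add(key)
                if read.is_reverse:
                    site = (read.reference_end - 1) - offset
                else:
                    site = read.reference_start + offset
                i = site - span.start
                if 0 <= i < span.length:
                    vals[i] += 1
                else:
                    dropped += 1
    finally:
        if owned:
            handle.close()
    if dropped:
        logger.info(
            "%d truncation sites outside span of %s dropped", dropped, t.transcript_id
        )
    return SignalTrack(t.transcript_id, "", "truncation", _orient(vals, span.strand))


def mutations_from_alignments(
    bam: Union[str, Path, pysam.AlignmentFile],
    t: TranscriptModel,
    filters: Optional[ReadFilterConfig] = None,
    kinds: Iterable[str] = ("mismatch", "deletion"),
    reference: Optional[Union[str, Path, pysam.FastaFile, Mapping[str, str]]] = None,
) -> SignalTrack:
    """Crosslink-induced mutation events over the transcript span.

    ``kinds`` selects any subset of {mismatch, deletion, insertion}. A
    deletion of k bases increments all k deleted reference positions; an
    insertion increments the reference base immediately 5' of the insertion
    point in read orientation. Mismatch calling needs either MD tags on the
    reads or an explicit ``reference`` (FASTA path/handle or a chrom->seq
    mapping); a read with neither raises an error naming the read.
    """
    filters = filters or ReadFilterConfig()
    kinds = frozenset(kinds)
    bad = kinds - {"mismatch", "deletion", "insertion"}
    if bad:
        raise ValueError(f"unknown mutation kinds: {sorted(bad)}")
    handle, owned = _open_bam(bam)
    ref_handle: Optional[pysam.FastaFile] = None
    ref_owned = False
    if isinstance(reference, (str, Path)):
        ref_handle = pysam.FastaFile(str(reference))
        ref_owned = True
    elif isinstance(reference, pysam.FastaFile):
        ref_handle = reference

    span = t.span
    vals = np.zeros(span.length, dtype=np.int64)

    def inc(gpos: int) -> None:
        i = gpos - span.start
        if 0 <= i < span.length:
            vals[i] += 1

    def ref_base(gpos: int) -> str:
        if ref_handle is not None:
            return ref_handle.fetch(span.chrom, gpos, gpos + 1).upper()
        return reference[span.chrom][gpos].upper()  # type: ignore[index]

    try:
        if span.chrom not in handle.references:
            logger.warning(
                "chromosome %s absent from alignment header; zero mutations for %s",
                span.chrom,
                t.transcript_id,
            )
        elif kinds:
            for read in _fetch_passing(handle, t, filters):
                if "mismatch" in kinds:
                    if reference is not None:
                        qseq = read.query_sequence
                        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                            if qseq[qpos].upper() != ref_base(rpos):
                                inc(rpos)
                    else:
                        try:
                            pairs = read.get_aligned_pairs(with_seq=True)
                        except ValueError as exc:
                            raise ValueError(
                                f"read {read.query_name} lacks an MD tag and no "
                                "reference sequence was provided"
                            ) from exc
                        for qpos, rpos, base in pairs:
                            if (
                                qpos is not None
                                and rpos is not None
                                and base is not None
                                and base.islower()
                            ):
                                inc(rpos)
                if "deletion" in kinds or "insertion" in kinds:
                    pos = read.reference_start
                    for op, ln in read.cigartuples:
                        if op == 2 and "deletion" in kinds:
                            for k in range(ln):
                                inc(pos + k)
                        if op == 1 and "insertion" in kinds:
                            inc(pos if read.is_reverse else pos - 1)
                        if op in _REF_CONSUME:
                            pos += ln
    finally:
        if owned:
            handle.close()
        if ref_owned and ref_handle is not None:
            ref_handle.close()
    return SignalTrack(t.transcript_id, "", "mutation", _orient(vals, span.strand))


class GenomeTrack:
    """In-memory genome-orientation coverage track (pyBigWig-like interface)."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self._arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def chroms(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._arrays.items()}

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._arrays:
            raise KeyError(f"chromosome {chrom} not in track")
        arr = self._arrays[chrom]
        if start < 0 or end > len(arr):
            raise ValueError(
                f"interval {chrom}:{start}-{end} beyond track bounds (len {len(arr)})"
            )
        return arr[start:end]


def _track_values(track, chrom: str, start: int, end: int) -> np.ndarray:
    """Fetch values from a GenomeTrack, open pyBigWig handle, or file path."""
    if isinstance(track, (str, Path)):
        import pyBigWig

        with pyBigWig.open(str(track)) as bw:
            return _track_values(bw, chrom, start, end)
    sizes = track.chroms()
    if chrom not in sizes:
        raise ValueError(f"chromosome {chrom} absent from coverage track")
    if end > sizes[chrom]:
        raise ValueError(
            f"span {chrom}:{start}-{end} extends beyond track chromosome "
            f"length {sizes[chrom]}"
        )
    vals = np.asarray(track.values(chrom, start, end), dtype=float)
    return np.nan_to_num(vals, nan=0.0)


def signal_from_track(
    t: TranscriptModel,
    plus=None,
    minus=None,
    signal_type: str = "track_value",
) -> SignalTrack:
    """Extract per-transcript values from strand-specific coverage tracks.

    ``plus``/``minus`` may each be a BigWig path, an open pyBigWig handle or
    a :class:`GenomeTrack`. If only one is given it is used for both strands
    (unstranded track). Missing intervals read as 0; the result is oriented
    5'->3'.
    """
    if plus is None and minus is None:
        raise ValueError("at least one of plus/minus tracks is required")
    track = plus if t.strand == "+" else minus
    if track is None:
        track = plus if plus is not None else minus
    vals = _track_values(track, t.chrom, t.span.start, t.span.end)
    return SignalTrack(t.transcript_id, "", signal_type, _orient(vals, t.strand))


def export_track(
    tracks: Sequence[SignalTrack],
    transcripts: Sequence[TranscriptModel],
    genome_sizes: Mapping[str, int],
    out_prefix: Union[str, Path],
    fmt: str = "bigwig",
) -> dict[str, str]:
    """Write per-transcript signals out as genome-orientation strand tracks.

    Values from transcripts overlapping on the same strand are summed (with
    a warning). Returns ``{"+": path, "-": path}``. ``fmt`` is "bigwig" or
    "wig"; on disjoint transcripts ``signal_from_track`` of the exported
    files reproduces the input exactly.
    """
    if fmt not in ("bigwig", "wig"):
        raise ValueError(f"fmt must be 'bigwig' or 'wig', got {fmt!r}")
    by_id = {t.transcript_id: t for t in transcripts}
    arrays = {
        s: {c: np.zeros(n, dtype=float) for c, n in genome_sizes.items()}
        for s in "+-"
    }
    touched = {s: {c: np.zeros(n, dtype=bool) for c, n in genome_sizes.items()} for s in "+-"}
    overlap_warned = False
    for track in tracks:
        t = by_id[track.transcript_id]
        span = t.span
        gvals = _orient(np.asarray(track.values, dtype=float), span.strand)
        sl = slice(span.start, span.end)
        if touched[span.strand][span.chrom][sl].any() and not overlap_warned:
            logger.warning("overlapping transcripts on the same strand: values summed")
            overlap_warned = True
        arrays[span.strand][span.chrom][sl] += gvals
        touched[span.strand][span.chrom][sl] = True

    suffix = "bw" if fmt == "bigwig" else "wig"
    out = {}
    for strand, label in (("+", "plus"), ("-", "minus")):
        path = f"{out_prefix}.{label}.{suffix}"
        if fmt == "bigwig":
            import pyBigWig

            bw = pyBigWig.open(path, "w")
            bw.addHeader(sorted(genome_sizes.items()))
            for chrom in sorted(genome_sizes):
                arr = arrays[strand][chrom]
                if arr.any():
                    bw.addEntries(chrom, 0, values=arr.tolist(), span=1, step=1)
            bw.close()
        else:
            with open(path, "w") as fh:
                for chrom in sorted(genome_sizes):
                    arr = arrays[strand][chrom]
                    if arr.any():
                        fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                        fh.write("\n".join(f"{v:g}" for v in arr) + "\n")
        out[strand] = path
    return out
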