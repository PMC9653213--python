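"""Independent brute-force oracles used to cross-check the extractors.

These deliberately avoid the library code paths: CIGAR strings are expanded
position by position, and mismatches are recovered by walking the MD tag
string by hand rather than via pysam's aligned-pairs machinery.
"""
from __future__ import annotations

import re

import numpy as np

# CIGAR op codes
M, I, D, N, S, EQ, X = 0, 1, 2, 3, 4, 7, 8
REF_CONSUME = {M, D, N, EQ, X}
COVERED = {M, D, EQ, X}


def read_covered_positions(ref_start: int, cigartuples) -> list[int]:
    """All reference positions a read covers (M/=/X/D; N gaps excluded)."""
    out, pos = [], ref_start
    for op, ln in cigartuples:
        for _ in range(ln):
            if op in COVERED:
                out.append(pos)
            if op in REF_CONSUME:
                pos += 1
            if op not in REF_CONSUME and op not in COVERED:
                pass
    return out


def pileup_coverage(reads, span_start: int, span_len: int) -> np.ndarray:
    """Per-base pileup by expanding each read's CIGAR one base at a time."""
    vals = np.zeros(span_len, dtype=np.int64)
    for read in reads:
        for pos in read_covered_positions(read.reference_start, read.cigartuples):
            if span_start <= pos < span_start + span_len:
                vals[pos - span_start] += 1
    return vals


def truncation_counts(reads, span_start: int, span_len: int, offset: int) -> np.ndarray:
    """Crosslink sites from each read's 5'-most aligned base, shifted by
    ``offset`` in read orientation."""
    vals = np.zeros(span_len, dtype=np.int64)
    for read in reads:
        covered = read_covered_positions(read.reference_start, read.cigartuples)
        if read.is_reverse:
            site = max(covered) - offset
        else:
            site = min(covered) + offset
        if span_start <= site < span_start + span_len:
            vals[site - span_start] += 1
    return vals


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def md_mismatch_positions(ref_start: int, cigartuples, md: str) -> list[int]:
    """Reference positions of mismatches, by expanding the MD tag by hand.

    MD walks the aligned+deleted reference bases in order (insertions and
    clips are invisible to it, N gaps are not represented), so we first list
    those reference positions from the CIGAR and then index into them.
    """
    md_space = []  # ref positions in MD order
    pos = ref_start
    for op, ln in cigartuples:
        for _ in range(ln):
            if op in (M, D, EQ, X):
                md_space.append(pos)
            if op in REF_CONSUME:
                pos += 1
    out, cursor = [], 0
    for num, dele, sub in _MD_TOKEN.findall(md):
        if num:
            cursor += int(num)
        elif dele:
            cursor += len(dele) - 1  # deleted bases, no mismatch
        else:
            out.append(md_space[cursor])
            cursor += 1
    return out


def mutation_counts(
    reads,
    span_start: int,
    span_len: int,
    kinds=("mismatch", "deletion"),
) -> np.ndarray:
    vals = np.zeros(span_len, dtype=np.int64)

    def inc(pos):
        if span_start <= pos < span_start + span_len:
            vals[pos - span_start] += 1

    for read in reads:
        if "mismatch" in kinds:
            for pos in md_mismatch_positions(
                read.reference_start, read.cigartuples, read.get_tag("MD")
            ):
                inc(pos)
        pos = read.reference_start
        for op, ln in read.cigartuples:
            if op == D and "deletion" in kinds:
                for k in range(ln):
                    inc(pos + k)
            if op == I and "insertion" in kinds:
                inc(pos if read.is_reverse else pos - 1)
            if op in REF_CONSUME:
                pos += ln
    return vals
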