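"""Background normalization of IP signal against size-matched input.

The IP and SMInput count tracks of one transcript are each converted into a
per-nucleotide density (a probability vector over transcript positions,
after adding a pseudocount), and the per-nucleotide *relative information*

    RI_i = p_i * log2(p_i / q_i)

is the contribution of nucleotide i to the relative entropy (Kullback-
Leibler divergence, in bits) of the IP density p from the SMInput density
q. Positions where the IP places more probability mass than the background
get positive RI; the transcript-wide sum is the KL divergence and is
non-negative by Gibbs' inequality, vanishing only when IP and background
coincide. Because both libraries are reduced to densities per transcript,
expression-level background cancels without any library-size scaling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import SignalTrack

__all__ = [
    "DensityProfile",
    "RIProfile",
    "to_density",
    "relative_information",
    "eligibility_filter",
]


@dataclass(frozen=True)
class DensityProfile:
    """Pseudocounted per-nucleotide probability vector for one transcript."""

    transcript_id: str
    values: np.ndarray
    pseudocount: float
    raw_total: float


@dataclass(frozen=True)
class RIProfile:
    """Signed per-nucleotide relative information (bits) for one transcript.

    ``total`` is the sum of ``values`` — the relative entropy of the IP
    density from the SMInput density.
    """

    transcript_id: str
    values: np.ndarray
    total: float


def to_density(track: SignalTrack, pseudocount: float = 1.0) -> DensityProfile:
    """Counts -> density: (x_i + c) / (sum(x) + c*L) with pseudocount c > 0."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    raw = np.asarray(track.values, dtype=float)
    if raw.size < 1:
        raise ValueError("empty signal track")
    total = float(raw.sum())
    vals = (raw + pseudocount) / (total + pseudocount * raw.size)
    return DensityProfile(track.transcript_id, vals, pseudocount, total)


def relative_information(
    ip: DensityProfile,
    smi: DensityProfile,
    base: float = 2.0,
    clip_negative: bool = False,
) -> RIProfile:
    """Per-nucleotide relative information of IP density vs SMInput density.

    ``base`` sets the logarithm base (2 = bits). ``clip_negative`` floors
    negative contributions at 0 for display parity with heatmaps; by
    default signed values are kept, preserving the decomposition of the KL
    divergence.
    """
    if ip.transcript_id != smi.transcript_id:
        raise ValueError(
            f"transcript mismatch: {ip.transcript_id} vs {smi.transcript_id}"
        )
    if ip.values.shape != smi.values.shape:
        raise ValueError(
            f"length mismatch for transcript {ip.transcript_id}: "
            f"{ip.values.size} vs {smi.values.size}"
        )
    p, q = ip.values, smi.values
    vals = p * (np.log(p) - np.log(q)) / np.log(base)
    if clip_negative:
        vals = np.maximum(vals, 0.0)
    return RIProfile(ip.transcript_id, vals, float(vals.sum()))


def eligibility_filter(
    ip: SignalTrack,
    smi: SignalTrack,
    min_ip_total: float = 1,
    min_smi_total: float = 0,
) -> tuple[bool, str]:
    """Decide whether a transcript enters normalization.

    Returns ``(eligible, reason)``; the reason is empty when eligible. A
    SMInput threshold of 0 permits an empty background (the pseudocount
    then makes q uniform).
    """
    ip_total, smi_total = ip.total, smi.total
    if ip_total < min_ip_total:
        if ip_total == 0:
            return False, "no IP signal"
        return False, f"IP total {ip_total:g} below threshold {min_ip_total:g}"
    if smi_total < min_smi_total:
        if smi_total == 0:
            return False, "no SMInput signal"
        return False, f"SMInput total {smi_total:g} below threshold {min_smi_total:g}"
    return True, ""
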