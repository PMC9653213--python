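"""Fixed-window extraction around feature anchors and metagene aggregation.

Every feature instance (a splice site, a branchpoint, a UTR boundary ...)
contributes one fixed-length row to an RBP map: a window of
``upstream + downstream`` nucleotides in transcript orientation whose
column 0 sits on the anchor base. No length scaling is ever applied, so
near-nucleotide resolution is preserved. Cells that fall outside the
transcript span are masked (NaN) and never enter aggregation denominators.

Anchor conventions: for a point feature the anchor is the point itself;
``five_prime_boundary`` anchors on the feature's 5'-most base;
``three_prime_boundary`` anchors on the first base *after* the feature's
3' end (e.g. the first exonic base downstream of an intron). Relative
position 0 is the anchor base; upstream positions are negative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import (
    POINT_FEATURES,
    CustomFeature,
    GenomicInterval,
    TranscriptModel,
)
from .normalize import RIProfile

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "FeatureInstance",
    "MetageneMatrix",
    "MetageneProfile",
    "collect_features",
    "resolve_anchor",
    "extract_window",
    "build_rbp_map",
    "aggregate",
    "plot_profile",
]

ANCHORS = ("point", "five_prime_boundary", "three_prime_boundary")


@dataclass(frozen=True)
class WindowSpec:
    """A fixed window: ``upstream`` nt before the anchor, ``downstream`` after.

    Columns run from -upstream to downstream-1; the anchor base is column 0.
    """

    feature_class: str
    anchor: str = "point"
    upstream: int = 50
    downstream: int = 50

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"anchor must be one of {ANCHORS}, got {self.anchor!r}")
        if self.upstream < 0 or self.downstream < 0 or self.upstream + self.downstream < 1:
            raise ValueError("need upstream >= 0, downstream >= 0, width >= 1")

    @property
    def width(self) -> int:
        return self.upstream + self.downstream

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream)


class FeatureInstance(NamedTuple):
    transcript: TranscriptModel
    site: GenomicInterval
    label: str


@dataclass
class MetageneMatrix:
    """RBP map: one row per (transcript, feature instance), columns = relative
    positions; masked (out-of-span) cells are NaN."""

    data: pd.DataFrame
    spec: WindowSpec

    @property
    def n_rows(self) -> int:
        return len(self.data)


@dataclass
class MetageneProfile:
    """Per-position aggregate over the unmasked cells of an RBP map."""

    positions: np.ndarray
    central: np.ndarray  # NaN where no unmasked cells
    n_per_position: np.ndarray
    stat: str
    label: str = ""


def collect_features(
    transcripts: Sequence[TranscriptModel],
    feature_class: str,
    custom_features: Optional[Sequence[CustomFeature]] = None,
) -> list[FeatureInstance]:
    """Enumerate feature instances of one class across transcripts.

    Built-in classes are resolved from each :class:`TranscriptModel`;
    anything else is looked up by name among ``custom_features``. Each
    occurrence (every intron, every branchpoint) is its own instance.
    """
    out: list[FeatureInstance] = []
    by_id = {t.transcript_id: t for t in transcripts}
    try:
        builtin = transcripts[0].features(feature_class) if transcripts else []
        is_builtin = True
    except KeyError:
        is_builtin = False
    if is_builtin:
        for t in transcripts:
            for site in t.features(feature_class):
                out.append(FeatureInstance(t, site, _label(t, site)))
    else:
        if custom_features is None:
            raise KeyError(
                f"{feature_class!r} is not a built-in feature class and no "
                "custom features were supplied"
            )
        for cf in custom_features:
            if cf.name != feature_class:
                continue
            t = by_id.get(cf.transcript_id)
            if t is None:
                logger.warning(
                    "custom feature for unknown transcript %s skipped", cf.transcript_id
                )
                continue
            out.append(FeatureInstance(t, cf.site, _label(t, cf.site)))
    return out


def _label(t: TranscriptModel, site: GenomicInterval) -> str:
    return f"{t.transcript_id}:{site.chrom}:{site.start}-{site.end}({site.strand})"


def resolve_anchor(t: TranscriptModel, site: GenomicInterval, anchor: str) -> int:
    """Transcript coordinate of the anchor base for one feature instance."""
    t5, length = t.transcript_extent(site)
    if anchor == "point":
        if length != 1:
            raise ValueError(
                f"anchor 'point' requires a single-base feature, got length {length}"
            )
        return t5
    if anchor == "five_prime_boundary":
        return t5
    return t5 + length  # three_prime_boundary: first base after the feature


def extract_window(
    profile: Union[RIProfile, np.ndarray],
    t: TranscriptModel,
    site: GenomicInterval,
    spec: WindowSpec,
) -> np.ndarray:
    """One RBP-map row: window values around the feature anchor, NaN-masked
    where the window leaves the transcript span."""
    values = profile.values if isinstance(profile, RIProfile) else np.asarray(profile)
    L = t.span_length
    if values.shape[0] != L:
        raise ValueError(
            f"profile length {values.shape[0]} != span length {L} "
            f"for transcript {t.transcript_id}"
        )
    anchor = resolve_anchor(t, site, spec.anchor)
    row = np.full(spec.width, np.nan)
    if not 0 <= anchor < L:
        logger.warning(
            "anchor at transcript position %d outside span of %s; row fully masked",
            anchor,
            t.transcript_id,
        )
        return row
    lo = anchor - spec.upstream
    hi = anchor + spec.downstream
    src_lo, src_hi = max(lo, 0), min(hi, L)
    row[src_lo - lo : src_hi - lo] = values[src_lo:src_hi]
    return row


def build_rbp_map(
    profiles: Mapping[str, RIProfile],
    features: Sequence[FeatureInstance],
    spec: WindowSpec,
) -> MetageneMatrix:
    """Assemble the RBP map for one feature class.

    One row per feature instance, stably sorted by (transcript_id, genomic
    position); instances whose transcript has no profile (e.g. excluded by
    the eligibility filter) are omitted and logged.
    """
    ordered = sorted(
        features, key=lambda f: (f.transcript.transcript_id, f.site.start, f.site.end)
    )
    rows, labels = [], []
    skipped = 0
    for inst in ordered:
        prof = profiles.get(inst.transcript.transcript_id)
        if prof is None:
            skipped += 1
            continue
        rows.append(extract_window(prof, inst.transcript, inst.site, spec))
        labels.append(inst.label)
    if skipped:
        logger.info("%d feature instances skipped (transcript excluded)", skipped)
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, spec.width)),
        index=labels,
        columns=spec.positions,
    )
    return MetageneMatrix(data, spec)


def aggregate(matrix: MetageneMatrix, stat: str = "mean") -> MetageneProfile:
    """Per-position mean or median over unmasked cells of an RBP map."""
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    if matrix.n_rows == 0:
        raise ValueError("cannot aggregate an empty RBP map")
    arr = matrix.data.to_numpy(dtype=float)
    n = np.sum(~np.isnan(arr), axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        if stat == "mean":
            central = np.nanmean(arr, axis=0)
        else:
            central = np.nanmedian(arr, axis=0)
    central = np.where(n > 0, central, np.nan)
    return MetageneProfile(
        positions=matrix.spec.positions.copy(),
        central=central,
        n_per_position=n,
        stat=stat,
        label=matrix.spec.feature_class,
    )


def plot_profile(
    profiles: Sequence[MetageneProfile],
    out: str,
    ylabel: str = "relative information (bits)",
) -> str:
    """Line plot of one or more metagene profiles sharing a position axis."""
    if len(profiles) == 0:
        raise ValueError("no profiles to plot")
    axis = profiles[0].positions
    for p in profiles[1:]:
        if not np.array_equal(p.positions, axis):
            raise ValueError("profiles do not share a common position axis")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for p in profiles:
        ax.plot(p.positions, p.central, label=p.label or p.stat)
    ax.axvline(0, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("relative position (nt)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
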