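"""Columnar TSV archives for per-transcript signal and RI profiles.

The on-disk format is a gzip-compressed TSV with columns
``transcript_id, position, value`` (position in transcript coordinates,
every position written including zeros so lengths round-trip), preceded by
``#key=value`` comment lines carrying the signal type, library and the
parameters used to produce it.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .signals import SignalTrack

__all__ = ["write_archive", "read_archive"]


def write_archive(
    path: Union[str, Path],
    tracks: Iterable[SignalTrack],
    meta: dict | None = None,
) -> None:
    tracks = list(tracks)
    meta = dict(meta or {})
    if tracks:
        meta.setdefault("signal_type", tracks[0].signal_type)
        meta.setdefault("library", tracks[0].library)
    with gzip.open(path, "wt") as fh:
        for key in sorted(meta):
            fh.write(f"#{key}={meta[key]}\n")
        fh.write("transcript_id\tposition\tvalue\n")
        for track in tracks:
            vals = np.asarray(track.values)
            for pos in range(vals.size):
                fh.write(f"{track.transcript_id}\t{pos}\t{vals[pos]:g}\n")


def read_archive(path: Union[str, Path]) -> tuple[dict[str, SignalTrack], dict]:
    """Read an archive back into SignalTracks keyed by transcript ID."""
    meta: dict[str, str] = {}
    with gzip.open(path, "rt") as fh:
        pos = fh.tell()
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].rstrip("\n").partition("=")
            meta[key] = val
    df = pd.read_csv(path, sep="\t", comment="#")
    signal_type = meta.get("signal_type", "track_value")
    library = meta.get("library", "")
    tracks: dict[str, SignalTrack] = {}
    for tid, sub in df.groupby("transcript_id", sort=True):
        sub = sub.sort_values("position")
        length = int(sub["position"].max()) + 1
        vals = np.zeros(length, dtype=float)
        vals[sub["position"].to_numpy()] = sub["value"].to_numpy()
        if signal_type in ("coverage", "truncation", "mutation"):
            vals = vals.astype(np.int64)
        tracks[str(tid)] = SignalTrack(str(tid), library, signal_type, vals)
    return tracks, meta
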