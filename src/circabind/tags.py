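"""Mapped-tag processing: deduplication, depth normalisation, merging and
window quantification.

Tags are 5'-end points carried as a DataFrame with columns
``chrom, pos, strand, library, timepoint`` (0-based positions).  Following
the study design, reads duplicated at the same position and strand within
one sequencing library (one ChIP library at one timepoint) are collapsed to
a single tag; each library is then rescaled to tags per 10^7 mapped tags
and libraries are summed per timepoint.  No shifting or extension happens
here -- fragment geometry belongs to the deconvolution model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TagTrack",
    "deduplicate",
    "normalize_and_merge",
    "quantify_window",
    "read_bed6",
    "write_bed6",
    "write_bedgraph",
]

TAG_COLUMNS = ["chrom", "pos", "strand", "library", "timepoint"]
_DEDUP_KEY = ["library", "timepoint", "chrom", "pos", "strand"]


def deduplicate(tags: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one tag per (library, timepoint, chrom,
    position, strand).

    Tags at the same position on opposite strands, or in different
    libraries/timepoints, are kept.  The result is sorted canonically so it
    does not depend on input order, and the operation is idempotent.
    """
    out = tags.drop_duplicates(subset=_DEDUP_KEY)
    return out.sort_values(_DEDUP_KEY, kind="mergesort").reset_index(drop=True)


class TagTrack:
    """Per-(chrom, strand, timepoint) sparse normalized tag weights.

    Weights are in units of tags per 10^7 mapped tags of the originating
    library, summed across libraries.  ``timepoint=None`` keys hold tracks
    collapsed over timepoints.
    """

    def __init__(self, data, timepoints, library_totals):
        # data: {(chrom, strand, timepoint): (sorted positions, weights)}
        self._data = data
        self.timepoints = list(timepoints)
        self.library_totals = dict(library_totals)

    @property
    def chroms(self):
        return sorted({k[0] for k in self._data})

    def profile(self, chrom, strand, timepoint=None):
        """Sorted (positions, weights) for one strand; ``timepoint=None``
        sums over timepoints."""
        if timepoint is not None or (chrom, strand, None) in self._data:
            pos, w = self._data.get(
                (chrom, strand, timepoint), (np.array([], int), np.array([]))
            )
            return pos, w
        frames = [
            self._data[k]
            for k in self._data
            if k[0] == chrom and k[1] == strand and k[2] is not None
        ]
        if not frames:
            return np.array([], dtype=int), np.array([])
        pos = np.concatenate([f[0] for f in frames])
        w = np.concatenate([f[1] for f in frames])
        order = np.argsort(pos, kind="mergesort")
        pos, w = pos[order], w[order]
        upos, idx = np.unique(pos, return_inverse=True)
        return upos, np.bincount(idx, weights=w)

    def window_sum(self, chrom, lo, hi, timepoint=None, strand=None) -> float:
        """Total weight with position in the closed interval [lo, hi]."""
        strands = ["+", "-"] if strand is None else [strand]
        total = 0.0
        for s in strands:
            pos, w = self.profile(chrom, s, timepoint)
            if pos.size:
                a, b = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "right")
                total += float(w[a:b].sum())
        return total

    def total_weight(self, timepoint=None) -> float:
        if timepoint is not None:
            keys = [k for k in self._data if k[2] == timepoint]
        else:
            keys = [k for k in self._data if k[2] is not None]
            if not keys:  # already collapsed over timepoints
                keys = list(self._data)
        return float(sum(self._data[k][1].sum() for k in keys))

    def collapse_timepoints(self) -> "TagTrack":
        """New track with all timepoints merged (timepoint key ``None``)."""
        data = {}
        for chrom in self.chroms:
            for strand in ("+", "-"):
                pos, w = self.profile(chrom, strand, None)
                if pos.size:
                    data[(chrom, strand, None)] = (pos, w)
        return TagTrack(data, [], self.library_totals)

    def mean_tag_weight(self) -> float:
        """Average normalized weight carried by one tag (for converting
        merged weights back to effective tag counts)."""
        totals = np.array(list(self.library_totals.values()), dtype=float)
        if totals.size == 0:
            raise ValueError("track has no library totals")
        return float(np.mean(1e7 / totals))


def normalize_and_merge(tags: pd.DataFrame) -> TagTrack:
    """Rescale each library to 10^7 mapped tags, then sum libraries per
    timepoint/strand/position.

    A library here is one (library id, timepoint) sequencing unit; each of
    its tags carries weight ``10^7 / (library total)``.  Raises on an empty
    input (missing data).
    """
    if tags.empty:
        raise ValueError("no tags: empty library")
    totals = tags.groupby(["library", "timepoint"], sort=False).size()
    if (totals == 0).any():
        raise ValueError("empty library")
    weights = tags.merge(
        (1e7 / totals).rename("weight").reset_index(), on=["library", "timepoint"]
    )
    data = {}
    grouped = weights.groupby(["chrom", "strand", "timepoint"], sort=True)
    for (chrom, strand, tp), grp in grouped:
        agg = grp.groupby("pos", sort=True)["weight"].sum()
        data[(chrom, strand, tp)] = (
            agg.index.to_numpy(dtype=int),
            agg.to_numpy(dtype=float),
        )
    tps = sorted(tags["timepoint"].unique())
    return TagTrack(data, tps, {k: int(v) for k, v in totals.items()})


def quantify_window(
    track: TagTrack, chrom: str, center: int, halfwidth: int = 250
) -> np.ndarray:
    """Per-timepoint normalized signal in the closed window
    ``[center - halfwidth, center + halfwidth]``, both strands summed.

    The window is implicitly clipped at chromosome bounds (no positions
    exist outside them).  Raises for a chromosome absent from the track.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if chrom not in track.chroms:
        raise KeyError(f"unknown chromosome {chrom!r}")
    lo, hi = center - halfwidth, center + halfwidth
    return np.array(
        [track.window_sum(chrom, lo, hi, timepoint=t) for t in track.timepoints]
    )


def write_bed6(tags: pd.DataFrame, path) -> None:
    """Tags as BED6: chrom, start, start+1, library:timepoint, score 1, strand."""
    out = pd.DataFrame(
        {
            "chrom": tags["chrom"],
            "start": tags["pos"],
            "end": tags["pos"] + 1,
            "name": tags["library"].astype(str) + ":" + tags["timepoint"].astype(str),
            "score": 1,
            "strand": tags["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    """Inverse of :func:`write_bed6`."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    lib_tp = bed["name"].str.rsplit(":", n=1, expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": bed["start"].astype(int),
            "strand": bed["strand"],
            "library": lib_tp[0],
            "timepoint": lib_tp[1].astype(float),
        }
    )


def write_bedgraph(track: TagTrack, timepoint, path) -> None:
    """Single-timepoint strand-merged weights as bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos_p, w_p = track.profile(chrom, "+", timepoint)
            pos_m, w_m = track.profile(chrom, "-", timepoint)
            pos = np.concatenate([pos_p, pos_m])
            w = np.concatenate([w_p, w_m])
            if not pos.size:
                continue
            upos, idx = np.unique(pos, return_inverse=True)
            uw = np.bincount(idx, weights=w)
            for p, v in zip(upos, uw):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6g}\n")
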