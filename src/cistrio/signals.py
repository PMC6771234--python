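"""Binned read-density quantification of sequencing tracks at peak sets.

The density unit throughout is reads per 10 million mapped reads per
100-bp bin (10*rpm/bp): a bin's tag count is scaled by ``1e7 /
total_mapped``, so tracks of different sequencing depth are directly
comparable. Windows are centered on the floor midpoint of each site and
split into half-open bins ``[c - flank + i*w, c - flank + (i+1)*w)``; a tag
exactly on a boundary belongs to the bin whose left edge it sits on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "TagTrack",
    "CoverageTrack",
    "BinnedMatrix",
    "read_tag_bed",
    "binned_density",
    "mean_profile",
    "site_signal",
    "intensity_correlation",
]


class TagTrack:
    """Single-bp tag positions of a sequencing library, per chromosome.

    One position per mapped read (the 5' end, optionally shifted by a fixed
    offset at load time). ``total_mapped`` is the library's total mapped
    read count and is the normalization denominator; it may exceed the
    number of stored tags (reads outside the regions of interest).
    """

    def __init__(
        self,
        label: str,
        tags: Mapping[str, np.ndarray],
        total_mapped: int | None = None,
    ):
        self.label = label
        self._tags: dict[str, np.ndarray] = {}
        n = 0
        for chrom, pos in tags.items():
            arr = np.asarray(pos, dtype=np.int64)
            if len(arr) and arr.min() < 0:
                raise ValueError(f"negative tag position on {chrom}")
            arr = np.sort(arr)
            self._tags[str(chrom)] = arr
            n += len(arr)
        self.n_tags = n
        if total_mapped is None:
            total_mapped = n
        total_mapped = int(total_mapped)
        if total_mapped <= 0:
            raise ValueError("total_mapped must be a positive integer")
        if total_mapped < n:
            raise ValueError(
                f"total_mapped ({total_mapped}) < number of tags ({n})"
            )
        self.total_mapped = total_mapped

    @property
    def scale(self) -> float:
        """Multiplier taking raw tag counts to reads per 10 M mapped."""
        return 1e7 / self.total_mapped

    def tags_for(self, chrom: str) -> np.ndarray:
        return self._tags.get(chrom, np.empty(0, dtype=np.int64))

    def chroms(self) -> list[str]:
        return list(self._tags)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        t = self.tags_for(chrom)
        return int(np.searchsorted(t, end) - np.searchsorted(t, start))


class CoverageTrack:
    """Step-function coverage (bedGraph) standing in for exact tags.

    The value of each step is interpreted as expected tags per bp, so the
    expected tag count in a window is value x overlapped basepairs. Exact
    tag input (:class:`TagTrack`) is preferred when available.
    """

    def __init__(self, label: str, steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]], total_mapped: int):
        self.label = label
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in steps.items():
            order = np.argsort(starts, kind="stable")
            self._steps[str(chrom)] = (
                np.asarray(starts, np.int64)[order],
                np.asarray(ends, np.int64)[order],
                np.asarray(values, float)[order],
            )
        if total_mapped <= 0:
            raise ValueError("total_mapped must be a positive integer")
        self.total_mapped = int(total_mapped)

    @classmethod
    def from_bedgraph(cls, path: str | Path, total_mapped: int, label: str | None = None) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
        steps = {
            str(chrom): (
                sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy()
            )
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        return cls(label or Path(path).stem, steps, total_mapped)

    @property
    def scale(self) -> float:
        return 1e7 / self.total_mapped

    def count_in(self, chrom: str, start: int, end: int) -> float:
        """Expected tag count in [start, end)."""
        if chrom not in self._steps:
            return 0.0
        ss, se, sv = self._steps[chrom]
        lo = np.searchsorted(se, start, side="right")
        hi = np.searchsorted(ss, end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(end, se[lo:hi]) - np.maximum(start, ss[lo:hi])
        return float((np.maximum(ov, 0) * sv[lo:hi]).sum())


def read_tag_bed(
    path: str | Path,
    label: str | None = None,
    total_mapped: int | None = None,
    shift: int = 0,
) -> TagTrack:
    """Load tags from a BED of read positions/intervals.

    Each line contributes one tag at ``start + shift`` (5'-end convention,
    clipped at 0). ``total_mapped`` defaults to the number of lines.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        usecols=[0, 1], names=["chrom", "start"], dtype={0: str, 1: np.int64},
    )
    tags = {
        str(chrom): np.maximum(sub["start"].to_numpy() + shift, 0)
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return TagTrack(label or Path(path).stem, tags, total_mapped)


@dataclass
class BinnedMatrix:
    """Site x bin density matrix in units of reads per 10 M mapped per bin."""

    site_ids: list[str]
    n_bins: int
    bin_width: int
    values: np.ndarray  # shape (n_sites, n_bins), nonnegative
    track_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.site_ids), self.n_bins):
            raise ValueError("values shape inconsistent with site_ids/n_bins")
        if (self.values < 0).any():
            raise ValueError("densities must be nonnegative")

    @property
    def window(self) -> int:
        return self.n_bins * self.bin_width

    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the site center (bp)."""
        return np.arange(self.n_bins) * self.bin_width - self.window // 2

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.site_ids, columns=self.bin_offsets())
        df.to_csv(path, sep="\t", index_label="site")


def _site_ids(sites: PeakSet) -> list[str]:
    df = sites.df
    names = df["name"]
    return [
        str(n) if n is not None and not pd.isna(n) else f"{c}:{s}-{e}"
        for c, s, e, n in zip(df["chrom"], df["start"], df["end"], names)
    ]


def binned_density(
    sites: PeakSet,
    track: TagTrack | CoverageTrack,
    flank: int = 2000,
    bin_width: int = 100,
) -> BinnedMatrix:
    """Normalized read density around each site center.

    Each site is extended ``flank`` bp either side of its floor midpoint
    and the window split into ``2*flank/bin_width`` bins (defaults: 4 kb,
    40 bins of 100 bp). Windows running below position 0 are clipped: the
    out-of-range bins are zero-filled and the clipping is logged.
    """
    if flank <= 0 or bin_width <= 0 or flank % bin_width != 0:
        raise ValueError("flank must be a positive multiple of bin_width")
    n_bins = 2 * flank // bin_width
    n_sites = len(sites)
    values = np.zeros((n_sites, n_bins), dtype=float)
    df = sites.df
    n_clipped = 0
    rel_edges = np.arange(n_bins + 1) * bin_width - flank
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        centers = (
            df["start"].to_numpy()[idx] + df["end"].to_numpy()[idx]
        ) // 2
        edges = centers[:, None] + rel_edges[None, :]
        n_clipped += int((edges[:, 0] < 0).sum())
        if isinstance(track, TagTrack):
            tags = track.tags_for(str(chrom))
            counts = np.diff(np.searchsorted(tags, edges), axis=1).astype(float)
        else:
            counts = np.zeros((len(idx), n_bins))
            for r in range(len(idx)):
                for b in range(n_bins):
                    counts[r, b] = track.count_in(
                        str(chrom), int(edges[r, b]), int(edges[r, b + 1])
                    )
        values[idx] = counts * track.scale
    if n_clipped:
        logger.warning(
            "%d site window(s) extended below position 0; out-of-range bins zero-filled",
            n_clipped,
        )
    return BinnedMatrix(_site_ids(sites), n_bins, bin_width, values, track.label)


def mean_profile(matrix: BinnedMatrix) -> np.ndarray:
    """Column-wise mean density across sites (the aggregate binding profile)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot profile an empty matrix")
    return matrix.values.mean(axis=0)


def site_signal(sites: PeakSet, track: TagTrack | CoverageTrack) -> np.ndarray:
    """Per-site normalized signal summed over the site's own span.

    Same 1e7/total_mapped scaling as :func:`binned_density`; summing the
    bins of a window that exactly tiles a site reproduces this total.
    """
    out = np.zeros(len(sites), dtype=float)
    df = sites.df
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        starts = df["start"].to_numpy()[idx]
        ends = df["end"].to_numpy()[idx]
        if isinstance(track, TagTrack):
            tags = track.tags_for(str(chrom))
            counts = (
                np.searchsorted(tags, ends) - np.searchsorted(tags, starts)
            ).astype(float)
        else:
            counts = np.array(
                [track.count_in(str(chrom), int(s), int(e)) for s, e in zip(starts, ends)]
            )
        out[idx] = counts * track.scale
    return out


def intensity_correlation(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson correlation of paired per-site signal vectors.

    Returns ``{"r": ..., "r_squared": ...}``; used to compare peak
    intensities of one factor across conditions. Raises on fewer than 3
    sites or zero variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 sites to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    r = float(stats.pearsonr(x, y).statistic)
    return {"r": r, "r_squared": r * r}
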