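"""Stitch-and-rank super-enhancer identification and nearest-gene assignment.

Follows the ROSE recipe: enhancer constituents within a stitching distance
(default 12.5 kb) are merged into regions, each region is scored by the
summed normalized signal of an activity mark (H3K27ac) over its
constituents, regions are ranked by signal, rank and signal are both
scaled to [0, 1], and the cutoff is placed where the slope of the
signal-vs-rank curve first exceeds 1. Regions above the cutoff — the
exceptionally signal-rich tail — are super-enhancers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, _merge_arrays
from .signals import TagTrack, CoverageTrack, site_signal

logger = logging.getLogger(__name__)

__all__ = [
    "StitchedRegion",
    "StitchRankResult",
    "GeneAssignment",
    "read_tss",
    "stitch",
    "score_regions",
    "rank_and_cut",
    "assign_nearest_gene",
]


@dataclass
class StitchedRegion:
    """A stitched enhancer region with its constituent peaks and signal."""

    interval: GenomicInterval
    constituent_count: int
    constituents: tuple[GenomicInterval, ...] = ()
    signal: float | None = None

    def __post_init__(self) -> None:
        if self.constituent_count < 1:
            raise ValueError("a stitched region has at least one constituent")
        for c in self.constituents:
            if not (
                c.chrom == self.interval.chrom
                and c.start >= self.interval.start
                and c.end <= self.interval.end
            ):
                raise ValueError("constituent outside stitched region")
        if self.signal is not None and self.signal < 0:
            raise ValueError("region signal must be nonnegative")


@dataclass
class StitchRankResult:
    """Ranked regions with the tangent cutoff separating super-enhancers."""

    regions: list[StitchedRegion]  # sorted ascending by signal
    cutoff_signal: float
    super_flags: np.ndarray  # aligned with regions; True iff signal > cutoff
    n_super: int
    scaled_rank: np.ndarray = field(default_factory=lambda: np.empty(0))
    scaled_signal: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def supers(self) -> list[StitchedRegion]:
        return [r for r, f in zip(self.regions, self.super_flags) if f]

    def rank_curve(self) -> pd.DataFrame:
        """Rank/signal table (scaled and raw) for plotting the hockey stick."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.regions) + 1),
                "scaled_rank": self.scaled_rank,
                "signal": [r.signal for r in self.regions],
                "scaled_signal": self.scaled_signal,
                "is_super": self.super_flags,
            }
        )


@dataclass(frozen=True)
class GeneAssignment:
    region_id: str
    gene: str
    distance: int  # region center to the gene's TSS, bp


def read_tss(path: str | Path) -> pd.DataFrame:
    """Load a TSS table: 4-column TSV (gene, chrom, pos, strand) or BED6.

    For BED6 input the TSS is the start for + strand and end - 1 for
    - strand. Returns a DataFrame with columns gene/chrom/pos/strand.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] >= 6 and df.iloc[:, 1].str.isdigit().all() and df.iloc[:, 2].str.isdigit().all():
        start = df.iloc[:, 1].astype(np.int64)
        end = df.iloc[:, 2].astype(np.int64)
        strand = df.iloc[:, 5]
        pos = np.where(strand == "-", end - 1, start)
        return pd.DataFrame(
            {"gene": df.iloc[:, 3], "chrom": df.iloc[:, 0], "pos": pos, "strand": strand}
        )
    out = df.iloc[:, :4].copy()
    out.columns = ["gene", "chrom", "pos", "strand"]
    out["pos"] = out["pos"].astype(np.int64)
    return out


def stitch(
    sites: PeakSet,
    stitch_gap: int = 12500,
    tss_table: pd.DataFrame | None = None,
    tss_window: int = 2000,
) -> list[StitchedRegion]:
    """Merge enhancer constituents within ``stitch_gap`` bp into regions.

    If a TSS table is given, constituents whose center lies within
    ``tss_window`` bp of any TSS are dropped before stitching (promoter
    exclusion). Idempotent: stitching the stitched spans again is a no-op.
    """
    if stitch_gap < 0:
        raise ValueError("stitch_gap must be >= 0")
    df = sites.df
    if tss_table is not None and len(tss_table):
        keep = np.ones(len(df), dtype=bool)
        tss_by_chrom = {
            str(c): np.sort(sub["pos"].to_numpy(np.int64))
            for c, sub in tss_table.groupby("chrom", sort=False)
        }
        centers = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        for chrom, idx in df.groupby("chrom", sort=False).indices.items():
            pos = tss_by_chrom.get(str(chrom))
            if pos is None or len(pos) == 0:
                continue
            c = centers[idx]
            j = np.searchsorted(pos, c)
            d_right = np.where(j < len(pos), pos[np.minimum(j, len(pos) - 1)] - c, np.iinfo(np.int64).max)
            d_left = np.where(j > 0, c - pos[np.maximum(j - 1, 0)], np.iinfo(np.int64).max)
            near = np.minimum(np.abs(d_right), np.abs(d_left)) <= tss_window
            keep[idx] &= ~near
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("promoter exclusion dropped %d constituent(s)", n_dropped)
        df = df.loc[keep]
    regions: list[StitchedRegion] = []
    work = PeakSet.from_dataframe(sites.label, df) if len(df) != len(sites.df) else sites
    for chrom, (starts, ends) in work.chrom_arrays().items():
        ms, me, gid = _merge_arrays(starts, ends, stitch_gap)
        counts = np.bincount(gid)
        for g in range(len(ms)):
            members = np.flatnonzero(gid == g)
            constituents = tuple(
                GenomicInterval(chrom, int(starts[m]), int(ends[m])) for m in members
            )
            regions.append(
                StitchedRegion(
                    GenomicInterval(chrom, int(ms[g]), int(me[g])),
                    int(counts[g]),
                    constituents,
                )
            )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def score_regions(
    regions: list[StitchedRegion],
    track: TagTrack | CoverageTrack,
    control: TagTrack | CoverageTrack | None = None,
) -> list[StitchedRegion]:
    """Attach to each region the summed normalized signal of its constituents.

    Constituent-based accounting (the stitched span's intervening gaps do
    not contribute). An optional control track is subtracted constituent-
    wise with the difference floored at zero.
    """
    out = []
    for i, region in enumerate(regions):
        cons = PeakSet(f"region{i}", region.constituents)
        sig = site_signal(cons, track)
        if control is not None:
            sig = np.maximum(sig - site_signal(cons, control), 0.0)
        out.append(
            StitchedRegion(
                region.interval,
                region.constituent_count,
                region.constituents,
                float(sig.sum()),
            )
        )
    return out


def rank_and_cut(regions: list[StitchedRegion]) -> StitchRankResult:
    """Rank regions by signal and place the tangent-slope-1 cutoff.

    Signals and ranks are min-max scaled to [0, 1]; the cutoff sits where
    a line of slope 1 is tangent to the sorted signal-vs-rank curve. For a
    convex curve that tangency point is exactly the rank maximizing
    ``scaled_rank - scaled_signal`` (the point farthest below the
    diagonal), and that global form is what is computed — it is robust to
    single large spacings in an empirical curve, where a literal
    first-discrete-slope-above-1 scan can fire spuriously at either end.
    Regions with signal strictly above the cutoff are flagged super. A
    curve never dipping below the diagonal (e.g. perfectly linear or
    concave) yields an empty super set with a warning. Flags are
    invariant under any positive affine rescaling of the signals.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions to locate an elbow")
    if any(r.signal is None for r in regions):
        raise ValueError("regions must be scored before ranking")
    regs = sorted(
        regions, key=lambda r: (r.signal, r.interval.chrom, r.interval.start)
    )
    sig = np.array([r.signal for r in regs], dtype=float)
    lo, hi = sig[0], sig[-1]
    if hi == lo:
        raise ValueError("all region signals equal; no elbow exists")
    n = len(sig)
    x = np.linspace(0.0, 1.0, n)
    y = (sig - lo) / (hi - lo)
    gap = x - y
    best = float(gap.max())
    if best <= 0:
        warnings.warn(
            "signal-vs-rank curve never dips below the diagonal; "
            "no super-enhancers called",
            stacklevel=2,
        )
        cutoff = float(sig[-1])
    else:
        # last index attaining the max: the most conservative tangency point
        idx = int(np.flatnonzero(gap == best)[-1])
        cutoff = float(sig[idx])
    flags = sig > cutoff
    return StitchRankResult(regs, cutoff, flags, int(flags.sum()), x, y)


def assign_nearest_gene(
    regions: list[StitchedRegion], tss: pd.DataFrame
) -> tuple[list[GeneAssignment], int]:
    """Assign each region to the gene with the nearest TSS (by region center).

    Distance ties are broken by lexicographic gene name. Regions on
    chromosomes absent from the TSS table are left unassigned (logged).
    Returns the assignments and the number of unique genes hit.
    """
    if tss is None or len(tss) == 0:
        raise ValueError("TSS table is empty")
    by_chrom = {
        str(c): (sub["pos"].to_numpy(np.int64), sub["gene"].to_numpy(str))
        for c, sub in tss.groupby("chrom", sort=False)
    }
    assignments: list[GeneAssignment] = []
    for i, region in enumerate(regions):
        chrom = region.interval.chrom
        if chrom not in by_chrom:
            logger.warning(
                "region %s:%d-%d on chromosome absent from TSS table; unassigned",
                chrom, region.interval.start, region.interval.end,
            )
            continue
        pos, genes = by_chrom[chrom]
        c = region.interval.center
        d = np.abs(pos - c)
        dmin = d.min()
        gene = min(genes[d == dmin])
        rid = f"{chrom}:{region.interval.start}-{region.interval.end}"
        assignments.append(GeneAssignment(rid, str(gene), int(dmin)))
    n_unique = len({a.gene for a in assignments})
    return assignments, n_unique
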