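"""Genomic intervals, BED I/O, merging and the overlap-coefficient screen.

All coordinates are 0-based half-open ``[start, end)`` (BED convention).
Chromosome names are matched by literal string equality; if your inputs mix
``chr1`` and ``1`` styles, normalize them with :func:`normalize_chroms`
before combining peak sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapScreenRow",
    "read_bed",
    "write_bed",
    "normalize_chroms",
    "merge_self",
    "overlap_flags",
    "count_overlapping",
    "overlap_screen",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region, optionally named and scored.

    ``score`` holds a nonnegative peak intensity (e.g. a MACS signal value);
    ``center`` is the floor midpoint, which is the anchor point for all
    window-based signal computations.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be nonnegative, got {self.score}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


_COLUMNS = ["chrom", "start", "end", "name", "score"]


class PeakSet:
    """A labelled, sorted collection of genomic intervals (one cistrome).

    Internally a pandas DataFrame sorted by ``(chrom, start, end)``; row
    order is the canonical site order that all per-site vectors (signals,
    codes, classes) align to.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval] = ()):
        rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.score) for iv in intervals]
        df = pd.DataFrame(rows, columns=_COLUMNS)
        self._init_from_df(label, df)

    @classmethod
    def from_dataframe(cls, label: str, df: pd.DataFrame) -> "PeakSet":
        """Build from a DataFrame with at least chrom/start/end columns."""
        obj = cls.__new__(cls)
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "start": df["start"].astype(np.int64),
                "end": df["end"].astype(np.int64),
                "name": df["name"] if "name" in df else None,
                "score": df["score"].astype(float) if "score" in df else np.nan,
            }
        )
        obj._init_from_df(label, out)
        return obj

    def _init_from_df(self, label: str, df: pd.DataFrame) -> None:
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if (df["start"] >= df["end"]).any():
                raise ValueError("interval with start >= end")
            df = df.sort_values(
                ["chrom", "start", "end"], kind="stable"
            ).reset_index(drop=True)
        self.label = label
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            score = None if pd.isna(row.score) else float(row.score)
            name = None if row.name is None or pd.isna(row.name) else str(row.name)
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), name, score)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a, b = self._df, other._df
        if len(a) != len(b):
            return False
        return bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, idx in self._df.groupby("chrom", sort=False).indices.items():
            out[str(chrom)] = (
                self._df["start"].to_numpy()[idx],
                self._df["end"].to_numpy()[idx],
            )
        return out

    def centers(self) -> np.ndarray:
        return ((self._df["start"].to_numpy() + self._df["end"].to_numpy()) // 2)

    def subset(self, mask: np.ndarray, label: str | None = None) -> "PeakSet":
        return PeakSet.from_dataframe(
            label if label is not None else self.label,
            self._df.loc[np.asarray(mask)],
        )

    def total_span(self) -> int:
        """Total covered basepairs after self-merging."""
        merged = merge_self(self)
        d = merged.df
        return int((d["end"] - d["start"]).sum())


def read_bed(path: str | Path, dialect: str = "bed3", label: str | None = None) -> PeakSet:
    """Read a BED file into a PeakSet.

    dialect:
      * ``bed3`` — chrom, start, end; further columns ignored.
      * ``bed5`` — adds name (col 4) and score (col 5).
      * ``narrowpeak`` — name from col 4, score from the signalValue column 7.

    Coordinates are taken as 0-based half-open. ``track``/``browser``/``#``
    lines are skipped. Malformed lines raise ``ValueError`` naming the line
    number. An empty file yields an empty PeakSet.
    """
    dialect = dialect.lower().replace("-", "").replace("_", "")
    if dialect not in {"bed3", "bed5", "narrowpeak"}:
        raise ValueError(f"unknown BED dialect: {dialect!r}")
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name, score = None, np.nan
            if dialect == "bed5" and len(fields) >= 5:
                name = fields[3]
                try:
                    score = float(fields[4])
                except ValueError:
                    score = np.nan
            elif dialect == "narrowpeak" and len(fields) >= 7:
                name = fields[3]
                try:
                    score = float(fields[6])
                except ValueError:
                    score = np.nan
            rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return PeakSet.from_dataframe(label if label is not None else path.stem, df)


def write_bed(peaks: PeakSet, path: str | Path, extra: Mapping[str, Sequence] | None = None) -> None:
    """Write a PeakSet as tab-separated BED (name/score columns if present).

    ``extra`` maps column names to per-site sequences appended after the
    standard columns (used e.g. for S-code or class annotations).
    """
    df = peaks.df.copy()
    cols = ["chrom", "start", "end"]
    if df["name"].notna().any() or df["score"].notna().any() or extra:
        df["name"] = df["name"].fillna(".")
        cols.append("name")
    if df["score"].notna().any() or extra:
        df["score"] = df["score"].fillna(0.0)
        cols.append("score")
    if extra:
        for key, values in extra.items():
            df[key] = list(values)
            cols.append(key)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def normalize_chroms(peaks: PeakSet, table: Mapping[str, str]) -> PeakSet:
    """Rename chromosomes via an explicit mapping (e.g. ``{"1": "chr1"}``)."""
    df = peaks.df.copy()
    df["chrom"] = df["chrom"].map(lambda c: table.get(c, c))
    return PeakSet.from_dataframe(peaks.label, df)


def _merge_arrays(
    starts: np.ndarray, ends: np.ndarray, gap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals closer than ``gap``; returns
    (merged_starts, merged_ends, group_id per input interval)."""
    n = len(starts)
    if n == 0:
        return starts, ends, np.zeros(0, dtype=np.int64)
    cummax_end = np.maximum.accumulate(ends)
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = starts[1:] > cummax_end[:-1] + gap
    gid = np.cumsum(new_group) - 1
    m_starts = starts[new_group]
    m_ends = np.zeros(gid[-1] + 1, dtype=ends.dtype)
    np.maximum.at(m_ends, gid, ends)
    return m_starts, m_ends, gid


def merge_self(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Merge intervals of one peak set that overlap or lie within ``gap`` bp.

    With ``gap=0`` the union of covered basepairs is preserved exactly.
    Names and scores are dropped (a merged peak has no single parent).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    frames = []
    for chrom, (starts, ends) in peaks.chrom_arrays().items():
        ms, me, _ = _merge_arrays(starts, ends, gap)
        frames.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not frames:
        return PeakSet(peaks.label)
    return PeakSet.from_dataframe(peaks.label, pd.concat(frames, ignore_index=True))


def overlap_flags(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean per interval of ``a`` (in ``a.df`` row order): does it share
    at least ``min_bp`` basepairs with any single interval of ``b``?"""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    flags = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return flags
    bmap = b.chrom_arrays()
    adf = a.df
    for chrom, idx in adf.groupby("chrom", sort=False).indices.items():
        if chrom not in bmap:
            continue
        bs, be = bmap[chrom]
        cummax_be = np.maximum.accumulate(be)
        a_start = adf["start"].to_numpy()[idx]
        a_end = adf["end"].to_numpy()[idx]
        # candidate j must satisfy bs[j] <= a_end - min_bp (starts sorted)
        # and be[j] >= a_start + min_bp (prefix-max of ends is sorted).
        hi = np.searchsorted(bs, a_end - min_bp, side="right")
        lo = np.searchsorted(cummax_be, a_start + min_bp, side="left")
        out = np.zeros(len(idx), dtype=bool)
        for j in range(len(idx)):
            l, h = lo[j], hi[j]
            if l >= h:
                continue
            ov = np.minimum(a_end[j], be[l:h]) - np.maximum(a_start[j], bs[l:h])
            out[j] = bool((ov >= min_bp).any())
        flags[idx] = out
    return flags


def count_overlapping(a: PeakSet, b: PeakSet, min_bp: int = 1) -> int:
    """Number of intervals of ``a`` overlapping >= ``min_bp`` bp with any
    interval of ``b``. Bounded by ``len(a)``; not symmetric in count."""
    return int(overlap_flags(a, b, min_bp).sum())


@dataclass(frozen=True)
class OverlapScreenRow:
    """One candidate factor's row in the cofactor overlap screen.

    Two denominator conventions are reported side by side:
    ``coefficient_anchor`` divides the overlap count by the anchor peak
    count; ``coefficient_merged`` divides the number of merged-union peaks
    containing contributions from both cistromes by the merged-union size.
    """

    factor_label: str
    overlap_count: int
    coefficient_anchor: float
    coefficient_merged: float


def overlap_screen(
    anchor: PeakSet, candidates: Sequence[PeakSet], min_bp: int = 1
) -> list[OverlapScreenRow]:
    """Rank candidate cistromes by their overlap with an anchor cistrome.

    Sorted descending by ``coefficient_anchor`` (ties broken by factor
    label) — the screen used to nominate cofactors of a nuclear receptor.
    """
    if len(anchor) == 0:
        raise ValueError("anchor peak set is empty")
    rows = []
    for cand in candidates:
        cnt = count_overlapping(anchor, cand, min_bp)
        coeff_anchor = cnt / len(anchor)
        union_df = pd.concat([anchor.df, cand.df], ignore_index=True)
        merged = merge_self(PeakSet.from_dataframe("union", union_df))
        if len(merged):
            both = overlap_flags(merged, anchor) & overlap_flags(merged, cand)
            coeff_merged = float(both.sum() / len(merged))
        else:
            coeff_merged = 0.0
        rows.append(
            OverlapScreenRow(cand.label, cnt, float(coeff_anchor), coeff_merged)
        )
    rows.sort(key=lambda r: (-r.coefficient_anchor, r.factor_label))
    return rows
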