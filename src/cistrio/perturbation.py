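"""Knockdown-perturbation analysis: per-site binding-change classification
and condition-level peak-set loss/gain.

Binding change is a fold-change call on normalized per-site signal between
a control and a knockdown library: sites at least ``fc_threshold``-fold
down are "weaker", at least that much up "stronger", everything between
"unchanged". A pseudocount keeps zero-signal sites finite. The threshold
and pseudocount are analysis parameters, stamped into every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import PeakSet, merge_self, count_overlapping
from .signals import TagTrack, CoverageTrack, site_signal, binned_density, mean_profile

__all__ = [
    "BindingChangeTable",
    "PeakSetDiff",
    "classify_binding_change",
    "peakset_diff",
    "stratified_profiles",
]

CLASSES = ("weaker", "unchanged", "stronger")


@dataclass
class BindingChangeTable:
    """Per-site control/knockdown signals, log2 fold change and class."""

    sites: PeakSet
    table: pd.DataFrame  # chrom,start,end,signal_control,signal_knockdown,log2fc,category
    fc_threshold: float
    pseudocount: float
    class_fractions: dict[str, float] = field(default_factory=dict)

    def class_sites(self, category: str) -> PeakSet:
        if category not in CLASSES:
            raise ValueError(f"unknown class {category!r}")
        mask = (self.table["category"] == category).to_numpy()
        return self.sites.subset(mask, label=f"{self.sites.label}:{category}")


def classify_binding_change(
    sites: PeakSet,
    control: TagTrack | CoverageTrack,
    knockdown: TagTrack | CoverageTrack,
    fc_threshold: float = 1.5,
    pseudocount: float = 0.5,
) -> BindingChangeTable:
    """Three-way weaker/unchanged/stronger classification of anchor sites.

    ``log2fc = log2((knockdown + pc) / (control + pc))`` on per-site
    normalized signal over each site's own span; the class thresholds are
    symmetric at ``+/- log2(fc_threshold)``. Swapping the two tracks
    exactly swaps the weaker and stronger calls.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    sig_c = site_signal(sites, control)
    sig_k = site_signal(sites, knockdown)
    log2fc = np.log2((sig_k + pseudocount) / (sig_c + pseudocount))
    thr = np.log2(fc_threshold)
    category = np.where(
        log2fc <= -thr, "weaker", np.where(log2fc >= thr, "stronger", "unchanged")
    )
    df = sites.df[["chrom", "start", "end"]].copy()
    df["signal_control"] = sig_c
    df["signal_knockdown"] = sig_k
    df["log2fc"] = log2fc
    df["category"] = category
    n = max(len(sites), 1)
    fractions = {c: float(np.sum(category == c) / n) for c in CLASSES}
    return BindingChangeTable(sites, df, fc_threshold, pseudocount, fractions)


@dataclass(frozen=True)
class PeakSetDiff:
    """Venn counts of two (self-merged) peak sets and the loss fraction."""

    n_only_a: int
    n_only_b: int
    n_shared: int
    lost_fraction: float  # n_only_a / |a|, peaks of a absent from b


def peakset_diff(a: PeakSet, b: PeakSet, min_bp: int = 1) -> PeakSetDiff:
    """Shared/exclusive peak counts between two conditions.

    Both sets are self-merged first so counts refer to non-redundant
    peaks; sharing is Boolean overlap at ``min_bp``. ``lost_fraction``
    reads condition ``a`` as the reference (e.g. shCtrl) and ``b`` as the
    perturbed condition.
    """
    ma = merge_self(a)
    mb = merge_self(b)
    shared = count_overlapping(ma, mb, min_bp)
    only_a = len(ma) - shared
    only_b = len(mb) - count_overlapping(mb, ma, min_bp)
    lost = only_a / len(ma) if len(ma) else 0.0
    return PeakSetDiff(only_a, only_b, shared, float(lost))


def stratified_profiles(
    table: BindingChangeTable,
    tracks: list[TagTrack | CoverageTrack],
    flank: int = 2000,
    bin_width: int = 100,
) -> dict[str, dict[str, np.ndarray]]:
    """Mean binned profile of each track within each binding-change class.

    Returns ``{class: {track_label: profile}}``; empty classes are omitted
    with a warning. For heatmap export, order rows by descending control
    signal (the convention used for ranked signal heatmaps).
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for category in CLASSES:
        sub = table.class_sites(category)
        if len(sub) == 0:
            warnings.warn(f"class {category!r} is empty; omitted", stacklevel=2)
            continue
        out[category] = {
            t.label: mean_profile(binned_density(sub, t, flank, bin_width))
            for t in tracks
        }
    return out


def heatmap_order(table: BindingChangeTable) -> np.ndarray:
    """Row order (indices into the site table) by descending control signal."""
    return np.argsort(-table.table["signal_control"].to_numpy(), kind="stable")
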