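"""Expression-code (E-code) patient stratification and survival comparison.

Each patient is coded over an ordered gene list: bit = 1 iff that
patient's expression is strictly above the cohort mean for the gene (a tie
at exactly the mean codes 0). With genes (FOXA1, NR2F2, GATA3), code
``110`` is a patient high on FOXA1 and NR2F2 and low on GATA3. Code
groups below a minimum size are flagged for exclusion rather than
silently tested. Survival machinery (product-limit curves, log-rank
tests) is backed by lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "SurvivalCurve",
    "read_cohort",
    "encode_expression",
    "km_estimate",
    "km_by_code",
    "logrank_test",
]


@dataclass
class CohortTable:
    """Patient expression + follow-up table, optionally E-coded.

    ``data`` columns: patient id index, ``time`` (follow-up, any
    consistent unit, > 0), ``event`` (1 = event observed, 0 = censored),
    one column per gene, and after encoding an ``ecode`` column.
    """

    data: pd.DataFrame
    genes: tuple[str, ...] = ()
    min_group_size: int = 5
    group_counts: dict[str, int] = field(default_factory=dict)
    excluded_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "time" not in self.data or "event" not in self.data:
            raise ValueError("cohort needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def group(self, code: str) -> pd.DataFrame:
        if "ecode" not in self.data:
            raise ValueError("cohort has not been encoded yet")
        return self.data[self.data["ecode"] == code]

    def included_codes(self) -> list[str]:
        return [c for c in sorted(self.group_counts) if c not in self.excluded_codes]


def read_cohort(path: str | Path, gene_columns: Sequence[str] | None = None) -> CohortTable:
    """Read a TSV with columns: patient, time, event, <gene expression...>."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    genes = tuple(gene_columns) if gene_columns else tuple(
        c for c in df.columns if c not in ("time", "event", "ecode")
    )
    return CohortTable(df, genes)


def encode_expression(
    cohort: CohortTable, genes: Sequence[str], min_group_size: int = 5
) -> CohortTable:
    """Assign each patient a binary E-code over the given gene order.

    Bit i is 1 iff expression of gene i is strictly greater than its
    cohort mean. Groups smaller than ``min_group_size`` are recorded in
    ``excluded_codes`` (and logged) so downstream tests can drop them, as
    is standard when some of the 2^k strata are nearly empty.
    """
    df = cohort.data.copy()
    for g in genes:
        if g not in df.columns:
            raise ValueError(f"gene {g!r} absent from expression matrix")
        if df[g].isna().any():
            raise ValueError(f"gene {g!r} has missing values; impute first")
        if float(df[g].std(ddof=0)) == 0.0:
            raise ValueError(f"gene {g!r} has zero variance across the cohort")
    bits = np.column_stack([(df[g] > df[g].mean()).to_numpy() for g in genes])
    codes = np.array(["".join("1" if b else "0" for b in row) for row in bits])
    df["ecode"] = codes
    uniq, counts = np.unique(codes, return_counts=True)
    group_counts = {str(c): int(n) for c, n in zip(uniq, counts)}
    excluded = tuple(c for c, n in sorted(group_counts.items()) if n < min_group_size)
    if excluded:
        logger.info(
            "E-code groups below min size %d flagged for exclusion: %s",
            min_group_size, ", ".join(excluded),
        )
    return CohortTable(df, tuple(genes), min_group_size, group_counts, excluded)


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate of one patient group."""

    times: np.ndarray  # sorted distinct event times
    survival: np.ndarray  # S(t) at each event time; non-increasing, starts <= 1
    at_risk: np.ndarray  # risk-set size just before each event time
    group_label: str = ""

    def at(self, t: float) -> float:
        """S(t): step-function value at time t (1 before the first event)."""
        i = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(
    time: np.ndarray, event: np.ndarray, group_label: str = ""
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate, S(t) = prod (1 - d_i / n_i).

    Censored subjects leave the risk set without contributing a factor.
    With no events the curve is flat at 1 (empty times array).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if len(time) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    et = kmf.event_table
    ev = et[et["observed"] > 0]
    ev = ev[ev.index > 0] if 0 in ev.index else ev
    times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return SurvivalCurve(times, surv, at_risk, group_label)


def km_by_code(cohort: CohortTable, include_excluded: bool = False) -> dict[str, SurvivalCurve]:
    """One KM curve per E-code group (small flagged groups skipped by default)."""
    codes = cohort.group_counts if include_excluded else cohort.included_codes()
    out = {}
    for code in sorted(codes):
        sub = cohort.group(code)
        if len(sub) == 0:
            continue
        out[code] = km_estimate(
            sub["time"].to_numpy(), sub["event"].to_numpy(), f"E{code}"
        )
    return out


def logrank_test(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    method: str = "asymptotic",
    n_permutations: int = 10000,
    seed: int = 0,
) -> dict[str, float]:
    """Log-rank comparison of two or more survival groups.

    ``asymptotic`` gives the usual chi-square test with (g - 1) degrees of
    freedom; ``permutation`` estimates the p-value by shuffling group
    labels (add-one estimator), useful at small sample sizes where the
    chi-square approximation is doubtful.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed in any group")
    res = multivariate_logrank_test(time, group, event)
    stat = float(res.test_statistic)
    out = {
        "statistic": stat,
        "p_value": float(res.p_value),
        "df": float(len(labels) - 1),
    }
    if method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(group)
            pstat = float(multivariate_logrank_test(time, perm, event).test_statistic)
            if pstat >= stat:
                hits += 1
        out["p_value"] = (1 + hits) / (1 + n_permutations)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    return out
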