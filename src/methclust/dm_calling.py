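"""Coverage filtering and effect-size differential-methylation calling.

Two coverage-trimming policies are supported for read-count (RRBS-style)
tables:

``drop_site``
    A CpG site is kept only if *every* sample covers it with at least
    ``min_reads`` reads (the cell-line two-group comparison).
``drop_sample``
    Per site, individual samples below ``min_reads`` (or missing) are
    masked; the site survives if each group retains at least
    ``min_samples_per_group`` unmasked samples (the patient-cohort rule).

A site is called differentially methylated when the two group means of
percent methylation differ by at least ``threshold_points`` percentage
points (absolute difference; ``strict=True`` switches the comparison to
a strict inequality).  Group means are unweighted means of per-sample
percent values, not pooled read counts.  Fraction-mode (HM450-style
beta-value) tables skip coverage filtering entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .io import GenomicSite, MethylationSiteTable

__all__ = [
    "FilterPolicy",
    "DMCall",
    "DMSummary",
    "apply_filter",
    "call_dm",
    "summarize_dm",
    "calls_to_frame",
    "frame_to_calls",
]

DEFAULT_THRESHOLD = 30.0


@dataclass(frozen=True)
class FilterPolicy:
    mode: str = "drop_site"  # "drop_site" | "drop_sample"
    min_reads: int = 10
    min_samples_per_group: int = 1  # used only by drop_sample

    def __post_init__(self) -> None:
        if self.mode not in ("drop_site", "drop_sample"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        if self.min_samples_per_group < 1:
            raise ValidationError("min_samples_per_group must be >= 1")


@dataclass(frozen=True)
class DMCall:
    """One differentially methylated CpG with group means and signed delta."""

    site: GenomicSite
    mean_a: float
    mean_b: float
    delta: float  # mean_b - mean_a, percentage points
    direction: str  # "hyper" (delta > 0) | "hypo" (delta < 0)
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"bad direction {self.direction!r}")
        if (self.delta > 0) != (self.direction == "hyper") or self.delta == 0:
            raise ValidationError("direction inconsistent with delta sign")


@dataclass
class DMSummary:
    n_tested: int
    n_dm: int
    n_hyper: int
    n_hypo: int
    n_excluded: int  # sites skipped because one group was empty
    threshold: float
    per_chrom: pd.DataFrame  # index chrom; columns n_tested, n_dm, n_hyper, n_hypo, pct_dm
    policy: FilterPolicy | None = None

    def __post_init__(self) -> None:
        if self.n_hyper + self.n_hypo != self.n_dm or self.n_dm > self.n_tested:
            raise ValidationError("inconsistent DM summary counts")


def apply_filter(table: MethylationSiteTable, policy: FilterPolicy) -> MethylationSiteTable:
    """Apply a coverage-trimming policy to a count-mode table.

    Returns a new table; in ``drop_sample`` mode masked cells become NaN.
    """
    if table.mode != "count":
        raise ContractError("coverage filtering applies to count-mode tables only")
    total = table.total
    covered = np.nan_to_num(total, nan=-1.0) >= policy.min_reads
    if policy.mode == "drop_site":
        keep = covered.all(axis=1)
        return table.subset(keep)
    # drop_sample: mask low-coverage cells, then require group survivorship
    meth = table.meth.copy()
    total = table.total.copy()
    meth[~covered] = np.nan
    total[~covered] = np.nan
    ga, gb = table.group_labels()
    keep = np.ones(table.n_sites, dtype=bool)
    for label in (ga, gb):
        cols = table.group_columns(label)
        keep &= covered[:, cols].sum(axis=1) >= policy.min_samples_per_group
    out = MethylationSiteTable(
        chrom=table.chrom.copy(),
        pos=table.pos.copy(),
        samples=list(table.samples),
        groups=dict(table.groups),
        mode="count",
        meth=meth,
        total=total,
    )
    return out.subset(keep)


def _group_stats(table: MethylationSiteTable):
    pct = table.percent_matrix()
    ga, gb = table.group_labels()
    ca, cb = table.group_columns(ga), table.group_columns(gb)
    n_a = np.sum(~np.isnan(pct[:, ca]), axis=1)
    n_b = np.sum(~np.isnan(pct[:, cb]), axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.where(n_a > 0, np.nansum(pct[:, ca], axis=1) / np.maximum(n_a, 1), np.nan)
        mean_b = np.where(n_b > 0, np.nansum(pct[:, cb], axis=1) / np.maximum(n_b, 1), np.nan)
    return mean_a, mean_b, n_a, n_b


def call_dm(
    table: MethylationSiteTable,
    threshold_points: float = DEFAULT_THRESHOLD,
    strict: bool = False,
    policy: FilterPolicy | None = None,
) -> tuple[list[DMCall], DMSummary]:
    """Call DM CpGs by the >= ``threshold_points``-point group-difference rule.

    The table must already be coverage-filtered (count mode) or be a
    fraction-mode table.  Sites where a group has no contributing sample
    are skipped and tallied in ``summary.n_excluded``.  Direction is
    ``hyper`` when the second group's mean exceeds the first's.
    """
    mean_a, mean_b, n_a, n_b = _group_stats(table)
    usable = (n_a > 0) & (n_b > 0)
    delta = mean_b - mean_a
    with np.errstate(invalid="ignore"):
        if strict:
            called = usable & (np.abs(delta) > threshold_points)
        else:
            called = usable & (np.abs(delta) >= threshold_points)
        called &= delta != 0  # a zero difference is never a call
    calls = [
        DMCall(
            site=GenomicSite(str(table.chrom[i]), int(table.pos[i])),
            mean_a=float(mean_a[i]),
            mean_b=float(mean_b[i]),
            delta=float(delta[i]),
            direction="hyper" if delta[i] > 0 else "hypo",
            n_a=int(n_a[i]),
            n_b=int(n_b[i]),
        )
        for i in np.flatnonzero(called)
    ]
    summary = summarize_dm(
        calls, table, threshold=threshold_points, policy=policy,
        n_excluded=int(np.sum(~usable)),
    )
    return calls, summary


def summarize_dm(
    calls: list[DMCall],
    table: MethylationSiteTable,
    threshold: float = DEFAULT_THRESHOLD,
    policy: FilterPolicy | None = None,
    n_excluded: int = 0,
) -> DMSummary:
    """Totals, hyper/hypo split, and per-chromosome counts and percentages.

    The per-chromosome percentage is 100 * (DM sites on chrom) / (tested
    sites on chrom), tested sites being all sites of ``table``.
    """
    chroms = pd.Index(sorted(set(map(str, table.chrom))), name="chrom")
    tested = pd.Series(0, index=chroms, dtype=int)
    for c, n in zip(*np.unique(table.chrom.astype(str), return_counts=True)):
        tested[c] = int(n)
    dm = pd.Series(0, index=chroms, dtype=int)
    hyper = pd.Series(0, index=chroms, dtype=int)
    for call in calls:
        dm[call.site.chrom] += 1
        if call.direction == "hyper":
            hyper[call.site.chrom] += 1
    per_chrom = pd.DataFrame(
        {
            "n_tested": tested,
            "n_dm": dm,
            "n_hyper": hyper,
            "n_hypo": dm - hyper,
            "pct_dm": np.where(tested > 0, 100.0 * dm / tested.replace(0, 1), 0.0),
        }
    )
    n_hyper = int(hyper.sum())
    return DMSummary(
        n_tested=table.n_sites,
        n_dm=len(calls),
        n_hyper=n_hyper,
        n_hypo=len(calls) - n_hyper,
        n_excluded=n_excluded,
        threshold=threshold,
        per_chrom=per_chrom,
        policy=policy,
    )


# ---------------------------------------------------------------------
# tabular round-trip for calls (the calls.tsv dialect)
# ---------------------------------------------------------------------

def calls_to_frame(calls: list[DMCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "delta": c.delta,
                "direction": c.direction,
                "n_a": c.n_a,
                "n_b": c.n_b,
            }
            for c in calls
        ],
        columns=["chrom", "pos", "mean_a", "mean_b", "delta", "direction", "n_a", "n_b"],
    )


def frame_to_calls(frame: pd.DataFrame) -> list[DMCall]:
    return [
        DMCall(
            site=GenomicSite(str(r.chrom), int(r.pos)),
            mean_a=float(r.mean_a),
            mean_b=float(r.mean_b),
            delta=float(r.delta),
            direction=str(r.direction),
            n_a=int(r.n_a),
            n_b=int(r.n_b),
        )
        for r in frame.itertuples(index=False)
    ]
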