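"""Differential expression and methylation-expression concordance.

Expression is compared between two groups on the FPKM scale (fragments
per kilobase of transcript per million mapped fragments).  A gene is
differentially expressed when its group-mean fold change reaches the
fold cutoff (default 2, in either direction, on pseudocount-stabilised
means) *and* an unpaired two-tailed t-test gives p below alpha (default
0.05); no multiple-testing correction is applied.  Concordance then
cross-tabulates genes carrying DM CpGs, per (region x methylation
direction) stratum, against their expression direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ValidationError
from .annotation import GeneDMSummary

__all__ = [
    "DECall",
    "DEResult",
    "ConcordanceSummary",
    "compute_fpkm",
    "call_de",
    "concordance",
    "concordance_to_frame",
]


@dataclass(frozen=True)
class DECall:
    gene_id: str
    mean_a: float
    mean_b: float
    fold_change: float  # (mean_b + eps) / (mean_a + eps)
    p_value: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"bad DE direction {self.direction!r}")


@dataclass
class DEResult:
    """Per-gene DE statistics (all tested genes) plus the called subset."""

    frame: pd.DataFrame  # index gene_id; mean_a mean_b fold_change p_value called direction
    fold: float
    alpha: float
    eps: float

    @property
    def calls(self) -> list[DECall]:
        sub = self.frame[self.frame["called"]]
        return [
            DECall(
                gene_id=str(g),
                mean_a=float(r.mean_a),
                mean_b=float(r.mean_b),
                fold_change=float(r.fold_change),
                p_value=float(r.p_value),
                direction=str(r.direction),
            )
            for g, r in zip(sub.index, sub.itertuples(index=False))
        ]

    def direction_of(self) -> dict[str, str]:
        """gene -> up/down/unchanged for every tested gene."""
        return {
            str(g): (str(d) if c else "unchanged")
            for g, c, d in zip(
                self.frame.index, self.frame["called"], self.frame["direction"]
            )
        }


@dataclass
class ConcordanceSummary:
    region: str  # promoter | gene_body
    meth_direction: str  # hyper | hypo
    n_genes: int
    fraction_down: float | None
    fraction_up: float | None
    fraction_unchanged: float | None


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series, totals=None) -> pd.DataFrame:
    """FPKM = fragments * 1e9 / (gene_length_bp * total_mapped_fragments).

    ``totals`` defaults to the per-sample column sums of ``counts``.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative count")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise ValidationError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValidationError("gene length must be > 0")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = pd.Series(totals).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValidationError("total mapped fragments must be > 0 for every sample")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def call_de(
    fpkm: pd.DataFrame,
    groups: dict[str, str],
    fold: float = 2.0,
    alpha: float = 0.05,
    eps: float = 0.1,
    strict: bool = False,
    equal_var: bool = True,
) -> DEResult:
    """Two-group DE calling by fold change + unpaired two-tailed t-test.

    Groups are ordered lexicographically by label (the first is group A);
    direction is ``up`` when the second group's mean exceeds the first's.
    Student's equal-variance t-test by default (``equal_var=False`` for
    Welch).
    """
    for s in fpkm.columns:
        if s not in groups:
            raise ValidationError(f"sample {s!r} absent from group mapping")
    labels = sorted({groups[s] for s in fpkm.columns})
    if len(labels) != 2:
        raise ValidationError(f"exactly two groups required, got {labels}")
    ga, gb = labels
    cols_a = [s for s in fpkm.columns if groups[s] == ga]
    cols_b = [s for s in fpkm.columns if groups[s] == gb]
    for label, cols in ((ga, cols_a), (gb, cols_b)):
        if len(cols) < 2:
            raise ContractError(f"group {label!r} has {len(cols)} sample(s); need >= 2")
    a = fpkm[cols_a].to_numpy(dtype=float)
    b = fpkm[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = (mean_b + eps) / (mean_a + eps)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    if strict:
        fold_ok = (fc > fold) | (fc < 1.0 / fold)
    else:
        fold_ok = (fc >= fold) | (fc <= 1.0 / fold)
    called = fold_ok & (p < alpha) & (mean_a != mean_b)
    frame = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "p_value": p,
            "called": called,
            "direction": np.where(mean_b > mean_a, "up", "down"),
        },
        index=fpkm.index,
    )
    return DEResult(frame=frame, fold=fold, alpha=alpha, eps=eps)


_STRATA = (
    ("promoter", "hyper"), ("promoter", "hypo"),
    ("gene_body", "hyper"), ("gene_body", "hypo"),
)


def concordance(
    gene_dm_summaries: list[GeneDMSummary],
    de: DEResult,
    min_cpg: int = 1,
) -> list[ConcordanceSummary]:
    """Cross-tabulate DM gene strata against expression direction.

    For each (region, methylation direction) stratum, genes with at least
    ``min_cpg`` DM CpGs of that direction in that region are classified
    as expression down / up / unchanged (tested but not DE).  Genes
    absent from the expression analysis are excluded from denominators.
    Fractions are None when a stratum is empty.
    """
    direction = de.direction_of()
    out = []
    for region, meth_dir in _STRATA:
        attr = ("promoter_" if region == "promoter" else "gene_body_") + meth_dir
        genes = [
            g.gene_id for g in gene_dm_summaries
            if getattr(g, attr) >= min_cpg and g.gene_id in direction
        ]
        n = len(genes)
        if n == 0:
            out.append(ConcordanceSummary(region, meth_dir, 0, None, None, None))
            continue
        n_down = sum(direction[g] == "down" for g in genes)
        n_up = sum(direction[g] == "up" for g in genes)
        out.append(
            ConcordanceSummary(
                region=region,
                meth_direction=meth_dir,
                n_genes=n,
                fraction_down=n_down / n,
                fraction_up=n_up / n,
                fraction_unchanged=(n - n_down - n_up) / n,
            )
        )
    return out


def concordance_to_frame(summaries: list[ConcordanceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": s.region,
                "meth_direction": s.meth_direction,
                "n_genes": s.n_genes,
                "fraction_down": np.nan if s.fraction_down is None else s.fraction_down,
                "fraction_up": np.nan if s.fraction_up is None else s.fraction_up,
                "fraction_unchanged": np.nan
                if s.fraction_unchanged is None
                else s.fraction_unchanged,
            }
            for s in summaries
        ],
        columns=[
            "region", "meth_direction", "n_genes",
            "fraction_down", "fraction_up", "fraction_unchanged",
        ],
    )
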