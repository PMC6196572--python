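"""Monte-Carlo test for adjacency clustering of DM CpGs.

For a gene region, the CpGs indexed by the assay (post-filter tested
sites) are laid out in genomic order as a boolean flag array, true where
a CpG is differentially methylated.  The clustering statistic is the
number of adjacent index pairs (i, i+1) with both flags true (a
site-based variant — flagged sites having a flagged neighbour — is
available via ``statistic="sites"``).  The null distribution places the
same number of flags uniformly at random without replacement among the
same number of positions; the p-value is the fraction of trials whose
null statistic reaches or exceeds the observed value, floored at
1/trials when no trial does.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import GeneModel, MethylationSiteTable

__all__ = [
    "IndexedFlagArray",
    "AdjacencyTestResult",
    "observed_adjacency",
    "exact_adjacency_sf",
    "permutation_test",
    "build_flag_arrays",
    "test_regions",
    "results_to_frame",
]

DEFAULT_TRIALS = 100_000


@dataclass
class IndexedFlagArray:
    """DM flags over the assay-indexed CpGs of one gene region."""

    region_id: str  # "<gene_id>:<region>"
    flags: np.ndarray  # bool, genomic order

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.size < 1:
            raise ContractError(f"{self.region_id}: empty flag array")


@dataclass(frozen=True)
class AdjacencyTestResult:
    region_id: str
    n_total: int
    n_dm: int
    observed_adjacent: int
    trials: int
    n_ge: int  # trials with null adjacency >= observed
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        expect = self.n_ge / self.trials if self.n_ge >= 1 else 1.0 / self.trials
        if self.p_value != expect or not 0.0 < self.p_value <= 1.0:
            raise ContractError("p_value inconsistent with n_ge/trials convention")


def observed_adjacency(flags, statistic: str = "pairs") -> int:
    """Count adjacency among flagged positions of an indexed CpG array.

    ``pairs``: number of index pairs (i, i+1) both flagged (default).
    ``sites``: number of flagged positions with at least one flagged
    neighbour.
    """
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        raise ContractError("empty flag array")
    both = f[:-1] & f[1:]
    if statistic == "pairs":
        return int(np.count_nonzero(both))
    if statistic == "sites":
        has_left = np.concatenate(([False], both))
        has_right = np.concatenate((both, [False]))
        return int(np.count_nonzero(has_left | has_right))
    raise ContractError(f"unknown statistic {statistic!r}")


def exact_adjacency_sf(n_total: int, n_dm: int, observed: int) -> float:
    """Exact null P(adjacent pairs >= observed) under uniform placement.

    The number of placements of k flags among n positions with exactly j
    adjacent flagged pairs is C(k-1, j) * C(n-k+1, k-j); this sums the
    tail and divides by C(n, k).  Pair statistic only.
    """
    if not 0 <= n_dm <= n_total:
        raise ContractError("need 0 <= n_dm <= n_total")
    if observed <= 0:
        return 1.0
    total = comb(n_total, n_dm)
    favorable = sum(
        comb(n_dm - 1, j) * comb(n_total - n_dm + 1, n_dm - j)
        for j in range(observed, n_dm)
    )
    return favorable / total


def _null_adjacency_counts(
    n_total: int, n_dm: int, trials: int, rng: np.random.Generator,
    statistic: str = "pairs",
) -> np.ndarray:
    """Null adjacency statistic for each of ``trials`` uniform placements."""
    counts = np.empty(trials, dtype=np.int64)
    if n_dm <= 1:
        counts[:] = 0
        return counts
    # chunked: draw uniform keys, take the n_dm smallest as flag positions
    chunk = max(1, int(4_000_000 / max(n_total, 1)))
    done = 0
    while done < trials:
        c = min(chunk, trials - done)
        keys = rng.random((c, n_total))
        pos = np.argpartition(keys, n_dm - 1, axis=1)[:, :n_dm]
        pos.sort(axis=1)
        adj = np.diff(pos, axis=1) == 1
        if statistic == "pairs":
            counts[done : done + c] = adj.sum(axis=1)
        else:
            left = np.concatenate((np.zeros((c, 1), bool), adj), axis=1)
            right = np.concatenate((adj, np.zeros((c, 1), bool)), axis=1)
            counts[done : done + c] = (left | right).sum(axis=1)
        done += c
    return counts


def permutation_test(
    n_total: int,
    n_dm: int,
    observed: int,
    trials: int = DEFAULT_TRIALS,
    seed: int | None = None,
    region_id: str = "",
    statistic: str = "pairs",
    rng: np.random.Generator | None = None,
) -> AdjacencyTestResult:
    """Monte-Carlo adjacency test for one region.

    Each trial places ``n_dm`` flags uniformly at random without
    replacement among ``n_total`` positions and counts adjacency;
    ``p = n_ge / trials`` with floor ``1/trials`` when no null trial
    reaches ``observed``.
    """
    if not 0 <= n_dm <= n_total:
        raise ContractError("need 0 <= n_dm <= n_total")
    if trials < 1:
        raise ContractError("trials must be >= 1")
    max_obs = max(n_dm - 1, 0) if statistic == "pairs" else n_dm
    if observed > max_obs or observed < 0:
        raise ContractError(
            f"observed adjacency {observed} impossible with n_dm={n_dm}"
        )
    if rng is None:
        if seed is None:
            raise ContractError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    counts = _null_adjacency_counts(n_total, n_dm, trials, rng, statistic)
    n_ge = int(np.count_nonzero(counts >= observed))
    p = n_ge / trials if n_ge >= 1 else 1.0 / trials
    return AdjacencyTestResult(
        region_id=region_id, n_total=n_total, n_dm=n_dm,
        observed_adjacent=observed, trials=trials, n_ge=n_ge,
        p_value=p, seed=-1 if seed is None else int(seed),
    )


def _region_seed(master_seed: int, region_id: str) -> np.random.SeedSequence:
    """Deterministic per-region stream independent of region order."""
    return np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(zlib.crc32(region_id.encode("utf-8")),),
    )


def build_flag_arrays(
    dm_sites: set[tuple[str, int]],
    tested: MethylationSiteTable,
    genes: list[GeneModel],
    region: str = "promoter",
    promoter_bp: int = 2000,
) -> list[IndexedFlagArray]:
    """One flag array per (gene, region) holding >= 1 DM site.

    The index is the post-filter tested-site table: all its CpGs falling
    in the gene's region, in genomic order.
    """
    if region not in ("promoter", "gene_body"):
        raise ContractError(f"region must be promoter or gene_body, got {region!r}")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in set(map(str, tested.chrom)):
        m = tested.chrom.astype(str) == chrom
        by_chrom[chrom] = np.sort(tested.pos[m])
    arrays: list[IndexedFlagArray] = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
        pos = by_chrom.get(g.chrom)
        if pos is None:
            continue
        if region == "promoter":
            lo, hi = g.promoter(promoter_bp)
            lo = max(lo, 0)
        else:
            lo, hi = g.body
        inside = pos[(pos >= lo) & (pos < hi)]
        if inside.size == 0:
            continue
        flags = np.array([(g.chrom, int(p)) in dm_sites for p in inside], dtype=bool)
        if flags.any():
            arrays.append(IndexedFlagArray(region_id=f"{g.gene_id}:{region}", flags=flags))
    return arrays


def test_regions(
    annotated_calls: pd.DataFrame,
    tested: MethylationSiteTable,
    genes: list[GeneModel],
    region: str = "promoter",
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    promoter_bp: int = 2000,
    statistic: str = "pairs",
) -> list[AdjacencyTestResult]:
    """Run the adjacency test for every (gene, region) with >= 1 DM CpG.

    Each region draws from an independent RNG stream derived from
    (seed, region_id), so results do not depend on region order.
    """
    dm_sites = {
        (str(c), int(p))
        for c, p in zip(annotated_calls["chrom"], annotated_calls["pos"])
    }
    results = []
    for arr in build_flag_arrays(dm_sites, tested, genes, region, promoter_bp):
        obs = observed_adjacency(arr.flags, statistic)
        rng = np.random.default_rng(_region_seed(seed, arr.region_id))
        res = permutation_test(
            n_total=arr.flags.size,
            n_dm=int(arr.flags.sum()),
            observed=obs,
            trials=trials,
            region_id=arr.region_id,
            statistic=statistic,
            rng=rng,
        )
        results.append(
            AdjacencyTestResult(
                region_id=res.region_id, n_total=res.n_total, n_dm=res.n_dm,
                observed_adjacent=res.observed_adjacent, trials=res.trials,
                n_ge=res.n_ge, p_value=res.p_value, seed=int(seed),
            )
        )
    return results


test_regions.__test__ = False  # plain function; keep pytest collection away


def results_to_frame(results: list[AdjacencyTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "n_total": r.n_total,
                "n_dm": r.n_dm,
                "observed": r.observed_adjacent,
                "trials": r.trials,
                "n_ge": r.n_ge,
                "p_value": r.p_value,
            }
            for r in results
        ],
        columns=["region_id", "n_total", "n_dm", "observed", "trials", "n_ge", "p_value"],
    )
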