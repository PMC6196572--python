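"""Seed-reproducible synthetic inputs with planted ground truth.

The generator emulates a two-group RRBS study plus a matched expression
study: non-overlapping stranded genes with exon blocks; CpG sites in
promoters, gene bodies and intergenic space; bimodal baseline
methylation (most CpGs near-unmethylated or near-fully methylated, as
genome-wide bisulfite data are); overdispersed (negative-binomial) read
coverage; planted group-level methylation differences, a configurable
fraction of which occupy runs of consecutive indexed CpGs within a gene
region (spatial clustering); and gene-level expression counts in which
a configurable fraction of promoter-hypermethylated genes is down-
regulated (the concordance parameter), alongside independent DE genes.

Every draw flows from a single seed through named ``SeedSequence``
children, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneModel, IntervalTrack, MethylationSiteTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_annotation",
    "simulate_methylation",
    "simulate_expression",
    "simulate_study",
    "SimulatedStudy",
    "write_truth",
    "read_truth",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard fixture.

    Defaults give ~200 genes and ~20k CpGs over two chromosomes with
    3 vs 3 methylation samples — small enough that the full pipeline
    runs in seconds, large enough for stable recovery statistics.
    """

    seed: int = 0
    # genome / gene track
    n_genes: int = 200
    chroms: tuple[str, ...] = ("chr1", "chr2")
    chrom_span: int = 12_000_000
    gene_length_range: tuple[int, int] = (3_000, 12_000)
    exon_count_range: tuple[int, int] = (2, 10)
    intergene_gap_range: tuple[int, int] = (6_000, 20_000)
    island_promoter_fraction: float = 0.7  # promoters overlapping a CpG island
    # CpG placement
    sites_per_promoter: int = 25
    sites_per_body: int = 60
    n_intergenic_sites: int = 3_000
    # coverage model (negative binomial: mean and dispersion/size)
    coverage_mean: float = 50.0
    coverage_dispersion: float = 8.0
    # baseline methylation: two-component beta mixture
    low_mode_ab: tuple[float, float] = (2.0, 20.0)   # mode ~5%
    high_mode_ab: tuple[float, float] = (19.0, 3.0)  # mode ~90%
    high_mode_weight: float = 0.5
    # planted differential methylation
    n_dm_sites: int = 400
    dm_delta_points: float = 50.0  # group-B shift, percentage points
    dm_hyper_fraction: float = 0.9
    clustered_fraction: float = 0.6  # fraction of DM sites placed in runs
    cluster_width: int = 8  # consecutive indexed CpGs per planted cluster
    cluster_region: str = "promoter"  # region hosting planted clusters
    # group sizes (methylation)
    n_samples_a: int = 3
    n_samples_b: int = 3
    # expression
    n_expr_a: int = 22
    n_expr_b: int = 22
    expr_mean_log: float = 5.0  # lognormal location of baseline mean counts
    expr_sigma_log: float = 1.0
    expr_dispersion: float = 20.0
    de_fold: float = 4.0
    concordance: float = 0.52  # promoter-hyper genes that go expression-down
    n_independent_de: int = 40

    def validate(self) -> None:
        if not 0.0 <= self.concordance <= 1.0:
            raise ValidationError("concordance must lie in [0,1]")
        if self.cluster_width < 1:
            raise ValidationError("cluster_width must be >= 1")
        for name in (
            "n_genes", "chrom_span", "sites_per_promoter", "sites_per_body",
            "coverage_mean", "coverage_dispersion", "n_samples_a", "n_samples_b",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.cluster_region not in ("promoter", "gene_body"):
            raise ValidationError("cluster_region must be promoter or gene_body")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic tables.

    ``dm_sites`` has one row per planted DM CpG: chrom, pos, gene_id,
    region, cluster_id (-1 for scattered sites), direction, the planted
    delta, the achieved delta after clipping to [0, 100], and a
    ``clipped`` flag.  ``de_genes`` has one row per planted expression
    change: gene_id, direction, fold, source (concordant | independent).
    """

    dm_sites: pd.DataFrame
    de_genes: pd.DataFrame
    concordance: float

    def planted_set(self) -> set[tuple[str, int]]:
        return {
            (str(c), int(p))
            for c, p in zip(self.dm_sites["chrom"], self.dm_sites["pos"])
        }


_DM_COLS = [
    "chrom", "pos", "gene_id", "region", "cluster_id",
    "direction", "delta_planted", "delta_achieved", "clipped",
]
_DE_COLS = ["gene_id", "direction", "fold", "source"]


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def _nb_counts(rng, mean: float, size_param: float, shape) -> np.ndarray:
    """Negative binomial with given mean and size (dispersion) parameter."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


# ---------------------------------------------------------------------
# gene + island tracks
# ---------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], IntervalTrack]:
    """Non-overlapping stranded genes with exon blocks, plus CpG islands.

    Genes are laid left-to-right per chromosome separated by random
    intergenic gaps (always > 2 kb so promoters never collide with the
    previous gene); a configurable fraction of promoters receives an
    overlapping CpG island.
    """
    config.validate()
    rng = _child_rng(config.seed, 1)
    genes: list[GeneModel] = []
    islands: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chroms}
    per_chrom = int(np.ceil(config.n_genes / len(config.chroms)))
    g_idx = 0
    for chrom in config.chroms:
        cursor = 5_000  # leave headroom for the first promoter
        for _ in range(per_chrom):
            if g_idx >= config.n_genes:
                break
            gap = int(rng.integers(*config.intergene_gap_range))
            length = int(rng.integers(*config.gene_length_range))
            tx_start = cursor + gap
            tx_end = tx_start + length
            if tx_end + 2_500 > config.chrom_span:
                raise ValidationError(
                    f"chrom_span {config.chrom_span} too small for {per_chrom} genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(rng, tx_start, tx_end, config.exon_count_range)
            g_idx += 1
            gene = GeneModel(
                gene_id=f"G{g_idx:04d}", chrom=chrom, strand=strand,
                tx_start=tx_start, tx_end=tx_end, exons=exons,
            )
            genes.append(gene)
            if rng.random() < config.island_promoter_fraction:
                ps, pe = gene.promoter(2000)
                mid = (ps + pe) // 2
                half = int(rng.integers(150, 500))
                islands[chrom].append((max(ps, mid - half), min(pe, mid + half)))
            cursor = tx_end
    track = IntervalTrack({c: np.array(v) for c, v in islands.items() if v})
    return genes, track


def _random_exons(rng, tx_start: int, tx_end: int, count_range) -> tuple:
    n_exons = int(rng.integers(count_range[0], count_range[1] + 1))
    length = tx_end - tx_start
    n_parts = 2 * n_exons - 1  # exon/intron alternation, exons at both edges
    if length < n_parts:
        n_exons, n_parts = 1, 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_parts - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [length])) + tx_start
    return tuple(
        (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)
    )


# ---------------------------------------------------------------------
# methylation table with planted DM
# ---------------------------------------------------------------------

def _place_sites(config: SimulationConfig, genes, rng):
    """CpG positions plus (gene, region) membership, in genomic order."""
    records = []  # (chrom, pos, gene_id, region)
    for g in genes:
        ps, pe = g.promoter(2000)
        ps = max(ps, 0)
        for p in np.sort(rng.choice(np.arange(ps, pe), config.sites_per_promoter, replace=False)):
            records.append((g.chrom, int(p), g.gene_id, "promoter"))
        body_pos = rng.choice(
            np.arange(g.tx_start, g.tx_end), config.sites_per_body, replace=False
        )
        for p in np.sort(body_pos):
            records.append((g.chrom, int(p), g.gene_id, "gene_body"))
    # intergenic sites: sample far past the last gene per chrom
    per_chrom = int(np.ceil(config.n_intergenic_sites / len(config.chroms)))
    for chrom in config.chroms:
        last_end = max(
            (g.tx_end for g in genes if g.chrom == chrom), default=0
        )
        lo = last_end + 10_000
        hi = max(lo + 10 * per_chrom, config.chrom_span)
        for p in np.sort(rng.choice(np.arange(lo, hi), per_chrom, replace=False)):
            records.append((chrom, int(p), "", "intergenic"))
    df = pd.DataFrame(records, columns=["chrom", "pos", "gene_id", "region"])
    df = df.drop_duplicates(subset=["chrom", "pos"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_methylation(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
) -> tuple[MethylationSiteTable, SyntheticTruth]:
    """Two-group read-count methylation table with planted DM sites.

    Per site a baseline methylation probability is drawn from the beta
    mixture; group B receives the planted delta (on the probability
    scale, clipped to [0, 1]) at DM sites.  Coverage is negative
    binomial per cell; methylated reads are binomial.  Clustered DM
    sites occupy runs of ``cluster_width`` consecutive indexed sites in
    randomly chosen gene regions; the rest are scattered.
    """
    config.validate()
    if genes is None:
        genes, _ = simulate_annotation(config)
    rng = _child_rng(config.seed, 2)
    site_df = _place_sites(config, genes, rng)
    n_sites = len(site_df)
    if config.n_dm_sites > n_sites:
        raise ValidationError(
            f"n_dm_sites {config.n_dm_sites} exceeds the {n_sites} simulated sites"
        )

    # baseline methylation probabilities (bimodal beta mixture)
    is_high = rng.random(n_sites) < config.high_mode_weight
    p_base = np.where(
        is_high,
        rng.beta(*config.high_mode_ab, size=n_sites),
        rng.beta(*config.low_mode_ab, size=n_sites),
    )

    # choose DM sites: clustered runs first, then scattered singles
    n_clustered_target = int(round(config.clustered_fraction * config.n_dm_sites))
    n_clusters = n_clustered_target // config.cluster_width
    host_pool = []
    for (gid, region), idx in site_df.groupby(["gene_id", "region"]).groups.items():
        idx = np.sort(np.asarray(list(idx)))
        if gid and region == config.cluster_region and len(idx) >= config.cluster_width:
            host_pool.append(idx)
    if n_clusters > len(host_pool):
        raise ValidationError(
            f"cannot place {n_clusters} clusters in {len(host_pool)} host regions"
        )
    order = rng.permutation(len(host_pool))
    dm_idx: list[int] = []
    cluster_of: dict[int, int] = {}
    for cid, which in enumerate(order[:n_clusters]):
        idx = host_pool[which]
        start = int(rng.integers(0, len(idx) - config.cluster_width + 1))
        for i in idx[start : start + config.cluster_width]:
            dm_idx.append(int(i))
            cluster_of[int(i)] = cid
    n_scattered = config.n_dm_sites - len(dm_idx)
    remaining = np.setdiff1d(np.arange(n_sites), np.array(dm_idx, dtype=int))
    scattered = rng.choice(remaining, size=n_scattered, replace=False)
    dm_idx.extend(int(i) for i in scattered)
    dm_idx_arr = np.array(sorted(dm_idx), dtype=int)

    # planted deltas
    hyper = rng.random(len(dm_idx_arr)) < config.dm_hyper_fraction
    delta = np.where(hyper, 1.0, -1.0) * (config.dm_delta_points / 100.0)
    # clustered sites model promoter runs that gain (or lose) methylation
    # coherently: their baseline is redrawn from the mode the shift fits,
    # so a planted cluster is not broken by saturation.  Scattered sites
    # keep their mixture baseline; clipping there is recorded in truth.
    in_cluster = np.array([int(i) in cluster_of for i in dm_idx_arr])
    if in_cluster.any():
        k = int(in_cluster.sum())
        low = rng.beta(*config.low_mode_ab, size=k)
        high = rng.beta(*config.high_mode_ab, size=k)
        p_base[dm_idx_arr[in_cluster]] = np.where(hyper[in_cluster], low, high)
    p_a = p_base.copy()
    p_b = p_base.copy()
    raw = p_b[dm_idx_arr] + delta
    p_b[dm_idx_arr] = np.clip(raw, 0.0, 1.0)
    clipped = (raw < 0.0) | (raw > 1.0)
    achieved = (p_b[dm_idx_arr] - p_a[dm_idx_arr]) * 100.0

    # read counts
    samples = [f"ctrl{i+1}" for i in range(config.n_samples_a)] + [
        f"case{i+1}" for i in range(config.n_samples_b)
    ]
    groups = {s: ("A" if s.startswith("ctrl") else "B") for s in samples}
    n_samp = len(samples)
    total = _nb_counts(rng, config.coverage_mean, config.coverage_dispersion, (n_sites, n_samp))
    p_cell = np.empty((n_sites, n_samp))
    p_cell[:, : config.n_samples_a] = p_a[:, None]
    p_cell[:, config.n_samples_a :] = p_b[:, None]
    meth = rng.binomial(total, p_cell)

    table = MethylationSiteTable(
        chrom=site_df["chrom"].to_numpy(dtype=object),
        pos=site_df["pos"].to_numpy(),
        samples=samples,
        groups=groups,
        mode="count",
        meth=meth.astype(float),
        total=total.astype(float),
    )
    truth_dm = pd.DataFrame(
        {
            "chrom": site_df["chrom"].to_numpy()[dm_idx_arr],
            "pos": site_df["pos"].to_numpy()[dm_idx_arr],
            "gene_id": site_df["gene_id"].to_numpy()[dm_idx_arr],
            "region": site_df["region"].to_numpy()[dm_idx_arr],
            "cluster_id": [cluster_of.get(int(i), -1) for i in dm_idx_arr],
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "delta_planted": delta * 100.0,
            "delta_achieved": achieved,
            "clipped": clipped,
        },
        columns=_DM_COLS,
    )
    truth = SyntheticTruth(
        dm_sites=truth_dm,
        de_genes=pd.DataFrame(columns=_DE_COLS),
        concordance=config.concordance,
    )
    return table, truth


# ---------------------------------------------------------------------
# expression counts tied to promoter hypermethylation
# ---------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    truth: SyntheticTruth,
    genes: list[GeneModel],
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Gene-level count matrix whose DE structure echoes the planted DM.

    Among genes with planted promoter hypermethylation, a fraction equal
    to the concordance parameter is down-regulated by ``de_fold`` in
    group B; ``n_independent_de`` additional genes (without promoter-
    hyper DM) change in random directions.  Returns (counts, exonic
    gene lengths, truth with ``de_genes`` filled in).
    """
    config.validate()
    rng = _child_rng(config.seed, 3)
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series({g.gene_id: g.exonic_length() for g in genes}, name="length")

    base_mean = rng.lognormal(config.expr_mean_log, config.expr_sigma_log, len(gene_ids))
    promoter_hyper = sorted(
        set(
            truth.dm_sites.loc[
                (truth.dm_sites["region"] == "promoter")
                & (truth.dm_sites["direction"] == "hyper"),
                "gene_id",
            ]
        )
        - {""}
    )
    de_records = []
    fold_b = np.ones(len(gene_ids))
    id_pos = {g: i for i, g in enumerate(gene_ids)}
    for gid in promoter_hyper:
        if rng.random() < config.concordance:
            fold_b[id_pos[gid]] = 1.0 / config.de_fold
            de_records.append((gid, "down", config.de_fold, "concordant"))
    eligible = [g for g in gene_ids if g not in set(promoter_hyper)]
    chosen = rng.choice(eligible, size=min(config.n_independent_de, len(eligible)), replace=False)
    for gid in chosen:
        up = rng.random() < 0.5
        fold_b[id_pos[gid]] = config.de_fold if up else 1.0 / config.de_fold
        de_records.append((gid, "up" if up else "down", config.de_fold, "independent"))

    samples = [f"exA{i+1}" for i in range(config.n_expr_a)] + [
        f"exB{i+1}" for i in range(config.n_expr_b)
    ]
    counts = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    for j in range(len(samples)):
        mean = base_mean * (fold_b if j >= config.n_expr_a else 1.0)
        counts[:, j] = _nb_vec(rng, mean, config.expr_dispersion)
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    new_truth = SyntheticTruth(
        dm_sites=truth.dm_sites,
        de_genes=pd.DataFrame(de_records, columns=_DE_COLS),
        concordance=config.concordance,
    )
    return frame, lengths, new_truth


def _nb_vec(rng, means: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + means)
    return rng.negative_binomial(size_param, p)


def expression_groups(config: SimulationConfig) -> dict[str, str]:
    return {
        **{f"exA{i+1}": "A" for i in range(config.n_expr_a)},
        **{f"exB{i+1}": "B" for i in range(config.n_expr_b)},
    }


# ---------------------------------------------------------------------
# one-call convenience + truth round-trip
# ---------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: list[GeneModel]
    islands: IntervalTrack
    methylation: MethylationSiteTable
    expression_counts: pd.DataFrame
    gene_lengths: pd.Series
    truth: SyntheticTruth

    def expression_groups(self) -> dict[str, str]:
        return expression_groups(self.config)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full coherent study (tracks, methylation, expression)."""
    genes, islands = simulate_annotation(config)
    table, truth = simulate_methylation(config, genes)
    counts, lengths, truth = simulate_expression(config, truth, genes)
    return SimulatedStudy(
        config=config, genes=genes, islands=islands, methylation=table,
        expression_counts=counts, gene_lengths=lengths, truth=truth,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Single-TSV truth dump: a ``record`` column distinguishes dm/de rows."""
    dm = truth.dm_sites.copy()
    dm.insert(0, "record", "dm")
    de = truth.de_genes.copy()
    de.insert(0, "record", "de")
    merged = pd.concat([dm, de], ignore_index=True)
    merged["concordance"] = truth.concordance
    merged.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])
    dm = df[df["record"] == "dm"][_DM_COLS].reset_index(drop=True)
    if len(dm):
        dm["clipped"] = dm["clipped"].map(
            lambda v: v if isinstance(v, (bool, np.bool_)) else str(v) == "True"
        )
    dm = dm.astype({"pos": int, "cluster_id": int, "clipped": bool})
    de = df[df["record"] == "de"][_DE_COLS].reset_index(drop=True)
    concordance = float(df["concordance"].iloc[0]) if len(df) else 0.0
    return SyntheticTruth(dm_sites=dm, de_genes=de, concordance=concordance)
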