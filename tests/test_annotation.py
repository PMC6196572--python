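"""Promoter/body/intergenic assignment, exon-intron splits, island context."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methclust.annotation import (
    GeneIndex,
    annotate_calls,
    assign_region,
    classify_intragenic,
    classify_island_context,
    island_gap,
    summarize_genes,
)
from methclust.errors import ContractError
from methclust.io import GeneModel, GenomicSite, IntervalTrack


# ---------------------------------------------------------------- categories

@pytest.mark.parametrize(
    "pos,expected",
    [(8_500, "promoter"), (10_050, "gene_body"), (7_999, "intergenic"),
     (19_999, "gene_body"), (20_000, "intergenic")],
)
def test_plus_strand_assignment(plus_gene, pos, expected):
    """Promoter of a + gene [10000,20000) is [8000,10000)."""
    a = assign_region(GenomicSite("chr1", pos), [plus_gene])
    assert a.category == expected


@pytest.mark.parametrize(
    "pos,expected",
    [(9_500, "promoter"), (4_999, "intergenic"), (10_999, "promoter"),
     (11_000, "intergenic"), (5_000, "gene_body")],
)
def test_minus_strand_assignment(minus_gene, pos, expected):
    """Promoter of a - gene [5000,9000) is [9000,11000)."""
    a = assign_region(GenomicSite("chr2", pos), [minus_gene])
    assert a.category == expected


def test_promoter_precedence_keeps_all_hits():
    """A site in gene A's promoter and gene B's body reports promoter but lists both."""
    ga = GeneModel("A", "chr1", "+", 10_000, 12_000, ((10_000, 12_000),))
    gb = GeneModel("B", "chr1", "+", 5_000, 11_000, ((5_000, 11_000),))
    a = assign_region(GenomicSite("chr1", 9_000), [ga, gb])
    assert a.category == "promoter"
    assert set(a.gene_hits) == {("A", "promoter"), ("B", "gene_body")}


def test_intergenic_iff_no_hits(plus_gene):
    a = assign_region(GenomicSite("chrX", 8_500), [plus_gene])
    assert a.category == "intergenic" and a.gene_hits == ()


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 5000))
def test_categories_partition_all_sites(seed):
    """Every site gets exactly one category from the three-way partition."""
    rng = np.random.default_rng(seed)
    genes = []
    cursor = 3000
    for i in range(5):
        start = cursor + int(rng.integers(2500, 5000))
        end = start + int(rng.integers(500, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i}", "chr1", strand, start, end, ((start, end),)))
        cursor = end
    index = GeneIndex(genes)
    for pos in rng.integers(0, cursor + 5000, size=80):
        a = assign_region(GenomicSite("chr1", int(pos)), index)
        assert a.category in ("promoter", "gene_body", "intergenic")
        assert (a.category == "intergenic") == (len(a.gene_hits) == 0)
        if a.category == "gene_body":
            assert a.subregion in ("exon", "intron")


def _mirror_gene(g: GeneModel, c: int) -> GeneModel:
    exons = tuple(sorted((c - e, c - s) for s, e in g.exons))
    return GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                     c - g.tx_end, c - g.tx_start, exons)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 5000))
def test_mirror_symmetry(seed):
    """Reflecting coordinates and flipping strands preserves every category."""
    rng = np.random.default_rng(seed)
    start = int(rng.integers(3000, 10_000))
    end = start + int(rng.integers(1000, 8000))
    mid = start + (end - start) // 3
    g = GeneModel("G", "chr1", "+" if rng.random() < 0.5 else "-",
                  start, end, ((start, mid), (mid + 10, end)))
    C = 50_000
    gm = _mirror_gene(g, C)
    # the exact reflection of half-open intervals pairs [s, e) with
    # [C - e, C - s) under the point map pos -> C - 1 - pos
    for pos in rng.integers(0, 30_000, size=40):
        a = assign_region(GenomicSite("chr1", int(pos)), [g])
        b = assign_region(GenomicSite("chr1", C - 1 - int(pos)), [gm])
        assert a.category == b.category
        assert a.subregion == b.subregion


# ---------------------------------------------------------------- exon/intron

def test_exon_intron_dichotomy():
    g = GeneModel("G", "chr1", "+", 100, 400, ((100, 200), (300, 400)))
    assert classify_intragenic(GenomicSite("chr1", 150), g) == "exon"
    assert classify_intragenic(GenomicSite("chr1", 250), g) == "intron"
    with pytest.raises(ContractError):
        classify_intragenic(GenomicSite("chr1", 450), g)


def test_exon_intron_partition_gene_body(plus_gene):
    """Every body position is exactly one of exon/intron."""
    for pos in range(plus_gene.tx_start, plus_gene.tx_end, 997):
        sub = classify_intragenic(GenomicSite("chr1", pos), plus_gene)
        in_exon = any(s <= pos < e for s, e in plus_gene.exons)
        assert sub == ("exon" if in_exon else "intron")


# ---------------------------------------------------------------- islands

@pytest.mark.parametrize(
    "pos,expected",
    [(1_500, "island"), (2_500, "shore"), (4_500, "shelf"), (7_000, "open_sea"),
     (999, "shore"), (1_000, "island"), (1_999, "island"), (2_000, "shore")],
)
def test_island_context_defaults(single_island, pos, expected):
    assert classify_island_context(GenomicSite("chr1", pos), single_island) == expected


def test_nearest_island_governs():
    """Between two islands the smaller edge distance decides the context."""
    islands = IntervalTrack({"chr1": np.array([[0, 100], [5_000, 5_100]])})
    site = GenomicSite("chr1", 3_000)
    # brute-force nearest-edge distances: 2901 to the first, 2000 to the second
    assert island_gap(site, islands) == 2000
    assert classify_island_context(site, islands) == "shore"


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 5000))
def test_island_context_matches_brute_force(seed):
    """Classification agrees with a per-position exhaustive distance scan."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(np.arange(0, 20_000, 10), size=3, replace=False))
    arr = np.array([[s, s + int(rng.integers(10, 400))] for s in starts])
    islands = IntervalTrack({"chr1": arr})
    shore_bp, shelf_bp = 300, 500
    for pos in rng.integers(0, 25_000, size=60):
        pos = int(pos)
        d = min(
            0 if s <= pos < e else min(abs(pos - s), abs(pos - (e - 1)))
            for s, e in arr
        )
        if d == 0:
            expected = "island"
        elif d <= shore_bp:
            expected = "shore"
        elif d <= shore_bp + shelf_bp:
            expected = "shelf"
        else:
            expected = "open_sea"
        got = classify_island_context(GenomicSite("chr1", pos), islands,
                                      shore_bp, shelf_bp)
        assert got == expected, (pos, d)


def test_no_islands_on_chrom_is_open_sea(single_island):
    assert classify_island_context(GenomicSite("chr9", 5), single_island) == "open_sea"


# ---------------------------------------------------------------- gene summaries

def _frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "direction", "gene_hits"])


def test_gene_summary_counts_promoter_hyper():
    ann = _frame([
        ("chr1", 1, "hyper", "G1:promoter"),
        ("chr1", 2, "hyper", "G1:promoter"),
        ("chr1", 3, "hyper", "G1:promoter"),
    ])
    summaries, hist = summarize_genes(ann)
    assert len(summaries) == 1
    assert summaries[0].promoter_hyper == 3
    assert hist.set_index("min_cpgs")["n_genes"].loc[2] == 1


def test_cpg_in_two_bodies_counts_once_per_gene():
    ann = _frame([("chr1", 5, "hypo", "G1:gene_body;G2:gene_body")])
    summaries, _ = summarize_genes(ann)
    assert {s.gene_id: s.gene_body_hypo for s in summaries} == {"G1": 1, "G2": 1}


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 5000))
def test_gene_summary_matches_quadratic_recount(seed):
    """Vector counts equal a nested-loop recount over sites x genes."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(6)]
    rows = []
    for pos in range(40):
        hits = [
            f"{g}:{'promoter' if rng.random() < 0.5 else 'gene_body'}"
            for g in genes if rng.random() < 0.25
        ]
        rows.append(("chr1", pos, "hyper" if rng.random() < 0.6 else "hypo",
                     ";".join(hits)))
    ann = _frame(rows)
    summaries, _ = summarize_genes(ann)
    got = {s.gene_id: (s.promoter_hyper, s.promoter_hypo,
                       s.gene_body_hyper, s.gene_body_hypo) for s in summaries}
    expected: dict[str, list[int]] = {}
    for _, _, direction, hits in rows:
        if not hits:
            continue
        for item in hits.split(";"):
            gid, role = item.split(":")
            cell = (0 if role == "promoter" else 2) + (0 if direction == "hyper" else 1)
            expected.setdefault(gid, [0, 0, 0, 0])[cell] += 1
    assert got == {k: tuple(v) for k, v in expected.items()}


def test_annotate_calls_appends_columns(plus_gene, single_island):
    calls = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [8_500, 10_050],
                          "direction": ["hyper", "hypo"]})
    ann = annotate_calls(calls, [plus_gene], single_island)
    assert list(ann.columns[-4:]) == ["category", "gene_hits", "subregion", "island_context"]
    assert list(ann["category"]) == ["promoter", "gene_body"]
    assert ann["subregion"].tolist() == ["none", "exon"]
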