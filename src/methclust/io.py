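"""Readers and writers for every on-disk table the pipeline touches.

Coordinate conventions
----------------------
All intervals are 0-based half-open, matching the BED ecosystem; refFlat
input (0-based starts, half-open ends) is consumed as-is.  A CpG site is
keyed by the plus-strand position of its cytosine; the two strands of a
CpG dinucleotide are not distinguished.  Chromosome names are kept
verbatim and compared case-sensitively.

File dialects
-------------
* Methylation table, count mode: TSV ``chrom pos <sample>_meth <sample>_total ...``
* Methylation table, fraction mode: TSV ``chrom pos <sample> ...`` with
  percent values in [0, 100] or ``NA``
* Sample sheet: 2-column TSV ``sample group`` (exactly two groups)
* Gene track: refFlat (11 columns; cds fields read but unused)
* CpG islands: 3-column BED
* Expression: TSV matrix, first column ``gene_id``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

__all__ = [
    "GenomicSite",
    "MethylationSiteTable",
    "GeneModel",
    "IntervalTrack",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_methylation_table",
    "write_methylation_table",
    "read_gene_track",
    "write_gene_track",
    "read_island_track",
    "write_island_track",
    "read_expression_matrix",
    "write_expression_matrix",
]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single CpG position (0-based cytosine coordinate)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos} on {self.chrom}")


@dataclass
class MethylationSiteTable:
    """Per-CpG, per-sample methylation measurements for a two-group study.

    In ``count`` mode each (site, sample) cell holds methylated / total
    read counts (float arrays so missing cells can be NaN); in
    ``fraction`` mode a percent-methylation value in [0, 100].  Sites are
    kept sorted by (chrom, pos).
    """

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    groups: dict[str, str]  # sample -> group label, insertion-ordered
    mode: str  # "count" | "fraction"
    meth: np.ndarray | None = None
    total: np.ndarray | None = None
    percent: np.ndarray | None = None

    # -- construction -------------------------------------------------
    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.validate()
        self._sort()

    def validate(self) -> None:
        if self.mode not in ("count", "fraction"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if set(self.samples) != set(self.groups):
            raise ValidationError("samples and sample->group mapping disagree")
        labels = self.group_labels()
        if len(labels) != 2:
            raise ValidationError(
                f"exactly two groups required, got {len(labels)}: {labels}"
            )
        if np.any(self.pos < 0):
            raise ValidationError("negative CpG position")
        key = pd.MultiIndex.from_arrays([self.chrom, self.pos])
        if key.has_duplicates:
            dup = key[key.duplicated()][0]
            raise ValidationError(f"duplicate site {dup[0]}:{dup[1]}")
        n, k = len(self.pos), len(self.samples)
        if self.mode == "count":
            if self.meth is None or self.total is None:
                raise ValidationError("count mode requires meth and total arrays")
            self.meth = np.asarray(self.meth, dtype=float)
            self.total = np.asarray(self.total, dtype=float)
            for name, arr in (("meth", self.meth), ("total", self.total)):
                if arr.shape != (n, k):
                    raise ValidationError(f"{name} array shape {arr.shape} != ({n},{k})")
            if np.isnan(self.meth).any() != np.isnan(self.total).any() or not np.array_equal(
                np.isnan(self.meth), np.isnan(self.total)
            ):
                raise ValidationError("meth/total missingness masks differ")
            with np.errstate(invalid="ignore"):
                if np.any(self.meth < 0) or np.any(self.total < 0):
                    raise ValidationError("negative read count")
                bad = self.meth > self.total
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"methylated > total at {self.chrom[i]}:{self.pos[i]} "
                    f"sample {self.samples[j]} "
                    f"({self.meth[i, j]:g}/{self.total[i, j]:g})"
                )
        else:
            if self.percent is None:
                raise ValidationError("fraction mode requires a percent array")
            self.percent = np.asarray(self.percent, dtype=float)
            if self.percent.shape != (n, k):
                raise ValidationError(
                    f"percent array shape {self.percent.shape} != ({n},{k})"
                )
            with np.errstate(invalid="ignore"):
                bad = (self.percent < 0) | (self.percent > 100)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"percent value out of [0,100] at {self.chrom[i]}:{self.pos[i]} "
                    f"sample {self.samples[j]} ({self.percent[i, j]:g})"
                )

    def _sort(self) -> None:
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if np.array_equal(order, np.arange(len(order))):
            return
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        for name in ("meth", "total", "percent"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, arr[order])

    # -- views --------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def group_labels(self) -> list[str]:
        """The two group labels, lexicographically ordered (group A first).

        Sorting makes the A/B roles a property of the label names alone,
        so exchanging the labels exchanges the groups' roles.
        """
        return sorted(set(self.groups.values()))

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == label]

    def group_columns(self, label: str) -> np.ndarray:
        idx = {s: j for j, s in enumerate(self.samples)}
        return np.array([idx[s] for s in self.samples_in_group(label)], dtype=int)

    def sites(self) -> list[GenomicSite]:
        return [GenomicSite(c, int(p)) for c, p in zip(self.chrom, self.pos)]

    def percent_matrix(self) -> np.ndarray:
        """Per-sample percent methylation (NaN where missing/masked)."""
        if self.mode == "fraction":
            return self.percent.copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.meth / self.total
        out[~np.isfinite(out)] = np.nan  # total == 0 is uninformative
        return out

    def to_fraction(self) -> "MethylationSiteTable":
        """Convert count-mode measurements to a fraction-mode table."""
        return MethylationSiteTable(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            samples=list(self.samples),
            groups=dict(self.groups),
            mode="fraction",
            percent=self.percent_matrix(),
        )

    def subset(self, mask: np.ndarray) -> "MethylationSiteTable":
        kw = dict(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            samples=list(self.samples),
            groups=dict(self.groups),
            mode=self.mode,
        )
        for name in ("meth", "total", "percent"):
            arr = getattr(self, name)
            if arr is not None:
                kw[name] = arr[mask]
        return MethylationSiteTable(**kw)

    def equals(self, other: "MethylationSiteTable") -> bool:
        if (
            self.mode != other.mode
            or self.samples != other.samples
            or self.groups != other.groups
            or not np.array_equal(self.chrom, other.chrom)
            or not np.array_equal(self.pos, other.pos)
        ):
            return False
        for name in ("meth", "total", "percent"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b, equal_nan=True):
                return False
        return True


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with transcript bounds and exon blocks.

    ``exons`` are sorted disjoint half-open intervals; the first starts at
    ``tx_start`` and the last ends at ``tx_end`` (transcript edges are
    exonic).  The promoter is the 2 kb (configurable) immediately upstream
    of the stranded TSS: ``[tx_start - bp, tx_start)`` on plus-strand
    genes, ``[tx_end, tx_end + bp)`` on minus-strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(map(int, e)) for e in self.exons))
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValidationError(f"{self.gene_id}: txStart {self.tx_start} >= txEnd {self.tx_end}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exon blocks")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.gene_id}: empty exon block [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping/unsorted exon blocks")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValidationError(
                f"{self.gene_id}: exon blocks do not span transcript bounds"
            )

    @property
    def tss(self) -> int:
        """Transcription start: tx_start on '+', tx_end on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter(self, promoter_bp: int = 2000) -> tuple[int, int]:
        """Half-open promoter interval (may start below 0; callers clip)."""
        if self.strand == "+":
            return (self.tx_start - promoter_bp, self.tx_start)
        return (self.tx_end, self.tx_end + promoter_bp)

    @property
    def body(self) -> tuple[int, int]:
        return (self.tx_start, self.tx_end)

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class IntervalTrack:
    """Named set of 0-based half-open intervals keyed by chromosome.

    Intervals on each chromosome are stored sorted by start.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValidationError(f"empty interval on {chrom}")
            norm[chrom] = arr[np.argsort(arr[:, 0], kind="stable")]
        self.intervals = norm

    def __len__(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def records(self):
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)


# ---------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------

def read_sample_sheet(path) -> dict[str, str]:
    """2-column TSV ``sample group`` -> insertion-ordered mapping."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            sample, group = parts
            if sample == "sample" and ln == 1:  # optional header
                continue
            if sample in groups:
                raise ValidationError(f"{path}:{ln}: duplicate sample {sample!r}")
            groups[sample] = group
    if len(set(groups.values())) != 2:
        raise ValidationError(
            f"{path}: sample sheet must define exactly two groups, "
            f"got {sorted(set(groups.values()))}"
        )
    return groups


def write_sample_sheet(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------

def _parse_numeric(block: pd.DataFrame, path) -> np.ndarray:
    """Parse a string block to float with NA sentinels, reporting bad cells."""
    raw = block.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for (i, j), val in np.ndenumerate(raw):
        sval = str(val).strip() if val is not None else NA_TOKEN
        if sval in (NA_TOKEN, "", "nan", "None"):
            out[i, j] = np.nan
            continue
        try:
            out[i, j] = float(sval)
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 2}, column {block.columns[j]!r}: "
                f"non-numeric cell {sval!r}"
            ) from None
    return out


def read_methylation_table(path, mode: str, sample_sheet) -> MethylationSiteTable:
    """Read a per-CpG methylation table in count or fraction dialect.

    ``sample_sheet`` is either a path to a 2-column TSV or an already
    parsed ``{sample: group}`` mapping; every data column in the file
    must be covered by it.
    """
    groups = sample_sheet if isinstance(sample_sheet, dict) else read_sample_sheet(sample_sheet)
    if mode not in ("count", "fraction"):
        raise ValidationError(f"unknown mode {mode!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed TSV structure
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ParseError(f"{path}: first two columns must be 'chrom' and 'pos'")
    try:
        pos = df["pos"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer position: {exc}") from exc
    chrom = df["chrom"].to_numpy(dtype=object)

    data_cols = list(df.columns[2:])
    if mode == "count":
        samples = []
        for col in data_cols:
            if col.endswith("_meth"):
                samples.append(col[: -len("_meth")])
        for s in samples:
            if f"{s}_total" not in data_cols:
                raise ParseError(f"{path}: column {s}_total missing")
        if len(samples) * 2 != len(data_cols):
            raise ParseError(f"{path}: count-mode columns must pair <sample>_meth/_total")
        _check_samples_covered(samples, groups, path)
        meth = _parse_numeric(df[[f"{s}_meth" for s in samples]], path)
        total = _parse_numeric(df[[f"{s}_total" for s in samples]], path)
        # a cell is missing only if both halves are missing
        half = np.isnan(meth) != np.isnan(total)
        if half.any():
            i, j = map(int, np.argwhere(half)[0])
            raise ParseError(
                f"{path}: site {chrom[i]}:{pos[i]} sample {samples[j]}: "
                "meth/total cells must both be NA or both numeric"
            )
        return MethylationSiteTable(
            chrom=chrom, pos=pos, samples=samples,
            groups={s: groups[s] for s in samples},
            mode="count", meth=meth, total=total,
        )
    samples = data_cols
    _check_samples_covered(samples, groups, path)
    percent = _parse_numeric(df[samples], path)
    return MethylationSiteTable(
        chrom=chrom, pos=pos, samples=samples,
        groups={s: groups[s] for s in samples},
        mode="fraction", percent=percent,
    )


def _check_samples_covered(samples, groups, path) -> None:
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValidationError(f"{path}: samples absent from sample sheet: {missing}")


def _fmt(x: float) -> str:
    if np.isnan(x):
        return NA_TOKEN
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_methylation_table(table: MethylationSiteTable, path) -> None:
    cols: dict[str, object] = {"chrom": table.chrom, "pos": table.pos}
    if table.mode == "count":
        for j, s in enumerate(table.samples):
            cols[f"{s}_meth"] = [_fmt(v) for v in table.meth[:, j]]
            cols[f"{s}_total"] = [_fmt(v) for v in table.total[:, j]]
    else:
        for j, s in enumerate(table.samples):
            cols[s] = [_fmt(v) for v in table.percent[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# gene track (refFlat)
# ---------------------------------------------------------------------

_REFFLAT_COLS = [
    "geneName", "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
]


def _parse_block_list(text: str, path, ln: int) -> list[int]:
    try:
        return [int(x) for x in str(text).rstrip(",").split(",") if x != ""]
    except ValueError:
        raise ParseError(f"{path}:{ln}: bad exon block list {text!r}") from None


def read_gene_track(path) -> list[GeneModel]:
    """Read a refFlat gene track into validated :class:`GeneModel` records.

    cds fields are read but unused.  Output is sorted by (chrom, tx_start).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_REFFLAT_COLS):
                raise ParseError(
                    f"{path}:{ln}: expected {len(_REFFLAT_COLS)} columns, got {len(parts)}"
                )
            rec = dict(zip(_REFFLAT_COLS, parts))
            starts = _parse_block_list(rec["exonStarts"], path, ln)
            ends = _parse_block_list(rec["exonEnds"], path, ln)
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{ln}: exonStarts/exonEnds length mismatch")
            try:
                tx_start, tx_end = int(rec["txStart"]), int(rec["txEnd"])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer transcript bounds") from None
            try:
                genes.append(
                    GeneModel(
                        gene_id=rec["geneName"],
                        chrom=rec["chrom"],
                        strand=rec["strand"],
                        tx_start=tx_start,
                        tx_end=tx_end,
                        exons=tuple(zip(starts, ends)),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{ln}: {exc}") from None
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


def write_gene_track(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.gene_id, g.gene_id, g.chrom, g.strand,
                        str(g.tx_start), str(g.tx_end),
                        str(g.tx_start), str(g.tx_end),
                        str(len(g.exons)), starts, ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------
# island track (BED3)
# ---------------------------------------------------------------------

def read_island_track(path) -> IntervalTrack:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer BED coordinates") from None
            if start >= end:
                raise ValidationError(f"{path}:{ln}: empty interval [{start},{end})")
            by_chrom.setdefault(parts[0], []).append((start, end))
    return IntervalTrack({c: np.array(v) for c, v in by_chrom.items()})


def write_island_track(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------

def read_expression_matrix(path) -> pd.DataFrame:
    """TSV matrix (first column gene_id) -> float DataFrame indexed by gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated gene_id {dup!r}")
    values = _parse_numeric(df[df.columns[1:]], path)
    return pd.DataFrame(values, index=pd.Index(df["gene_id"], name="gene_id"),
                        columns=df.columns[1:])


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="gene_id", na_rep=NA_TOKEN)


def warn_missing_chroms(table: MethylationSiteTable, genes: list[GeneModel]) -> list[str]:
    """Log chroms present in the methylation table but absent from the track."""
    track_chroms = {g.chrom for g in genes}
    missing = sorted(set(table.chrom) - track_chroms)
    if missing:
        logger.warning(
            "chromosomes in methylation table absent from gene track: %s", missing
        )
    return missing
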