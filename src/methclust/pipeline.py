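"""End-to-end orchestration: simulate/load -> filter -> call -> annotate ->
cluster-test -> integrate, as one configured, logged, seeded run.

All outputs are plain TSV plus a JSON manifest recording package and
library versions, the seed, every parameter, and SHA-256 checksums of
the inputs — enough to reproduce the run exactly.  A single master seed
fans out to per-stage (and, inside the clustering stage, per-region)
``SeedSequence`` streams; no stage touches global RNG state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import MethclustError, ValidationError
from . import io as mio
from .dm_calling import FilterPolicy, apply_filter, call_dm, calls_to_frame
from .annotation import annotate_calls, summarize_genes, gene_summaries_to_frame
from .clustering import test_regions, results_to_frame
from .expression import compute_fpkm, call_de, concordance, concordance_to_frame
from .simulate import SimulationConfig, simulate_study, write_truth, expression_groups

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(MethclustError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    outdir: str = "methclust_out"
    seed: int = 0
    # inputs: either a simulation config or file paths
    simulation: SimulationConfig | None = None
    methylation_table: str | None = None
    sample_sheet: str | None = None
    gene_track: str | None = None
    islands: str | None = None
    expression_counts: str | None = None
    gene_lengths: str | None = None
    expression_sample_sheet: str | None = None
    mode: str = "count"  # methylation table dialect
    # parameters
    filter_mode: str = "drop_site"
    min_reads: int = 10
    min_samples_per_group: int = 1
    threshold: float = 30.0
    strict: bool = False
    promoter_bp: int = 2000
    shore_bp: int = 2000
    shelf_bp: int = 2000
    cluster_region: str = "promoter"
    trials: int = 100_000
    adjacency_statistic: str = "pairs"
    fold: float = 2.0
    alpha: float = 0.05
    eps: float = 0.1
    min_cpg: int = 1

    def validate(self) -> None:
        if self.simulation is None:
            needed = ["methylation_table", "sample_sheet", "gene_track"]
            missing = [n for n in needed if getattr(self, n) is None]
            if missing:
                raise ValidationError(
                    f"no simulation configured and inputs missing: {missing}"
                )
            for name in (
                "methylation_table", "sample_sheet", "gene_track", "islands",
                "expression_counts", "gene_lengths", "expression_sample_sheet",
            ):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValidationError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary.

    On any stage error the run aborts with :class:`PipelineError` naming
    the stage; the ``INCOMPLETE`` marker left in the output directory
    flags partial outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    inputs: dict[str, str] = {}
    outputs: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs.append(name)

    # ---- stage: inputs (simulate or load) ---------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=int(config.seed))
        study = _simulate_inputs(sim)
        table = study.methylation
        genes, islands = study.genes, study.islands
        expr_counts, lengths = study.expression_counts, study.gene_lengths
        expr_groups = study.expression_groups()
        fixtures = outdir / "fixtures"
        fixtures.mkdir(exist_ok=True)
        mio.write_methylation_table(table, fixtures / "methylation.tsv")
        mio.write_sample_sheet(table.groups, fixtures / "samples.tsv")
        mio.write_gene_track(genes, fixtures / "genes.refflat")
        mio.write_island_track(islands, fixtures / "islands.bed")
        mio.write_expression_matrix(expr_counts, fixtures / "expression_counts.tsv")
        lengths.to_frame().to_csv(fixtures / "gene_lengths.tsv", sep="\t",
                                  index_label="gene_id")
        mio.write_sample_sheet(expr_groups, fixtures / "expression_samples.tsv")
        write_truth(study.truth, fixtures / "truth.tsv")
    else:
        table, genes, islands, expr_counts, lengths, expr_groups = _load_inputs(config)
        for name in (
            "methylation_table", "sample_sheet", "gene_track", "islands",
            "expression_counts", "gene_lengths", "expression_sample_sheet",
        ):
            p = getattr(config, name)
            if p is not None:
                inputs[name] = _sha256(Path(p))

    # ---- stage: filter + call ---------------------------------------
    policy = FilterPolicy(
        mode=config.filter_mode,
        min_reads=config.min_reads,
        min_samples_per_group=config.min_samples_per_group,
    )
    filtered, calls, summary = _call_stage(table, policy, config)
    calls_frame = calls_to_frame(calls)
    emit("calls.tsv", lambda p: calls_frame.to_csv(p, sep="\t", index=False))
    global_summary = pd.DataFrame(
        [
            {
                "n_tested": summary.n_tested,
                "n_dm": summary.n_dm,
                "n_hyper": summary.n_hyper,
                "n_hypo": summary.n_hypo,
                "n_excluded": summary.n_excluded,
                "threshold": summary.threshold,
            }
        ]
    )
    emit("summary.tsv", lambda p: global_summary.to_csv(p, sep="\t", index=False))
    emit("per_chromosome.tsv", lambda p: summary.per_chrom.to_csv(p, sep="\t"))
    emit(
        "tested_sites.tsv",
        lambda p: pd.DataFrame({"chrom": filtered.chrom, "pos": filtered.pos}).to_csv(
            p, sep="\t", index=False
        ),
    )

    # ---- stage: annotate --------------------------------------------
    annotated = _annotate_stage(calls_frame, genes, islands, config)
    emit("annotated.tsv", lambda p: annotated.to_csv(p, sep="\t", index=False))
    gene_summaries, hist = summarize_genes(annotated)
    emit(
        "gene_summary.tsv",
        lambda p: gene_summaries_to_frame(gene_summaries).to_csv(p, sep="\t", index=False),
    )
    emit("gene_histogram.tsv", lambda p: hist.to_csv(p, sep="\t", index=False))

    # ---- stage: cluster test ----------------------------------------
    cluster_frame = _cluster_stage(annotated, filtered, genes, config)
    emit("cluster_test.tsv", lambda p: cluster_frame.to_csv(p, sep="\t", index=False))

    # ---- stage: expression integration ------------------------------
    if expr_counts is not None:
        conc_frame = _integration_stage(
            expr_counts, lengths, expr_groups, gene_summaries, config
        )
        emit("concordance.tsv", lambda p: conc_frame.to_csv(p, sep="\t", index=False))

    manifest = {
        "package": "methclust",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": int(config.seed),
        "parameters": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "input_checksums": inputs,
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    marker.unlink()
    return manifest


@_stage("simulate")
def _simulate_inputs(sim: SimulationConfig):
    return simulate_study(sim)


@_stage("load-inputs")
def _load_inputs(config: PipelineConfig):
    table = mio.read_methylation_table(
        config.methylation_table, config.mode, config.sample_sheet
    )
    genes = mio.read_gene_track(config.gene_track)
    mio.warn_missing_chroms(table, genes)
    islands = mio.read_island_track(config.islands) if config.islands else None
    expr_counts = lengths = expr_groups = None
    if config.expression_counts:
        expr_counts = mio.read_expression_matrix(config.expression_counts)
        lengths = pd.read_csv(
            config.gene_lengths, sep="\t", index_col="gene_id"
        ).iloc[:, 0] if config.gene_lengths else None
        expr_groups = mio.read_sample_sheet(config.expression_sample_sheet)
    return table, genes, islands, expr_counts, lengths, expr_groups


@_stage("call-dm")
def _call_stage(table, policy, config: PipelineConfig):
    filtered = apply_filter(table, policy) if table.mode == "count" else table
    calls, summary = call_dm(
        filtered, threshold_points=config.threshold, strict=config.strict, policy=policy
    )
    return filtered, calls, summary


@_stage("annotate")
def _annotate_stage(calls_frame, genes, islands, config: PipelineConfig):
    return annotate_calls(
        calls_frame, genes, islands,
        promoter_bp=config.promoter_bp,
        shore_bp=config.shore_bp, shelf_bp=config.shelf_bp,
    )


@_stage("cluster-test")
def _cluster_stage(annotated, tested, genes, config: PipelineConfig):
    results = test_regions(
        annotated, tested, genes,
        region=config.cluster_region,
        trials=config.trials,
        seed=int(config.seed),
        promoter_bp=config.promoter_bp,
        statistic=config.adjacency_statistic,
    )
    return results_to_frame(results)


@_stage("integrate")
def _integration_stage(expr_counts, lengths, expr_groups, gene_summaries, config):
    if lengths is None:
        raise ValidationError("expression integration requires gene lengths")
    fpkm = compute_fpkm(expr_counts, lengths)
    de = call_de(
        fpkm, expr_groups, fold=config.fold, alpha=config.alpha, eps=config.eps
    )
    return concordance_to_frame(concordance(gene_summaries, de, min_cpg=config.min_cpg))
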