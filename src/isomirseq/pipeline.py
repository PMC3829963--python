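"""End-to-end orchestration: preprocess -> match -> quantify -> differential
-> grouping (-> enrichment), with stage-level logging, read-count
conservation checks, and tab-separated outputs.

The file-based entry point (:func:`run_pipeline`) is what the CLI drives;
:func:`analyze_libraries` is the in-memory core shared with the test suite
and the simulation harness.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, enrichment, grouping, io, matcher, preprocess, quantify

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and tunables of a full two-condition run."""

    hairpin_fasta: str = ""
    mature_gff3: str | None = None
    mature_fasta: str | None = None
    fastq_case: str = ""
    fastq_control: str = ""
    case_label: str = "case"
    control_label: str = "control"
    family_map: str | None = None
    target_table: str | None = None
    gmt: str | None = None
    outdir: str = "results"
    # tunables
    min_mean_q: int = preprocess.DEFAULT_MIN_MEAN_Q
    adapter3: str | None = None  # None: input already trimmed
    min_overlap: int = preprocess.DEFAULT_MIN_OVERLAP
    max_mismatch_rate: float = preprocess.DEFAULT_MAX_MISMATCH_RATE
    min_len: int = preprocess.DEFAULT_MIN_LEN
    multimap_policy: str = "all"
    max_mismatches: int = matcher.DEFAULT_MAX_MISMATCHES
    window: int = matcher.DEFAULT_WINDOW
    min_count: int = quantify.DEFAULT_MIN_COUNT
    pseudocount: float = differential.DEFAULT_PSEUDOCOUNT
    fc_threshold: float = differential.DEFAULT_THRESHOLD
    estimator: str = "sum"
    cluster_max_gap: int = grouping.DEFAULT_MAX_GAP
    top_n: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        required = [
            ("hairpin_fasta", self.hairpin_fasta),
            ("fastq_case", self.fastq_case),
            ("fastq_control", self.fastq_control),
        ]
        optional = [
            ("mature_gff3", self.mature_gff3),
            ("mature_fasta", self.mature_fasta),
            ("family_map", self.family_map),
            ("target_table", self.target_table),
            ("gmt", self.gmt),
        ]
        for name, p in required:
            if not p or not Path(p).exists():
                raise ConfigError(f"{name}: missing input file {p!r}")
        for name, p in optional:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: missing input file {p!r}")
        if (self.mature_gff3 is None) == (self.mature_fasta is None):
            raise ConfigError("provide exactly one of mature_gff3 / mature_fasta")
        if self.multimap_policy not in matcher.MULTIMAP_POLICIES:
            raise ConfigError(f"unknown multimap policy {self.multimap_policy!r}")
        if not 0 <= self.max_mismatch_rate <= 1:
            raise ConfigError("max_mismatch_rate outside [0, 1]")
        if self.min_len < 1 or self.min_mean_q < 0 or self.fc_threshold < 0:
            raise ConfigError("tunable outside documented range")


@dataclass
class LibraryResult:
    library_id: str
    stats: preprocess.PreprocessStats
    tags: pd.DataFrame
    hits: pd.DataFrame
    expression: pd.DataFrame
    mapped_total: int
    length_hist: pd.Series


def process_library(
    reads,
    library_id: str,
    precursors,
    cfg: PipelineConfig,
) -> LibraryResult:
    """Preprocess and quantify one library against the precursor set."""
    tags, stats = preprocess.preprocess_library(
        reads,
        library_id,
        min_mean_q=cfg.min_mean_q,
        adapter3=cfg.adapter3,
        min_overlap=cfg.min_overlap,
        max_mismatch_rate=cfg.max_mismatch_rate,
        min_len=cfg.min_len,
    )
    logger.info(
        "%s: %d reads in, %d removed (quality), %d rejected (empty insert), "
        "%d removed (length), %d tags",
        library_id,
        stats.reads_in,
        stats.removed_quality,
        stats.rejected_empty,
        stats.removed_length,
        len(tags),
    )
    hits = matcher.match_tag_table(
        tags,
        precursors,
        policy=cfg.multimap_policy,
        max_mismatches=cfg.max_mismatches,
        window=cfg.window,
    )
    expr, total, hist = quantify.quantify_library(hits, library_id, cfg.min_count)
    logger.info("%s: %d mapped reads, %d matures quantified", library_id, total, len(expr))
    return LibraryResult(library_id, stats, tags, hits, expr, total, hist)


def analyze_libraries(
    case: LibraryResult,
    control: LibraryResult,
    precursors,
    cfg: PipelineConfig,
    family_map: pd.DataFrame | None = None,
) -> dict:
    """Differential, estimator comparison, and grouping for two libraries."""
    all_matures = [m.id for p in precursors for m in p.matures]
    diff = differential.differential_table(
        case.expression,
        control.expression,
        threshold=cfg.fc_threshold,
        pseudocount=cfg.pseudocount,
        estimator=cfg.estimator,
        all_matures=all_matures,
    )
    reports = differential.compare_estimators(diff, top_n=cfg.top_n)
    groups = grouping.cluster_groups(precursors, cfg.cluster_max_gap)
    groups += grouping.build_families(precursors, family_map=family_map)
    expr_by_library = {
        case.library_id: case.expression,
        control.library_id: control.expression,
    }
    group_tab = grouping.group_report(groups, diff, expr_by_library)
    return {
        "differential": diff,
        "comparison": reports["comparison"],
        "top_up": reports["top_up"],
        "top_down": reports["top_down"],
        "groups": group_tab,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based end-to-end run; writes every result table under outdir."""
    cfg.validate_paths()
    family_map = io.read_family_map(cfg.family_map) if cfg.family_map else None
    precursors = io.load_precursors(
        cfg.hairpin_fasta,
        mature_gff3=cfg.mature_gff3,
        mature_fasta=cfg.mature_fasta,
        family_map=family_map,
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lib_results = {}
    for label, path in (
        (cfg.case_label, cfg.fastq_case),
        (cfg.control_label, cfg.fastq_control),
    ):
        reads = preprocess.read_fastq(path)
        lib_results[label] = process_library(reads, label, precursors, cfg)

    case, control = lib_results[cfg.case_label], lib_results[cfg.control_label]
    results = analyze_libraries(case, control, precursors, cfg, family_map)
    results["libraries"] = lib_results

    # ---- write artefacts -------------------------------------------------
    stats_rows = []
    for lib in (case, control):
        stats_rows.append(dataclasses.asdict(lib.stats))
        lib.tags.to_csv(outdir / f"tags.{lib.library_id}.tsv", sep="\t", index=False)
        lib.hits.to_csv(outdir / f"hits.{lib.library_id}.tsv", sep="\t", index=False)
        lib.length_hist.reset_index().to_csv(
            outdir / f"length_histogram.{lib.library_id}.tsv", sep="\t", index=False
        )
    pd.DataFrame(stats_rows).to_csv(outdir / "preprocess_log.tsv", sep="\t", index=False)

    expr = _expression_matrix(case, control)
    expr.to_csv(outdir / "expression_matrix.tsv", sep="\t", index=False)
    for name in ("differential", "comparison", "top_up", "top_down", "groups"):
        results[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    results["expression_matrix"] = expr

    if cfg.target_table and cfg.gmt:
        de_ids = results["differential"].query("status in ('up', 'down')")[
            "mature_id"
        ].tolist()
        table = enrichment.load_target_table(cfg.target_table)
        pathways = io.read_gmt(cfg.gmt)
        enr, _ = enrichment.enrich_from_tables(de_ids, table, pathways)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        results["enrichment"] = enr
    return results


def _expression_matrix(*libs: LibraryResult) -> pd.DataFrame:
    frames = [lib.expression for lib in libs if not lib.expression.empty]
    if not frames:
        return pd.DataFrame(
            columns=["mature_id", "library_id", "dominant_count", "sum_count",
                     "n_isomirs", "dominant_rpm", "sum_rpm"]
        )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["mature_id", "library_id"], kind="stable"
    ).reset_index(drop=True)
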