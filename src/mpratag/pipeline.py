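"""End-to-end orchestration: config validation, stage wiring, output bundle.

A single YAML config drives the pipeline.  Top-level keys:

``seed``
    integer; the only entropy source for the simulate subcommand.
``paths``
    ``variant_table`` (TSV), plus either ``tag_assignments`` (TSV) or
    ``association_reads`` (FASTA/FASTQ); either ``sample_counts``
    (tag-level TSV) or ``sample_reads_manifest`` (TSV with columns
    cell_line, replicate, assay, path); ``output_dir``.
``analysis``
    ``alpha`` (default 0.05), ``bh_family_mode`` (separate|combined),
    ``qc_k`` (default 3.0), ``min_support`` (default 2), optional
    ``exclusions`` TSV path (cell_line, replicate, optional construct_id).
``simulation``
    a :class:`~mpratag.simulate.SimulationParams` field mapping, used by
    the simulate subcommand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import mpratag
from mpratag.library import (
    build_constructs,
    read_variant_table,
    write_constructs_fasta,
    write_variant_table,
)
from mpratag.simulate import (
    SimulationParams,
    simulate_counts,
    simulate_library,
    simulate_reads,
)
from mpratag.stats import AnalysisResult, analyze_dataset
from mpratag.tags import (
    aggregate_by_construct,
    associate_tags,
    count_tags,
    read_assignments_tsv,
    read_sample_counts_tsv,
    read_sequences,
    write_assignments_tsv,
    write_sample_counts_tsv,
)

logger = logging.getLogger("mpratag")

FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class PipelineConfig:
    seed: int = 0
    variant_table: Path | None = None
    tag_assignments: Path | None = None
    association_reads: Path | None = None
    sample_counts: Path | None = None
    sample_reads_manifest: Path | None = None
    output_dir: Path = Path("mpratag_out")
    alpha: float = 0.05
    bh_family_mode: str = "separate"
    qc_k: float = 3.0
    min_support: int = 2
    exclusions: Path | None = None
    simulation: SimulationParams | None = None
    raw: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw, base_dir=Path(path).parent)


def validate_config(raw: dict, *, base_dir: Path = Path(".")) -> PipelineConfig:
    """Validate a parsed config mapping; errors are aggregated, not
    fail-fast."""
    errors: list[str] = []
    cfg = PipelineConfig(raw=raw)
    cfg.seed = int(raw.get("seed", 0))

    paths = raw.get("paths", {}) or {}
    for key in ("variant_table", "tag_assignments", "association_reads",
                "sample_counts", "sample_reads_manifest", "exclusions"):
        section = paths if key != "exclusions" else (raw.get("analysis", {}) or {})
        value = section.get(key)
        if value is None:
            continue
        p = (base_dir / value).resolve() if not Path(value).is_absolute() else Path(value)
        if not p.exists():
            errors.append(f"paths.{key}: file not found: {value}")
        setattr(cfg, key, p)
    out = paths.get("output_dir", "mpratag_out")
    cfg.output_dir = (base_dir / out) if not Path(out).is_absolute() else Path(out)

    analysis = raw.get("analysis", {}) or {}
    cfg.alpha = float(analysis.get("alpha", 0.05))
    if not 0.0 < cfg.alpha < 1.0:
        errors.append(f"analysis.alpha out of range (0,1): {cfg.alpha}")
    cfg.bh_family_mode = str(analysis.get("bh_family_mode", "separate"))
    if cfg.bh_family_mode not in ("separate", "combined"):
        errors.append(
            f"analysis.bh_family_mode must be separate|combined: {cfg.bh_family_mode}"
        )
    cfg.qc_k = float(analysis.get("qc_k", 3.0))
    if cfg.qc_k <= 0:
        errors.append(f"analysis.qc_k must be positive: {cfg.qc_k}")
    cfg.min_support = int(analysis.get("min_support", 2))
    if cfg.min_support < 1:
        errors.append(f"analysis.min_support must be >= 1: {cfg.min_support}")

    sim = raw.get("simulation")
    if sim is not None:
        sim = dict(sim)
        sim.setdefault("seed", cfg.seed)
        if "outlier_replicates" in sim:
            sim["outlier_replicates"] = tuple(
                tuple(entry) for entry in sim["outlier_replicates"]
            )
        known = {f.name for f in dataclasses.fields(SimulationParams)}
        unknown = set(sim) - known
        if unknown:
            errors.append(f"simulation: unknown parameter(s) {sorted(unknown)}")
        else:
            try:
                cfg.simulation = SimulationParams(**sim)
            except (ValueError, TypeError) as exc:
                errors.append(f"simulation: {exc}")

    if errors:
        raise ConfigError(errors)
    return cfg


def config_hash(raw: dict) -> str:
    canonical = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def read_exclusions_tsv(path) -> list[tuple[str, int, str | None]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_line", "replicate"}
    if not required <= set(df.columns):
        raise ConfigError([f"exclusions table must have columns {sorted(required)}"])
    out = []
    for rec in df.itertuples(index=False):
        cid = getattr(rec, "construct_id", None)
        if cid is not None and (pd.isna(cid) or cid == ""):
            cid = None
        out.append((rec.cell_line, int(rec.replicate), cid))
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_results_bundle(result: AnalysisResult, out_dir: Path) -> dict[str, int]:
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "replicate_log_ratios.tsv": result.replicate_ratios,
        "results_derived_vs_ancestral.tsv": result.results_da,
        "results_vs_negcontrol.tsv": result.results_nc,
        "correlations.tsv": result.correlations,
        "classification.tsv": result.classification,
        "qc_flags.tsv": result.qc_flags,
    }
    row_counts = {}
    for name, df in tables.items():
        _write_tsv(df, out_dir / name)
        row_counts[name] = len(df)
    return row_counts


def run_simulate(cfg: PipelineConfig, *, assoc_reads_per_tag: int = 5) -> Path:
    """Generate a full synthetic dataset into the output directory."""
    if cfg.simulation is None:
        raise ConfigError(["simulate requires a simulation block in the config"])
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.simulation
    library = simulate_library(params)
    pairs, constructs, assignments = library
    samples, truth = simulate_counts(library, params)

    write_variant_table(pairs, out / "variants.tsv")
    write_constructs_fasta(constructs, out / "constructs.fasta")
    write_assignments_tsv(assignments, out / "tag_assignments.tsv")
    write_sample_counts_tsv(samples, out / "sample_counts.tsv")

    # plasmid-pool sequencing reads for tag-construct association
    from mpratag.tags import SampleCounts

    assoc_sample = SampleCounts(
        cell_line=params.cell_lines[0],
        replicate=1,
        assay="DNA",
        counts={a.tag: assoc_reads_per_tag for a in assignments},
    )
    with open(out / "association_reads.fasta", "wt", encoding="utf-8") as fh:
        for i, read in enumerate(simulate_reads(library, assoc_sample, params)):
            fh.write(f">assoc_{i}\n{read}\n")

    truth_rows = [
        {"variant_id": v, "true_activity_ratio": r}
        for v, r in sorted(truth.activity_ratios.items())
    ]
    _write_tsv(pd.DataFrame(truth_rows), out / "ground_truth.tsv")
    outlier_rows = [
        {"cell_line": cl, "replicate": rep, "mode": mode, "factor": factor}
        for cl, rep, mode, factor in truth.outliers
    ]
    _write_tsv(
        pd.DataFrame(outlier_rows, columns=["cell_line", "replicate", "mode", "factor"]),
        out / "injected_outliers.tsv",
    )
    logger.info("simulated %d variants, %d samples -> %s", len(pairs), len(samples), out)
    return out


def run_pipeline(cfg: PipelineConfig) -> AnalysisResult:
    """associate -> count -> aggregate -> analyze, from config inputs.

    Writes the results bundle plus a run log and a verbatim config echo to
    the output directory; re-running on the same inputs is bit-identical.
    """
    if cfg.variant_table is None:
        raise ConfigError(["paths.variant_table is required"])
    pairs = read_variant_table(cfg.variant_table)
    constructs = build_constructs(pairs)
    stage_rows: dict[str, int] = {"variants": len(pairs), "constructs": len(constructs)}

    if cfg.tag_assignments is not None:
        assignments = read_assignments_tsv(cfg.tag_assignments)
    elif cfg.association_reads is not None:
        assignments = associate_tags(
            read_sequences(cfg.association_reads),
            constructs,
            min_support=cfg.min_support,
        )
    else:
        raise ConfigError(
            ["either paths.tag_assignments or paths.association_reads is required"]
        )
    stage_rows["tag_assignments"] = len(assignments)
    stage_rows["unique_tags"] = sum(1 for a in assignments if a.status == "unique")

    if cfg.sample_counts is not None:
        samples = read_sample_counts_tsv(cfg.sample_counts)
    elif cfg.sample_reads_manifest is not None:
        manifest = pd.read_csv(cfg.sample_reads_manifest, sep="\t")
        samples = []
        for rec in manifest.itertuples(index=False):
            reads_path = Path(rec.path)
            if not reads_path.is_absolute():
                reads_path = cfg.sample_reads_manifest.parent / reads_path
            counted = count_tags(
                read_sequences(reads_path),
                assignments,
                cell_line=rec.cell_line,
                replicate=int(rec.replicate),
                assay=rec.assay,
            )
            samples.append(counted.sample)
    else:
        raise ConfigError(
            ["either paths.sample_counts or paths.sample_reads_manifest is required"]
        )
    stage_rows["samples"] = len(samples)

    rows = []
    for s in samples:
        for cid, n in sorted(aggregate_by_construct(s, assignments).items()):
            rows.append(
                {
                    "cell_line": s.cell_line,
                    "replicate": s.replicate,
                    "assay": s.assay,
                    "construct_id": cid,
                    "count": n,
                }
            )
    counts_df = pd.DataFrame(rows)
    stage_rows["construct_counts"] = len(counts_df)

    exclusions = read_exclusions_tsv(cfg.exclusions) if cfg.exclusions else []
    result = analyze_dataset(
        counts_df,
        constructs,
        alpha=cfg.alpha,
        qc_k=cfg.qc_k,
        bh_family_mode=cfg.bh_family_mode,
        external_exclusions=exclusions,
    )

    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(counts_df, out / "construct_counts.tsv")
    row_counts = write_results_bundle(result, out)
    stage_rows.update(row_counts)

    with open(out / "config_echo.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=False)
    log_lines = [
        f"mpratag version: {mpratag.__version__}",
        f"config hash: {config_hash(cfg.raw)}",
        *(f"rows[{k}]: {v}" for k, v in sorted(stage_rows.items())),
        *(f"note: {m}" for m in result.messages),
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    for line in log_lines:
        logger.info("%s", line)
    return result


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
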