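"""End-to-end orchestration: filter -> annotate -> abundance -> enrich -> select.

``run_all`` drives the whole analysis from a single config (all thresholds
— read length, top-N, fold-change cutoff, reference pool — are data, not
constants) and writes per-stage tables plus a summary of selected clones.
Per-stage record counts are logged so the read attrition at every gate is
auditable.  Outputs are pure functions of (inputs, config), so reruns are
byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import sequence_io
from .annotation import (
    AnchorConfig,
    DEFAULT_ANCHORS,
    DEFAULT_TYPE_RULES,
    NotVnarError,
    annotate,
    extract_cdr3,
    type_rules_from_json,
)
from .enrichment import (
    fold_change_matrix,
    read_binding_table,
    records_to_frame,
    select_candidates,
)
from .pools import PoolId
from .repertoire import AbundanceTable, abundance_matrix, count_cdr3, top_n

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    manifest: str
    binding_table: str | None = None
    anchors: str | None = None
    type_rules: str | None = None
    reference: str = "N3"
    fc_threshold: float = 10.0
    top_n: int = 500
    min_len: int = 400
    revcomp: bool = False
    outdir: str = "vnarpan_out"
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def load_anchors(self) -> AnchorConfig:
        return AnchorConfig.from_json(self.anchors) if self.anchors else DEFAULT_ANCHORS

    def load_type_rules(self):
        return type_rules_from_json(self.type_rules) if self.type_rules else DEFAULT_TYPE_RULES


@dataclass
class PoolResult:
    table: AbundanceTable
    n_reads: int
    n_passed: int
    reject_counts: dict[str, int]
    example_proteins: dict[str, str] = field(default_factory=dict)


@dataclass
class RunResult:
    outdir: Path
    tables: dict[str, AbundanceTable]
    selection: pd.DataFrame  # summary of selected clones
    records: dict[str, pd.DataFrame]  # per-pool enrichment records
    stage_log: list[dict]


def process_pool_reads(
    reads: Iterable,
    pool: PoolId,
    anchors: AnchorConfig = DEFAULT_ANCHORS,
    min_len: int = 400,
    revcomp: bool = False,
    keep_proteins: bool = False,
) -> PoolResult:
    """Filter, frame-select and count one pool's reads (in memory).

    Accepts NucleotideRead objects or (id, sequence) pairs, so simulator
    output can be analysed without a FASTQ round-trip.
    """
    candidates = sequence_io.filter_and_translate_pool(
        reads, pool, anchors=anchors, min_len=min_len, revcomp=revcomp
    )
    cdr3s: list[str] = []
    examples: dict[str, str] = {}
    reject_counts: dict[str, int] = {}
    for cand in candidates:
        if not cand.passed_filters:
            reject_counts[cand.reject_reason] = reject_counts.get(cand.reject_reason, 0) + 1
            continue
        cdr3 = cand.cdr3 if cand.cdr3 is not None else extract_cdr3(cand.protein, anchors)
        if cdr3 is None:  # unreachable for frame-selected reads, kept defensive
            reject_counts["no_anchor"] = reject_counts.get("no_anchor", 0) + 1
            continue
        cdr3s.append(cdr3)
        if keep_proteins and cdr3 not in examples:
            examples[cdr3] = cand.protein
    table = count_cdr3(cdr3s, pool)
    return PoolResult(
        table=table,
        n_reads=len(candidates),
        n_passed=len(cdr3s),
        reject_counts=reject_counts,
        example_proteins=examples,
    )


def analyze_study(
    pool_reads: Mapping[str, Iterable],
    reference: str = "N3",
    binding: Mapping[str, bool] | None = None,
    anchors: AnchorConfig = DEFAULT_ANCHORS,
    fc_threshold: float = 10.0,
    min_len: int = 400,
) -> tuple[dict[str, AbundanceTable], dict[str, list]]:
    """In-memory pipeline over {pool label: reads}: tables and selections.

    Returns the per-pool abundance tables and, for every round-3 condition
    pool other than the reference, its enrichment-selection records.
    """
    if reference not in pool_reads:
        raise ConfigError(f"reference pool {reference!r} missing from inputs")
    if "Input" not in pool_reads:
        raise ConfigError("Input pool missing from inputs")
    tables: dict[str, AbundanceTable] = {}
    for label, reads in pool_reads.items():
        pool = PoolId.from_label(label)
        tables[label] = process_pool_reads(
            reads, pool, anchors=anchors, min_len=min_len
        ).table
    selections: dict[str, list] = {}
    if binding is not None:
        ref_round = PoolId.from_label(reference).round
        for label, table in tables.items():
            pool = table.pool
            if label == reference or pool.condition == "Input" or pool.round != ref_round:
                continue
            selections[label] = select_candidates(
                table, tables[reference], tables["Input"], binding, fc_threshold
            )
    return tables, selections


def run_all(config: RunConfig) -> RunResult:
    """Run the full file-based pipeline; abort naming the failing stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"

    def fail(stage: str, exc: BaseException):
        marker.write_text(f"failed at stage: {stage}\n")
        raise StageError(stage, exc) from exc

    # ---- configuration validation (before any compute) -------------------
    try:
        entries = sequence_io.read_manifest(config.manifest)
        labels = [pool.label for _, pool in entries]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate pools in manifest: {sorted(labels)}")
        if config.reference not in labels:
            raise ConfigError(f"reference pool {config.reference!r} not in manifest")
        if "Input" not in labels:
            raise ConfigError("manifest must include the Input pool")
        for path, _pool in entries:
            if not Path(path).exists():
                raise ConfigError(f"manifest file not found: {path}")
        anchors = config.load_anchors()
        type_rules = config.load_type_rules()
        binding = read_binding_table(config.binding_table) if config.binding_table else {}
    except (OSError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    stage_log: list[dict] = []
    tables: dict[str, AbundanceTable] = {}
    proteins_by_pool: dict[str, dict[str, str]] = {}
    ref_round = PoolId.from_label(config.reference).round

    # ---- stage 1+2: filter, translate, count ------------------------------
    try:
        for path, pool in entries:
            reads = sequence_io.read_pool(path, pool)
            keep = pool.condition not in ("Input",) and pool.round == ref_round
            result = process_pool_reads(
                reads,
                pool,
                anchors=anchors,
                min_len=config.min_len,
                revcomp=config.revcomp,
                keep_proteins=keep,
            )
            tables[pool.label] = result.table
            if keep:
                proteins_by_pool[pool.label] = result.example_proteins
            result.table.to_tsv(outdir / f"abundance_{pool.label}.tsv")
            entry = {
                "stage": "filter+count",
                "pool": pool.label,
                "reads_in": result.n_reads,
                "reads_passed": result.n_passed,
                "distinct_cdr3": len(result.table.counts),
                **{f"rejected_{k}": v for k, v in sorted(result.reject_counts.items())},
            }
            stage_log.append(entry)
            logger.info("%s", entry)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("filter+count", exc)

    # ---- stage 3: abundance matrices per condition ------------------------
    try:
        by_condition: dict[str, list[AbundanceTable]] = {}
        for label, table in tables.items():
            cond = table.pool.condition
            if cond == "Input":
                continue
            by_condition.setdefault(cond, []).append(table)
        for cond, cond_tables in sorted(by_condition.items()):
            final = max(cond_tables, key=lambda t: t.pool.round)
            rows = top_n(final, config.top_n)
            group = [tables["Input"], *sorted(cond_tables, key=lambda t: t.pool.round)]
            matrix = abundance_matrix(group, rows)
            matrix.to_tsv(outdir / f"abundance_matrix_{cond}.tsv")
            if config.make_plots:
                from .plotting import combined_heatmap

                if config.reference in tables:
                    fc_vals, _ = fold_change_matrix([final], tables[config.reference], rows)
                    combined_heatmap(
                        matrix.values, fc_vals, outdir / f"heatmap_{cond}.png"
                    )
    except Exception as exc:  # noqa: BLE001
        fail("abundance_matrix", exc)

    # ---- stage 4: enrichment + selection ----------------------------------
    records: dict[str, pd.DataFrame] = {}
    summary_rows = []
    try:
        ref_table = tables[config.reference]
        input_table = tables["Input"]
        for label, table in sorted(tables.items()):
            pool = table.pool
            if label == config.reference or pool.condition == "Input" or pool.round != ref_round:
                continue
            recs = select_candidates(
                table, ref_table, input_table, binding, config.fc_threshold
            )
            df = records_to_frame(recs)
            df.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t", index=False)
            records[label] = df
            n_selected = int(df["selected"].sum())
            stage_log.append(
                {"stage": "selection", "pool": label, "selected": n_selected}
            )
            for rec in recs:
                if not rec.selected:
                    continue
                vnar_type = "unknown"
                protein = proteins_by_pool.get(label, {}).get(rec.cdr3)
                if protein is not None:
                    try:
                        vnar_type = annotate(protein, anchors, type_rules).vnar_type
                    except NotVnarError:
                        pass
                summary_rows.append(
                    {
                        "clone": rec.cdr3,
                        "pool": label,
                        "abundance_pct": rec.abundance_pct,
                        "reference_abundance_pct": rec.reference_abundance_pct,
                        "input_abundance_pct": input_table.abundance_pct(rec.cdr3),
                        "fold_change": rec.fold_change,
                        "censored": rec.censored,
                        "vnar_type": vnar_type,
                    }
                )
    except Exception as exc:  # noqa: BLE001
        fail("selection", exc)

    # ---- stage 5: summary + logs ------------------------------------------
    try:
        summary = pd.DataFrame(
            summary_rows,
            columns=[
                "clone",
                "pool",
                "abundance_pct",
                "reference_abundance_pct",
                "input_abundance_pct",
                "fold_change",
                "censored",
                "vnar_type",
            ],
        )
        summary.to_csv(outdir / "selected_clones.tsv", sep="\t", index=False, na_rep="n.d.")
        with open(outdir / "stage_log.json", "w") as fh:
            json.dump(stage_log, fh, indent=2)
    except Exception as exc:  # noqa: BLE001
        fail("summary", exc)

    if marker.exists():
        marker.unlink()
    return RunResult(
        outdir=outdir,
        tables=tables,
        selection=summary,
        records=records,
        stage_log=stage_log,
    )
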