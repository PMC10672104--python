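"""Fold-change enrichment versus the reference pool and clone selection.

Fold change of a CDR3 is its abundance in a query pool divided by its
abundance in the reference pool (N3 — the normal-condition round-3 pool —
for every query, by convention of the analysis).  When the reference does
not contain the CDR3 at all, the denominator is floored at one reference
read (100 x 1 / reference total) and the result is flagged *censored*: it
is a lower bound ("fold change >= value"), the detection-limit reading of a
not-detected denominator.

A clone is *selected* as condition-specifically enriched when it satisfies
all three criteria: not detected in the Input pool, fold change strictly
above the threshold (default 10; a censored lower bound qualifies if the
floored value itself clears it), and experimentally confirmed
antigen-binding activity.  Binding is an external input — a CDR3 -> boolean
table — never computed from sequence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pools import PoolId
from .repertoire import ND, AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    cdr3: str
    pool: PoolId
    abundance_pct: float
    reference_abundance_pct: float  # NaN when reference n.d.
    fold_change: float
    censored: bool
    input_detected: bool
    binding_active: bool | None  # None = unknown
    selected: bool


def fold_change(
    cdr3: str, pool_table: AbundanceTable, ref_table: AbundanceTable
) -> tuple[float, bool]:
    """Fold change of one CDR3 versus the reference pool.

    Returns ``(value, censored)``; censored means the reference was n.d.
    and the one-read floor was used, so the value is a lower bound.
    """
    pool_count = pool_table.count(cdr3)
    if pool_count < 1:
        raise ValueError(f"fold change undefined: {cdr3!r} not observed in {pool_table.pool}")
    ref_total = ref_table.total_cdr3_reads
    if ref_total < 1:
        raise ValueError("reference pool is empty")
    abundance = 100.0 * pool_count / pool_table.total_cdr3_reads
    ref_count = ref_table.count(cdr3)
    if ref_count == 0:
        floor = 100.0 * 1 / ref_total
        return abundance / floor, True
    return abundance / (100.0 * ref_count / ref_total), False


def select_candidates(
    pool_table: AbundanceTable,
    ref_table: AbundanceTable,
    input_table: AbundanceTable,
    binding: Mapping[str, bool],
    fc_threshold: float = 10.0,
) -> list[EnrichmentRecord]:
    """Score every CDR3 of a pool and apply the three selection criteria.

    Emits one record per pool CDR3, selected clones first (then fold change
    descending, then CDR3 lexicographic).  CDR3s missing from the binding
    table get ``binding_active=None`` and are never selected.
    """
    pool_total = pool_table.total_cdr3_reads
    ref_total = ref_table.total_cdr3_reads
    if ref_total < 1:
        raise ValueError("reference pool is empty")
    floor = 100.0 / ref_total

    records: list[EnrichmentRecord] = []
    n_unknown = 0
    ref_counts = ref_table.counts
    input_counts = input_table.counts
    for cdr3, count in pool_table.counts.items():
        if count == 0:
            continue
        abundance = 100.0 * count / pool_total
        ref_count = ref_counts.get(cdr3, 0)
        if ref_count == 0:
            fc, censored, ref_ab = abundance / floor, True, ND
        else:
            ref_ab = 100.0 * ref_count / ref_total
            fc, censored = abundance / ref_ab, False
        input_detected = input_counts.get(cdr3, 0) > 0
        active = binding.get(cdr3)
        if active is None:
            n_unknown += 1
        selected = (not input_detected) and fc > fc_threshold and active is True
        records.append(
            EnrichmentRecord(
                cdr3=cdr3,
                pool=pool_table.pool,
                abundance_pct=abundance,
                reference_abundance_pct=ref_ab,
                fold_change=fc,
                censored=censored,
                input_detected=input_detected,
                binding_active=active,
                selected=selected,
            )
        )
    if n_unknown:
        logger.warning(
            "%s: %d CDR3s missing from the binding table (binding_active=unknown)",
            pool_table.pool.label,
            n_unknown,
        )
    records.sort(key=lambda r: (not r.selected, -r.fold_change, r.cdr3))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cdr3": [r.cdr3 for r in records],
            "pool": [r.pool.label for r in records],
            "abundance_pct": [r.abundance_pct for r in records],
            "reference_abundance_pct": [r.reference_abundance_pct for r in records],
            "fold_change": [r.fold_change for r in records],
            "censored": [r.censored for r in records],
            "input_detected": [r.input_detected for r in records],
            "binding_active": [r.binding_active for r in records],
            "selected": [r.selected for r in records],
        }
    )


def fold_change_matrix(
    tables: Sequence[AbundanceTable],
    ref_table: AbundanceTable,
    rows: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold change of ``rows`` across pools, with a censoring mask.

    Returns ``(values, censored)`` DataFrames indexed by CDR3 with one
    column per pool.  CDR3s not detected in a pool (undefined numerator)
    hold NaN in ``values`` and False in ``censored``.
    """
    ref_total = ref_table.total_cdr3_reads
    if ref_total < 1:
        raise ValueError("reference pool is empty")
    floor = 100.0 / ref_total
    values = {}
    censored = {}
    for table in tables:
        total = table.total_cdr3_reads
        col = np.full(len(rows), np.nan)
        cen = np.zeros(len(rows), dtype=bool)
        for i, cdr3 in enumerate(rows):
            c = table.counts.get(cdr3, 0)
            if c == 0:
                continue
            abundance = 100.0 * c / total
            rc = ref_table.counts.get(cdr3, 0)
            if rc == 0:
                col[i] = abundance / floor
                cen[i] = True
            else:
                col[i] = abundance / (100.0 * rc / ref_total)
        values[table.pool.label] = col
        censored[table.pool.label] = cen
    idx = list(rows)
    return pd.DataFrame(values, index=idx), pd.DataFrame(censored, index=idx)


def read_binding_table(path) -> dict[str, bool]:
    """Load a CDR3 -> binding-activity TSV (columns cdr3, binding_active)."""
    df = pd.read_csv(path, sep="\t", dtype={"cdr3": str})
    missing = {"cdr3", "binding_active"} - set(df.columns)
    if missing:
        raise ValueError(f"binding table lacks columns {sorted(missing)}")
    truthy = {"true", "1", "yes", "y"}
    return {
        row.cdr3: (str(row.binding_active).strip().lower() in truthy)
        for row in df.itertuples(index=False)
    }


def write_binding_table(binding: Mapping[str, bool], path) -> None:
    pd.DataFrame(
        {"cdr3": list(binding), "binding_active": [bool(v) for v in binding.values()]}
    ).to_csv(path, sep="\t", index=False)
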