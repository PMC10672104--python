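"""Per-pool CDR3 abundance tables and the cross-round abundance matrix.

A clone is identified by its CDR3 amino-acid string.  Abundance is the
percentage of a pool's CDR3-bearing reads carrying that CDR3; a CDR3 with
zero reads after all filters is *not detected* (n.d.), which is stored as an
explicit marker (NaN) distinct from 0 so that downstream censoring logic
stays unambiguous.  Reports round abundances to three decimals in percent;
full precision is kept internally.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pools import PoolId

#: Marker for "not detected" cells in matrices (distinct from 0.0).
ND = float("nan")


@dataclass
class AbundanceTable:
    """Exact CDR3 counts and abundances for one pool."""

    pool: PoolId
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.counts.items() if v < 0]
        if bad:
            raise ValueError(f"negative counts for {bad[:3]}")

    @property
    def total_cdr3_reads(self) -> int:
        return sum(self.counts.values())

    def count(self, cdr3: str) -> int:
        return self.counts.get(cdr3, 0)

    def abundance_pct(self, cdr3: str) -> float:
        """100 x count / total; NaN (n.d.) when the CDR3 is absent."""
        c = self.counts.get(cdr3, 0)
        if c == 0:
            return ND
        return 100.0 * c / self.total_cdr3_reads

    @property
    def entries(self) -> dict[str, tuple[int, float]]:
        total = self.total_cdr3_reads
        return {k: (v, 100.0 * v / total) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        total = self.total_cdr3_reads
        df = pd.DataFrame(
            {"cdr3": list(self.counts), "count": list(self.counts.values())}
        ).sort_values(["count", "cdr3"], ascending=[False, True], ignore_index=True)
        df["abundance_pct"] = 100.0 * df["count"] / total if total else np.nan
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["abundance_pct"] = df["abundance_pct"].round(3)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, pool: PoolId, df: pd.DataFrame) -> "AbundanceTable":
        return cls(pool, dict(zip(df["cdr3"], df["count"].astype(int))))


def count_cdr3(domains: Iterable, pool: PoolId) -> AbundanceTable:
    """Tally CDR3s from a stream of annotated domains (or plain strings)."""
    counter: Counter[str] = Counter(
        d if isinstance(d, str) else d.cdr3 for d in domains
    )
    return AbundanceTable(pool, dict(counter))


def top_n(table: AbundanceTable, n: int = 500) -> list[str]:
    """The n most abundant CDR3s, count-descending, ties lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [cdr3 for cdr3, _ in ranked[:n]]


@dataclass
class AbundanceMatrix:
    """CDR3 x pool abundance (%) with explicit n.d. cells.

    ``values`` is a DataFrame indexed by CDR3 with one column per pool
    label; n.d. cells hold NaN.  Column order is Input first, then rounds
    ascending; row order follows the supplied row list.
    """

    values: pd.DataFrame
    pools: tuple[PoolId, ...]

    @property
    def rows(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        out = self.values.round(4)
        out.to_csv(path, sep="\t", na_rep="n.d.", index_label="cdr3")


def abundance_matrix(
    tables: Sequence[AbundanceTable], rows: Sequence[str]
) -> AbundanceMatrix:
    """Assemble the heat-map data layer from a set of pool tables.

    ``tables`` normally covers Input plus one condition's rounds; columns
    are ordered Input first, then by round.  Duplicate pools are an error.
    """
    labels = [t.pool.label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate pool ids in {labels}")
    ordered = sorted(tables, key=lambda t: (t.pool.condition != "Input", t.pool.round))
    data = {}
    for t in ordered:
        total = t.total_cdr3_reads
        col = np.full(len(rows), ND)
        for i, cdr3 in enumerate(rows):
            c = t.counts.get(cdr3, 0)
            if c:
                col[i] = 100.0 * c / total
        data[t.pool.label] = col
    values = pd.DataFrame(data, index=list(rows))
    return AbundanceMatrix(values=values, pools=tuple(t.pool for t in ordered))


def round3_row_order(table: AbundanceTable, n: int = 500) -> list[str]:
    """Deterministic heat-map row order: round-3 abundance descending.

    Replaces alignment-based row ordering with a reproducible sort (an
    externally supplied order can be passed straight to
    :func:`abundance_matrix` instead).
    """
    return top_n(table, n)
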