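"""Literature co-mention baseline and multi-list intersection analysis.

The co-mention baseline ranks genes by how often PubMed-style abstracts
mention them together with a context term (e.g. "aging"), either as a raw
co-mention count or normalized by the gene's total mention count to correct
for overall gene prevalence.  Counts arrive as a table; no live querying.

The intersection analysis summarizes per-disease top-k gene lists the way an
upset plot does: one count per exclusive membership pattern, plus the set of
genes common to every list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd

from .scoring import GeneScore, RankedList


@dataclass(frozen=True)
class ComentionRecord:
    """Abstract counts for one gene: co-mentions with the context term, total."""

    symbol: str
    co_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.co_count < 0 or self.total_count < 0:
            raise ValueError(f"negative count for {self.symbol}")
        if self.co_count > self.total_count:
            raise ValueError(
                f"{self.symbol}: co-mention count exceeds total mention count"
            )


@dataclass(frozen=True)
class IntersectionReport:
    """Upset-style summary of several gene lists.

    ``patterns`` maps each exclusive membership pattern (the frozenset of
    list labels a gene belongs to) to its gene count; ``common`` is the set
    of genes present in every list.
    """

    labels: tuple[str, ...]
    patterns: Mapping[frozenset, int]
    common: frozenset

    def pattern_count(self, labels: Sequence[str]) -> int:
        return self.patterns.get(frozenset(labels), 0)


def load_comention_table(source: str | Path | IO[str]) -> list[ComentionRecord]:
    """Read a tab-separated table with columns symbol, co_count, total_count."""
    frame = pd.read_csv(source, sep="\t")
    required = {"symbol", "co_count", "total_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"co-mention table lacks columns {sorted(missing)}")
    return [
        ComentionRecord(
            symbol=str(r.symbol).strip().upper(),
            co_count=int(r.co_count),
            total_count=int(r.total_count),
        )
        for r in frame.itertuples(index=False)
    ]


def comention_rank(
    records: Sequence[ComentionRecord],
    mode: str = "normalized",
    top_k: int | None = None,
    context_term: str = "aging",
) -> RankedList:
    """Rank genes by co-mention count (raw) or co/total fraction (normalized).

    Normalized mode excludes genes never mentioned at all (total_count 0).
    Ties are broken lexicographically on the symbol.
    """
    if mode not in ("raw", "normalized"):
        raise ValueError(f"unknown co-mention mode {mode!r}")
    scores = []
    for rec in records:
        if mode == "normalized":
            if rec.total_count == 0:
                continue
            value = rec.co_count / rec.total_count
        else:
            value = float(rec.co_count)
        scores.append(
            GeneScore(
                symbol=rec.symbol,
                raw_probability=value,
                final_score=value,
                log_raw=math.log(value) if value > 0 else float("-inf"),
                log_final=math.log(value) if value > 0 else float("-inf"),
            )
        )
    scores.sort(key=lambda s: (-s.final_score, s.symbol))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    meta = {"mode": mode, "context_term": context_term}
    if top_k is not None:
        meta["top_k"] = top_k
    return RankedList(label=f"comention:{context_term}", scores=tuple(scores),
                      metadata=meta)


def intersect_lists(lists: Mapping[str, set]) -> IntersectionReport:
    """Exclusive membership-pattern counts plus the all-lists common set."""
    if len(lists) < 2:
        raise ValueError("need at least two lists to intersect")
    labels = tuple(lists)
    membership: dict[str, frozenset] = {}
    for label, symbols in lists.items():
        for symbol in symbols:
            membership[symbol] = membership.get(symbol, frozenset()) | {label}
    patterns: dict[frozenset, int] = {}
    for pattern in membership.values():
        patterns[pattern] = patterns.get(pattern, 0) + 1
    all_labels = frozenset(labels)
    common = frozenset(
        s for s, pattern in membership.items() if pattern == all_labels
    )
    return IntersectionReport(labels=labels, patterns=patterns, common=common)


def occurrence_across_lists(
    lists: Mapping[str, set], min_lists: int = 1
) -> dict[str, int]:
    """Symbols appearing in at least ``min_lists`` of the lists, with counts."""
    if min_lists < 1:
        raise ValueError("min_lists must be >= 1")
    counts: dict[str, int] = {}
    for symbols in lists.values():
        for symbol in symbols:
            counts[symbol] = counts.get(symbol, 0) + 1
    return {s: c for s, c in counts.items() if c >= min_lists}


def write_intersection_report(report: IntersectionReport, patterns_path,
                              common_path) -> None:
    """Pattern/count TSV rows plus a plain-text common-set file."""
    with open(patterns_path, "w", encoding="utf-8") as fh:
        fh.write("pattern\tcount\n")
        ordered = sorted(
            report.patterns.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        )
        for pattern, count in ordered:
            fh.write("|".join(sorted(pattern)) + f"\t{count}\n")
    with open(common_path, "w", encoding="utf-8") as fh:
        for symbol in sorted(report.common):
            fh.write(symbol + "\n")
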