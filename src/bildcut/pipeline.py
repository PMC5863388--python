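"""End-to-end wiring: hits -> alignment -> cut scores -> outliers -> label.

This is the library-level engine behind the CLI and the synthetic
evaluation harness.  A query with no surviving hits is a normal
unclassified outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from bildcut import bild
from bildcut.bild import JEFFREYS, CutScoreSeries, DirichletPrior, cut_score_series
from bildcut.blast_io import BlastHit, filter_and_rank
from bildcut.classify import OutlierResult, call_outliers
from bildcut.msa import build_msa
from bildcut.taxonomy import Assignment, Lineage, assign


@dataclass(frozen=True)
class QueryResult:
    """Everything the pipeline produced for one query."""

    assignment: Assignment
    outliers: OutlierResult
    series: CutScoreSeries | None


def _unclassified(query_id: str) -> QueryResult:
    return QueryResult(
        assignment=Assignment(
            query_id=query_id, lineage=Lineage(()), depth=0, n_outliers=0
        ),
        outliers=OutlierResult(
            query_id=query_id,
            status="unclassified",
            peak_index=None,
            outlier_ids=(),
            peak_score=None,
        ),
        series=None,
    )


def classify_query(
    query_id: str,
    query_sequence: str,
    hits: Sequence[BlastHit],
    taxmap: Mapping[str, Lineage],
    *,
    prior: DirichletPrior = JEFFREYS,
    a: float = 2.7,
    coverage_min: float = 0.90,
    max_hits: int = 100,
) -> QueryResult:
    """Run the full method on one query and its raw BLAST hits."""
    ranked = filter_and_rank(
        hits, len(query_sequence), coverage_min=coverage_min, max_hits=max_hits
    )
    if not ranked.hits:
        return _unclassified(query_id)
    msa = build_msa(query_sequence, ranked)
    series = cut_score_series(msa, prior=prior, a=a)
    result = call_outliers(ranked, series)
    return QueryResult(
        assignment=assign(result, taxmap), outliers=result, series=series
    )


def classify_all(
    queries: Mapping[str, str],
    hits: Iterable[BlastHit],
    taxmap: Mapping[str, Lineage],
    **params,
) -> list[QueryResult]:
    """Classify every query in ``queries`` (id -> sequence).

    ``hits`` may interleave queries; they are grouped by query id here.
    Queries without any hit row are reported unclassified.  Results come
    back in the iteration order of ``queries``."""
    by_query: dict[str, list[BlastHit]] = {qid: [] for qid in queries}
    for h in hits:
        if h.query_id in by_query:
            by_query[h.query_id].append(h)
    return [
        classify_query(qid, seq, by_query[qid], taxmap, **params)
        for qid, seq in queries.items()
    ]


def write_assignment_table(results: Iterable[QueryResult], handle) -> None:
    """TSV: query_id, status, depth, lineage, n_outliers, peak_score."""
    handle.write("query_id\tstatus\tdepth\tlineage\tn_outliers\tpeak_score\n")
    for r in results:
        a = r.assignment
        peak = "" if r.outliers.peak_score is None else f"{r.outliers.peak_score:.4f}"
        handle.write(
            f"{a.query_id}\t{a.status}\t{a.depth}\t{a.lineage}\t{a.n_outliers}\t{peak}\n"
        )


def write_outlier_sets(results: Iterable[QueryResult], handle) -> None:
    """TSV: query_id, semicolon-joined outlier ids (classified queries only)."""
    for r in results:
        if r.outliers.classified:
            handle.write(f"{r.outliers.query_id}\t{';'.join(r.outliers.outlier_ids)}\n")


def read_outlier_sets(stream: Iterable[str]) -> list[list[str]]:
    """Parse the outlier-sets TSV written by :func:`write_outlier_sets`."""
    sets: list[list[str]] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        _, _, ids = line.partition("\t")
        sets.append([s for s in ids.split(";") if s])
    return sets


def write_all_series(results: Iterable[QueryResult], handle) -> None:
    """Concatenated per-query score-series dump for diagnostics."""
    for r in results:
        if r.series is not None:
            bild.write_score_series(r.series, handle)
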