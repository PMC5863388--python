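"""First-peak detection and the classify/unclassify decision.

Scanning the cut-score series from i = 0 upward, the first index whose
score is non-negative and strictly exceeds both neighbours marks the
boundary of the outlier set: the i hits grouped with the query above
that cut are its phylogenetically closest matches.  A series that never
peaks — or peaks at i = 0, grouping the query with nothing — leaves the
query unclassified, to be handled downstream by a phylogenetic method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from bildcut.bild import CutScoreSeries
from bildcut.blast_io import RankedHitSet
from bildcut.errors import ConsistencyError


@dataclass(frozen=True)
class OutlierResult:
    """Outcome of outlier detection for one query.

    ``outlier_ids`` is always a prefix of the ranked hit list; it is
    non-empty exactly when ``status`` is "classified"."""

    query_id: str
    status: str  # "classified" | "unclassified"
    peak_index: int | None
    outlier_ids: tuple[str, ...]
    peak_score: float | None

    @property
    def classified(self) -> bool:
        return self.status == "classified"


def find_first_peak(series: CutScoreSeries | Sequence[float]) -> int | None:
    """Return the first index i with V_i >= 0, V_i > V_{i-1}, V_i > V_{i+1}.

    Boundary handling: the first index needs only to dominate its right
    neighbour.  The last index is never a peak candidate — it is the
    degenerate cut with an empty bottom group, whose score is
    identically zero and carries no evidence for a split — so it serves
    only as right-neighbour context, and a single-point series has no
    peak.  Plateaus are not peaks — the strict inequalities are
    honoured as written.
    """
    scores = list(series.scores if isinstance(series, CutScoreSeries) else series)
    n = len(scores)
    for i, v in enumerate(scores[: n - 1]):
        if v < 0:
            continue
        if i > 0 and not v > scores[i - 1]:
            continue
        if not v > scores[i + 1]:
            continue
        return i
    return None


def call_outliers(ranked: RankedHitSet, series: CutScoreSeries) -> OutlierResult:
    """Extract the outlier set O_q from the first peak of the series.

    A peak at index p >= 1 classifies the query with the top-p hits as
    outliers; no peak, or a peak at 0, leaves it unclassified."""
    if len(series) != len(ranked.hits) + 1:
        raise ConsistencyError(
            f"query {ranked.query_id}: series length {len(series)} does not "
            f"match {len(ranked.hits)} ranked hits"
        )
    p = find_first_peak(series)
    if p is None or p == 0:
        return OutlierResult(
            query_id=ranked.query_id,
            status="unclassified",
            peak_index=None,
            outlier_ids=(),
            peak_score=None,
        )
    return OutlierResult(
        query_id=ranked.query_id,
        status="classified",
        peak_index=p,
        outlier_ids=ranked.subject_ids[:p],
        peak_score=float(series[p]),
    )
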