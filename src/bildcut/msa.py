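"""Query-anchored multiple alignment imposed from pairwise BLAST alignments.

The alignment M has one column per query position (1..len(query)) and one
row per sequence, the query first, then the hits in ranked order.  Each
hit row is filled by walking its pairwise alignment: columns where the
query segment is gapped (an insertion in the subject) are dropped for
that row, columns where the subject is gapped become null, and positions
outside the hit's query span are null.  No realignment is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from bildcut.blast_io import RankedHitSet
from bildcut.errors import ConsistencyError

# Row/column cell codes.  A..T index the count vector; NULL marks absent
# coverage or a subject deletion; AMBIG marks IUPAC-ambiguous letters,
# which count as null for scoring but are tracked separately.
A, C, G, T, NULL, AMBIG = 0, 1, 2, 3, 4, 5

_CODE = {"A": A, "C": C, "G": G, "T": T, "U": T}
_CHAR = {A: "A", C: "C", G: "G", T: "T", NULL: "-", AMBIG: "N"}


def _encode(base: str) -> int:
    return _CODE.get(base, AMBIG)


@dataclass(frozen=True)
class ColumnCounts:
    """Nucleotide counts of one alignment column over (A, C, G, T),
    ignoring null and ambiguous characters; ``c_star`` is their sum."""

    counts: tuple[int, int, int, int]

    @property
    def c_star(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class MultipleAlignment:
    """The imposed alignment: an (n_rows, m) code matrix, query row first."""

    query_id: str
    row_ids: tuple[str, ...]
    matrix: np.ndarray  # uint8 codes, shape (n_rows, m)

    @property
    def column_count(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_hits(self) -> int:
        return len(self.row_ids) - 1

    @property
    def rows(self) -> list[tuple[str, str]]:
        """Rows as (id, string) pairs; null rendered '-', ambiguous 'N'."""
        return [
            (rid, "".join(_CHAR[c] for c in row))
            for rid, row in zip(self.row_ids, self.matrix)
        ]


def build_msa(query_sequence: str, ranked: RankedHitSet) -> MultipleAlignment:
    """Impose the query-anchored alignment on the query and its ranked hits.

    Raises :class:`ConsistencyError` when a hit's query segment does not
    match the query sequence over its stated coordinates.
    """
    query_sequence = query_sequence.upper()
    m = len(query_sequence)
    if ranked.query_length != m:
        raise ConsistencyError(
            f"query {ranked.query_id}: sequence length {m} != ranked set "
            f"query_length {ranked.query_length}"
        )
    n_rows = len(ranked.hits) + 1
    mat = np.full((n_rows, m), NULL, dtype=np.uint8)
    mat[0] = [_encode(b) for b in query_sequence]

    for r, hit in enumerate(ranked.hits, start=1):
        qpos = hit.q_start - 1  # 0-based query cursor
        for qc, sc in zip(hit.q_segment, hit.s_segment):
            if qc == "-":
                # insertion in the subject relative to the query: dropped
                continue
            if qc != query_sequence[qpos]:
                raise ConsistencyError(
                    f"hit {hit.query_id}/{hit.subject_id}: query segment "
                    f"letter {qc!r} at query position {qpos + 1} does not "
                    f"match query sequence letter {query_sequence[qpos]!r}"
                )
            if sc != "-":
                mat[r, qpos] = _encode(sc)
            # subject deletion leaves NULL
            qpos += 1
        if qpos != hit.q_end:
            raise ConsistencyError(
                f"hit {hit.query_id}/{hit.subject_id}: segment walk ended at "
                f"query position {qpos} but q_end is {hit.q_end}"
            )
    return MultipleAlignment(
        query_id=ranked.query_id,
        row_ids=(ranked.query_id,) + ranked.subject_ids,
        matrix=mat,
    )


def column_counts(
    msa: MultipleAlignment,
    j: int,
    rows: Iterable[int] | None = None,
) -> ColumnCounts:
    """Counts of A, C, G, T at 1-based column ``j`` over the selected rows
    (all rows when ``rows`` is None).  Null and ambiguous cells contribute
    nothing."""
    if not 1 <= j <= msa.column_count:
        raise IndexError(
            f"column {j} out of range 1..{msa.column_count}"
        )
    col = msa.matrix[:, j - 1]
    if rows is not None:
        col = col[np.fromiter(rows, dtype=np.intp)]
    counts = np.bincount(col, minlength=6)[:4]
    return ColumnCounts(counts=tuple(int(x) for x in counts))


def count_matrix(msa: MultipleAlignment, rows: Sequence[int] | None = None) -> np.ndarray:
    """(m, 4) integer count matrix over the selected rows — the vectorised
    counterpart of :func:`column_counts` used by the scoring core."""
    mat = msa.matrix if rows is None else msa.matrix[np.asarray(rows, dtype=np.intp)]
    onehot = mat[:, :, None] == np.arange(4, dtype=np.uint8)
    return onehot.sum(axis=0)


def write_fasta(msa: MultipleAlignment, handle) -> None:
    """Dump the alignment as multi-FASTA for inspection (null as '-')."""
    for rid, row in msa.rows:
        handle.write(f">{rid}\n{row}\n")
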