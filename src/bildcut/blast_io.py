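"""Reading, validating, filtering and ranking BLAST tabular hits.

The expected input is BLAST+ ``-outfmt 6`` with exactly these 14 columns::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore qseq sseq

i.e. the standard 12 columns plus the two aligned segment strings, which
are required to impose the query-anchored multiple alignment downstream.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from bildcut.errors import BlastParseError, ConsistencyError, ValidationError

#: The exact outfmt specification the parser expects.
OUTFMT = (
    "6 qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qseq sseq"
)

_N_FIELDS = 14


@dataclass(frozen=True)
class BlastHit:
    """One high-scoring segment pair (HSP) from a BLAST tabular row.

    Coordinates are 1-based inclusive, as BLAST reports them.  The two
    segment strings are the aligned query and subject sequences over
    ``{A,C,G,T,N,-}`` and have equal length ``aln_length``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    q_segment: str
    s_segment: str

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError`."""
        if len(self.q_segment) != len(self.s_segment):
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: aligned segments have "
                f"unequal lengths {len(self.q_segment)} != {len(self.s_segment)}"
            )
        if len(self.q_segment) != self.aln_length:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: segment length "
                f"{len(self.q_segment)} != reported alignment length {self.aln_length}"
            )
        if self.q_start > self.q_end:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: q_start {self.q_start} "
                f"> q_end {self.q_end}"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: negative E-value"
            )
        for q, s in zip(self.q_segment, self.s_segment):
            if q == "-" and s == "-":
                raise ValidationError(
                    f"hit {self.query_id}/{self.subject_id}: column gapped in "
                    "both segments"
                )
        span = self.q_end - self.q_start + 1
        n_res = sum(1 for q in self.q_segment if q != "-")
        if n_res != span:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: query segment has "
                f"{n_res} residues but coordinates span {span}"
            )


@dataclass(frozen=True)
class RankedHitSet:
    """The ordered hit set S_q for one query: coverage-filtered hits in
    decreasing bit-score order, truncated to the top ``max_hits``."""

    query_id: str
    query_length: int
    hits: tuple[BlastHit, ...]

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(h.subject_id for h in self.hits)


def parse_blast_tab(stream: Iterable[str]) -> list[BlastHit]:
    """Parse BLAST tabular lines (14 columns, see :data:`OUTFMT`).

    Hits for multiple queries may be interleaved; file order is preserved.
    Blank lines are skipped.  Raises :class:`BlastParseError` naming the
    offending line on a malformed row, :class:`ValidationError` if a row
    parses but violates a hit invariant.
    """
    hits: list[BlastHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != _N_FIELDS:
            raise BlastParseError(
                f"line {lineno}: expected {_N_FIELDS} tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            hit = BlastHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                aln_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
                q_segment=fields[12].upper(),
                s_segment=fields[13].upper(),
            )
        except ValueError as exc:
            raise BlastParseError(f"line {lineno}: {exc}") from exc
        hit.validate()
        hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], handle) -> None:
    """Write hits back out in the 14-column tabular format."""
    for h in hits:
        handle.write(
            "\t".join(
                (
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.3f}",
                    str(h.aln_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    f"{h.e_value:.2e}",
                    f"{h.bit_score:.1f}",
                    h.q_segment,
                    h.s_segment,
                )
            )
            + "\n"
        )


def coverage(hit: BlastHit, query_length: int) -> float:
    """Fraction of the query's positions spanned by the hit's local alignment.

    Computed from query coordinates, ``(q_end - q_start + 1) / query_length``,
    so gap columns in the alignment do not inflate it.
    """
    if query_length < hit.q_end:
        raise ConsistencyError(
            f"hit {hit.query_id}/{hit.subject_id}: q_end {hit.q_end} exceeds "
            f"query length {query_length}"
        )
    return (hit.q_end - hit.q_start + 1) / query_length


def filter_and_rank(
    hits: Sequence[BlastHit],
    query_length: int,
    coverage_min: float = 0.90,
    max_hits: int = 100,
) -> RankedHitSet:
    """Build S_q: discard hits covering <= ``coverage_min`` of the query,
    sort the survivors by decreasing bit-score, keep the top ``max_hits``.

    The coverage cut is strict: a hit covering exactly ``coverage_min``
    is discarded.  Sorting is stable, so equal bit-scores keep their
    input (BLAST output) order.  All hits must share one query id.
    """
    query_ids = {h.query_id for h in hits}
    if len(query_ids) > 1:
        raise ValidationError(
            f"filter_and_rank called with mixed query ids: {sorted(query_ids)}"
        )
    query_id = next(iter(query_ids)) if query_ids else ""
    kept = [h for h in hits if coverage(h, query_length) > coverage_min]
    kept.sort(key=lambda h: -h.bit_score)
    return RankedHitSet(
        query_id=query_id, query_length=query_length, hits=tuple(kept[:max_hits])
    )


def run_blastn(
    query_fasta: str,
    database: str,
    max_target_seqs: int = 100,
) -> Iterator[str]:
    """Optional convenience wrapper: shell out to ``blastn -task megablast``
    with the exact outfmt this package parses, yielding output lines.

    Requires the NCBI BLAST+ ``blastn`` binary on PATH and a formatted
    nucleotide database.  Never used by the library itself.
    """
    cmd = (
        f"blastn -task megablast -query {shlex.quote(query_fasta)} "
        f"-db {shlex.quote(database)} -max_target_seqs {max_target_seqs} "
        f"-outfmt {shlex.quote(OUTFMT)}"
    )
    proc = subprocess.run(
        shlex.split(cmd), capture_output=True, text=True, check=True
    )
    yield from proc.stdout.splitlines()
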