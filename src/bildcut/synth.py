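"""Synthetic references, emulated BLAST tables, and leave-one-out scoring.

The generator grows a balanced six-rank taxonomy (Kingdom..Genus) from a
random root sequence by point substitution: the divergence vector gives,
per rank, the substitution fraction on branches from an ancestor of that
rank down to its children, with the Genus entry governing the spread of
individual sequences inside a genus.  Divergences therefore shrink from
Kingdom down to Genus, mimicking the nested similarity structure of 16S
rRNA reference sets.  Evolution is substitution-only by default, which
keeps the emulated BLAST rows exact, ungapped, end-to-end alignments; an
indel-free model does not exercise insertion dropping, so tests cover
that path with hand-built alignments instead.

The evaluation harness mirrors standard leave-one-out protocols: per
query, either the query's own sequence (leave_one_sequence_out) or its
whole genus (leave_one_genus_out) is removed from the database before
classification, and assignments are tallied per rank as correctly
classified, misclassified, or falsely unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from bildcut.bild import JEFFREYS, DirichletPrior
from bildcut.blast_io import BlastHit
from bildcut.errors import ValidationError
from bildcut.pipeline import classify_query
from bildcut.taxonomy import RANKS, Assignment, Lineage

_BASES = "ACGT"

#: Default per-rank divergences (Kingdom..Genus): branch substitution
#: fractions shrinking toward the leaves.  Genus 2% and Family 10% give
#: within-genus identities of ~96% and within-family identities of ~78%,
#: the strata of a 16S reference set; the upper ranks sit just above the
#: family level because 16S is globally conserved — making them much
#: larger would push within-order identities below anything BLAST could
#: align, which real 16S never does.
DEFAULT_DIVERGENCES = (0.13, 0.12, 0.11, 0.10, 0.10, 0.02)

LEAVE_ONE_SEQUENCE_OUT = "leave_one_sequence_out"
LEAVE_ONE_GENUS_OUT = "leave_one_genus_out"


@dataclass(frozen=True)
class SimulatedReference:
    """A simulated reference set with known six-rank taxonomy.

    ``sequences`` maps sequence id to nucleotide string; ``taxonomy``
    maps the same ids to full (depth-6) lineages.  Reproducible: the
    same seed yields byte-identical output."""

    sequences: dict[str, str]
    taxonomy: dict[str, Lineage]
    rank_divergences: tuple[float, ...]
    seed: int

    def genus_of(self, seq_id: str) -> str:
        return self.taxonomy[seq_id].ranks[-1]

    def write_fasta(self, handle) -> None:
        for sid in self.sequences:
            handle.write(f">{sid}\n{self.sequences[sid]}\n")

    def write_taxonomy(self, handle) -> None:
        for sid, lineage in self.taxonomy.items():
            handle.write(f"{sid}\t{lineage}\n")


def mutate(sequence: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ``round(fraction * len)`` distinct positions, each to a
    uniformly chosen different base."""
    if not 0 <= fraction <= 0.75:
        raise ValidationError(
            f"divergence {fraction} outside [0, 0.75] (0.75 is the expected "
            "distance between unrelated sequences)"
        )
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lookup[ord(b)] = i
    enc = lookup[codes]
    n_mut = round(fraction * len(sequence))
    if n_mut:
        pos = rng.choice(len(sequence), size=n_mut, replace=False)
        enc[pos] = (enc[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return "".join(_BASES[i] for i in enc)


def _rank_branching(n_genera: int) -> tuple[int, ...]:
    """Per-rank branching factors (Phylum..Genus) with product n_genera.

    Prime factors are assigned from the Genus level upward, largest
    first, so the fan-out grows toward the leaves the way real
    taxonomies do (many genera per family, fewer families per order)."""
    primes: list[int] = []
    n, p = n_genera, 2
    while n > 1:
        while n % p == 0:
            primes.append(p)
            n //= p
        p += 1 if p == 2 else 2
    factors = [1] * 5
    level = 4
    for p in sorted(primes, reverse=True):
        factors[level] *= p
        level = level - 1 if level > 0 else 4
    return tuple(factors)


def simulate_reference(
    n_genera: int = 20,
    seqs_per_genus: int = 5,
    length: int = 1500,
    rank_divergences: Sequence[float] = DEFAULT_DIVERGENCES,
    seed: int = 0,
) -> SimulatedReference:
    """Generate a reference set over a balanced taxonomy.

    A random root sequence (the single Kingdom ancestor) is mutated
    recursively down a b-ary tree of the five lower ranks; the first
    ``n_genera`` genus paths (depth-first order) each emit
    ``seqs_per_genus`` leaf sequences.  Divergences must not increase
    from Kingdom down to Genus and must each lie in [0, 0.75].
    """
    div = tuple(float(d) for d in rank_divergences)
    if len(div) != 6:
        raise ValidationError(f"need 6 per-rank divergences, got {len(div)}")
    for d in div:
        if not 0 <= d <= 0.75:
            raise ValidationError(f"divergence {d} outside [0, 0.75]")
    if any(lo > hi for hi, lo in zip(div, div[1:])):
        raise ValidationError(
            f"divergences must not increase from Kingdom to Genus: {div}"
        )
    if n_genera < 1 or seqs_per_genus < 1 or length < 1:
        raise ValidationError("n_genera, seqs_per_genus and length must be >= 1")

    rng = np.random.default_rng(seed)
    root = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    branching = _rank_branching(n_genera)
    genus_paths = list(product(*(range(b) for b in branching)))

    # Ancestor sequences created lazily, top-down, in depth-first genus
    # order, so the draw sequence (and hence the output) is seed-stable.
    ancestors: dict[tuple[int, ...], str] = {(): root}
    labels: dict[tuple[int, ...], str] = {(): "K1"}
    counters = [0] * 6  # label counters for Phylum..Genus (index 1..5)

    def node(path: tuple[int, ...]) -> str:
        if path not in ancestors:
            parent = node(path[:-1])
            rank_idx = len(path)  # 1 = Phylum .. 5 = Genus
            # branch from rank (rank_idx - 1) ancestor -> uses div[rank_idx - 1]
            ancestors[path] = mutate(parent, div[rank_idx - 1], rng)
            counters[rank_idx] += 1
            labels[path] = f"{RANKS[rank_idx][0]}{counters[rank_idx]}"
        return ancestors[path]

    sequences: dict[str, str] = {}
    taxonomy: dict[str, Lineage] = {}
    for path in genus_paths:
        genus_seq = node(path)
        lineage = Lineage(tuple(labels[path[:k]] for k in range(6)))
        genus_label = lineage.ranks[-1]
        for s in range(1, seqs_per_genus + 1):
            sid = f"{genus_label}_s{s}"
            sequences[sid] = mutate(genus_seq, div[5], rng)
            taxonomy[sid] = lineage
    return SimulatedReference(
        sequences=sequences, taxonomy=taxonomy, rank_divergences=div, seed=seed
    )


def emulate_blast(
    query_id: str,
    query: str,
    reference: SimulatedReference | Mapping[str, str],
    max_hits: int = 100,
    exclude_ids: Iterable[str] = (),
) -> list[BlastHit]:
    """Emulate the BLAST tabular output for one query.

    Each reference sequence is compared to the query as an ungapped
    end-to-end alignment (all sequences must share the query's length).
    The bit-score surrogate ``2*matches - 3*mismatches`` is strictly
    monotone in identity, which is all the downstream ranking uses; the
    E-value surrogate decays exponentially in it.  References scoring
    zero or below (identity <= 60%) produce no row at all, just as
    BLAST reports no alignment without a positive score — megablast
    would never return a full-length hit for sequences that diverged.
    Rows are sorted by surrogate descending (ties broken by subject id)
    and truncated to ``max_hits``.
    """
    seqs = (
        reference.sequences
        if isinstance(reference, SimulatedReference)
        else reference
    )
    excluded = set(exclude_ids)
    L = len(query)
    q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    rows: list[BlastHit] = []
    for sid, seq in seqs.items():
        if sid in excluded:
            continue
        if len(seq) != L:
            raise ValidationError(
                f"reference {sid} has length {len(seq)} != query length {L}; "
                "the indel-free emulation needs equal lengths"
            )
        s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        matches = int((q_arr == s_arr).sum())
        mismatches = L - matches
        bit = float(2 * matches - 3 * mismatches)
        if bit <= 0:
            continue
        rows.append(
            BlastHit(
                query_id=query_id,
                subject_id=sid,
                percent_identity=100.0 * matches / L,
                aln_length=L,
                mismatches=mismatches,
                gap_opens=0,
                q_start=1,
                q_end=L,
                s_start=1,
                s_end=L,
                e_value=float(L * L * 2.0 ** (-bit)) if bit < 1000 else 0.0,
                bit_score=bit,
                q_segment=query,
                s_segment=seq,
            )
        )
    rows.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return rows[:max_hits]


@dataclass(frozen=True)
class EvalCounts:
    """Per-rank leave-one-out tallies; the three counts at each rank sum
    to the number of queries."""

    correctly_classified: tuple[int, ...]
    misclassified: tuple[int, ...]
    falsely_unclassified: tuple[int, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "correctly_classified": self.correctly_classified,
                "misclassified": self.misclassified,
                "falsely_unclassified": self.falsely_unclassified,
            },
            index=list(RANKS),
        )


def evaluate(
    assignments: Sequence[Assignment],
    truth: Mapping[str, Lineage],
    db_lineages: Sequence[Lineage],
    mode: str = LEAVE_ONE_SEQUENCE_OUT,
) -> EvalCounts:
    """Tally assignments per rank against the known truth.

    At each rank a query is *correctly classified* when its assigned
    label matches the true label, or when it is unassigned and no other
    database sequence carries its true label; *misclassified* when the
    assigned label differs from the true label; *falsely unclassified*
    when it is unassigned although the true label exists independently
    in the database.  ``db_lineages`` is the full database lineage
    collection; ``mode`` controls what "independently" removes per
    query: one copy of the query's own lineage, or every lineage of the
    query's genus.
    """
    if mode not in (LEAVE_ONE_SEQUENCE_OUT, LEAVE_ONE_GENUS_OUT):
        raise ValidationError(f"unknown evaluation mode {mode!r}")
    prefix_counts: dict[tuple[str, ...], int] = {}
    full_counts: dict[tuple[str, ...], int] = {}
    for lin in db_lineages:
        for d in range(1, lin.depth + 1):
            key = lin.prefix(d)
            prefix_counts[key] = prefix_counts.get(key, 0) + 1
        if lin.depth == len(RANKS):
            full_counts[lin.ranks] = full_counts.get(lin.ranks, 0) + 1

    correct = [0] * len(RANKS)
    mis = [0] * len(RANKS)
    false_un = [0] * len(RANKS)
    for a in assignments:
        if a.query_id not in truth:
            raise ValidationError(f"assignment for unknown query {a.query_id!r}")
        t = truth[a.query_id]
        if t.depth != len(RANKS):
            raise ValidationError(
                f"query {a.query_id}: truth lineage must have all six ranks"
            )
        for r in range(len(RANKS)):
            true_prefix = t.prefix(r + 1)
            if a.depth > r:
                if a.lineage.prefix(r + 1) == true_prefix:
                    correct[r] += 1
                else:
                    mis[r] += 1
            else:
                n = prefix_counts.get(true_prefix, 0)
                if mode == LEAVE_ONE_SEQUENCE_OUT:
                    exists = n - 1 > 0  # remove the query's own sequence
                else:
                    # remove the query's whole genus: all sequences whose
                    # full lineage equals the query's
                    exists = n - full_counts.get(t.ranks, 0) > 0
                if exists:
                    false_un[r] += 1
                else:
                    correct[r] += 1
    return EvalCounts(
        correctly_classified=tuple(correct),
        misclassified=tuple(mis),
        falsely_unclassified=tuple(false_un),
    )


def run_leave_one_out(
    reference: SimulatedReference,
    mode: str = LEAVE_ONE_SEQUENCE_OUT,
    *,
    prior: DirichletPrior = JEFFREYS,
    a: float = 2.7,
    coverage_min: float = 0.90,
    max_hits: int = 100,
) -> tuple[list[Assignment], EvalCounts]:
    """Classify every reference sequence against the rest of the set.

    In ``leave_one_sequence_out`` mode only the query's own sequence is
    withheld; in ``leave_one_genus_out`` mode every sequence of the
    query's genus is.  Returns the per-query assignments and the
    per-rank tallies."""
    if mode not in (LEAVE_ONE_SEQUENCE_OUT, LEAVE_ONE_GENUS_OUT):
        raise ValidationError(f"unknown evaluation mode {mode!r}")
    assignments: list[Assignment] = []
    for qid, seq in reference.sequences.items():
        if mode == LEAVE_ONE_SEQUENCE_OUT:
            exclude = {qid}
        else:
            genus = reference.genus_of(qid)
            exclude = {
                sid
                for sid in reference.sequences
                if reference.genus_of(sid) == genus
            }
        hits = emulate_blast(
            qid, seq, reference, max_hits=max_hits, exclude_ids=exclude
        )
        result = classify_query(
            qid,
            seq,
            hits,
            reference.taxonomy,
            prior=prior,
            a=a,
            coverage_min=coverage_min,
            max_hits=max_hits,
        )
        assignments.append(result.assignment)
    counts = evaluate(
        assignments,
        reference.taxonomy,
        list(reference.taxonomy.values()),
        mode=mode,
    )
    return assignments, counts
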