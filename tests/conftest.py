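"""Shared fixtures and factories for the test suite."""

import math

import pytest

from bildcut.blast_io import BlastHit


def make_hit(
    query_id="q1",
    subject_id="s1",
    q_segment="ACGT",
    s_segment="ACGT",
    q_start=1,
    q_end=None,
    bit_score=100.0,
    **overrides,
):
    """BlastHit factory with consistent defaults for hand-built rows."""
    if q_end is None:
        q_end = q_start + sum(1 for c in q_segment if c != "-") - 1
    n = len(q_segment)
    mismatches = sum(
        1 for a, b in zip(q_segment, s_segment) if a != b and a != "-" and b != "-"
    )
    fields = dict(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * (n - mismatches) / n,
        aln_length=n,
        mismatches=mismatches,
        gap_opens=0,
        q_start=q_start,
        q_end=q_end,
        s_start=1,
        s_end=sum(1 for c in s_segment if c != "-"),
        e_value=1e-50,
        bit_score=bit_score,
        q_segment=q_segment,
        s_segment=s_segment,
    )
    fields.update(overrides)
    return BlastHit(**fields)


def polya_log_prob(counts, alpha=(0.5, 0.5, 0.5, 0.5)):
    """Independent oracle for the Dirichlet-multinomial marginal: the
    Polya-urn sequential product for one specific draw order.

    P = prod over draws of (alpha_k + n_k_seen) / (alpha* + n_seen);
    exchangeability makes the order irrelevant."""
    alpha_star = sum(alpha)
    logp = 0.0
    seen = 0
    for k, c in enumerate(counts):
        for j in range(c):
            logp += math.log((alpha[k] + j) / (alpha_star + seen))
            seen += 1
    return logp


@pytest.fixture(scope="session")
def small_reference():
    """A tiny seeded reference set shared by pipeline-level tests."""
    from bildcut import synth

    return synth.simulate_reference(
        n_genera=4, seqs_per_genus=3, length=400, seed=7
    )
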