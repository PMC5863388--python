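"""Entropy-weighted BILD (Bayesian Integral Log-Odds) cut scoring.

Each alignment column is scored by the log marginal probability of its
nucleotide count vector c under a Dirichlet(alpha) prior on the column's
nucleotide frequencies:

    L(c) = ln[ Gamma(a*) / Gamma(a* + c*) * prod_k Gamma(a_k + c_k) / Gamma(a_k) ]

with a* = sum(alpha) and c* = sum(c).  A horizontal cut splits a column
into sub-columns X and Y; the log-odds score for preferring the split is

    V = L(X) + L(Y) - L(X + Y).

Positive V means two independent columns explain the data better than
one.  The per-cut total over the alignment weights each column by the
a-th power of its base-4 entropy, so perfectly conserved columns (weight
0) are silent and maximally diverse columns (weight 1) count fully.

Natural logarithms are used throughout; the classification decision
depends only on signs and ordering, which are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from bildcut.errors import ValidationError
from bildcut.msa import ColumnCounts, MultipleAlignment, count_matrix


@dataclass(frozen=True)
class DirichletPrior:
    """Dirichlet prior over nucleotide frequencies; all components positive."""

    alpha: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if len(self.alpha) != 4 or any(a <= 0 for a in self.alpha):
            raise ValidationError(
                f"Dirichlet prior needs 4 positive components, got {self.alpha}"
            )

    @property
    def alpha_star(self) -> float:
        return float(sum(self.alpha))


#: Jeffreys' prior: all concentration parameters 1/2, alpha* = 2.
JEFFREYS = DirichletPrior((0.5, 0.5, 0.5, 0.5))


@dataclass(frozen=True)
class CutScoreSeries:
    """Entropy-weighted cut scores for one query.

    ``scores[i]`` is the score for the cut with the query plus the first
    ``i`` ranked hits above the cut; index 0 is the query alone, index
    n_hits puts every row above the cut (score identically 0)."""

    query_id: str
    scores: tuple[float, ...]
    a: float = 2.7
    alpha: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, i):
        return self.scores[i]


def _as_counts(counts) -> np.ndarray:
    arr = (
        np.asarray(counts.counts, dtype=float)
        if isinstance(counts, ColumnCounts)
        else np.asarray(counts, dtype=float)
    )
    if arr.shape[-1] != 4:
        raise ValidationError(f"count vector must have 4 components, got {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError("negative counts are not a valid column")
    return arr


def dirichlet_log_marginal(counts: np.ndarray, prior: DirichletPrior = JEFFREYS) -> np.ndarray:
    """Vectorised L over the trailing axis of 4 counts (natural log)."""
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(prior.alpha)
    c_star = counts.sum(axis=-1)
    return (
        gammaln(prior.alpha_star)
        - gammaln(prior.alpha_star + c_star)
        + (gammaln(alpha + counts) - gammaln(alpha)).sum(axis=-1)
    )


def column_log_prob(counts, prior: DirichletPrior = JEFFREYS) -> float:
    """L for one column: log marginal probability of its count vector."""
    return float(dirichlet_log_marginal(_as_counts(counts), prior))


def cut_score_column(x_counts, y_counts, prior: DirichletPrior = JEFFREYS) -> float:
    """Log-odds score V for splitting a column into sub-columns X and Y."""
    x = _as_counts(x_counts)
    y = _as_counts(y_counts)
    return float(
        dirichlet_log_marginal(x, prior)
        + dirichlet_log_marginal(y, prior)
        - dirichlet_log_marginal(x + y, prior)
    )


def column_entropy(counts) -> float:
    """Base-4 Shannon entropy of the column's nucleotide usage, in [0, 1].

    0 for a perfectly conserved column, 1 for uniform usage; defined as 0
    for an empty (all-null) column."""
    arr = _as_counts(counts)
    c_star = arr.sum()
    if c_star == 0:
        return 0.0
    p = arr[arr > 0] / c_star
    return float(-(p * (np.log(p) / np.log(4.0))).sum()) + 0.0


def _entropy_profile(full_counts: np.ndarray) -> np.ndarray:
    """Base-4 entropy per column of an (m, 4) count matrix; 0 where empty."""
    c_star = full_counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(c_star > 0, full_counts / np.maximum(c_star, 1), 0.0)
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1) / np.log(4.0)


def _log_marginal_table(counts: np.ndarray, prior: DirichletPrior) -> np.ndarray:
    """L over integer count arrays (..., 4) via log-gamma lookup tables.

    Exploits the fact that column counts are integers, so every gammaln
    argument is alpha + k for small integer k; one table per distinct
    alpha component replaces millions of gammaln evaluations."""
    c_star = counts.sum(axis=-1)
    n_max = int(c_star.max(initial=0))
    ks = np.arange(n_max + 1, dtype=float)
    tables = {a: gammaln(a + ks) for a in set(prior.alpha)}
    out = np.full(c_star.shape, gammaln(prior.alpha_star), dtype=float)
    out -= gammaln(prior.alpha_star + c_star)
    for k, a in enumerate(prior.alpha):
        out += tables[a][counts[..., k]] - gammaln(a)
    return out


def cut_score_series(
    msa: MultipleAlignment,
    prior: DirichletPrior = JEFFREYS,
    a: float = 2.7,
) -> CutScoreSeries:
    """Score every horizontal cut of the alignment.

    Cut ``i`` groups the query and the first ``i`` hit rows above the
    cut; V_i sums the per-column split scores weighted by (e_j)^a, where
    e_j is the base-4 entropy of the FULL column (all rows).  Columns
    with no informative character are skipped (weight and score both 0).
    """
    if msa.n_hits < 1:
        raise ValidationError(
            f"query {msa.query_id}: cut scoring needs at least one hit row"
        )
    if a <= 0:
        raise ValidationError(f"entropy exponent a must be positive, got {a}")

    onehot = (msa.matrix[:, :, None] == np.arange(4, dtype=np.uint8)).astype(np.int64)
    full = onehot.sum(axis=0)  # (m, 4)
    weights = _entropy_profile(full) ** a

    # top[i] = counts over {query, hit_1..hit_i}; shape (n_rows, m, 4)
    top = np.cumsum(onehot, axis=0)
    bottom = full[None, :, :] - top
    l_full = _log_marginal_table(full, prior)  # (m,)
    v_ji = (
        _log_marginal_table(top, prior)
        + _log_marginal_table(bottom, prior)
        - l_full[None, :]
    )
    scores = (weights[None, :] * v_ji).sum(axis=1)
    return CutScoreSeries(
        query_id=msa.query_id,
        scores=tuple(float(s) for s in scores),
        a=a,
        alpha=tuple(prior.alpha),
    )


def write_score_series(series: CutScoreSeries, handle) -> None:
    """TSV dump (cut index, score) for diagnostics."""
    handle.write(f"# query={series.query_id}\ta={series.a}\talpha={series.alpha}\n")
    for i, v in enumerate(series.scores):
        handle.write(f"{i}\t{v:.6f}\n")
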