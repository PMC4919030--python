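"""Smith–Waterman local alignment with PRSS-style shuffle significance.

The homology criterion of the survey: align two sequences locally
(affine gaps, BLOSUM50, open −10 / extend −2), estimate significance by
re-aligning against 200 random permutations of the subject, fit a Gumbel
(extreme-value) distribution to the shuffle scores by the method of moments,
and call homology when the expect value falls below 1e-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scoring import ScoringScheme, encode

EULER_GAMMA = 0.5772156649015329


class DegenerateNullError(RuntimeError):
    """Shuffle scores have zero variance, so no extreme-value fit exists
    (e.g. a homopolymer subject is invariant under permutation)."""


@dataclass
class LocalAlignment:
    """One optimal local alignment.

    Intervals are 0-based half-open on the unaligned sequences.
    ``column_states`` is one of ``match | mismatch | subject_gap | query_gap``
    per aligned column; ``identity_percent`` uses all aligned columns
    (including gap columns) as the denominator by default.
    """

    score: int
    query_interval: tuple
    subject_interval: tuple
    column_states: list
    query_aln: str = ""
    subject_aln: str = ""
    identity_denominator: str = "columns"

    @property
    def overlap_length(self) -> int:
        return len(self.column_states)

    @property
    def identity_percent(self) -> float:
        matches = sum(1 for c in self.column_states if c == "match")
        if self.identity_denominator == "matched":
            denom = sum(1 for c in self.column_states if c in ("match", "mismatch"))
        else:
            denom = self.overlap_length
        return 100.0 * matches / denom if denom else 0.0


@dataclass
class ShuffleSignificance:
    """Observed score against the permutation null of one subject."""

    n_shuffles: int
    observed_score: int
    shuffle_scores: np.ndarray
    gumbel_mu: float
    gumbel_lambda: float
    p_value: float
    #: Expect value under the single-comparison convention: E() = p.
    expect: float

    @property
    def expect_per_shuffle_set(self) -> float:
        """Alternative normalisation: expected hits among the shuffles."""
        return self.p_value * self.n_shuffles


def _score_diag(qc: np.ndarray, sc: np.ndarray, scheme: ScoringScheme) -> int:
    """Score-only affine local alignment, vectorised over anti-diagonals."""
    m, n = len(qc), len(sc)
    if m == 0 or n == 0:
        return 0
    S = scheme.matrix
    ge = scheme.gap_extend
    goe = scheme.gap_open + scheme.gap_extend
    NEG = -(10 ** 9)
    # cell (i, j), 1-based, lives at index i of the diagonal d = i + j
    h0 = np.zeros(m + 1)          # d - 2
    h1 = np.zeros(m + 1)          # d - 1
    e1 = np.full(m + 1, NEG, dtype=float)
    f1 = np.full(m + 1, NEG, dtype=float)
    best = 0.0
    # substitution scores per diagonal need subject reversed
    for d in range(2, m + n + 1):
        lo = max(1, d - n)
        hi = min(m, d - 1)
        h2 = np.zeros(m + 1)
        e2 = np.full(m + 1, NEG, dtype=float)
        f2 = np.full(m + 1, NEG, dtype=float)
        sub = S[qc[lo - 1:hi], sc[d - lo - 1:d - hi - 2 if d - hi - 2 >= 0 else None:-1]]
        e2[lo:hi + 1] = np.maximum(h1[lo - 1:hi] + goe, e1[lo - 1:hi] + ge)
        f2[lo:hi + 1] = np.maximum(h1[lo:hi + 1] + goe, f1[lo:hi + 1] + ge)
        h = h0[lo - 1:hi] + sub
        np.maximum(h, e2[lo:hi + 1], out=h)
        np.maximum(h, f2[lo:hi + 1], out=h)
        np.maximum(h, 0.0, out=h)
        h2[lo:hi + 1] = h
        m_d = h.max() if len(h) else 0.0
        if m_d > best:
            best = m_d
        h0, h1, e1, f1 = h1, h2, e2, f2
    return int(best)


def _fill_matrices(qc, sc, scheme):
    """Full H/E/F dynamic-programming matrices (for traceback)."""
    m, n = len(qc), len(sc)
    S = scheme.matrix
    ge = scheme.gap_extend
    goe = scheme.gap_open + scheme.gap_extend
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG, dtype=float)  # gap in subject (vertical)
    F = np.full((m + 1, n + 1), NEG, dtype=float)  # gap in query (horizontal)
    for d in range(2, m + n + 1):
        lo = max(1, d - n)
        hi = min(m, d - 1)
        ii = np.arange(lo, hi + 1)
        jj = d - ii
        E[ii, jj] = np.maximum(H[ii - 1, jj] + goe, E[ii - 1, jj] + ge)
        F[ii, jj] = np.maximum(H[ii, jj - 1] + goe, F[ii, jj - 1] + ge)
        h = H[ii - 1, jj - 1] + S[qc[ii - 1], sc[jj - 1]]
        np.maximum(h, E[ii, jj], out=h)
        np.maximum(h, F[ii, jj], out=h)
        np.maximum(h, 0.0, out=h)
        H[ii, jj] = h
    return H, E, F


def smith_waterman(query: str, subject: str, scheme: ScoringScheme | None = None,
                   identity_denominator: str = "columns") -> LocalAlignment:
    """Optimal affine-gap local alignment of two protein sequences.

    Traceback tie-break: diagonal over subject-gap over query-gap; among
    equal-scoring end cells the lexicographically smallest
    (query_end, subject_end) is chosen; within a gap run, closing the gap is
    preferred over extending when scores tie.
    """
    scheme = scheme or ScoringScheme()
    qc, sc = encode(query), encode(subject)
    if len(qc) == 0 or len(sc) == 0:
        return LocalAlignment(0, (0, 0), (0, 0), [],
                              identity_denominator=identity_denominator)
    H, E, F = _fill_matrices(qc, sc, scheme)
    best = H.max()
    if best <= 0:
        return LocalAlignment(0, (0, 0), (0, 0), [],
                              identity_denominator=identity_denominator)
    ends = np.argwhere(H == best)
    i, j = min((int(a), int(b)) for a, b in ends)
    qe, se = i, j
    S = scheme.matrix
    ge = scheme.gap_extend
    goe = scheme.gap_open + scheme.gap_extend
    cols = []
    qa, sa = [], []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + S[qc[i - 1], sc[j - 1]] if i > 0 and j > 0 else None
            if diag is not None and H[i, j] == diag:
                cols.append("match" if query[i - 1].upper() == subject[j - 1].upper()
                            else "mismatch")
                qa.append(query[i - 1])
                sa.append(subject[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in subject, consumes query residue
            cols.append("subject_gap")
            qa.append(query[i - 1])
            sa.append("-")
            if E[i, j] == H[i - 1, j] + goe:
                state = "H"
            i -= 1
        else:  # F: gap in query, consumes subject residue
            cols.append("query_gap")
            qa.append("-")
            sa.append(subject[j - 1])
            if F[i, j] == H[i, j - 1] + goe:
                state = "H"
            j -= 1
    cols.reverse()
    qa.reverse()
    sa.reverse()
    return LocalAlignment(int(best), (i, qe), (j, se), cols,
                          "".join(qa), "".join(sa),
                          identity_denominator=identity_denominator)


def sw_score(query: str, subject: str, scheme: ScoringScheme | None = None) -> int:
    """Score-only Smith–Waterman (fast path used by the shuffle null)."""
    scheme = scheme or ScoringScheme()
    return _score_diag(encode(query), encode(subject), scheme)


def fit_gumbel(scores: np.ndarray) -> tuple:
    """Method-of-moments Gumbel fit: lambda = pi/(sigma*sqrt(6)),
    mu = mean - euler_gamma/lambda."""
    scores = np.asarray(scores, dtype=float)
    sigma = scores.std(ddof=1)
    if sigma == 0:
        raise DegenerateNullError(
            "shuffle scores have zero variance; the permutation null is "
            "degenerate (subject may be permutation-invariant)")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = scores.mean() - EULER_GAMMA / lam
    return mu, lam


def gumbel_sf(score: float, mu: float, lam: float) -> float:
    """P(S >= score) under Gumbel(mu, lambda): 1 - exp(-exp(-lam (s - mu)))."""
    z = min(-lam * (score - mu), 700.0)  # exp overflow guard; tail is 1 anyway
    return float(-np.expm1(-np.exp(z)))


def shuffle_significance(query: str, subject: str, scheme: ScoringScheme | None = None,
                         n_shuffles: int = 200, seed: int = 0) -> ShuffleSignificance:
    """PRSS-style significance: the subject is uniformly permuted
    ``n_shuffles`` times, each permutation re-aligned to the query, and a
    Gumbel is fitted to the null scores.  ``expect`` is the tail probability
    of the observed score under that fit (single-comparison convention)."""
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    scheme = scheme or ScoringScheme()
    qc, sc = encode(query), encode(subject)
    observed = _score_diag(qc, sc, scheme)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles, dtype=float)
    for k in range(n_shuffles):
        null[k] = _score_diag(qc, rng.permutation(sc), scheme)
    mu, lam = fit_gumbel(null)
    p = gumbel_sf(observed, mu, lam)
    return ShuffleSignificance(n_shuffles, observed, null, mu, lam, p, p)


def is_homolog(sig: ShuffleSignificance, threshold: float = 1e-3) -> bool:
    """Homology call at the survey's cutoff: expect strictly below 1e-3."""
    return sig.expect < threshold
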