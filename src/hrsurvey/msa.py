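"""Multiple alignment: k-mer distances, UPGMA guide tree, and a single-pass
progressive profile–profile aligner.

This replaces an external aligner at desk scale: sequences are clustered on
shared k-mer fractions, then aligned bottom-up along the guide tree with
affine-gap global profile alignment (average-of-pairs substitution scores).
Iterative refinement is deliberately omitted; downstream parameter-recovery
checks gate alignment quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .scoring import ALPHABET, ScoringScheme, encode
from .tree import Node, Tree

log = logging.getLogger(__name__)

GAP = 21  # index of the gap "residue" in profile columns


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class MultipleAlignment:
    """Rows of (id, gapped sequence), all the same length."""

    rows: list

    def __post_init__(self):
        if self.rows:
            w = len(self.rows[0][1])
            if any(len(s) != w for _, s in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list:
        return [r[0] for r in self.rows]

    def ungapped(self, seq_id: str) -> str:
        for rid, s in self.rows:
            if rid == seq_id:
                return s.replace("-", "")
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)

    def to_fasta(self, path):
        from .io import write_fasta
        write_fasta(path, self.rows)

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        from .io import read_fasta
        return cls(read_fasta(path))

    def to_stockholm(self, path):
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            width = max(len(r[0]) for r in self.rows) + 2
            for rid, s in self.rows:
                fh.write(f"{rid:<{width}}{s}\n")
            fh.write("//\n")

    @classmethod
    def from_stockholm(cls, path) -> "MultipleAlignment":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line or line.startswith(("#", "//")):
                    continue
                rid, seq = line.split(None, 1)
                rows.append((rid, seq.replace(".", "-").strip()))
        return cls(rows)


def kmer_distance(seqs: list, k: int = 3) -> DistanceMatrix:
    """d(a, b) = 1 - |K_a & K_b| / min(|K_a|, |K_b|) over k-mer sets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = [s[0] for s in seqs]
    sets = []
    for rid, seq in seqs:
        if len(seq) < k:
            log.warning("sequence %s shorter than k=%d; distance 1 to all", rid, k)
            sets.append(frozenset())
        else:
            sets.append(frozenset(seq[i:i + k] for i in range(len(seq) - k + 1)))
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            frac = len(sets[i] & sets[j]) / denom if denom else 0.0
            m[i, j] = m[j, i] = 1.0 - frac
    return DistanceMatrix(labels, m)


def upgma(dm: DistanceMatrix) -> Tree:
    """Average-linkage clustering into a rooted ultrametric guide tree.

    Ties are broken by the lexicographically smallest pair of cluster
    representative labels, so the result is deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    d = {frozenset([i]): {} for i in range(n)}
    clusters = {frozenset([i]): (Node(dm.labels[i]), 0.0, 1) for i in range(n)}
    keys = list(clusters)
    dist = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(keys[a], keys[b])] = dm.matrix[a, b]

    def rep(c):
        return min(dm.labels[i] for i in c)

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    while len(clusters) > 1:
        pair = min(((a, b) for i, a in enumerate(clusters) for b in list(clusters)[i + 1:]),
                   key=lambda ab: (get(*ab), tuple(sorted((rep(ab[0]), rep(ab[1]))))))
        a, b = pair
        na, ha, ca = clusters[a]
        nb, hb, cb = clusters[b]
        height = get(a, b) / 2.0
        parent = Node()
        na.length = max(height - ha, 0.0)
        nb.length = max(height - hb, 0.0)
        parent.add(na)
        parent.add(nb)
        merged = a | b
        del clusters[a], clusters[b]
        for c in clusters:
            dist[(merged, c)] = (get(a, c) * ca + get(b, c) * cb) / (ca + cb)
        clusters[merged] = (parent, height, ca + cb)
    (root, _, _), = clusters.values()
    return Tree(root)


def _profile_freqs(rows: list) -> np.ndarray:
    """Column frequency matrix over the 22-symbol space (20 aa, X, gap)."""
    L = len(rows[0][1])
    F = np.zeros((L, 22))
    code = {aa: i for i, aa in enumerate(ALPHABET)}
    for _, s in rows:
        for j, ch in enumerate(s):
            F[j, GAP if ch == "-" else code.get(ch.upper(), 20)] += 1
    return F / len(rows)


def _pair_score_matrix(scheme: ScoringScheme) -> np.ndarray:
    """22x22 column-pair scores: residues from the substitution matrix,
    gap-vs-residue = gap_extend, gap-vs-gap = 0."""
    S = np.zeros((22, 22))
    S[:21, :21] = scheme.matrix
    S[GAP, :21] = scheme.gap_extend
    S[:21, GAP] = scheme.gap_extend
    S[GAP, GAP] = 0.0
    return S


def _align_profiles(rows_a: list, rows_b: list, scheme: ScoringScheme) -> list:
    """Global affine alignment of two profiles (once a gap, always a gap)."""
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    M = FA @ _pair_score_matrix(scheme) @ FB.T
    m, n = M.shape
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    NEG = -1e30
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in B (consumes A column)
    F = np.full((m + 1, n + 1), NEG)  # gap in A
    H[0, 0] = 0.0
    for i in range(1, m + 1):
        E[i, 0] = go + ge * i
        H[i, 0] = E[i, 0]
    for j in range(1, n + 1):
        F[0, j] = go + ge * j
        H[0, j] = F[0, j]
    for i in range(1, m + 1):
        Mi = M[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i - 1, j] + go + ge, E[i - 1, j] + ge)
            F[i, j] = max(H[i, j - 1] + go + ge, F[i, j - 1] + ge)
            H[i, j] = max(H[i - 1, j - 1] + Mi[j - 1], E[i, j], F[i, j])
    # traceback: prefer diagonal, then gap-in-B, then gap-in-A
    i, j = m, n
    ops = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + M[i - 1, j - 1]:
                ops.append("D")
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("A")  # column from A, gap in B
            if E[i, j] == H[i - 1, j] + go + ge or i == 1:
                state = "H"
            i -= 1
        else:
            ops.append("B")
            if F[i, j] == H[i, j - 1] + go + ge or j == 1:
                state = "H"
            j -= 1
    ops.reverse()
    out_a = {rid: [] for rid, _ in rows_a}
    out_b = {rid: [] for rid, _ in rows_b}
    ia = jb = 0
    for op in ops:
        if op in ("D", "A"):
            for rid, s in rows_a:
                out_a[rid].append(s[ia])
            ia += 1
        else:
            for rid, _ in rows_a:
                out_a[rid].append("-")
        if op in ("D", "B"):
            for rid, s in rows_b:
                out_b[rid].append(s[jb])
            jb += 1
        else:
            for rid, _ in rows_b:
                out_b[rid].append("-")
    rows = [(rid, "".join(out_a[rid])) for rid, _ in rows_a]
    rows += [(rid, "".join(out_b[rid])) for rid, _ in rows_b]
    return rows


def progressive_align(seqs: list, scheme: ScoringScheme | None = None,
                      guide: Tree | None = None, k: int = 3) -> MultipleAlignment:
    """Align sequences bottom-up along a guide tree (UPGMA on k-mer
    distances unless one is supplied)."""
    scheme = scheme or ScoringScheme()
    seqs = list(seqs)
    if len(seqs) == 1:
        return MultipleAlignment(seqs)
    if guide is None:
        guide = upgma(kmer_distance(seqs, k=k))
    by_id = dict(seqs)
    if set(guide.leaf_names()) != set(by_id):
        raise ValueError("guide tree leaves do not match sequence ids")
    for seq_id, s in seqs:
        encode(s)  # validate alphabet early

    def build(node: Node) -> list:
        if node.is_leaf:
            return [(node.name, by_id[node.name])]
        sub = [build(c) for c in node.children]
        rows = sub[0]
        for other in sub[1:]:
            rows = _align_profiles(rows, other, scheme)
        return rows

    rows = build(guide.root)
    order = {rid: i for i, (rid, _) in enumerate(seqs)}
    rows.sort(key=lambda r: order[r[0]])
    return MultipleAlignment(rows)


def average_pair_score(aln: MultipleAlignment, scheme: ScoringScheme | None = None) -> float:
    """Mean over row pairs of the summed column scores (gap convention as in
    the profile aligner); used as a coarse alignment-quality figure."""
    scheme = scheme or ScoringScheme()
    F = _profile_freqs(aln.rows) * len(aln.rows)  # counts
    S = _pair_score_matrix(scheme)
    n = len(aln.rows)
    total = 0.0
    for j in range(aln.n_columns):
        c = F[j]
        total += 0.5 * (c @ S @ c - (c * np.diag(S)).sum())
    return total / (n * (n - 1) / 2)
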