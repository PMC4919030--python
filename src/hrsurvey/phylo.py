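"""Maximum-likelihood phylogenetics under LG+Gamma.

The inference path mirrors the survey's tree protocol at desk scale:
neighbour-joining start tree on pairwise ML distances, Felsenstein-pruning
likelihood with discrete-gamma rate categories, per-branch scalar
optimisation, NNI hill-climbing, aLRT branch supports from the chi-square
mixture, collapse of branches below 0.6 support, midpoint (or outgroup)
rooting, monophyly tests and site bootstrap.

SPR moves are deliberately omitted: at the problem sizes this package
targets, NNI search from an NJ start recovers simulated topologies, which is
what the validation relies on (rather than matching any particular
optimiser's exact optimum).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .msa import DistanceMatrix, MultipleAlignment
from .ratemodel import RateModel
from .scoring import AMINO_ACIDS
from .tree import Node, Tree

log = logging.getLogger(__name__)

BRANCH_MIN, BRANCH_MAX = 1e-8, 20.0
MISSING = 20


# ---------------------------------------------------------------------------
# site patterns and pruning likelihood
# ---------------------------------------------------------------------------

@dataclass
class SitePatternTable:
    tip_order: list
    patterns: np.ndarray       # (n_tips, n_patterns) int codes, 20 = missing
    weights: np.ndarray        # multiplicities, sum = alignment length

    @classmethod
    def from_alignment(cls, aln: MultipleAlignment) -> "SitePatternTable":
        code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        mat = np.array([[code.get(ch.upper(), MISSING) for ch in seq]
                        for _, seq in aln.rows], dtype=np.int8)
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        return cls([rid for rid, _ in aln.rows], patterns, weights)


class _Pruner:
    """Caches tip partials and evaluates the category-averaged pruning
    likelihood of a rooted (or anchor-rooted unrooted) tree."""

    def __init__(self, aln: MultipleAlignment, model: RateModel):
        self.model = model
        self.table = SitePatternTable.from_alignment(aln)
        self.tip_partials = {}
        P = self.table.patterns.shape[1]
        eye = np.vstack([np.eye(20), np.ones(20)])  # code 20 -> missing
        for row, tip in enumerate(self.table.tip_order):
            self.tip_partials[tip] = eye[self.table.patterns[row]]  # (P, 20)

    def log_likelihood(self, tree: Tree) -> float:
        tips = set(tree.leaf_names())
        if tips != set(self.table.tip_order):
            raise ValueError("tree tips do not match alignment rows")
        model = self.model
        ncat = model.n_categories
        P = self.table.patterns.shape[1]

        def partial(node: Node) -> np.ndarray:   # (ncat, P, 20)
            if node.is_leaf:
                base = self.tip_partials[node.name]
                return np.broadcast_to(base, (ncat, P, 20))
            out = np.ones((ncat, P, 20))
            for child in node.children:
                mats = model.category_matrices(max(child.length, 0.0))
                out = out * np.matmul(partial(child), mats.transpose(0, 2, 1))
            return out

        root = partial(tree.root)
        site = np.tensordot(root, model.frequencies, axes=([2], [0]))  # (ncat, P)
        site = (site * model.weights[:, None]).sum(axis=0)
        if np.any(site <= 0):
            return -np.inf
        return float(self.table.weights @ np.log(site))


def log_likelihood(tree: Tree, aln: MultipleAlignment, model: RateModel) -> float:
    """Category-averaged pruning log-likelihood; gaps/X are missing data."""
    if len(aln.rows) == 1:
        code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        freqs = model.frequencies
        return float(sum(math.log(freqs[code[ch]]) for ch in aln.rows[0][1]
                         if ch.upper() in code))
    return _Pruner(aln, model).log_likelihood(tree)


# ---------------------------------------------------------------------------
# distances and neighbour joining
# ---------------------------------------------------------------------------

def ml_distance(seq_a: str, seq_b: str, model: RateModel) -> float:
    """Pairwise ML distance under the model (gamma-averaged)."""
    code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, 20))
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in code and b in code:
            counts[code[a], code[b]] += 1
    if counts.sum() == 0:
        return BRANCH_MAX
    freqs = model.frequencies

    def nll(t):
        mats = model.category_matrices(t)
        joint = (mats * model.weights[:, None, None]).sum(axis=0)
        probs = freqs[:, None] * joint
        with np.errstate(divide="ignore"):
            lp = np.where(counts > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
        return -(counts * lp).sum()

    res = minimize_scalar(nll, bounds=(1e-6, BRANCH_MAX), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def ml_distance_matrix(aln: MultipleAlignment, model: RateModel) -> DistanceMatrix:
    labels = aln.ids
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = ml_distance(aln.rows[i][1], aln.rows[j][1], model)
    return DistanceMatrix(labels, m)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining; unrooted (trifurcating anchor node).
    Negative branch-length estimates are clamped to zero.  Ties in the
    Q-criterion are broken by the lexicographically smallest label pair."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = {lbl: Node(lbl) for lbl in labels}
    if n == 2:
        root = Node()
        a, b = labels
        nodes[a].length = dm.matrix[0, 1] / 2
        nodes[b].length = dm.matrix[0, 1] / 2
        root.add(nodes[a])
        root.add(nodes[b])
        return Tree(root)
    active = labels[:]
    d = {frozenset((a, b)): dm.matrix[i, j]
         for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}

    def dist(a, b):
        return d[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        sums = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * dist(a, b) - sums[a] - sums[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        da = 0.5 * dist(a, b) + (sums[a] - sums[b]) / (2 * (r - 2))
        db = dist(a, b) - da
        if da < 0 or db < 0:
            log.debug("NJ clamped a negative branch length")
        parent = Node(name=f"__{a}+{b}")
        nodes[a].length = max(da, 0.0)
        nodes[b].length = max(db, 0.0)
        parent.add(nodes[a])
        parent.add(nodes[b])
        new = parent.name
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new, c))] = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        active = [c for c in active if c not in (a, b)] + [new]
        nodes[new] = parent
    root = Node()
    if len(active) == 3:
        x, y, z = active
        lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
        ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
        lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
        for lbl, ln in ((x, lx), (y, ly), (z, lz)):
            nodes[lbl].length = max(ln, 0.0)
            root.add(nodes[lbl])
    else:
        for lbl in active:
            root.add(nodes[lbl])
    for node in root.walk():
        if node.name.startswith("__"):
            node.name = ""
    return Tree(root)


# ---------------------------------------------------------------------------
# branch-length optimisation and NNI search
# ---------------------------------------------------------------------------

def _optimizable_branches(tree: Tree) -> list:
    return [n for n in tree.root.walk() if n.parent is not None]


def optimize_branch_lengths(tree: Tree, aln: MultipleAlignment,
                            model: RateModel, tol: float = 1e-6,
                            max_rounds: int = 20,
                            pruner: "_Pruner" = None) -> tuple:
    """Iterated per-branch bounded scalar optimisation.  Returns
    ``(tree, log_likelihood)``; the tree is modified in place.  The monotone
    contract: the likelihood never decreases between rounds."""
    pruner = pruner or _Pruner(aln, model)
    current = pruner.log_likelihood(tree)
    for round_no in range(max_rounds):
        for node in _optimizable_branches(tree):
            def nll(t, node=node):
                node.length = t
                return -pruner.log_likelihood(tree)
            best_t = node.length
            ll_here = pruner.log_likelihood(tree)
            res = minimize_scalar(nll, bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded", options={"xatol": 1e-6})
            if -res.fun >= ll_here:
                node.length = float(res.x)
            else:
                node.length = best_t
        new = pruner.log_likelihood(tree)
        if new < current - 1e-9:
            log.warning("branch optimisation decreased the likelihood")
        if new - current < tol:
            current = max(new, current)
            break
        current = new
    else:
        log.debug("branch optimisation stopped at max_rounds=%d", max_rounds)
    return tree, current


def _nni_neighbourhood(edge_child: Node):
    """The two NNI rearrangements around the edge above ``edge_child``.

    Yields (swap_a, swap_b) node pairs: exchanging them produces the
    alternative topology.  ``edge_child`` must be internal with a parent.
    """
    parent = edge_child.parent
    siblings = [c for c in parent.children if c is not edge_child]
    if not siblings or len(edge_child.children) < 2:
        return
    z = siblings[0]
    x, y = edge_child.children[0], edge_child.children[1]
    yield (z, x)
    yield (z, y)


def _swap(a: Node, b: Node):
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _local_branches(edge_child: Node) -> list:
    out = [edge_child]
    out += list(edge_child.children)
    parent = edge_child.parent
    out += [c for c in parent.children if c is not edge_child]
    if parent.parent is not None:
        out.append(parent)
    return out


def _optimize_subset(tree, pruner, branches, rounds: int = 2) -> float:
    current = pruner.log_likelihood(tree)
    for _ in range(rounds):
        for node in branches:
            def nll(t, node=node):
                node.length = t
                return -pruner.log_likelihood(tree)
            keep = node.length
            res = minimize_scalar(nll, bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded", options={"xatol": 1e-5})
            if -res.fun >= current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = keep
    return pruner.log_likelihood(tree)


def nni_search(tree: Tree, aln: MultipleAlignment, model: RateModel,
               max_rounds: int = 20, tol: float = 1e-6) -> tuple:
    """NNI hill-climbing: per round, try both rearrangements of every
    internal edge (with local branch re-optimisation), accept the best
    improving move, stop at a local optimum.  Returns (tree, loglik)."""
    pruner = _Pruner(aln, model)
    tree, current = optimize_branch_lengths(tree, aln, model, pruner=pruner)
    for _ in range(max_rounds):
        best_move = None
        saved = [(n, n.length) for n in tree.root.walk()]
        for edge_child in tree.internal_edges():
            for a, b in _nni_neighbourhood(edge_child):
                _swap(a, b)
                cand = _optimize_subset(tree, pruner,
                                        _local_branches(edge_child), rounds=2)
                if cand > current + tol and (best_move is None or cand > best_move[0]):
                    best_move = (cand, a, b)
                _swap(a, b)  # revert (swap is involutive on positions)
                for n, ln in saved:
                    n.length = ln
        if best_move is None:
            break
        _, a, b = best_move
        _swap(a, b)
        tree, current = optimize_branch_lengths(tree, aln, model,
                                                pruner=pruner, max_rounds=5)
    return tree, current


def ml_tree(aln: MultipleAlignment, model: RateModel) -> tuple:
    """NJ starting tree on pairwise ML distances, then NNI search."""
    start = nj_tree(ml_distance_matrix(aln, model))
    return nni_search(start, aln, model)


# ---------------------------------------------------------------------------
# aLRT supports, collapsing, rooting
# ---------------------------------------------------------------------------

def alrt_support(tree: Tree, aln: MultipleAlignment, model: RateModel) -> Tree:
    """Per internal branch: statistic 2(l_best - l_second) against the better
    of the two NNI alternatives (branch lengths re-optimised over the five
    surrounding branches); support = 1 - p under the 0.5 chi2_0 + 0.5 chi2_1
    mixture.  Supports are written onto the child node of each branch."""
    pruner = _Pruner(aln, model)
    best_ll = pruner.log_likelihood(tree)
    for edge_child in tree.internal_edges():
        second = -np.inf
        saved = [(n, n.length) for n in tree.root.walk()]
        for a, b in _nni_neighbourhood(edge_child):
            _swap(a, b)
            cand = _optimize_subset(tree, pruner, _local_branches(edge_child),
                                    rounds=2)
            second = max(second, cand)
            _swap(a, b)
            for n, ln in saved:
                n.length = ln
        stat = 2.0 * (best_ll - second)
        if stat < 0:
            log.warning("aLRT found a better NNI alternative (stat %.3g); "
                        "support set to 0 — rerun the topology search", stat)
            stat = 0.0
        p = (1.0 if stat <= 0 else 0.0) * 0.5 + 0.5 * float(chi2.sf(stat, df=1))
        edge_child.support = 1.0 - p
    return tree


def collapse_low_support(tree: Tree, threshold: float = 0.6) -> Tree:
    """Contract internal branches with support below the threshold into
    polytomies (the survey collapses below 0.6).  Idempotent."""
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.root.walk()):
            if (node.parent is not None and not node.is_leaf
                    and node.support is not None and node.support < threshold):
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for i, ch in enumerate(node.children):
                    ch.parent = parent
                    parent.children.insert(idx + i, ch)
                changed = True
                break
    return tree


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    dists = tree.tip_distances()
    if not dists:
        raise ValueError("tree has fewer than 2 tips")
    (u, v), diameter = max(dists.items(), key=lambda kv: (kv[1], kv[0]))
    if diameter <= 0:
        log.warning("zero-diameter tree; rooting at the current anchor node")
        return tree.copy()
    adj, sup = _adjacency(tree)
    path = _path(adj, u, v)
    walked = 0.0
    target = diameter / 2.0
    for a, b in zip(path, path[1:]):
        w = adj[a][b]
        if walked + w >= target - 1e-12:
            return _root_on_edge(adj, sup, a, b, target - walked)
        walked += w
    raise AssertionError("midpoint not found on diameter path")


def outgroup_root(tree: Tree, outgroup_tips: list) -> Tree:
    """Root on the branch above the smallest clade containing the outgroup
    (the mechanism behind 'rooted following the topology of' a guide tree)."""
    tree = tree.copy()
    target = set(outgroup_tips)
    best = None
    for node in tree.root.walk():
        tips = set(node.leaf_names())
        if target <= tips and (best is None or len(tips) < len(best[1])):
            best = (node, tips)
    node = best[0]
    if node.parent is None:
        raise ValueError("outgroup spans the whole tree; cannot root")
    adj, sup = _adjacency(tree)
    # split the outgroup's parent edge at its middle
    a = _find_name_key(adj, node)
    return _root_on_edge(adj, sup, _node_key(node.parent), _node_key(node),
                         adj[_node_key(node.parent)][_node_key(node)] / 2.0)


def _node_key(node: Node):
    return node.name if node.is_leaf else id(node)


def _find_name_key(adj, node):
    return _node_key(node)


def _adjacency(tree: Tree):
    """Undirected weighted adjacency plus per-edge supports."""
    adj: dict = {}
    sup: dict = {}
    for node in tree.root.walk():
        key = _node_key(node)
        adj.setdefault(key, {})
        if node.parent is not None:
            pkey = _node_key(node.parent)
            adj.setdefault(pkey, {})
            adj[key][pkey] = node.length
            adj[pkey][key] = node.length
            if node.support is not None:
                sup[frozenset((key, pkey))] = node.support
    return adj, sup


def _path(adj, u, v):
    stack = [(u, [u])]
    seen = {u}
    while stack:
        node, path = stack.pop()
        if node == v:
            return path
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append((nb, path + [nb]))
    raise AssertionError("disconnected tree")


def _root_on_edge(adj, sup, a, b, dist_from_a) -> Tree:
    """Rebuild a rooted tree with a new root splitting edge (a, b)."""
    w = adj[a][b]
    root = Node()
    del adj[a][b], adj[b][a]

    def build(key, parent_key, length):
        node = Node(key if isinstance(key, str) else "", length)
        for nb, wn in adj[key].items():
            if nb == parent_key:
                continue
            child = build(nb, key, wn)
            edge = frozenset((key, nb))
            if edge in sup:
                child.support = sup[edge]
            node.add(child)
        return node

    ca = build(a, None, dist_from_a)
    cb = build(b, None, w - dist_from_a)
    edge = frozenset((a, b))
    if edge in sup:
        ca.support = sup[edge]
        cb.support = sup[edge]
    root.add(ca)
    root.add(cb)
    # drop degree-2 pass-through nodes created by the old anchor
    _suppress_unifurcations(root)
    return Tree(root)


def _suppress_unifurcations(root: Node):
    for node in list(root.walk()):
        while (len(node.children) == 1 and node.parent is not None):
            child = node.children[0]
            child.length += node.length
            if node.support is not None and child.support is None:
                child.support = node.support
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
            node = child
    while len(root.children) == 1 and not root.children[0].is_leaf:
        only = root.children[0]
        root.children = []
        for ch in only.children:
            ch.length += 0.0  # lengths below are already correct
            root.add(ch)


def is_monophyletic(tree: Tree, tip_subset) -> bool:
    """True iff some clade's tip set equals the subset exactly."""
    target = set(tip_subset)
    all_tips = set(tree.leaf_names())
    unknown = target - all_tips
    if unknown:
        raise KeyError(f"unknown tips: {sorted(unknown)}")
    for node in tree.root.walk():
        if set(node.leaf_names()) == target:
            return True
    return False


# ---------------------------------------------------------------------------
# bootstrap and gamma-shape estimation
# ---------------------------------------------------------------------------

def bootstrap(aln: MultipleAlignment, model: RateModel,
              n_replicates: int = 100, seed: int = 0,
              full_ml: bool = False) -> dict:
    """Site bootstrap: resample columns with replacement, rebuild the tree
    per replicate (NJ on ML distances by default; ``full_ml`` adds the NNI
    search), return bipartition frequencies."""
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    counts: dict = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rows = [(rid, "".join(seq[j] for j in cols)) for rid, seq in aln.rows]
        rep = MultipleAlignment(rows)
        if full_ml:
            t, _ = ml_tree(rep, model)
        else:
            t = nj_tree(ml_distance_matrix(rep, model))
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    return {split: c / n_replicates for split, c in counts.items()}


def estimate_gamma_shape(tree: Tree, aln: MultipleAlignment, model: RateModel,
                         bounds: tuple = (0.05, 20.0)) -> float:
    """1-D estimation of the gamma shape: coarse log grid, then
    golden-section refinement, alternated once with branch re-optimisation."""
    tree = tree.copy()

    def ll_at(alpha, opt_branches=False):
        m = model.with_shape(alpha)
        if opt_branches:
            _, ll = optimize_branch_lengths(tree, aln, m, max_rounds=2)
            return ll
        return log_likelihood(tree, aln, m)

    grid = np.exp(np.linspace(math.log(bounds[0]), math.log(bounds[1]), 8))
    coarse = max(grid, key=lambda a: ll_at(a, opt_branches=False))
    optimize_branch_lengths(tree, aln, model.with_shape(coarse), max_rounds=3)
    lo = max(bounds[0], coarse / 3)
    hi = min(bounds[1], coarse * 3)
    res = minimize_scalar(lambda a: -ll_at(a), bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-3})
    alpha = float(res.x)
    optimize_branch_lengths(tree, aln, model.with_shape(alpha), max_rounds=2)
    res = minimize_scalar(lambda a: -ll_at(a), bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-3})
    return float(res.x)
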