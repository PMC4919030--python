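"""Curated profile HMMs: building from a seed alignment (with anchor-residue
up-weighting), local Viterbi/forward scanning in log-odds space, shuffle-free
E-value calibration against random background sequences, and the
single-domain / long classification of hits.

The architecture is a simplified Plan7: match / insert / delete states per
node, uniform local entry into and exit out of any node, flanking residues
emitted by the background (zero log-odds).  Anchor columns — here the
iron-coordinating residues of the oxygen-binding hemerythrin site — get
their stated residue's count multiplied by a weight before normalisation,
which sharpens the profile exactly where the family's chemistry lives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .msa import MultipleAlignment
from .pairwise import (DegenerateNullError, fit_gumbel, gumbel_sf,
                       shuffle_significance, smith_waterman, sw_score)
from .ratemodel import RateModel
from .scoring import AMINO_ACIDS, ScoringScheme, encode

log = logging.getLogger(__name__)

LN2 = math.log(2.0)
NEG = -1e30


class EmptyModelError(ValueError):
    """No alignment column passed the match-state occupancy rule."""


@dataclass
class ProfileHMM:
    profile_id: str
    match_emissions: np.ndarray      # (M, 20)
    insert_emissions: np.ndarray     # (M+1, 20); row 0 is the pre-node insert
    transitions: dict                # keys tMM,tMI,tMD,tIM,tII,tDM,tDD -> (M,)
    background: np.ndarray           # (20,)
    anchor_nodes: tuple = ()         # (node index, residue, weight)

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        M = self.node_count
        if M < 1:
            raise EmptyModelError("profile must have at least one node")
        if self.insert_emissions.shape != (M + 1, 20):
            raise ValueError("insert_emissions must be (node_count+1, 20)")
        for name, row_sums in [("match", self.match_emissions.sum(axis=1)),
                               ("insert", self.insert_emissions.sum(axis=1)),
                               ("background", np.array([self.background.sum()]))]:
            if np.any(np.abs(row_sums - 1.0) > 1e-9):
                raise ValueError(f"{name} emissions must sum to 1")
        t = self.transitions
        for grp in (t["tMM"] + t["tMI"] + t["tMD"],
                    t["tIM"] + t["tII"], t["tDM"] + t["tDD"]):
            if np.any(np.abs(np.asarray(grp) - 1.0) > 1e-9):
                raise ValueError("transition groups must sum to 1")

    @property
    def node_count(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass
class DomainHit:
    """One profile match on one protein.

    ``reference_coverage`` is the fraction of profile nodes spanned by the
    hit; ``protein_coverage`` the fraction of the protein covered by the
    envelope.  The survey's seed-collection threshold (>95%) applies to the
    former kind of coverage, the single/long split (85%) to the latter.
    """

    protein_id: str
    profile_id: str
    bit_score: float
    query_envelope: tuple
    profile_span: tuple
    protein_length: int = 0
    evalue: float = float("nan")
    classification: str | None = None

    @property
    def reference_coverage(self) -> float:
        return (self.profile_span[1] - self.profile_span[0]) / self._nodes

    @property
    def protein_coverage(self) -> float:
        if not self.protein_length:
            return 0.0
        return (self.query_envelope[1] - self.query_envelope[0]) / self.protein_length

    _nodes: int = 1


@dataclass
class EvalueCalibration:
    profile_id: str
    n_random: int
    length: int
    gumbel_mu: float
    gumbel_lambda: float

    def evalue(self, bit_score: float, database_size: int = 1) -> float:
        return database_size * gumbel_sf(bit_score, self.gumbel_mu,
                                         self.gumbel_lambda)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_phmm(msa: MultipleAlignment, match_rule: float = 0.5,
               pseudocount: float = 1.0, anchors: list | None = None,
               profile_id: str = "profile",
               background: np.ndarray | None = None) -> ProfileHMM:
    """Build a profile from a seed alignment.

    Columns whose non-gap occupancy is at least ``match_rule`` become match
    nodes.  Match emissions are Laplace-smoothed counts; for an anchor
    ``(column, residue, weight)`` the residue's raw count is multiplied by
    ``weight`` before the pseudocount is added.  Transition probabilities are
    counted from the per-row state paths with a pseudocount of 1 per
    outcome.  Insert emissions are the background distribution.
    """
    if len(msa.rows) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    anchors = anchors or []
    L = msa.n_columns
    n_rows = len(msa.rows)
    code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    cols = [msa.column(j) for j in range(L)]
    occupancy = np.array([sum(c != "-" for c in col) / n_rows for col in cols])
    is_match = occupancy >= match_rule
    match_cols = np.flatnonzero(is_match)
    M = len(match_cols)
    if M == 0:
        raise EmptyModelError("every column fell below the occupancy rule")
    bg = (np.asarray(background, dtype=float) if background is not None
          else RateModel(n_categories=1).frequencies)
    bg = bg / bg.sum()

    counts = np.zeros((M, 20))
    for node, j in enumerate(match_cols):
        for ch in cols[j]:
            if ch != "-" and ch.upper() in code:
                counts[node, code[ch.upper()]] += 1
    anchor_nodes = []
    col_to_node = {int(j): node for node, j in enumerate(match_cols)}
    for col, res, weight in anchors:
        node = col_to_node.get(int(col))
        if node is None:
            log.warning("anchor column %d is not a match node; ignored", col)
            continue
        counts[node, code[res.upper()]] *= weight
        anchor_nodes.append((node, res.upper(), float(weight)))
    match_em = (counts + pseudocount)
    match_em /= match_em.sum(axis=1, keepdims=True)

    insert_em = np.tile(bg, (M + 1, 1))

    # transition counts from per-row state paths
    tc = {k: np.zeros(M) for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}
    for _, row in msa.rows:
        state, node = None, -1  # node = index of last match node visited
        for j, ch in enumerate(row):
            if is_match[j]:
                new = "M" if ch != "-" else "D"
                if state is not None and node >= 0:
                    key = state + new
                    if key in tc:
                        tc[key][node] += 1
                state, node = new, node + 1
            elif ch != "-":
                if state is not None and node >= 0:
                    if state in "MI":
                        tc[state + "I"][node] += 1
                    state = "I"
        # transitions into END are absorbed into the MM pseudocount

    def norm(*keys):
        tot = sum(tc[k] + 1.0 for k in keys)
        return {f"t{k}": (tc[k] + 1.0) / tot for k in keys}

    transitions = {}
    transitions.update(norm("MM", "MI", "MD"))
    transitions.update(norm("IM", "II"))
    transitions.update(norm("DM", "DD"))
    return ProfileHMM(profile_id, match_em, insert_em, transitions, bg,
                      tuple(anchor_nodes))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _log_odds(model: ProfileHMM):
    with np.errstate(divide="ignore"):  # zero-probability transitions -> -inf
        em = np.log(model.match_emissions) - np.log(model.background)[None, :]
        ei = (np.log(model.insert_emissions[1:, :])
              - np.log(model.background)[None, :])
        t = {k: np.log(v) for k, v in model.transitions.items()}
    return em, ei, t


def _delete_entry(vm_prev, lMD, lDM, lDD, accumulate):
    """Contribution of delete chains to the next match row.

    Returns d[k] = op_{j <= k-2} ( vm_prev[j] + lMD[j]
                   + sum_{l=j+1}^{k-2} lDD[l] ) + lDM[k-1]
    where ``op`` is max (Viterbi) or logsumexp (forward), computed with a
    telescoped prefix ``accumulate`` (np.maximum.accumulate or
    np.logaddexp.accumulate).  Delete states live at nodes 1..M-1, so the
    shortest chain into M_k is M_{k-2} -> D_{k-1} -> M_k.
    """
    M = len(vm_prev)
    d = np.full(M, NEG)
    if M < 2:
        return d
    # C[m] = sum_{l=1}^{m} lDD[l], C[0] = 0
    C = np.concatenate([[0.0], np.cumsum(lDD[1:M])])
    inner = accumulate(vm_prev + lMD - C)
    d[2:] = inner[:-2] + C[:-2] + lDM[1:-1]
    # j = k-2 term uses C[k-2] - C[k-2] = 0 contribution of lDD: correct,
    # since the chain M_{k-2} -> D_{k-1} -> M_k crosses no D->D edge.
    return d


def _viterbi_fill(model: ProfileHMM, codes: np.ndarray):
    """Vectorised local Viterbi fill; returns (VM, VI) of shape (L, M) plus
    the best (score_nats, end_i, end_k)."""
    L, M = len(codes), model.node_count
    em, ei, t = _log_odds(model)
    entry = -math.log(M)
    exit_ = -math.log(M)
    lMM, lMI = t["tMM"], t["tMI"]
    lIM, lII = t["tIM"], t["tII"]
    lMD, lDM, lDD = t["tMD"], t["tDM"], t["tDD"]
    VM = np.full((L, M), NEG)
    VI = np.full((L, M), NEG)
    best = (NEG, -1, -1)
    for i in range(L):
        x = codes[i]
        e_row = em[:, x] if x < 20 else np.zeros(M)
        cur = np.full(M, entry)
        if i > 0:
            vm_prev, vi_prev = VM[i - 1], VI[i - 1]
            cont = np.full(M, NEG)
            cont[1:] = np.maximum(vm_prev[:-1] + lMM[:-1],
                                  vi_prev[:-1] + lIM[:-1])
            cont = np.maximum(cont, _delete_entry(vm_prev, lMD, lDM, lDD,
                                                  np.maximum.accumulate))
            np.maximum(cur, cont, out=cur)
            vi = np.maximum(vm_prev + lMI, vi_prev + lII)
            if x < 20:
                vi = vi + ei[:, x]
            VI[i] = vi
        VM[i] = e_row + cur
        k_best = int(VM[i].argmax())
        s = VM[i, k_best] + exit_
        if s > best[0]:
            best = (s, i, k_best)
    return VM, VI, em, ei, t, best


def _traceback(VM, VI, em, ei, t, codes, end_i, end_k, entry):
    """Walk back from (end_i, end_k) to the entry cell.

    Delete rows are recomputed on demand from the stored match rows.
    Tie-break: match continuation, then delete, then insert, then entry.
    """
    lMM, lMI = t["tMM"], t["tMI"]
    lIM, lII = t["tIM"], t["tII"]
    lMD, lDM, lDD = t["tMD"], t["tDM"], t["tDD"]
    eps = 1e-9
    i, k, state = end_i, end_k, "M"
    while True:
        if state == "M":
            x = codes[i]
            e = em[k, x] if x < 20 else 0.0
            v = VM[i, k] - e
            if i > 0 and k > 0:
                if abs(v - (VM[i - 1, k - 1] + lMM[k - 1])) < eps:
                    i, k = i - 1, k - 1
                    continue
                d = _delete_entry(VM[i - 1], lMD, lDM, lDD,
                                  np.maximum.accumulate)
                if abs(v - d[k]) < eps:
                    # find the match state the delete chain left from
                    C = np.concatenate([[0.0], np.cumsum(lDD[1:len(d)])])
                    target = v - lDM[k - 1] - C[k - 2]
                    cand = VM[i - 1] + lMD - C
                    j = int(np.flatnonzero(np.abs(cand[:k - 1] - target) < eps)[-1])
                    i, k = i - 1, j
                    continue
                if abs(v - (VI[i - 1, k - 1] + lIM[k - 1])) < eps:
                    i, k, state = i - 1, k - 1, "I"
                    continue
            return i, k
        else:  # insert at node k
            x = codes[i]
            e = ei[k, x] if x < 20 else 0.0
            v = VI[i, k] - e
            if abs(v - (VM[i - 1, k] + lMI[k])) < eps:
                state = "M"
            i -= 1


def viterbi_scan(model: ProfileHMM, protein: str, protein_id: str = "query",
                 floor: float = 0.0, multihit: bool = False,
                 score_only: bool = False):
    """Best local match of the profile in the protein.

    Returns a :class:`DomainHit` (or a list of non-overlapping hits when
    ``multihit``), or ``None`` if the best bit score is below ``floor``.
    The score is the log2-odds of the best state path against the background
    null; flanking residues are free.  ``score_only`` skips the traceback
    (the envelope is then the single best-scoring cell).
    """
    if multihit:
        return _multihit(model, protein, protein_id, floor)
    hit = _viterbi_one(model, protein, protein_id, 0, score_only)
    if hit is None or hit.bit_score < floor:
        return None
    return hit


def _viterbi_one(model: ProfileHMM, protein: str, protein_id: str,
                 offset: int, score_only: bool = False):
    codes = encode(protein)
    if len(codes) == 0:
        return None
    VM, VI, em, ei, t, best = _viterbi_fill(model, codes)
    score_nats, end_i, end_k = best
    if end_i < 0 or score_nats <= NEG / 2:
        return None
    M = model.node_count
    if score_only:
        start_i, start_k = end_i, end_k
    else:
        start_i, start_k = _traceback(VM, VI, em, ei, t, codes, end_i, end_k,
                                      -math.log(M))
    hit = DomainHit(protein_id, model.profile_id, score_nats / LN2,
                    (start_i + offset, end_i + 1 + offset),
                    (start_k, end_k + 1), protein_length=len(protein))
    hit._nodes = M
    return hit


def _multihit(model, protein, protein_id, floor):
    """Iteratively take the best hit, then rescan the flanks."""
    hits = []
    segments = [(0, len(protein))]
    while segments:
        s, e = segments.pop()
        if e - s < 5:
            continue
        hit = _viterbi_one(model, protein[s:e], protein_id, offset=s)
        if hit is None or hit.bit_score < floor:
            continue
        hits.append(hit)
        a, b = hit.query_envelope
        segments.append((s, a))
        segments.append((b, e))
    hits.sort(key=lambda h: h.query_envelope)
    return hits


def forward_score(model: ProfileHMM, protein: str) -> float:
    """Log2-odds forward (sum over all paths) score; >= the Viterbi score."""
    codes = encode(protein)
    L, M = len(codes), model.node_count
    if L == 0:
        return NEG
    em, ei, t = _log_odds(model)
    entry = -math.log(M)
    exit_ = -math.log(M)
    lMM, lMI = t["tMM"], t["tMI"]
    lIM, lII = t["tIM"], t["tII"]
    lMD, lDM, lDD = t["tMD"], t["tDM"], t["tDD"]
    FM = np.full(M, NEG)
    FI = np.full(M, NEG)
    total = NEG
    for i in range(L):
        x = codes[i]
        e_row = em[:, x] if x < 20 else np.zeros(M)
        cur = np.full(M, entry)
        if i > 0:
            cont = np.full(M, NEG)
            cont[1:] = np.logaddexp(FM[:-1] + lMM[:-1], FI[:-1] + lIM[:-1])
            cont = np.logaddexp(cont, _delete_entry(FM, lMD, lDM, lDD,
                                                    np.logaddexp.accumulate))
            cur = np.logaddexp(cur, cont)
            fi = np.logaddexp(FM + lMI, FI + lII)
            if x < 20:
                fi = fi + ei[:, x]
        else:
            fi = np.full(M, NEG)
        FM = e_row + cur
        FI = fi
        total = np.logaddexp(total, _logsumexp(FM) + exit_)
    return float(total / LN2)


def _logsumexp(v):
    m = v.max()
    if m <= NEG / 2:
        return NEG
    return m + math.log(np.exp(v - m).sum())


# ---------------------------------------------------------------------------
# calibration, classification, seed collection
# ---------------------------------------------------------------------------

def calibrate_evalue(model: ProfileHMM, n_random: int = 1000,
                     length: int = 300, seed: int = 0) -> EvalueCalibration:
    """Fit a Gumbel to Viterbi bit scores of random background sequences."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for r in range(n_random):
        codes = rng.choice(20, size=length, p=model.background)
        seq = "".join(AMINO_ACIDS[c] for c in codes)
        hit = _viterbi_one(model, seq, "random", offset=0)
        scores[r] = hit.bit_score if hit else 0.0
    mu, lam = fit_gumbel(scores)
    return EvalueCalibration(model.profile_id, n_random, length, mu, lam)


def evalue(calibration: EvalueCalibration, bit_score: float,
           database_size: int) -> float:
    return calibration.evalue(bit_score, database_size)


def classify_coverage(hit: DomainHit, threshold: float = 0.85) -> str:
    """'long' iff the hit envelope covers strictly less than ``threshold``
    of the protein; otherwise 'single_domain'."""
    return "long" if hit.protein_coverage < threshold else "single_domain"


def collect_seed(reference_queries: list, database: list,
                 expect_cutoff: float = 1e-5, coverage_cutoff: float = 0.95,
                 scheme: ScoringScheme | None = None, n_shuffles: int = 200,
                 seed: int = 0, prescreen_score: int = 40) -> list:
    """Collect seed homologs for profile building.

    A database sequence is kept when its best pairwise alignment to any
    reference covers more than ``coverage_cutoff`` of that reference and the
    shuffle expect value is below ``expect_cutoff``.  Sequences whose raw
    local score is below ``prescreen_score`` are skipped without shuffling —
    at that score the permutation null cannot approach the cutoff, so the
    prescreen only saves time.
    """
    scheme = scheme or ScoringScheme()
    refs = list(reference_queries)
    if hasattr(database, "proteins"):  # SyntheticProteome
        database = database.proteins
    kept = []
    for idx, (pid, seq) in enumerate(database):
        best = None
        for ref_id, ref in refs:
            s = sw_score(ref, seq, scheme)
            if best is None or s > best[0]:
                best = (s, ref_id, ref)
        if best[0] < prescreen_score:
            continue
        _, ref_id, ref = best
        aln = smith_waterman(ref, seq, scheme)
        cov = (aln.query_interval[1] - aln.query_interval[0]) / len(ref)
        if cov <= coverage_cutoff:
            continue
        try:
            sig = shuffle_significance(ref, seq, scheme, n_shuffles,
                                       seed=seed + idx)
        except DegenerateNullError:
            continue
        if sig.expect < expect_cutoff:
            kept.append((pid, seq))
    if not kept:
        log.warning("collect_seed: no sequence passed the thresholds")
    return kept


# ---------------------------------------------------------------------------
# serialization (versioned plain text, lossless to 12 significant digits)
# ---------------------------------------------------------------------------

FORMAT_TAG = "HRSURVEY-PHMM 1"
_TKEYS = ("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD")


def write_phmm(model: ProfileHMM, path) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_TAG + "\n")
        fh.write(f"PROFILE {model.profile_id}\n")
        fh.write(f"NODES {model.node_count}\n")
        fh.write("BACKGROUND " + _fmt(model.background) + "\n")
        for node, res, w in model.anchor_nodes:
            fh.write(f"ANCHOR {node} {res} {w:.12e}\n")
        fh.write("INSERT0 " + _fmt(model.insert_emissions[0]) + "\n")
        for k in range(model.node_count):
            fh.write(f"NODE {k}\n")
            fh.write("  MATCH " + _fmt(model.match_emissions[k]) + "\n")
            fh.write("  INSERT " + _fmt(model.insert_emissions[k + 1]) + "\n")
            fh.write("  TRANS " + _fmt([model.transitions[t][k] for t in _TKEYS]) + "\n")
        fh.write("END\n")


def read_phmm(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != FORMAT_TAG:
        raise ValueError("not an hrsurvey profile file")
    profile_id, M, bg = None, None, None
    anchors = []
    i = 1
    insert0 = None
    while i < len(lines) and not lines[i].startswith("NODE "):
        tok = lines[i].split()
        if tok[0] == "PROFILE":
            profile_id = tok[1]
        elif tok[0] == "NODES":
            M = int(tok[1])
        elif tok[0] == "BACKGROUND":
            bg = np.array([float(x) for x in tok[1:]])
        elif tok[0] == "ANCHOR":
            anchors.append((int(tok[1]), tok[2], float(tok[3])))
        elif tok[0] == "INSERT0":
            insert0 = np.array([float(x) for x in tok[1:]])
        i += 1
    match = np.zeros((M, 20))
    insert = np.zeros((M + 1, 20))
    insert[0] = insert0
    trans = {k: np.zeros(M) for k in _TKEYS}
    while i < len(lines) and lines[i] != "END":
        k = int(lines[i].split()[1])
        match[k] = [float(x) for x in lines[i + 1].split()[1:]]
        insert[k + 1] = [float(x) for x in lines[i + 2].split()[1:]]
        tv = [float(x) for x in lines[i + 3].split()[1:]]
        for key, v in zip(_TKEYS, tv):
            trans[key][k] = v
        i += 4
    return ProfileHMM(profile_id, match, insert, trans, bg, tuple(anchors))


def _fmt(vals) -> str:
    return " ".join(f"{float(v):.12e}" for v in vals)
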