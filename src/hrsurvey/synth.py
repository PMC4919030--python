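"""Seeded synthetic proteomes with planted hemerythrin-like domains.

Real surveys scan thousands of genomes for a ~118-residue oxygen-binding
hemerythrin (O2-Hr) domain whose iron-coordination site (five histidines,
one glutamate, one aspartate) is strongly conserved.  This module emulates
that statistical structure so the whole pipeline is testable offline:

* a conserved O2-Hr-like template with the seven anchor residues,
* a divergent sister family (HHE-like: same fold length, altered anchors),
* decoy domain families with unrelated consensus sequences,
* multi-domain host proteins (linkers, decoys, orphan elongations),
* gap-free alignments evolved along a known tree under LG+Gamma.

Every operation takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import MultipleAlignment
from .ratemodel import RateModel
from .scoring import AMINO_ACIDS
from .tree import Tree

#: Anchor layout of the O2-Hr iron-coordination site, 0-based positions on a
#: 118-residue domain (modelled on the myohemerythrin ligand spacing).
HR_ANCHORS = [(24, "H"), (53, "H"), (57, "E"), (72, "H"),
              (76, "H"), (105, "H"), (110, "D")]
HR_LENGTH = 118


@dataclass(frozen=True)
class DomainTemplate:
    """A domain family: consensus sequence plus conserved anchor residues."""

    template_id: str
    consensus: str
    anchor_positions: tuple = ()
    anchor_conservation: float = 0.95

    def __post_init__(self):
        if len(self.consensus) < 20:
            raise ValueError("template length must be >= 20")
        if any(c not in AMINO_ACIDS for c in self.consensus):
            raise ValueError("consensus must use the 20 standard amino acids")
        for pos, res in self.anchor_positions:
            if not 0 <= pos < len(self.consensus):
                raise ValueError("anchor position out of bounds")
            if self.consensus[pos] != res:
                raise ValueError("consensus disagrees with anchor residue")
        if not 0.0 <= self.anchor_conservation <= 1.0:
            raise ValueError("anchor_conservation must be a probability")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class Segment:
    """One piece of an architecture: a domain, a linker, or an orphan
    elongation.  Linker/orphan lengths are geometric with the given mean."""

    kind: str  # "domain" | "linker" | "orphan"
    template_id: str | None = None
    mean_length: float = 30.0

    def __post_init__(self):
        if self.kind not in ("domain", "linker", "orphan"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "domain" and not self.template_id:
            raise ValueError("domain segments need a template_id")
        if self.mean_length < 0:
            raise ValueError("segment lengths must be >= 0")


@dataclass(frozen=True)
class ArchitectureSpec:
    segments: tuple

    def __post_init__(self):
        if not self.segments:
            raise ValueError("architecture needs at least one segment")


@dataclass(frozen=True)
class TruthRecord:
    protein_id: str
    template_id: str
    start: int
    end: int
    divergence: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")


@dataclass
class SyntheticProteome:
    species_id: str
    taxon_group: str
    proteins: list  # (protein_id, sequence)
    truth: list = field(default_factory=list)

    def __post_init__(self):
        ids = [p for p, _ in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("protein ids must be unique")
        lengths = dict(zip(ids, (len(s) for _, s in self.proteins)))
        for t in self.truth:
            if t.protein_id not in lengths or t.end > lengths[t.protein_id]:
                raise ValueError(f"truth record out of bounds: {t}")

    def write(self, fasta_path, truth_path=None):
        from .io import write_fasta, write_truth_tsv
        write_fasta(fasta_path, self.proteins)
        if truth_path is not None:
            write_truth_tsv(truth_path, self.truth)


def _draw_consensus(length: int, rng: np.random.Generator,
                    freqs: np.ndarray) -> list:
    codes = rng.choice(20, size=length, p=freqs)
    return [AMINO_ACIDS[c] for c in codes]


def make_default_templates(seed: int, anchor_conservation: float = 0.95):
    """The study-condition template set.

    Returns ``(hemerythrin, sister_hhe, decoys)``: a 118-residue O2-Hr-like
    template with the canonical 5xH + 1xE + 1xD anchors; an HHE-like sister
    of the same length, diverged at >= 40% of positions with >= 2 altered
    anchors; and two anchor-free decoy families (lengths 60 and 200).
    Non-anchor consensus residues are drawn from the LG equilibrium
    frequencies, so different seeds give different consensus backgrounds
    with identical anchors.
    """
    rng = np.random.default_rng(seed)
    freqs = RateModel(n_categories=1).frequencies

    cons = _draw_consensus(HR_LENGTH, rng, freqs)
    for pos, res in HR_ANCHORS:
        cons[pos] = res
    hemerythrin = DomainTemplate("O2_Hr", "".join(cons), tuple(HR_ANCHORS),
                                 anchor_conservation)

    # sister family: resample 55% of non-anchor positions, replace three
    # anchors (the HHE site keeps only part of the O2-Hr ligand set)
    anchor_pos = {p for p, _ in HR_ANCHORS}
    while True:
        sister = list(hemerythrin.consensus)
        for i in range(HR_LENGTH):
            if i in anchor_pos:
                continue
            if rng.random() < 0.55:
                choices = [a for a in AMINO_ACIDS if a != sister[i]]
                sister[i] = choices[rng.integers(len(choices))]
        diff = sum(a != b for a, b in zip(sister, hemerythrin.consensus))
        if diff / HR_LENGTH >= 0.40:
            break
    replacements = {76: "N", 105: "Q", 110: "S"}
    for pos, res in replacements.items():
        sister[pos] = res
    sister_anchors = tuple((p, r) for p, r in HR_ANCHORS if p not in replacements)
    sister_anchors += tuple((p, r) for p, r in sorted(replacements.items()))
    sister_hhe = DomainTemplate("HHE", "".join(sister), sister_anchors,
                                anchor_conservation)

    decoys = []
    for name, length in (("DecoyA", 60), ("DecoyB", 200)):
        while True:
            cand = "".join(_draw_consensus(length, rng, freqs))
            n = min(length, HR_LENGTH)
            ident = sum(a == b for a, b in zip(cand[:n], hemerythrin.consensus[:n])) / n
            if ident < 0.20:
                break
        decoys.append(DomainTemplate(name, cand, (), anchor_conservation))
    return hemerythrin, sister_hhe, decoys


def mutate_from_template(template: DomainTemplate, divergence: float,
                         seed: int) -> str:
    """Sample one homolog: each site substituted with probability
    1 - exp(-divergence); anchor sites only with the residual probability
    (1 - anchor_conservation) times that.  Replacement residues are uniform
    over the 19 alternatives; output length equals the template length."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed)
    p = -np.expm1(-divergence)
    anchor_pos = {pos for pos, _ in template.anchor_positions}
    out = []
    for i, res in enumerate(template.consensus):
        p_i = p * (1.0 - template.anchor_conservation) if i in anchor_pos else p
        if rng.random() < p_i:
            choices = [a for a in AMINO_ACIDS if a != res]
            out.append(choices[rng.integers(19)])
        else:
            out.append(res)
    return "".join(out)


def _geometric_length(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0)) - 1)


def single_domain_spec(template_id: str = "O2_Hr") -> ArchitectureSpec:
    return ArchitectureSpec((Segment("domain", template_id),))


def default_architecture_specs() -> list:
    """Host-protein architectures emulating the survey's catalogue: the
    focal domain alone, at either terminus of a decoy fusion, internal,
    and flanked by orphan elongations."""
    return [
        single_domain_spec(),
        ArchitectureSpec((Segment("domain", "DecoyA"), Segment("linker"),
                          Segment("domain", "O2_Hr"))),              # C-terminal
        ArchitectureSpec((Segment("domain", "O2_Hr"), Segment("linker"),
                          Segment("domain", "DecoyB"))),             # N-terminal
        ArchitectureSpec((Segment("domain", "DecoyA"), Segment("linker"),
                          Segment("domain", "O2_Hr"), Segment("linker"),
                          Segment("domain", "DecoyB"))),             # internal
        ArchitectureSpec((Segment("orphan", mean_length=80),
                          Segment("domain", "O2_Hr"))),              # orphan + Hr
    ]


def generate_proteome(templates: list, architecture_specs: list,
                      n_proteins: int, planting_rate: float, seed: int,
                      species_id: str = "synth", taxon_group: str = "synthetic",
                      divergence_range: tuple = (0.1, 1.5),
                      background_length: tuple = (100, 400),
                      background_freqs: np.ndarray | None = None) -> SyntheticProteome:
    """Draw a proteome: each protein is planted (with truth records) with
    probability ``planting_rate``, else pure background.  Background residues
    come from the LG equilibrium frequencies unless overridden."""
    if not templates:
        raise ValueError("need at least one template")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= planting_rate <= 1.0:
        raise ValueError("planting_rate must be a probability")
    rng = np.random.default_rng(seed)
    freqs = (np.asarray(background_freqs) if background_freqs is not None
             else RateModel(n_categories=1).frequencies)
    by_id = {t.template_id: t for t in templates}
    lo, hi = divergence_range
    proteins, truth = [], []
    for idx in range(n_proteins):
        pid = f"{species_id}_{idx:05d}"
        if rng.random() < planting_rate:
            spec = architecture_specs[rng.integers(len(architecture_specs))]
            parts = []
            pos = 0
            records = []
            for seg in spec.segments:
                if seg.kind == "domain":
                    tmpl = by_id[seg.template_id]
                    div = float(rng.uniform(lo, hi))
                    frag = mutate_from_template(tmpl, div,
                                                int(rng.integers(2 ** 31)))
                    records.append(TruthRecord(pid, tmpl.template_id, pos,
                                               pos + len(frag), div))
                    parts.append(frag)
                    pos += len(frag)
                else:
                    n = _geometric_length(rng, seg.mean_length)
                    frag = "".join(_draw_consensus(n, rng, freqs)) if n else ""
                    parts.append(frag)
                    pos += n
            seq = "".join(parts)
            if not seq:
                seq = "".join(_draw_consensus(30, rng, freqs))
                records = []
            proteins.append((pid, seq))
            truth.extend(records)
        else:
            n = int(rng.integers(background_length[0], background_length[1] + 1))
            proteins.append((pid, "".join(_draw_consensus(n, rng, freqs))))
    return SyntheticProteome(species_id, taxon_group, proteins, truth)


def evolve_along_tree(root_length: int, tree: Tree, model: RateModel,
                      seed: int) -> MultipleAlignment:
    """Simulate a gap-free alignment along a tree under the model.

    The root sequence is drawn from the equilibrium frequencies; each site is
    assigned a gamma rate category; each branch applies P(rate * length)
    computed by the exact matrix exponential.  Columns are homologous by
    construction (no indels), so the output is already an alignment.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    tips = tree.leaves()
    if len(tips) < 2:
        raise ValueError("tree must have at least two tips")
    for node in tree.root.walk():
        if node.length < 0:
            raise ValueError("negative branch length")
    rng = np.random.default_rng(seed)
    cats = rng.integers(model.n_categories, size=root_length)
    states = {tree.root: model.sample_equilibrium(root_length, rng)}
    rows = []
    for node in tree.root.walk():
        if node is tree.root:
            pass
        else:
            parent_states = states[node.parent]
            child = np.empty(root_length, dtype=np.int64)
            for c in range(model.n_categories):
                mask = cats == c
                if not mask.any():
                    continue
                P = model.transition_matrix(node.length, model.rates[c])
                cum = np.cumsum(P, axis=1)
                u = rng.random(int(mask.sum()))
                par = parent_states[mask]
                child[mask] = np.minimum(
                    (u[:, None] > cum[par]).sum(axis=1), 19)
            states[node] = child
        if node.is_leaf:
            rows.append((node.name,
                         "".join(AMINO_ACIDS[s] for s in states[node])))
    return MultipleAlignment(rows)
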