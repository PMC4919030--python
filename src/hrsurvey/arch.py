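"""Domain-architecture resolution and survey tables.

Overlapping domain hits on a protein are resolved greedily in ascending
E-value order (a hit is rejected if its envelope shares any residue with an
already-accepted hit).  Accepted domains plus sufficiently long unannotated
regions ("orphan elongations") yield an architecture string and a terminus
class for the focal domain; catalogues, per-species copy-number tables and
presence/absence matrices summarise a whole survey.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORPHAN = "ORPHAN"


@dataclass
class ResolvedAnnotation:
    protein_id: str
    protein_length: int
    accepted: list                 # DomainHit, sorted by envelope start
    rejected: list = field(default_factory=list)
    min_orphan: int = 50
    overlap_tolerance: int = 0
    orphan_regions: list = field(default_factory=list)

    def __post_init__(self):
        self.accepted.sort(key=lambda h: h.query_envelope)
        for a, b in zip(self.accepted, self.accepted[1:]):
            if a.query_envelope[1] - b.query_envelope[0] > self.overlap_tolerance:
                raise AssertionError("accepted hits overlap")
        self.orphan_regions = self._orphans()

    def _orphans(self):
        regions = []
        pos = 0
        envs = [h.query_envelope for h in self.accepted] + [(self.protein_length,
                                                             self.protein_length)]
        for s, e in envs:
            if s - pos >= self.min_orphan:
                regions.append((pos, s))
            pos = max(pos, e)
        return regions


@dataclass(frozen=True)
class ArchitectureString:
    tokens: tuple                  # domain names and ORPHAN markers, in order
    terminus_class: str            # of the focal domain

    def __str__(self):
        return "|".join(self.tokens)


def resolve_overlaps(hits: list, min_orphan: int = 50,
                     overlap_tolerance: int = 0) -> ResolvedAnnotation:
    """Greedy acceptance in ascending E-value; ties broken by longer
    envelope, then lexicographic profile id.  Overlap means sharing more
    than ``overlap_tolerance`` residues (default: any shared residue)."""
    if not hits:
        raise ValueError("no hits to resolve")
    proteins = {h.protein_id for h in hits}
    if len(proteins) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    length = max(h.protein_length for h in hits)
    order = sorted(hits, key=lambda h: (
        h.evalue, -(h.query_envelope[1] - h.query_envelope[0]), h.profile_id,
        h.query_envelope))
    accepted, rejected = [], []
    for h in order:
        s, e = h.query_envelope
        clash = any(min(e, b) - max(s, a) > overlap_tolerance
                    for a, b in (x.query_envelope for x in accepted))
        (rejected if clash else accepted).append(h)
    return ResolvedAnnotation(hits[0].protein_id, length, accepted, rejected,
                              min_orphan, overlap_tolerance)


def architecture_string(annotation: ResolvedAnnotation,
                        focal_profile: str = "O2_Hr") -> ArchitectureString:
    events = [(h.query_envelope[0], h.profile_id) for h in annotation.accepted]
    events += [(s, ORPHAN) for s, _ in annotation.orphan_regions]
    tokens = tuple(name for _, name in sorted(events))
    cls = terminus_class(annotation, focal_profile) \
        if any(h.profile_id == focal_profile for h in annotation.accepted) else "absent"
    return ArchitectureString(tokens, cls)


def terminus_class(annotation: ResolvedAnnotation, focal_profile: str) -> str:
    """Placement of the focal domain: ``N-terminal`` when nothing annotated
    (domain or orphan region) precedes it, ``C-terminal`` symmetrically,
    ``only-domain`` when both hold, ``internal`` otherwise."""
    focal = [h for h in annotation.accepted if h.profile_id == focal_profile]
    if not focal:
        raise KeyError(f"focal profile {focal_profile!r} not in accepted set")
    h = focal[0]
    s, e = h.query_envelope
    before = any(x.query_envelope[0] < s for x in annotation.accepted if x is not h)
    before |= any(a < s for a, _ in annotation.orphan_regions)
    after = any(x.query_envelope[0] > s for x in annotation.accepted if x is not h)
    after |= any(a > s for a, _ in annotation.orphan_regions)
    if not before and not after:
        return "only-domain"
    if not before:
        return "N-terminal"
    if not after:
        return "C-terminal"
    return "internal"


@dataclass
class ArchitectureCatalog:
    counts: dict                   # architecture string -> count
    species: dict                  # architecture string -> set of species

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def catalog(annotations: list, species_map: dict,
            focal_profile: str = "O2_Hr", missing: str = "error") -> ArchitectureCatalog:
    """Tabulate architecture strings over proteins; ``species_map`` maps
    protein id to species id (unknown ids error or bucket as 'unknown')."""
    if not annotations:
        raise ValueError("no annotations")
    counts: Counter = Counter()
    species = defaultdict(set)
    for ann in annotations:
        sp = _species_of(ann.protein_id, species_map, missing)
        key = str(architecture_string(ann, focal_profile))
        counts[key] += 1
        species[key].add(sp)
    return ArchitectureCatalog(dict(counts), dict(species))


def _species_of(protein_id, species_map, missing):
    if protein_id in species_map:
        return species_map[protein_id]
    if missing == "unknown":
        return "unknown"
    raise KeyError(f"species_map has no entry for {protein_id}")


def copy_number_table(annotations: list, species_map: dict,
                      focal_profile: str = "O2_Hr",
                      missing: str = "error") -> pd.DataFrame:
    """Per-species counts of single-domain and long focal-domain proteins
    (classification read from the focal hit)."""
    rows: dict = defaultdict(lambda: {"single_domain": 0, "long": 0})
    for ann in annotations:
        focal = [h for h in ann.accepted if h.profile_id == focal_profile]
        if not focal:
            continue
        sp = _species_of(ann.protein_id, species_map, missing)
        for h in focal:
            cls = h.classification or "long"
            rows[sp][cls] += 1
    df = pd.DataFrame([{"species": sp, **v} for sp, v in sorted(rows.items())],
                      columns=["species", "single_domain", "long"])
    df["total"] = df["single_domain"] + df["long"]
    return df


def presence_absence(cat: ArchitectureCatalog, taxa: list) -> pd.DataFrame:
    """Binary matrix: architectures (rows) x taxa (columns)."""
    archs = sorted(cat.counts)
    data = np.zeros((len(archs), len(taxa)), dtype=int)
    for i, a in enumerate(archs):
        present = cat.species.get(a, set())
        for j, t in enumerate(taxa):
            data[i, j] = int(t in present)
    return pd.DataFrame(data, index=archs, columns=list(taxa))


@dataclass
class FunctionCategoryMap:
    mapping: dict                  # domain name -> category label

    @classmethod
    def default(cls) -> "FunctionCategoryMap":
        """A small built-in map for the domains most often fused to the
        focal domain in real surveys."""
        return cls({
            "MCP_signal": "signal transduction",
            "HAMP": "signal transduction",
            "GGDEF": "signal transduction",
            "Cache_1": "signal transduction",
            "Response_reg": "phosphorelay response regulation",
            "AMP-binding": "protein binding",
        })


def function_summary(cat: ArchitectureCatalog, fmap: FunctionCategoryMap,
                     focal_profile: str = "O2_Hr") -> tuple:
    """Proportions of mapped functional categories over accepted non-focal
    domain occurrences.  Returns (category -> proportion, unmapped count);
    proportions sum to <= 1."""
    totals: Counter = Counter()
    unmapped = 0
    n = 0
    for arch, count in cat.counts.items():
        for token in arch.split("|"):
            if token in (focal_profile, ORPHAN) or not token:
                continue
            n += count
            category = fmap.mapping.get(token)
            if category is None:
                unmapped += count
            else:
                totals[category] += count
    props = {c: v / n for c, v in sorted(totals.items())} if n else {}
    return props, unmapped
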