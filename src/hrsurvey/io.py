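"""File I/O: FASTA (via biopython), truth tables and domain-hit tables.

File coordinates are 1-based inclusive; in-memory coordinates are 0-based
half-open.  The conversion happens here and only here.
"""

from __future__ import annotations

import hashlib

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HITS_COLUMNS = ["protein_id", "profile_id", "bit_score", "evalue",
                "env_start", "env_end", "profile_start", "profile_end",
                "reference_coverage", "protein_coverage", "classification"]


def read_fasta(path) -> list:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, seqs) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # wraps at 60 columns


def write_truth_tsv(path, truth) -> None:
    rows = [{"protein_id": t.protein_id, "template_id": t.template_id,
             "start": t.start, "end": t.end, "divergence": t.divergence}
            for t in truth]
    pd.DataFrame(rows, columns=["protein_id", "template_id", "start",
                                "end", "divergence"]).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def hits_to_frame(hits) -> pd.DataFrame:
    """Domain hits to a domtbl-like table (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        rows.append({
            "protein_id": h.protein_id, "profile_id": h.profile_id,
            "bit_score": round(h.bit_score, 3), "evalue": h.evalue,
            "env_start": h.query_envelope[0] + 1, "env_end": h.query_envelope[1],
            "profile_start": h.profile_span[0] + 1, "profile_end": h.profile_span[1],
            "reference_coverage": round(h.reference_coverage, 4),
            "protein_coverage": round(h.protein_coverage, 4),
            "classification": h.classification or "",
        })
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


def write_hits_tsv(path, hits) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path):
    from .phmm import DomainHit
    df = pd.read_csv(path, sep="\t")
    hits = []
    for r in df.itertuples():
        env = (int(r.env_start) - 1, int(r.env_end))
        span = (int(r.profile_start) - 1, int(r.profile_end))
        h = DomainHit(
            protein_id=r.protein_id, profile_id=r.profile_id,
            bit_score=float(r.bit_score), evalue=float(r.evalue),
            query_envelope=env, profile_span=span,
            classification=(str(r.classification)
                            if isinstance(r.classification, str) else None))
        # coverages are derived quantities; recover the denominators
        if float(r.protein_coverage) > 0:
            h.protein_length = round((env[1] - env[0]) / float(r.protein_coverage))
        if float(r.reference_coverage) > 0:
            h._nodes = round((span[1] - span[0]) / float(r.reference_coverage))
        hits.append(h)
    return hits


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
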