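#!/usr/bin/env python
"""One-time fetch of the reference hemerythrin chain sequences (network
required) for the pairwise-identity checks in tests/test_acceptance.py.

Downloads the PDB entry FASTA for the myohemerythrin/hemerythrin chains and
writes one single-record FASTA per label under tests/data/table1/.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

#: label -> (PDB id, chain substring preference)
CHAINS = {
    "2MHR": "2MHR",      # Themiste hennahi myohemerythrin
    "1I4Y": "1I4Y",      # Phascolopsis gouldii hemerythrin
    "4XPX": "4XPX",      # Methylococcus capsulatus McHr
    "DVU_HR": "2AWY",    # Desulfovibrio vulgaris hemerythrin-like chain
}

OUT = Path(__file__).resolve().parent.parent / "tests" / "data" / "table1"


def fetch(pdb_id: str) -> str:
    url = f"https://www.rcsb.org/fasta/entry/{pdb_id}"
    with urllib.request.urlopen(url, timeout=30) as fh:
        return fh.read().decode()


def first_record(fasta_text: str, label: str) -> str:
    blocks = [b for b in fasta_text.split(">") if b.strip()]
    header, *lines = blocks[0].splitlines()
    seq = "".join(lines)
    return f">{label} {header}\n{seq}\n"


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, pdb_id in CHAINS.items():
        try:
            text = fetch(pdb_id)
        except OSError as err:
            print(f"failed to fetch {pdb_id}: {err}", file=sys.stderr)
            return 1
        (OUT / f"{label}.fasta").write_text(first_record(text, label))
        print(f"wrote {OUT / f'{label}.fasta'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
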