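"""Fetch the worked-example structures from the PDB (network required).

Downloads entries 2CKY (Arabidopsis thaliana TPP riboswitch, chain A,
77 nt) and 2GDI (E. coli TPP riboswitch, chain X) from RCSB and stores
backbone-reduced copies (P, C4', N1/N9 atoms only) under tests/data/ so
they stay small.  The worked-example tests use these files; they fail
with a pointer to this script when the files are absent.

Usage:  python scripts/fetch_examples.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from relrna.structures import parse_structure, write_pdb  # noqa: E402

ENTRIES = [("2CKY", "A"), ("2GDI", "X")]


def main() -> None:
    out_dir = ROOT / "tests" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    for pdb_id, chain in ENTRIES:
        url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
        print(f"fetching {url}")
        text = urllib.request.urlopen(url, timeout=60).read().decode()
        st = parse_structure(text, chain)
        path = out_dir / f"{pdb_id.lower()}_{chain}.pdb"
        path.write_text(write_pdb(st))
        print(f"  wrote {path} ({len(st)} nt)")


if __name__ == "__main__":
    main()
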