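#!/usr/bin/env python
"""Fetch the deposited inputs used by the paper-number acceptance checks.

Network access is required.  Downloads into data/deposited/:

* PDB entries 6RXD (apo), 6RXE (InsS6 complex), 6RXF (phosphohistidine
  intermediate), 6RXG (Pi complex) and the comparator pair 4FDU/4FDT,
  as mmCIF from RCSB;
* the enzyme precursor sequence GenBank ACJ51391.1 from NCBI;
* the comparator (BtMINPP, from the 4FDU entry) sequence from RCSB;
* a pairwise alignment of the two sequences computed with MAFFT
  (precomputed alignments are pipeline inputs; the alignment step itself
  is outside the package scope).

Usage:  python scripts/fetch_deposited.py [--dest data/deposited]
"""

from __future__ import annotations

import argparse
import subprocess
import urllib.request
from pathlib import Path

ENTRIES = ["6rxd", "6rxe", "6rxf", "6rxg", "4fdu", "4fdt"]
RCSB_CIF = "https://files.rcsb.org/download/{code}.cif"
RCSB_FASTA = "https://www.rcsb.org/fasta/entry/{code}"
NCBI_FASTA = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id=ACJ51391.1&rettype=fasta&retmode=text"
)


def fetch(url: str, dest: Path) -> None:
    print(f"fetching {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--dest", type=Path,
        default=Path(__file__).resolve().parent.parent / "data" / "deposited",
    )
    args = parser.parse_args()
    dest = args.dest
    dest.mkdir(parents=True, exist_ok=True)

    for code in ENTRIES:
        fetch(RCSB_CIF.format(code=code.upper()), dest / f"{code}.cif")
    fetch(NCBI_FASTA, dest / "ACJ51391.fasta")
    fetch(RCSB_FASTA.format(code="4FDU"), dest / "btminpp.fasta")

    combined = dest / "blminpp_btminpp.fasta"
    combined.write_bytes(
        (dest / "ACJ51391.fasta").read_bytes()
        + (dest / "btminpp.fasta").read_bytes()
    )
    aln = dest / "blminpp_btminpp_aln.fasta"
    print("aligning with MAFFT")
    with open(aln, "w") as fh:
        subprocess.run(
            ["mafft", "--auto", str(combined)], stdout=fh, check=True
        )
    print(f"done; files under {dest}")


if __name__ == "__main__":
    main()
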