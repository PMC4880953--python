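#!/usr/bin/env python
"""Fetch the 31 mammalian mitochondrial genomes used by the full-scale tree
benchmark and explain how to build the reference tree.

Running this script requires network access to NCBI (Biopython Entrez).
It writes benchmark/genomes.fasta.  The alignment-based reference tree
(benchmark/reference.nwk) is NOT produced here: build it with an external
multiple-alignment pipeline, e.g.

    clustalw -infile=benchmark/genomes.fasta -tree

or any aligner + neighbor-joining/UPGMA tool that emits Newick, and save
the result as benchmark/reference.nwk.  Once both files exist, the
benchmark test in tests/test_acceptance.py runs automatically.
"""

from __future__ import annotations

import argparse
from pathlib import Path

ACCESSIONS = [
    "V00662", "D38116", "D38113", "D38114", "X99256", "Y18001", "AY863426",
    "D38115", "U20753", "EF551003", "EF551002", "U96639", "EU442884",
    "AJ002189", "AF010406", "V00654", "AY488491", "X97336", "Y07726",
    "X63726", "X72004", "AJ224821", "DQ316068", "DQ402478", "AF303110",
    "AF303111", "AJ001588", "X88898", "X14848", "AF348082", "AJ238588",
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    parser.add_argument(
        "--out", type=Path, default=Path("benchmark/genomes.fasta")
    )
    args = parser.parse_args()

    from Bio import Entrez, SeqIO

    Entrez.email = args.email
    args.out.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for acc in ACCESSIONS:
        print(f"fetching {acc} ...")
        with Entrez.efetch(
            db="nucleotide", id=acc, rettype="fasta", retmode="text"
        ) as handle:
            record = SeqIO.read(handle, "fasta")
            record.id = acc
            record.description = ""
            records.append(record)
    SeqIO.write(records, args.out, "fasta")
    print(f"wrote {len(records)} genomes to {args.out}")


if __name__ == "__main__":
    main()
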