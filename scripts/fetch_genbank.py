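#!/usr/bin/env python
"""Assemble the real tree-peony sequence panel from GenBank (optional).

Downloads the deposited chloroplast (KJ945637-KJ946200) and nuclear
(KM092534-KM093728) records, groups them by annotated gene/region and
organism, and writes one unaligned FASTA per group under --out.  The
records must then be aligned per locus (e.g. with ``mafft --auto``) and
relabelled with the ``SPECIES|...`` / ``CULTIVAR|...`` convention before
the pipeline can consume them.

Requires network access and an NCBI Entrez e-mail; nothing in the package
or its test suite depends on this script.

Usage:
    python scripts/fetch_genbank.py --email you@example.org --out data/genbank
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

from Bio import Entrez, SeqIO

RANGES = {
    "chloroplast": ("KJ945637", "KJ946200"),
    "nuclear": ("KM092534", "KM093728"),
}


def accessions(first: str, last: str) -> list[str]:
    prefix = first[:2]
    lo, hi = int(first[2:]), int(last[2:])
    return [f"{prefix}{i:06d}" for i in range(lo, hi + 1)]


def fetch(email: str, out_dir: Path, batch: int = 100) -> None:
    Entrez.email = email
    out_dir.mkdir(parents=True, exist_ok=True)
    for genome, (first, last) in RANGES.items():
        accs = accessions(first, last)
        groups: dict[str, list] = {}
        for start in range(0, len(accs), batch):
            chunk = accs[start : start + batch]
            with Entrez.efetch(
                db="nucleotide", id=",".join(chunk), rettype="gb",
                retmode="text",
            ) as handle:
                for rec in SeqIO.parse(handle, "genbank"):
                    region = "unknown"
                    for feat in rec.features:
                        for key in ("gene", "product", "note"):
                            if key in feat.qualifiers:
                                region = feat.qualifiers[key][0]
                                break
                        if region != "unknown":
                            break
                    groups.setdefault(region.replace(" ", "_"), []).append(rec)
            time.sleep(0.4)  # NCBI rate limit
        for region, records in groups.items():
            path = out_dir / f"{genome}_{region}.fasta"
            SeqIO.write(records, path, "fasta")
            print(f"wrote {len(records):4d} records -> {path}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", required=True, help="NCBI Entrez e-mail")
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()
    fetch(args.email, args.out)


if __name__ == "__main__":
    main()
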