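"""Fetch the deposited woodrat CYP2B clone set (GenBank JN105874-JN105960).

Optional helper: requires network access to NCBI E-utilities.  Writes
``data/deposited/cyp2b_clones.fasta`` with headers in the package's
``id|animal|population|diet`` convention.  The GenBank records do not
encode the feeding-trial metadata, so animal/population/diet fields are
filled with placeholders; the reproduction tests that use this file only
depend on the sequences themselves (unique counts, invariant codons,
p-distance, global dN/dS).

Usage:  python scripts/fetch_deposited.py [--out data/deposited]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
FIRST, LAST = 105874, 105960  # JN105874 .. JN105960


def accessions() -> list[str]:
    return [f"JN{i}" for i in range(FIRST, LAST + 1)]


def fetch_batch(ids: list[str]) -> str:
    params = urllib.parse.urlencode(
        {"db": "nucleotide", "id": ",".join(ids), "rettype": "fasta",
         "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as fh:
        return fh.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/deposited")
    args = parser.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    records: list[tuple[str, str]] = []
    ids = accessions()
    for start in range(0, len(ids), 30):
        chunk = ids[start : start + 30]
        text = fetch_batch(chunk)
        for block in text.strip().split(">"):
            if not block.strip():
                continue
            header, *lines = block.strip().splitlines()
            acc = header.split()[0].split(".")[0]
            records.append((acc, "".join(lines).upper()))
        time.sleep(0.4)  # NCBI rate limit

    if len(records) != len(ids):
        print(f"warning: fetched {len(records)} of {len(ids)} records",
              file=sys.stderr)
    out = outdir / "cyp2b_clones.fasta"
    with out.open("w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}|unknown|GB|juniper\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    print(f"wrote {len(records)} records to {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
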