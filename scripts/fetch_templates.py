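#!/usr/bin/env python
"""Fetch genomic template sequences for the shipped probe primer table from NCBI.

Optional helper, requires network access; nothing in the package or test
suite depends on its output.  It downloads each accession referenced in the
primer table via NCBI E-utilities and writes a single (large) FASTA that can
be fed to ``ishpattern amplicon --fasta``.

Usage:
    python scripts/fetch_templates.py --out templates.fa [--email you@example.org]

Note the accessions are whole chromosomes; expect multi-hundred-MB downloads.
"""

from __future__ import annotations

import argparse
import sys
import urllib.parse
import urllib.request

from ishpattern import load_probe_primer_table

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", required=True)
    parser.add_argument("--email", default="", help="contact email passed to NCBI")
    args = parser.parse_args()

    accessions = sorted({p.accession for p in load_probe_primer_table()})
    with open(args.out, "w") as out:
        for accession in accessions:
            params = {
                "db": "nuccore",
                "id": accession,
                "rettype": "fasta",
                "retmode": "text",
            }
            if args.email:
                params["email"] = args.email
            url = f"{EFETCH}?{urllib.parse.urlencode(params)}"
            print(f"fetching {accession} ...", file=sys.stderr)
            with urllib.request.urlopen(url) as response:
                out.write(response.read().decode())
    print(f"wrote {len(accessions)} templates to {args.out}", file=sys.stderr)


if __name__ == "__main__":
    main()
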