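#!/usr/bin/env python
"""Fetch the real inputs for the comparative analysis (requires network).

This is a documented convenience script, not a tested code path: the
package's tests and acceptance runs use the synthetic generators instead.

Inputs assembled:
  1. SIRT6 protein orthologs from NCBI (Entrez protein, query
     "SIRT6[Gene Name] AND mammalia[Organism] AND refseq[Filter]"),
     written as FASTA with Genus_species ids;
  2. the AnAge species/maximum-lifespan table
     (https://genomics.senescence.info/species/dataset.zip), reduced to
     species_id + max_lifespan_years TSV;
  3. a mammal supertree from VertLife (https://vertlife.org/phylosubsets),
     Newick.

After assembly, align the sequences with an external aligner, e.g.
    clustalo -i sirt6_orthologs.fasta -o sirt6_aligned.fasta
(or mafft), then run:
    phosevol run --config run.yaml
with reference_id Homo_sapiens and ref_boundary 290.
"""

import argparse
import csv
import io
import sys
import time
import urllib.parse
import urllib.request
import zipfile

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
ANAGE_URL = "https://genomics.senescence.info/species/dataset.zip"


def _get(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=60) as r:
        return r.read()


def fetch_sirt6_fasta(out_path: str, email: str) -> None:
    query = 'SIRT6[Gene Name] AND mammalia[Organism] AND refseq[Filter]'
    search = _get(
        f"{EUTILS}/esearch.fcgi?db=protein&retmax=2000&term="
        + urllib.parse.quote(query)
        + f"&email={email}"
    ).decode()
    ids = [line.split("<Id>")[1].split("</Id>")[0]
           for line in search.splitlines() if "<Id>" in line]
    print(f"{len(ids)} protein records", file=sys.stderr)
    with open(out_path, "w") as fh:
        for i in range(0, len(ids), 200):
            chunk = ",".join(ids[i : i + 200])
            fh.write(
                _get(
                    f"{EUTILS}/efetch.fcgi?db=protein&id={chunk}"
                    f"&rettype=fasta&retmode=text&email={email}"
                ).decode()
            )
            time.sleep(0.4)  # NCBI rate limit


def fetch_anage_tsv(out_path: str) -> None:
    data = zipfile.ZipFile(io.BytesIO(_get(ANAGE_URL)))
    name = next(n for n in data.namelist() if n.endswith(".txt"))
    with data.open(name) as fh, open(out_path, "w", newline="") as out:
        reader = csv.DictReader(io.TextIOWrapper(fh, "utf-8"), delimiter="\t")
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(["species_id", "max_lifespan_years"])
        for row in reader:
            if row.get("Class") != "Mammalia" or not row.get("Maximum longevity (yrs)"):
                continue
            writer.writerow(
                [f"{row['Genus']}_{row['Species']}", row["Maximum longevity (yrs)"]]
            )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", required=True, help="contact email for NCBI Entrez")
    ap.add_argument("--out-dir", default="real_data")
    args = ap.parse_args()
    import pathlib

    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fetch_sirt6_fasta(out / "sirt6_orthologs.fasta", args.email)
    fetch_anage_tsv(out / "lifespans.tsv")
    print(
        "Tree: download a mammal subset from https://vertlife.org/phylosubsets "
        "and save as tree.nwk; then align sequences and run `phosevol run`.",
        file=sys.stderr,
    )


if __name__ == "__main__":
    main()
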