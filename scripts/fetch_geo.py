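#!/usr/bin/env python
"""Download the GEO series-matrix files the acceptance report can consume.

Requires network access; the analysis library itself never downloads. Files
land uncompressed under ``data/geo/`` with the names
``scripts/acceptance.py`` expects. Platform probe annotations are NOT
fetched automatically: GEO platform tables (GPL4133, GPL571, GPL6100,
GPL6246, GPL6096, GPL2872) must be exported to
``data/geo/<name>_annotation.tsv`` with columns probe_id, gene_symbol,
transcript_accession.

Usage:
    python scripts/fetch_geo.py [--dest data/geo]
"""

from __future__ import annotations

import argparse
import gzip
import shutil
import urllib.request
from pathlib import Path

SERIES = {
    # our study deposits human and mouse arrays under one accession
    "GSE49974": ["GSE49974"],
    "GSE14098": ["GSE14098"],
    "GSE23714": ["GSE23714"],
    "GSE37098": ["GSE37098"],
    "GSE33009": ["GSE33009"],
}

URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{prefix}nnn/{gse}/matrix/"
    "{gse}_series_matrix.txt.gz"
)


def fetch(gse: str, dest: Path) -> None:
    prefix = gse[: len(gse) - 3]
    url = URL.format(prefix=prefix, gse=gse)
    gz_path = dest / f"{gse}_series_matrix.txt.gz"
    out_path = dest / f"{gse}_series_matrix.txt"
    print(f"fetching {url}")
    urllib.request.urlretrieve(url, gz_path)
    with gzip.open(gz_path, "rb") as src, out_path.open("wb") as dst:
        shutil.copyfileobj(src, dst)
    gz_path.unlink()
    print(f"wrote {out_path}")


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("data/geo"))
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for gse in SERIES:
        fetch(gse, args.dest)
    print(
        "note: multi-platform series (e.g. GSE49974) ship one matrix per "
        "platform; split/rename them to the *_series_matrix.txt names the "
        "acceptance script expects, and provide *_annotation.tsv files."
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
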