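"""Readers and writers for the plain-text interchange formats.

Conventions are strict by design so that artifacts round-trip bit-exactly:
BED is 0-based half-open and sorted; FASTQ is four-line records; TSV carries
a header row and tolerates ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

# Columns of an integration table (see discovery.IntegrationTable contract).
INTEGRATION_COLUMNS = ["chrom", "position", "strand", "sample", "replicate", "group"]


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality: int = 35) -> None:
    """Write (name, sequence) pairs as strict four-line FASTQ records."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Strict four-line FASTQ reader returning (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_integrations_bed(path: str | Path, table: pd.DataFrame) -> None:
    """Write an integration table as BED6, name = ``sample:replicate:group``.

    Output is sorted by (chrom, start) and 0-based half-open with unit width.
    """
    bed = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["position"].astype(int),
            "end": table["position"].astype(int) + 1,
            "name": (
                table["sample"].astype(str)
                + ":"
                + table["replicate"].astype(str)
                + ":"
                + table["group"].astype(str)
            ),
            "score": 1,
            "strand": table["strand"],
        }
    ).sort_values(["chrom", "start", "name"], kind="mergesort")
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_integrations_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", names=BED6_COLUMNS, comment="#")
    parts = bed["name"].str.split(":", expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "position": bed["start"].astype(int),
            "strand": bed["strand"],
            "sample": parts[0],
            "replicate": parts[1].astype(int),
            "group": parts[2],
        }
    )


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_of_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, *, config_hash: str, seed: int,
                   artifacts: Iterable[str | Path]) -> None:
    """Record provenance (config hash, seed, per-file checksums) as JSON."""
    entries = {
        str(Path(p).name): sha256_of_file(p) for p in sorted(map(str, artifacts))
    }
    payload = {"config_sha256": config_hash, "seed": seed, "artifacts": entries}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
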