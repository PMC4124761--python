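"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ parsing goes through Biopython; GFF3 and BED are read with
pandas (they are tab-separated tables) and written by hand.  All genomic
coordinates are 0-based half-open in memory and converted at the GFF3
boundary only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class FastqRead:
    """One sequencing read: identifier, bases, Phred+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream a (optionally gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield FastqRead(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            handle.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a name -> sequence mapping."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame with 0-based half-open start/end.

    The ``ID`` and ``Parent`` attributes are lifted into their own columns.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
            dtype={"seqid": str, "type": str, "strand": str, "attributes": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed GFF3 file {path}: {exc}") from exc
    if df.empty:
        df = pd.DataFrame(columns=GFF3_COLUMNS + ["ID", "Parent"])
        return df
    try:
        if df["start"].isna().any() or df["end"].isna().any():
            raise ValueError("missing coordinates")
        df["start"] = df["start"].astype(int) - 1  # GFF3 is 1-based inclusive
        df["end"] = df["end"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed GFF3 file {path}: {exc}") from exc

    def attr(field: str, attrs: str) -> str | None:
        for part in str(attrs).split(";"):
            if part.startswith(field + "="):
                return part[len(field) + 1 :]
        return None

    df["ID"] = [attr("ID", a) for a in df["attributes"]]
    df["Parent"] = [attr("Parent", a) for a in df["attributes"]]
    return df


def write_gff3(records: Iterable[dict], path: str | Path) -> None:
    """Write GFF3 from dicts with 0-based half-open ``start``/``end`` keys.

    Expected keys: seqid, source, type, start, end, strand, id and
    optionally parent.
    """
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for rec in records:
            attrs = f"ID={rec['id']}"
            if rec.get("parent"):
                attrs += f";Parent={rec['parent']}"
            handle.write(
                "\t".join(
                    [
                        rec["seqid"],
                        rec.get("source", "smallrna_sig"),
                        rec["type"],
                        str(rec["start"] + 1),
                        str(rec["end"]),
                        ".",
                        rec["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                         dtype={"chrom": str, "name": str, "strand": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed BED file {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
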