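"""Readers and writers for the plain-text formats used throughout the package.

FASTA goes through Biopython; BED6 and the small tabular formats are plain
pandas tables. All genomic intervals are 0-based half-open, matching BED.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps N; case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    return df


def write_bed6(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_spacers(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read spacers from FASTA or from a 2-column TSV (id, sequence)."""
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return list(read_fasta(path).items())
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "sequence"], comment="#")
    return [(str(r.id), str(r.sequence).upper()) for r in df.itertuples()]


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def validate_dna(seq: str, what: str = "sequence", alphabet: Iterable[str] = "ACGT") -> str:
    """Uppercase and check a DNA string against an alphabet; raise ValueError."""
    seq = seq.upper()
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq
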