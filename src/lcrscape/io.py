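"""File readers and writers shared across the pipeline stages."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import LCRegion, ProteomeAnnotation
from .entropy import ProteinRecord


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA; the id is the header up to first whitespace."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteome: Iterable[ProteinRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in proteome),
        str(path),
        "fasta",
    )


def read_lcr_table(path) -> pd.DataFrame:
    """Read an LCR interval table written by :meth:`ProteomeAnnotation.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start0", "end_excl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LCR table {path} lacks columns: {sorted(missing)}")
    return df


def read_id_list(path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    if not out:
        raise ValueError(f"no identifiers read from {path}")
    return out


def read_synonym_map(path) -> dict[str, str]:
    """Two-column TSV mapping alias -> canonical identifier."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 2:
                out[fields[0].strip()] = fields[1].strip()
    return out
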