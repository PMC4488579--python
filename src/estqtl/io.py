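"""File-format dialects: multi-FASTA via Biopython, header-row TSV via pandas.

Conventions: TSVs are tab-delimited UTF-8 with a mandatory header row and
``.`` decimal separator; cM coordinates print with one decimal; FASTA wraps
at 70 columns and ids contain no whitespace.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WRAP = 70
_CM_COLUMNS = ("position_cM", "ci_lo_cM", "ci_hi_cM", "lo_cM", "hi_cM",
               "region_lo_cM", "region_hi_cM")


def read_fasta(path) -> dict[str, str]:
    """Read a multi-FASTA into an ordered id -> sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path) -> None:
    """Write sequences wrapped at 70 columns; ids must be whitespace-free."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for sid, seq in seqs.items():
        if any(c.isspace() for c in sid):
            raise ValueError(f"sequence id contains whitespace: {sid!r}")
        records.append(SeqRecord(Seq(seq), id=sid, description=""))
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a header-row TSV; empty cells stay empty strings, never NaN."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a TSV with cM columns formatted to one decimal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if col in _CM_COLUMNS:
            out[col] = out[col].map(
                lambda v: f"{float(v):.1f}" if v != "" else "")
    out.to_csv(path, sep="\t", index=False)


__all__ = ["read_fasta", "write_fasta", "read_tsv", "write_tsv", "FASTA_WRAP"]
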