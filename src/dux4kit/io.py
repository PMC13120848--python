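"""Readers and writers for the pipeline's text formats.

FASTA for guide strands and 3'UTR collections (record id = gene/transcript
id, description ignored), tab-separated tables with a required header for
everything else.  Errors name the offending file and column/record.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scoring import CtTable
from .seeds import GuideStrand, UtrRecord


class ParseError(ValueError):
    """Malformed input file."""


def read_guides_fasta(path) -> list[GuideStrand]:
    """Load guide strands from FASTA.

    Guides written in DNA alphabet (T instead of U) are transcribed to RNA
    on read; validation errors name the file and record.
    """
    guides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        try:
            guides.append(GuideStrand(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not guides:
        raise ParseError(f"{path}: no FASTA records found")
    return guides


def read_utrs_fasta(path) -> list[UtrRecord]:
    utrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            utrs.append(UtrRecord(gene_id=rec.id, utr_sequence=str(rec.seq)))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not utrs:
        raise ParseError(f"{path}: no FASTA records found")
    return utrs


def write_fasta(records, path, width: int = 60) -> None:
    """Write GuideStrand/UtrRecord collections as 60-column FASTA."""
    seq_records = []
    for r in records:
        if isinstance(r, GuideStrand):
            seq_records.append(SeqRecord(Seq(r.sequence), id=r.id, description=""))
        else:
            seq_records.append(SeqRecord(Seq(r.utr_sequence), id=r.gene_id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_table(path, required_columns: Sequence[str] = (), index_col=None) -> pd.DataFrame:
    """Read a tab-separated table with a header, checking required columns."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=index_col)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_ct_table(path) -> CtTable:
    """Read a Ct table: columns ``sample``, ``condition``, optional
    ``group``, then one column per gene."""
    df = read_table(path, required_columns=("sample", "condition"))
    df = df.set_index("sample")
    condition = df.pop("condition")
    group = df.pop("group") if "group" in df.columns else None
    return CtTable(ct=df.astype(float), condition=condition, group=group)


def write_ct_table(table: CtTable, path) -> None:
    df = table.ct.copy()
    df.insert(0, "condition", table.condition)
    if table.group is not None:
        df.insert(1, "group", table.group)
    df.index.name = "sample"
    write_table(df, path)


def read_gene_set(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if not genes:
        raise ParseError(f"{path}: no gene ids found")
    return genes
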