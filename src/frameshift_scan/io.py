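"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; tab-separated tables through pandas. BAM
ingestion of transcript-aligned ribosome footprints is optional and only
imports pysam when used.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import CodingSequence, InvalidSequenceError

logger = logging.getLogger(__name__)

RPF_COLUMNS = ["transcript_id", "five_prime_pos", "read_length", "condition", "replicate"]
PEPTIDE_COLUMNS = ["sequence", "sample_id", "condition", "replicate"]


def read_cds_fasta(path: str | Path, strict: bool = True) -> list[CodingSequence]:
    """Load coding sequences from FASTA (description ignored; U -> T applied).

    With ``strict=False`` invalid ORFs are skipped with a warning instead
    of raising.
    """
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(CodingSequence.from_raw(rec.id, str(rec.seq)))
        except InvalidSequenceError:
            if strict:
                raise
            logger.warning("skipping invalid CDS %s", rec.id)
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA as {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (header, sequence) pairs; deterministic byte output for fixed input."""
    records = [
        SeqRecord(Seq(seq), id=header, description="") for header, seq in entries
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_rpf_table(path: str | Path) -> pd.DataFrame:
    """RPF alignment table: transcript_id, five_prime_pos, read_length, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    missing = set(RPF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RPF table {path} missing columns: {sorted(missing)}")
    return df


def read_rpf_bam(path: str | Path, condition: str, replicate: int = 1) -> pd.DataFrame:
    """Ingest a transcript-aligned BAM: reference name is the transcript id,
    POS converts 1-based to the 0-based five_prime_pos."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append(
                (aln.reference_name, aln.reference_start, aln.query_length, condition, replicate)
            )
    return pd.DataFrame(rows, columns=RPF_COLUMNS)


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Identified-peptide table: sequence, sample_id, condition, replicate[, probability]."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table {path} missing columns: {sorted(missing)}")
    df["sequence"] = df["sequence"].str.upper()
    return df


def read_expression_table(path: str | Path, value_col: str) -> pd.DataFrame:
    """Long-format expression table: gene_id, condition, replicate, <value_col>."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "replicate", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} missing columns: {sorted(missing)}")
    return df


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Two-column gene_id / transcript_id map."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "transcript_id"} - set(df.columns)
    if missing:
        raise ValueError(f"gene map {path} missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
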