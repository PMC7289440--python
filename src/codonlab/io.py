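"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython, SAM through pysam, tables through pandas.
All tables are tab-separated with a header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_model import CodonUsageTable, TRNAPool
from .genetic_code import SENSE_CODONS
from .ribo_occupancy import RPFAlignment, TranscriptAnnotation
from .trna_editing import TRNAReference


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an id -> sequence mapping (first whitespace token as id)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_trna_pool_tsv(path: str | Path) -> TRNAPool:
    """TSV with columns amino_acid, anticodon, gene_copy_number."""
    df = pd.read_csv(path, sep="\t")
    return TRNAPool.from_frame(df)


def write_trna_pool_tsv(pool: TRNAPool, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "amino_acid": e.amino_acid,
                "anticodon": e.anticodon,
                "gene_copy_number": e.gene_copy_number,
            }
            for e in pool.entries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_codon_usage_tsv(path: str | Path, scope: str = "") -> CodonUsageTable:
    """TSV with columns codon, count (Kazusa-style count tables importable)."""
    df = pd.read_csv(path, sep="\t")
    counts = df.set_index("codon")["count"]
    return CodonUsageTable(counts.reindex(SENSE_CODONS, fill_value=0), scope=scope)


def write_codon_usage_tsv(usage: CodonUsageTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {"count": usage.counts, "freq_per_thousand": usage.freq_per_thousand}
    )
    out.rename_axis("codon").to_csv(path, sep="\t")


def read_trna_references(fasta_path: str | Path, meta_path: str | Path) -> list[TRNAReference]:
    """References from FASTA plus a TSV of trna_id, amino_acid, anticodon, wobble_index."""
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t").set_index("trna_id")
    refs = []
    for tid, row in meta.iterrows():
        if tid not in seqs:
            raise ValueError(f"reference {tid} missing from FASTA")
        refs.append(
            TRNAReference(
                trna_id=str(tid),
                amino_acid=row["amino_acid"],
                anticodon=row["anticodon"],
                sequence=seqs[tid],
                wobble_index=int(row["wobble_index"]),
            )
        )
    return refs


def write_trna_references(refs: Sequence[TRNAReference], fasta_path: str | Path, meta_path: str | Path) -> None:
    write_fasta({r.trna_id: r.sequence for r in refs}, fasta_path)
    pd.DataFrame(
        [
            {
                "trna_id": r.trna_id,
                "amino_acid": r.amino_acid,
                "anticodon": r.anticodon,
                "wobble_index": r.wobble_index,
            }
            for r in refs
        ]
    ).to_csv(meta_path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> list[RPFAlignment]:
    """Internal alignment table: read_id, transcript_id, five_prime_pos, read_length."""
    df = pd.read_csv(path, sep="\t")
    return [
        RPFAlignment(
            read_id=str(r.read_id),
            transcript_id=str(r.transcript_id),
            five_prime_pos=int(r.five_prime_pos),
            read_length=int(r.read_length),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignments_tsv(alignments: Iterable[RPFAlignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "transcript_id": a.transcript_id,
                "five_prime_pos": a.five_prime_pos,
                "read_length": a.read_length,
            }
            for a in alignments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_rpf_sam(path: str | Path) -> list[RPFAlignment]:
    """Transcriptome-coordinate SAM/BAM to footprint alignments.

    Unmapped, secondary and supplementary records are dropped; a record
    flagged secondary marks its read as multi-mapped, so all its records are
    excluded (unique-match rule).
    """
    import pysam

    multi: set[str] = set()
    primary: list[RPFAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.is_secondary or rec.is_supplementary:
                multi.add(rec.query_name)
                continue
            primary.append(
                RPFAlignment(
                    read_id=rec.query_name,
                    transcript_id=rec.reference_name,
                    five_prime_pos=rec.reference_start + 1,
                    read_length=rec.query_length,
                )
            )
    return [a for a in primary if a.read_id not in multi]


def read_annotations(fasta_path: str | Path, orf_table_path: str | Path) -> dict[str, TranscriptAnnotation]:
    """Transcript FASTA plus a TSV of transcript_id, orf_start (1-based)."""
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(orf_table_path, sep="\t").set_index("transcript_id")
    out = {}
    for tid, row in meta.iterrows():
        if tid not in seqs:
            raise ValueError(f"transcript {tid} missing from FASTA")
        out[str(tid)] = TranscriptAnnotation(str(tid), seqs[tid], int(row["orf_start"]))
    return out


def write_annotations(
    annotations: Mapping[str, TranscriptAnnotation],
    fasta_path: str | Path,
    orf_table_path: str | Path,
) -> None:
    write_fasta({t: a.sequence for t, a in annotations.items()}, fasta_path)
    pd.DataFrame(
        [{"transcript_id": t, "orf_start": a.orf_start} for t, a in annotations.items()]
    ).to_csv(orf_table_path, sep="\t", index=False)


def read_peptide_ratios(path: str | Path) -> pd.DataFrame:
    """TSV of protein_id, peptide_id, ratio."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "peptide_id", "ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns {sorted(missing)}")
    return df
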