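"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; MAF blocks through a small reader/writer matching the
UCSC block layout; PSM/score/expression tables as TSV through pandas; trees
as newick text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .orf_catalog import GeneAnnotation, NucleotideRecord, PotentialOrf
from .proteomics import Psm
from .synteny import MsaBlock

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike, kind: str = "genome-contig") -> List[NucleotideRecord]:
    return [
        NucleotideRecord(id=rec.id, sequence=str(rec.seq), kind=kind)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: PathLike, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_orf_fasta(path: PathLike, orfs: Iterable[PotentialOrf]) -> None:
    write_fasta(path, {orf.id: orf.aa_sequence for orf in orfs})


def write_orf_bed(path: PathLike, orfs: Iterable[PotentialOrf]) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            iv = orf.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{orf.id}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Annotation (minimal GFF/GTF-like TSV: contig, source, feature, start, end,
# score, strand, frame, attributes; 1-based closed input coordinates)


def read_gff_genes(path: PathLike, feature: str = "gene") -> List[GeneAnnotation]:
    out: List[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] != feature:
                continue
            contig, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            attrs = parts[8] if len(parts) > 8 else ""
            gene_id = attrs.split(";")[0].split("=")[-1].strip() or f"{contig}:{start}"
            out.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    interval=GenomicInterval(contig, start - 1, end, strand),
                )
            )
    return out


# ---------------------------------------------------------------------------
# MAF


def write_maf(path: PathLike, blocks: Sequence[MsaBlock]) -> None:
    """Write blocks in MAF layout; the reference row is emitted first."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            iv = block.reference_interval
            order = [block.reference_species] + sorted(
                s for s in block.rows if s != block.reference_species
            )
            for sp in order:
                row = block.rows[sp]
                size = sum(c != "-" for c in row)
                start = iv.start if sp == block.reference_species else 0
                src_size = iv.end if sp == block.reference_species else size
                fh.write(
                    f"s {sp}.{iv.contig} {start} {size} + {src_size} {row}\n"
                )
            fh.write("\n")


def read_maf(path: PathLike, reference_species: str) -> List[MsaBlock]:
    blocks: List[MsaBlock] = []
    rows: Dict[str, str] = {}
    contig = None
    start = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("a"):
                rows, contig, start = {}, None, None
            elif line.startswith("s "):
                _, src, s_start, _size, _strand, _src_size, text = line.split()
                sp, _, ctg = src.partition(".")
                rows[sp] = text
                if sp == reference_species:
                    contig, start = ctg, int(s_start)
            elif not line.strip() and rows:
                blocks.append(_finish_block(rows, contig, start, reference_species))
                rows = {}
    if rows:
        blocks.append(_finish_block(rows, contig, start, reference_species))
    return blocks


def _finish_block(
    rows: Dict[str, str], contig: Optional[str], start: Optional[int],
    reference_species: str,
) -> MsaBlock:
    if contig is None or start is None:
        raise ValueError("MAF block lacks a reference row")
    size = sum(c != "-" for c in rows[reference_species])
    return MsaBlock(
        reference_interval=GenomicInterval(contig, start, start + size, "+"),
        rows=dict(rows),
        reference_species=reference_species,
    )


# ---------------------------------------------------------------------------
# PSM tables


PSM_COLUMNS = [
    "peptide", "score", "is_decoy", "run", "observed_rt", "predicted_rt", "group",
]


def write_psm_table(path: PathLike, psms: Sequence[Psm]) -> None:
    df = pd.DataFrame(
        {
            "peptide": [p.peptide for p in psms],
            "score": [p.score for p in psms],
            "is_decoy": [int(p.is_decoy) for p in psms],
            "run": [p.run_id for p in psms],
            "observed_rt": [p.observed_rt for p in psms],
            "predicted_rt": [p.predicted_rt for p in psms],
            "group": [p.parent_group for p in psms],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_psm_table(path: PathLike) -> List[Psm]:
    df = pd.read_csv(path, sep="\t")
    out: List[Psm] = []
    for row in df.itertuples(index=False):
        out.append(
            Psm(
                peptide=str(row.peptide),
                score=float(row.score),
                is_decoy=bool(row.is_decoy),
                run_id="" if pd.isna(row.run) else str(row.run),
                observed_rt=None if pd.isna(row.observed_rt) else float(row.observed_rt),
                predicted_rt=None if pd.isna(row.predicted_rt) else float(row.predicted_rt),
                parent_group="" if pd.isna(row.group) else str(row.group),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Generic TSV matrices


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(path: PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")
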