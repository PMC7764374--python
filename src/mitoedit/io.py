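"""Readers and writers for the pipeline's file formats.

Tabular inputs (pileup counts, design, gene counts, Ct measurements) are
plain TSV/CSV read with pandas.  Gene models travel as GFF3 (1-based,
inclusive) parsed with gffutils; genomes as FASTA via Biopython; germline
variants as VCF via cyvcf2.  The GFF3 layout written here is
gene -> mRNA -> exon/intron, with the CDS offset carried as a
``cds_start_tpos`` attribute on the mRNA and intron labels in ``Name``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_models import GeneModel, Intron

__all__ = [
    "read_pileups",
    "read_design",
    "read_counts",
    "read_ct_table",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_vcf",
]

PILEUP_COLUMNS = ["sample_id", "tissue", "replicate", "chrom", "pos", "ref", "na", "nc", "ng", "nt"]


def read_pileups(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pileup TSV missing columns {sorted(missing)}")
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "tissue", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design CSV missing columns {sorted(missing)}")
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "sample_id", "read_pairs"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: counts TSV missing columns {sorted(missing)}")
    return df


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = {"tissue", "replicate", "amplicon", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct CSV missing columns {sorted(missing)}")
    return df


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.span
        lines.append(_gff_line(g.chrom, "gene", lo, hi, g.strand, f"ID={g.gene_id}"))
        lines.append(
            _gff_line(
                g.chrom, "mRNA", lo, hi, g.strand,
                f"ID={g.gene_id}.t1;Parent={g.gene_id};cds_start_tpos={g.cds_start_tpos}",
            )
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                _gff_line(g.chrom, "exon", s, e, g.strand, f"ID={g.gene_id}.exon{i};Parent={g.gene_id}.t1")
            )
        for i, intron in enumerate(g.introns, start=1):
            lines.append(
                _gff_line(
                    g.chrom, "intron", intron.start, intron.end, g.strand,
                    f"ID={g.gene_id}.intron{i};Parent={g.gene_id}.t1;Name={intron.label}",
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_line(chrom, ftype, start, end, strand, attrs) -> str:
    return "\t".join([chrom, "mitoedit", ftype, str(start), str(end), ".", strand, ".", attrs])


def read_gff3(path) -> List[GeneModel]:
    """Load gene models from GFF3 (in-memory gffutils database)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: List[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        strand = mrna.strand
        exons = sorted(
            ((f.start, f.end) for f in db.children(mrna, featuretype="exon")),
            reverse=(strand == "-"),
        )
        introns = sorted(
            (
                Intron(f.start, f.end, f.attributes.get("Name", [f.id])[0])
                for f in db.children(mrna, featuretype="intron")
            ),
            key=lambda i: i.start,
            reverse=(strand == "-"),
        )
        cds_start = int(mrna.attributes.get("cds_start_tpos", ["1"])[0])
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=strand,
                exons=tuple(exons),
                introns=tuple(introns),
                cds_start_tpos=cds_start,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span))
    return genes


VCF_HEADER = """##fileformat=VCFv4.2
##source=mitoedit-synthetic
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Write a minimal germline VCF (chrom, pos, ref, alt columns)."""
    lines = [VCF_HEADER.rstrip("\n")]
    for _, v in variants.sort_values(["chrom", "pos"]).iterrows():
        lines.append(
            "\t".join([str(v["chrom"]), str(int(v["pos"])), ".", v["ref"], v["alt"], ".", "PASS", "."])
        )
    Path(path).write_text("\n".join(lines) + "\n")
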