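"""Readers and writers for the interchange formats binding the stages.

All in-memory and TSV coordinates are 1-based inclusive, matching VCF and
GFF3; BED output alone is 0-based half-open. Malformed lines are reported
with their line number; cross-file chromosome mismatches raise a
consistency error naming both files.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .models import GeneModel, ValidationError, Variant


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# -- GFF3 -------------------------------------------------------------------


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\temsomics\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{a}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\temsomics\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\temsomics\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            cds_order = g.cds if g.strand == "+" else list(reversed(g.cds))
            cum = 0
            phased = []
            for s, e in cds_order:
                phased.append((s, e, (3 - cum % 3) % 3))
                cum += e - s + 1
            for s, e, phase in sorted(phased):
                fh.write(
                    f"{g.chrom}\temsomics\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"Parent={mrna}\n"
                )
            for s, e in g.utr5:
                fh.write(
                    f"{g.chrom}\temsomics\tfive_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.chrom}\temsomics\tthree_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons, cds, utr5, utr3 = [], [], [], []
        for mrna in db.children(g, featuretype="mRNA"):
            exons += [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds += [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            utr5 += [
                (f.start, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")
            ]
            utr3 += [
                (f.start, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")
            ]
        gm = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            start=g.start,
            end=g.end,
            exons=sorted(exons),
            cds=sorted(cds),
            utr5=sorted(utr5),
            utr3=sorted(utr3),
        )
        if gm.cds_length % 3:
            # flagged, not fatal: annotations in the wild contain partial CDS
            import warnings

            warnings.warn(f"{gm.gene_id}: CDS length {gm.cds_length} not divisible by 3")
        genes.append(gm)
    return genes


# -- VCF --------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(variants: list[Variant], genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmutant\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gt = "0/1" if v.zygosity == "het" else "1/1"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_vcf(path: str | Path, genome: dict[str, str] | None = None) -> list[Variant]:
    """Read VCF 4.2; multi-allelic records are split into biallelic variants.

    When a genome is supplied, each record's REF is validated against it.
    """
    out: list[Variant] = []
    for rec in VCF(str(path)):
        if genome is not None:
            if rec.CHROM not in genome:
                raise ValidationError(
                    f"{path}: chromosome {rec.CHROM!r} absent from the genome FASTA"
                )
            ref_here = genome[rec.CHROM][rec.POS - 1 : rec.POS - 1 + len(rec.REF)]
            if ref_here != rec.REF:
                raise ValidationError(
                    f"{path}: {rec.CHROM}:{rec.POS} REF {rec.REF!r} does not match FASTA"
                )
        if rec.genotypes:
            a, b = rec.genotypes[0][:2]
            zyg = "het" if a != b else "hom"
        else:
            zyg = "hom"
        for alt in rec.ALT:
            out.append(Variant(rec.CHROM, rec.POS, rec.REF, alt, zyg))
    return out


# -- count table ------------------------------------------------------------

_COUNT_COLS = ["gene_id", "length_bp", "count_control", "count_mutant"]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False, columns=_COUNT_COLS)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COUNT_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing count-table columns {sorted(missing)}")
    for col in _COUNT_COLS[1:]:
        if (df[col] < 0).any():
            line = int(df.index[df[col] < 0][0]) + 2  # header + 1-based
            raise ValidationError(f"{path}:{line}: negative {col}")
    return df


# -- cytosine report --------------------------------------------------------

_CYT_COLS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


def write_cytosine_report(
    sites: pd.DataFrame, path: str | Path, genome: dict[str, str] | None = None
) -> None:
    """Bismark-style per-cytosine report (headerless TSV, 1-based positions)."""
    df = sites.copy()
    if "trinucleotide" not in df.columns:
        df["trinucleotide"] = df["context"]
    df.to_csv(path, sep="\t", index=False, header=False, columns=_CYT_COLS)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_CYT_COLS)
    for col in ("count_methylated", "count_unmethylated"):
        bad = df[col] < 0
        if bad.any():
            raise ValidationError(f"{path}:{int(df.index[bad][0]) + 1}: negative {col}")
    if not df["context"].isin(["CG", "CHG", "CHH"]).all():
        bad = ~df["context"].isin(["CG", "CHG", "CHH"])
        raise ValidationError(f"{path}:{int(df.index[bad][0]) + 1}: bad context value")
    return df


# -- BED and tables ---------------------------------------------------------


def write_bed(intervals, path: str | Path) -> None:
    """(chrom, start, end[, name]) tuples with 1-based inclusive starts are
    written as 0-based half-open BED."""
    with open(path, "w") as fh:
        fh.write('#coordinates: 0-based half-open\n')
        for iv in intervals:
            chrom, start, end = iv[:3]
            name = iv[3] if len(iv) > 3 else "."
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
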