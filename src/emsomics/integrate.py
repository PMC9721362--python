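"""Three-way integration of variant, transcriptome and methylome gene sets.

Set R holds genes with large-impact variants, set T the called DEGs, and set
M the genes whose body or promoter overlaps a DMR. All seven Venn cells are
computed and a candidate table reports, per intersection gene, both
expression values, the fold change and test statistics, with an explicit NA
marker for genes never quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .models import DMR, GeneModel


@dataclass
class IntegrationReport:
    set_R: set[str]
    set_T: set[str]
    set_M: set[str]
    cells: dict[str, set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.cells.items()}

    def to_dict(self) -> dict:
        out = {k: sorted(v) for k, v in self.cells.items()}
        out["counts"] = self.counts
        out["percent_of_T"] = {
            "RT": 100.0 * len(self.cells["RT"] | self.cells["RTM"]) / len(self.set_T)
            if self.set_T
            else 0.0
        }
        return out


def assign_dmr_genes(
    dmrs: list[DMR], genes: list[GeneModel], promoter_bp: int = 2000
) -> set[str]:
    """Genes whose body or promoter overlaps at least one DMR by >= 1 bp."""
    out: set[str] = set()
    for gene in genes:
        if gene.strand == "+":
            start, end = gene.start - promoter_bp, gene.end
        else:
            start, end = gene.start, gene.end + promoter_bp
        for d in dmrs:
            if d.chrom == gene.chrom and d.start <= end and d.end >= start:
                out.add(gene.gene_id)
                break
    return out


def overlap_sets(set_R: set[str], set_T: set[str], set_M: set[str]) -> IntegrationReport:
    """All seven disjoint Venn cells of the three gene sets."""
    r, t, m = set(set_R), set(set_T), set(set_M)
    triple = r & t & m
    cells = {
        "R_only": r - t - m,
        "T_only": t - r - m,
        "M_only": m - r - t,
        "RT": (r & t) - m,
        "TM": (t & m) - r,
        "RM": (r & m) - t,
        "RTM": triple,
    }
    return IntegrationReport(set_R=r, set_T=t, set_M=m, cells=cells)


def candidate_report(
    report: IntegrationReport,
    deg_table: pd.DataFrame,
    annotations: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Candidate-gene table over every pairwise/triple intersection gene.

    Columns mirror a two-omics candidate listing: the intersection class,
    both expression values (FPKM), log2 fold change, raw and adjusted
    p-values and a functional annotation passthrough. Genes without
    expression data carry "NA" strings.
    """
    annotations = annotations or {}
    deg = deg_table.set_index("gene_id") if len(deg_table) else pd.DataFrame()
    class_of = [
        ("R vs T", sorted(report.cells["RT"] | report.cells["RTM"])),
        ("T vs M", sorted(report.cells["TM"])),
        ("R vs M", sorted(report.cells["RM"])),
    ]
    rows = []
    for label, gene_ids in class_of:
        for gid in gene_ids:
            if len(deg) and gid in deg.index:
                rec = deg.loc[gid]
                rows.append(
                    {
                        "classification": label,
                        "gene_id": gid,
                        "fpkm_control": round(float(rec["fpkm_control"]), 2),
                        "fpkm_mutant": round(float(rec["fpkm_mutant"]), 2),
                        "log2fc": round(float(rec["log2fc"]), 2),
                        "pvalue": float(rec["pvalue"]),
                        "padj": float(rec["padj"]),
                        "annotation": annotations.get(gid, ""),
                    }
                )
            else:
                rows.append(
                    {
                        "classification": label,
                        "gene_id": gid,
                        "fpkm_control": "NA",
                        "fpkm_mutant": "NA",
                        "log2fc": "NA",
                        "pvalue": "NA",
                        "padj": "NA",
                        "annotation": annotations.get(gid, ""),
                    }
                )
    columns = [
        "classification",
        "gene_id",
        "fpkm_control",
        "fpkm_mutant",
        "log2fc",
        "pvalue",
        "padj",
        "annotation",
    ]
    return pd.DataFrame(rows, columns=columns)
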