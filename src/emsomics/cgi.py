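"""CpG-island prediction and methylation-expression pattern classification.

Islands are found Gardiner-Garden & Frommer style: a 100 bp window slid by
1 bp; windows with GC >= 50% and observed/expected CpG >= 0.6
(Exp = countC * countG / window length) are merged, and a merged region is
reported when it is >= 200 bp long and still satisfies both thresholds as a
whole. Ns count toward window length but not toward C/G.

The island search region of a gene spans 2,000 bp upstream of the
transcription start to the end of the 3' UTR (gene end when no UTR is
annotated), strand aware, clipped to the chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .models import CpGIsland, DEGResult, GeneModel


def gene_region(gene: GeneModel, chrom_length: int, promoter_bp: int = 2000) -> tuple[int, int]:
    """Promoter-to-3'UTR interval of a gene, 1-based inclusive, clipped."""
    if gene.strand == "+":
        start, end = gene.start - promoter_bp, gene.end
    else:
        start, end = gene.start, gene.end + promoter_bp
    return max(1, start), min(chrom_length, end)


def _window_stats(seq_u: np.ndarray, cpg: np.ndarray, start: int, end: int) -> tuple[float, float]:
    """(GC percent, obs/exp CpG) of seq[start:end] (0-based half-open)."""
    length = end - start
    n_c = int((seq_u[start:end] == b"C").sum())
    n_g = int((seq_u[start:end] == b"G").sum())
    gc = 100.0 * (n_c + n_g) / length
    obs = int(cpg[start : end - 1].sum()) if end - start >= 2 else 0
    exp = n_c * n_g / length
    oe = obs / exp if exp > 0 else 0.0
    return gc, oe


def find_cgis(
    sequence: str,
    chrom: str = "",
    offset: int = 0,
    config: PipelineConfig | None = None,
) -> list[CpGIsland]:
    """CpG islands of a sequence; coordinates are 1-based within the
    sequence, shifted by ``offset`` (pass the region start - 1 to obtain
    chromosome coordinates)."""
    config = config or PipelineConfig()
    w = config.cgi_window
    shift = config.cgi_shift
    seq_u = np.frombuffer(sequence.upper().encode(), dtype="S1")
    L = len(seq_u)
    if L < w:
        return []
    is_c = (seq_u == b"C").astype(np.int64)
    is_g = (seq_u == b"G").astype(np.int64)
    cpg = np.zeros(L, dtype=np.int64)
    if L >= 2:
        cpg[:-1] = (seq_u[:-1] == b"C") & (seq_u[1:] == b"G")
    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_cpg = np.concatenate(([0], np.cumsum(cpg)))

    starts = np.arange(0, L - w + 1, shift)
    n_c = cum_c[starts + w] - cum_c[starts]
    n_g = cum_g[starts + w] - cum_g[starts]
    gc = 100.0 * (n_c + n_g) / w
    obs = cum_cpg[starts + w - 1] - cum_cpg[starts]  # CpG fully inside window
    exp = n_c * n_g / w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, obs / exp, 0.0)
    ok = (gc >= config.cgi_min_gc) & (oe >= config.cgi_min_obs_exp)

    islands: list[CpGIsland] = []
    i = 0
    idx = np.flatnonzero(ok)
    while i < len(idx):
        j = i
        region_start = int(starts[idx[i]])
        region_end = region_start + w  # half-open
        while j + 1 < len(idx) and int(starts[idx[j + 1]]) <= region_end:
            j += 1
            region_end = max(region_end, int(starts[idx[j]]) + w)
        length = region_end - region_start
        if length >= config.cgi_min_length:
            rgc, roe = _window_stats(seq_u, cpg, region_start, region_end)
            if rgc >= config.cgi_min_gc and roe >= config.cgi_min_obs_exp:
                islands.append(
                    CpGIsland(
                        chrom=chrom,
                        start=offset + region_start + 1,
                        end=offset + region_end,
                        gc_percent=rgc,
                        obs_exp_cpg=roe,
                    )
                )
        i = j + 1
    return islands


def find_gene_cgis(
    gene: GeneModel,
    genome: dict[str, str],
    config: PipelineConfig | None = None,
) -> list[CpGIsland]:
    """Islands in the gene's promoter-to-3'UTR region, chromosome coordinates."""
    config = config or PipelineConfig()
    chrom_seq = genome[gene.chrom]
    start, end = gene_region(gene, len(chrom_seq), config.promoter_bp)
    islands = find_cgis(chrom_seq[start - 1 : end], gene.chrom, offset=start - 1, config=config)
    for isl in islands:
        isl.gene_id = gene.gene_id
    return islands


def count_meth_in_cgi(island: CpGIsland, called_sites: pd.DataFrame) -> dict[str, int]:
    """Methylated-called sites inside the island, per context, one sample."""
    sub = called_sites[
        (called_sites["chrom"] == island.chrom)
        & (called_sites["pos"] >= island.start)
        & (called_sites["pos"] <= island.end)
        & called_sites["methylated"]
    ]
    counts = sub["context"].value_counts()
    return {c: int(counts.get(c, 0)) for c in ("CG", "CHG", "CHH")}


def classify_pattern(deg: DEGResult, meth_delta: float) -> str:
    """opposite / concordant / flat methylation-expression relationship.

    ``meth_delta`` is the mutant-minus-control methylated-site count (or
    level) difference within the gene's islands. Only called DEGs apply.
    """
    if deg.status == "ns":
        raise ValueError("pattern classification applies to called DEGs only")
    if meth_delta == 0:
        return "flat"
    sign_expr = 1.0 if deg.status == "up" else -1.0
    return "opposite" if sign_expr * meth_delta < 0 else "concordant"


def cgi_methylation_table(
    genes: list[GeneModel],
    deg_table: pd.DataFrame,
    genome: dict[str, str],
    called_sites_by_sample: dict[str, pd.DataFrame],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-DEG island methylation counts and the pattern classification.

    One row per CGI-bearing called DEG: per-context methylated-site counts
    inside its islands for each sample, the summed mutant-minus-control
    delta, and the opposite/concordant/flat pattern.
    """
    config = config or PipelineConfig()
    deg = deg_table.set_index("gene_id")
    rows = []
    for gene in genes:
        if gene.gene_id not in deg.index:
            continue
        status = deg.loc[gene.gene_id, "status"]
        if status == "ns":
            continue
        islands = find_gene_cgis(gene, genome, config)
        if not islands:
            continue
        totals = {s: {"CG": 0, "CHG": 0, "CHH": 0} for s in called_sites_by_sample}
        for isl in islands:
            for sample, sites in called_sites_by_sample.items():
                for c, n in count_meth_in_cgi(isl, sites).items():
                    totals[sample][c] += n
        delta = sum(totals["mutant"].values()) - sum(totals["control"].values())
        result = DEGResult(
            gene_id=gene.gene_id,
            log2fc=float(deg.loc[gene.gene_id, "log2fc"]),
            pvalue=float(deg.loc[gene.gene_id, "pvalue"]),
            padj=float(deg.loc[gene.gene_id, "padj"]),
            status=status,
        )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_islands": len(islands),
                "status": status,
                **{
                    f"{s}_{c}": totals[s][c]
                    for s in sorted(totals)
                    for c in ("CG", "CHG", "CHH")
                },
                "meth_delta": delta,
                "pattern": classify_pattern(result, delta),
            }
        )
    return pd.DataFrame(rows)
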