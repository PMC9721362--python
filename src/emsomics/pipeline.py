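"""File-based pipeline stages chaining the analysis modules.

Each stage reads the conventional files in a working directory, writes its
outputs there, and records a structured log entry (parameters actually
used, record counts in/out) in ``<outdir>/logs/<stage>.json``, sufficient
to re-run identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import cgi as cgi_mod
from . import expression, integrate, io, methylation, simulate, variants as va
from .config import PipelineConfig, SimConfig
from .models import LARGE_IMPACT

FILES = {
    "genome": "genome.fa",
    "gff3": "genes.gff3",
    "vcf": "variants.vcf",
    "counts": "counts.tsv",
    "cyt_control": "cytosines_control.tsv",
    "cyt_mutant": "cytosines_mutant.tsv",
    "truth": "truth.json",
    "effects": "variant_effects.tsv",
    "variant_summary": "variant_summary.json",
    "deg": "deg.tsv",
    "windows_control": "windows_control.tsv",
    "windows_mutant": "windows_mutant.tsv",
    "dmrs_tsv": "dmrs.tsv",
    "dmrs_bed": "dmrs.bed",
    "meth_summary": "methylation_summary.json",
    "cgi": "cgi_patterns.tsv",
    "integration": "integration.json",
    "candidates": "candidates.tsv",
}


def _log(outdir: Path, stage: str, params, counts: dict) -> None:
    logdir = outdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "parameters": params, "records": counts}
    io.write_json(payload, logdir / f"{stage}.json")


def stage_simulate(sim: SimConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate.simulate_genome(sim)
    vars_, vtruth = simulate.simulate_variants(genome, genes, sim)
    counts, ctruth = simulate.simulate_counts(genes, sim)
    tables, mtruth = simulate.simulate_methylome(genome, sim)
    io.write_fasta(genome, outdir / FILES["genome"])
    io.write_gff3(genes, outdir / FILES["gff3"])
    io.write_vcf(vars_, genome, outdir / FILES["vcf"])
    io.write_counts(counts, outdir / FILES["counts"])
    io.write_cytosine_report(tables["control"], outdir / FILES["cyt_control"])
    io.write_cytosine_report(tables["mutant"], outdir / FILES["cyt_mutant"])
    truth = simulate.TruthSet(
        de_gene_ids=ctruth.de_gene_ids,
        de_directions=ctruth.de_directions,
        dmr_intervals=mtruth.dmr_intervals,
        variant_labels=vtruth.variant_labels,
    )
    io.write_json(truth.to_dict(), outdir / FILES["truth"])
    _log(
        outdir,
        "simulate",
        dataclasses.asdict(sim),
        {
            "chromosomes": len(genome),
            "genes": len(genes),
            "variants": len(vars_),
            "count_rows": len(counts),
            "cytosines_per_sample": len(tables["control"]),
        },
    )


def stage_annotate(outdir: Path, config: PipelineConfig) -> list[va.VariantEffect]:
    genome = io.read_fasta(outdir / FILES["genome"])
    genes = io.read_gff3(outdir / FILES["gff3"])
    vars_ = io.read_vcf(outdir / FILES["vcf"], genome=genome)
    effects = va.annotate_all(vars_, genes, genome, config)
    rows = [
        {
            "chrom": e.variant.chrom,
            "pos": e.variant.pos,
            "ref": e.variant.ref,
            "alt": e.variant.alt,
            "zygosity": e.variant.zygosity,
            "gene_id": e.gene_id or "",
            "region": e.region,
            "coding_effect": e.coding_effect,
            "aa_change": e.aa_change,
        }
        for e in effects
    ]
    pd.DataFrame(rows).to_csv(outdir / FILES["effects"], sep="\t", index=False)
    summary = va.variant_summaries(vars_, effects)
    io.write_json(summary, outdir / FILES["variant_summary"])
    _log(
        outdir,
        "annotate",
        dataclasses.asdict(config),
        {"variants": len(vars_), "effects": len(effects)},
    )
    return effects


def stage_deg(outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    counts = io.read_counts(outdir / FILES["counts"])
    deg = expression.run_deg(counts, config)
    deg.to_csv(outdir / FILES["deg"], sep="\t", index=False)
    _log(
        outdir,
        "deg",
        dataclasses.asdict(config),
        {
            "genes_in": len(counts),
            "genes_tested": len(deg),
            "up": int((deg["status"] == "up").sum()),
            "down": int((deg["status"] == "down").sum()),
        },
    )
    return deg


def stage_methylome(outdir: Path, config: PipelineConfig):
    genome = io.read_fasta(outdir / FILES["genome"])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    out = {}
    for sample in ("control", "mutant"):
        sites = io.read_cytosine_report(outdir / FILES[f"cyt_{sample}"])
        unknown = set(sites["chrom"]) - set(chrom_lengths)
        if unknown:
            raise io.ValidationError(
                f"cytosine report names chromosomes absent from the FASTA: {sorted(unknown)}"
            )
        control_mask = sites["chrom"] == simulate.CONTROL_SEQ_ID
        r = methylation.estimate_nonconversion(sites[control_mask]).rate
        genome_sites = sites[~control_mask]
        called, qc = methylation.call_sites(genome_sites, r, config)
        windows = methylation.make_windows(genome_sites, chrom_lengths, config)
        windows.to_csv(outdir / FILES[f"windows_{sample}"], sep="\t", index=False)
        out[sample] = {
            "r": r,
            "sites": genome_sites,
            "called": called,
            "qc": qc,
            "windows": windows,
            "summary": methylation.genome_summary(called),
        }
    dmrs = methylation.call_dmrs(
        out["control"]["windows"],
        out["mutant"]["windows"],
        out["control"]["sites"],
        out["mutant"]["sites"],
        config,
    )
    pd.DataFrame([dataclasses.asdict(d) for d in dmrs]).to_csv(
        outdir / FILES["dmrs_tsv"], sep="\t", index=False
    )
    io.write_bed(
        [(d.chrom, d.start, d.end, d.direction) for d in dmrs], outdir / FILES["dmrs_bed"]
    )
    io.write_json(
        {
            s: {
                "nonconversion_rate": out[s]["r"],
                "qc": out[s]["qc"],
                **out[s]["summary"],
            }
            for s in out
        }
        | {"n_dmrs": len(dmrs)},
        outdir / FILES["meth_summary"],
    )
    _log(
        outdir,
        "methylome",
        dataclasses.asdict(config),
        {s: out[s]["qc"] for s in out} | {"dmrs": len(dmrs)},
    )
    return out, dmrs


def stage_cgi(outdir: Path, config: PipelineConfig, meth_out=None) -> pd.DataFrame:
    genome = io.read_fasta(outdir / FILES["genome"])
    genes = io.read_gff3(outdir / FILES["gff3"])
    deg = pd.read_csv(outdir / FILES["deg"], sep="\t")
    if meth_out is None:
        meth_out, _ = stage_methylome(outdir, config)
    called = {s: meth_out[s]["called"] for s in ("control", "mutant")}
    table = cgi_mod.cgi_methylation_table(genes, deg, genome, called, config)
    table.to_csv(outdir / FILES["cgi"], sep="\t", index=False)
    _log(outdir, "cgi", dataclasses.asdict(config), {"cgi_degs": len(table)})
    return table


def stage_integrate(outdir: Path, config: PipelineConfig, dmrs=None):
    genes = io.read_gff3(outdir / FILES["gff3"])
    effects_df = pd.read_csv(
        outdir / FILES["effects"], sep="\t", keep_default_na=False
    )
    deg = pd.read_csv(outdir / FILES["deg"], sep="\t")
    if dmrs is None:
        ddf = pd.read_csv(outdir / FILES["dmrs_tsv"], sep="\t")
        from .models import DMR

        dmrs = [
            DMR(
                chrom=r.chrom,
                start=int(r.start),
                end=int(r.end),
                delta_ml=float(r.delta_ml),
                pvalue=float(r.pvalue),
                padj=float(r.padj),
                direction=r.direction,
                n_sites=int(r.n_sites),
            )
            for r in ddf.itertuples()
        ] if len(ddf) else []
    classes = (
        LARGE_IMPACT if config.impact_classes == "large" else frozenset({"nonsynonymous"})
    )
    set_r = {
        str(r.gene_id)
        for r in effects_df.itertuples()
        if r.gene_id and r.coding_effect in classes
    }
    set_t = set(deg.loc[deg["status"] != "ns", "gene_id"])
    set_m = integrate.assign_dmr_genes(dmrs, genes, config.promoter_bp)
    report = integrate.overlap_sets(set_r, set_t, set_m)
    io.write_json(report.to_dict(), outdir / FILES["integration"])
    table = integrate.candidate_report(report, deg, config=config)
    table.to_csv(outdir / FILES["candidates"], sep="\t", index=False)
    _log(
        outdir,
        "integrate",
        dataclasses.asdict(config),
        {"R": len(set_r), "T": len(set_t), "M": len(set_m)} | report.counts,
    )
    return report


def run_all(sim: SimConfig, config: PipelineConfig, outdir: Path):
    """Simulate and run every analysis stage; returns the integration report."""
    outdir = Path(outdir)
    stage_simulate(sim, outdir)
    stage_annotate(outdir, config)
    stage_deg(outdir, config)
    meth_out, dmrs = stage_methylome(outdir, config)
    stage_cgi(outdir, config, meth_out)
    return stage_integrate(outdir, config, dmrs)
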