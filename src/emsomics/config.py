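"""Configuration objects for the simulator and the analysis pipeline.

Defaults follow the study design this package emulates: a 3,000 bp window
with 600 bp step for methylome aggregation, BH-corrected p < 0.005 with a
two-fold change for DEG calling, 5 kb gene flanks for variant region
assignment, a 2,000 bp promoter for CpG-island extraction and DMR-to-gene
assignment, and 5x minimum cytosine coverage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .models import ValidationError


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omics dataset.

    The defaults emulate an EMS-mutagenised plant line re-sequenced against
    its progenitor: mostly heterozygous, transition-biased SNPs, indels
    below 50 bp, two single-library RNA-seq conditions with negative
    binomial counts, and a plant-like methylome (high mCG/mCHG, low mCHH)
    read at ~99.96% bisulfite conversion.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_genes: int = 40
    # variants
    snp_rate: float = 2e-4
    transition_fraction: float = 0.7
    het_fraction: float = 0.946
    indel_rate: float = 2e-5
    max_indel: int = 10
    # expression
    n_de_genes: int = 8
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.01
    mean_count: float = 50.0
    library_size_ratio: float = 1.0
    # methylome
    meth_level_cg: float = 0.576
    meth_level_chg: float = 0.328
    meth_level_chh: float = 0.026
    meth_ml: float = 0.8  # within-site ML of a methylated cytosine
    n_dmrs: int = 4
    dmr_delta: float = 0.4
    dmr_base_ml: float = 0.2
    dmr_length: int = 4_000
    read_depth: float = 10.0
    nonconversion_rate: float = 0.0004
    control_seq_length: int = 20_000

    # layout constants (see docs/methods.md)
    gene_flank: int = 12_000

    def validate(self) -> "SimConfig":
        probs = {
            "snp_rate": self.snp_rate,
            "transition_fraction": self.transition_fraction,
            "het_fraction": self.het_fraction,
            "indel_rate": self.indel_rate,
            "meth_level_cg": self.meth_level_cg,
            "meth_level_chg": self.meth_level_chg,
            "meth_level_chh": self.meth_level_chh,
            "meth_ml": self.meth_ml,
            "dmr_delta": self.dmr_delta,
            "dmr_base_ml": self.dmr_base_ml,
            "nonconversion_rate": self.nonconversion_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if not 1 <= self.max_indel < 50:
            raise ValidationError("max_indel must be in [1, 50)")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.mean_count <= 0:
            raise ValidationError("mean_count must be > 0")
        if self.n_de_genes > 0 and self.de_log2fc == 0:
            raise ValidationError("de_log2fc must be nonzero when DE genes are planted")
        return self

    @classmethod
    def emulation(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Preset matching the reported mutant statistics.

        transition_fraction 0.589 yields Ti/Tv = 0.589/0.411 = 1.43, and
        het_fraction 0.946 the reported heterozygosity.
        """
        params = dict(seed=seed, transition_fraction=0.589, het_fraction=0.946)
        params.update(overrides)
        return cls(**params).validate()


@dataclass
class PipelineConfig:
    """Analysis-stage parameters; every default is the study value."""

    # expression_diff
    deg_padj: float = 0.005
    deg_min_abs_log2fc: float = 1.0  # |log2FC| >= 1 <=> fold change >= 2
    pseudocount: float = 0.1
    normal_approx_above: int = 10_000
    # variant_annotation
    flank_bp: int = 5_000
    splice_site_on: str = "intron"  # {"intron", "exon"}
    # methylome
    window_size: int = 3_000
    step_size: int = 600
    min_coverage: int = 5
    site_fdr: float = 0.05
    dmr_fdr: float = 0.05
    dmr_min_delta: float = 0.1
    dmr_min_sites: int = 3
    merge_cpg_strands: bool = False
    # cgi
    cgi_window: int = 100
    cgi_shift: int = 1
    cgi_min_length: int = 200
    cgi_min_gc: float = 50.0
    cgi_min_obs_exp: float = 0.6
    promoter_bp: int = 2_000
    # integration
    impact_classes: str = "large"  # {"large", "nonsynonymous"}

    def validate(self) -> "PipelineConfig":
        if self.splice_site_on not in ("intron", "exon"):
            raise ValidationError("splice_site_on must be 'intron' or 'exon'")
        for name in ("deg_padj", "site_fdr", "dmr_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.window_size < self.step_size:
            raise ValidationError("window_size must be >= step_size")
        return self


def load_config(path: str) -> tuple[SimConfig, PipelineConfig]:
    """Read a YAML file with optional ``simulate:`` and ``pipeline:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _from_mapping(SimConfig, raw.get("simulate", {}))
    pipe = _from_mapping(PipelineConfig, raw.get("pipeline", {}))
    return sim.validate(), pipe.validate()


def _from_mapping(cls, mapping):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(mapping) - known
    if bad:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    return cls(**mapping)
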