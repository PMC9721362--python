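"""Variant-effect annotation against gene models, SnpEff-style.

Region assignment uses the priority exon (CDS) > splice site > intron > UTR >
5-kb gene flank > intergenic. Coding consequences of CDS SNPs are computed
per codon (the test suite checks them against an independent whole-protein
re-translation oracle). Indels inside the CDS are frameshifts when their
size is not a multiple of three, otherwise codon insertions/deletions.

Conventions: insertions are classified by their anchor base, deletions by
the first deleted base. Splice sites default to the first/last 2 bp of an
intron (``splice_site_on="exon"`` switches to the exon-side reading).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import Counter, defaultdict

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .config import PipelineConfig
from .models import (
    LARGE_IMPACT,
    REGIONS,
    GeneModel,
    ValidationError,
    Variant,
    VariantEffect,
    revcomp,
)


class UnplacedVariantError(ValidationError):
    """Variant refers to a chromosome absent from the annotation/genome."""


class ReferenceMismatchError(ValidationError):
    """Variant REF allele disagrees with the reference sequence."""


class GeneIndex:
    """Per-chromosome sorted gene lookup."""

    def __init__(self, genes: list[GeneModel], chroms: set[str] | None = None):
        self._by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in genes:
            self._by_chrom[g.chrom].append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)
        self._starts = {c: [g.start for g in lst] for c, lst in self._by_chrom.items()}
        self.chroms = set(chroms) if chroms is not None else set(self._by_chrom)

    def candidates(self, chrom: str, pos: int, pad: int) -> list[GeneModel]:
        """Genes whose span padded by ``pad`` could contain ``pos``."""
        if chrom not in self.chroms:
            raise UnplacedVariantError(f"chromosome {chrom!r} absent from annotation")
        lst = self._by_chrom.get(chrom, [])
        starts = self._starts.get(chrom, [])
        hi = bisect_right(starts, pos + pad)
        out = []
        for g in lst[:hi]:
            if g.end + pad >= pos:
                out.append(g)
        return out


def _affected_pos(variant: Variant) -> int:
    return variant.pos + 1 if variant.vtype == "deletion" else variant.pos


def _splice_window(gene: GeneModel, pos: int, on: str) -> str | None:
    """'splice_donor'/'splice_acceptor' if pos is in a splice dinucleotide."""
    introns = gene.introns
    if not introns:
        return None
    if on == "intron":
        for s, e in introns:
            # donor = intron start on the gene strand, acceptor = intron end
            five = (s, s + 1) if gene.strand == "+" else (e - 1, e)
            three = (e - 1, e) if gene.strand == "+" else (s, s + 1)
            if five[0] <= pos <= five[1]:
                return "splice_donor"
            if three[0] <= pos <= three[1]:
                return "splice_acceptor"
        return None
    # exon convention: terminal 2 bp of exons flanking an intron
    for k, (s, e) in enumerate(gene.exons):
        left = (s, s + 1) if k > 0 else None  # adjoins upstream intron (+)
        right = (e - 1, e) if k < len(gene.exons) - 1 else None
        for window, junction_is_right in ((left, False), (right, True)):
            if window and window[0] <= pos <= window[1]:
                donor_side = junction_is_right if gene.strand == "+" else not junction_is_right
                return "splice_donor" if donor_side else "splice_acceptor"
    return None


def classify_region(
    variant: Variant, index: GeneIndex, config: PipelineConfig | None = None
) -> VariantEffect:
    """Assign the genomic region label and owning gene, if any."""
    config = config or PipelineConfig()
    pos = _affected_pos(variant)
    genic = index.candidates(variant.chrom, pos, 0)
    for gene in genic:
        if not gene.contains(pos):
            continue
        if config.splice_site_on == "exon":
            sub = _splice_window(gene, pos, "exon")
            if sub is not None:
                return VariantEffect(variant, gene.gene_id, "splice_site", sub)
        if any(s <= pos <= e for s, e in gene.cds):
            return VariantEffect(variant, gene.gene_id, "exon")
        if config.splice_site_on == "intron":
            sub = _splice_window(gene, pos, "intron")
            if sub is not None:
                return VariantEffect(variant, gene.gene_id, "splice_site", sub)
        if any(s <= pos <= e for s, e in gene.introns):
            return VariantEffect(variant, gene.gene_id, "intron")
        if any(s <= pos <= e for s, e in gene.utr5):
            return VariantEffect(variant, gene.gene_id, "utr5")
        if any(s <= pos <= e for s, e in gene.utr3):
            return VariantEffect(variant, gene.gene_id, "utr3")
        return VariantEffect(variant, gene.gene_id, "exon")
    best = None
    for gene in index.candidates(variant.chrom, pos, config.flank_bp):
        if gene.contains(pos):
            continue
        dist = gene.start - pos if pos < gene.start else pos - gene.end
        if dist > config.flank_bp:
            continue
        upstream = (pos < gene.start) == (gene.strand == "+")
        region = "upstream_5kb" if upstream else "downstream_5kb"
        if best is None or (dist, gene.gene_id) < (best[0], best[1]):
            best = (dist, gene.gene_id, region)
    if best is not None:
        return VariantEffect(variant, best[1], best[2])
    return VariantEffect(variant, None, "intergenic")


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the spliced CDS."""
    off = 0
    if gene.strand == "+":
        for s, e in gene.cds:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
    else:
        for s, e in reversed(gene.cds):
            if s <= pos <= e:
                return off + (e - pos)
            off += e - s + 1
    raise ValueError("position not in CDS")


def coding_effect(
    effect: VariantEffect,
    gene: GeneModel,
    genome: dict[str, str],
    config: PipelineConfig | None = None,
) -> VariantEffect:
    """Fill in the coding consequence for a genic variant."""
    variant = effect.variant
    seq = genome[variant.chrom]
    if seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)] != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} REF {variant.ref!r} does not match reference"
        )
    if effect.region == "splice_site":
        return effect  # subtype already stored as the coding effect
    if effect.region == "exon":
        if variant.vtype != "snp":
            if variant.size % 3:
                effect.coding_effect = "frameshift"
            elif variant.vtype == "insertion":
                effect.coding_effect = "codon_insertion"
            else:
                effect.coding_effect = "codon_deletion"
            return effect
        off = _cds_offset(gene, variant.pos)
        cds_seq = gene.cds_sequence(seq)
        ci, within = divmod(off, 3)
        ref_codon = cds_seq[3 * ci : 3 * ci + 3]
        alt_base = variant.alt if gene.strand == "+" else revcomp(variant.alt)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            effect.coding_effect = "synonymous"
            return effect
        effect.aa_change = f"{seq3(ref_aa)}{ci + 1}{seq3(alt_aa)}"
        if ci == 0 and ref_codon == "ATG":
            effect.coding_effect = "start_lost"
        elif alt_aa == "*":
            effect.coding_effect = "stop_gained"
        elif ref_aa == "*":
            effect.coding_effect = "stop_lost"
        else:
            effect.coding_effect = "nonsynonymous"
        return effect
    if effect.region == "utr5" and variant.vtype == "snp":
        if _creates_utr5_atg(variant, gene, seq):
            effect.coding_effect = "start_gained"
    return effect


def _creates_utr5_atg(variant: Variant, gene: GeneModel, seq: str) -> bool:
    pos = variant.pos
    for s, e in gene.utr5:
        if not s <= pos <= e:
            continue
        if gene.strand == "+":
            for q in range(max(s, pos - 2), min(pos, e - 2) + 1):
                tri = list(seq[q - 1 : q + 2])
                ref_tri = "".join(tri)
                tri[pos - q] = variant.alt
                if "".join(tri) == "ATG" and ref_tri != "ATG":
                    return True
        else:
            for q in range(max(pos, s + 2), min(e, pos + 2) + 1):
                tri = list(seq[q - 3 : q])
                ref_tri = revcomp("".join(tri))
                tri[pos - (q - 2)] = variant.alt
                if revcomp("".join(tri)) == "ATG" and ref_tri != "ATG":
                    return True
    return False


def annotate_variant(
    variant: Variant,
    index: GeneIndex,
    genome: dict[str, str],
    genes_by_id: dict[str, GeneModel],
    config: PipelineConfig | None = None,
) -> VariantEffect:
    config = config or PipelineConfig()
    effect = classify_region(variant, index, config)
    if effect.gene_id is not None and effect.region in ("exon", "splice_site", "utr5"):
        effect = coding_effect(effect, genes_by_id[effect.gene_id], genome, config)
    return effect


def annotate_all(
    variants: list[Variant],
    genes: list[GeneModel],
    genome: dict[str, str],
    config: PipelineConfig | None = None,
) -> list[VariantEffect]:
    """Annotate every variant; one effect record per variant here because
    simulated genes never overlap (overlapping annotations would yield one
    record per overlapped gene)."""
    config = config or PipelineConfig()
    index = GeneIndex(genes, chroms=set(genome))
    by_id = {g.gene_id: g for g in genes}
    return [annotate_variant(v, index, genome, by_id, config) for v in variants]


# ---------------------------------------------------------------------------
# summaries


def titv(variants: list[Variant]) -> float:
    """Transition/transversion ratio over SNPs; inf when no transversions."""
    ti = sum(1 for v in variants if v.vtype == "snp" and v.is_transition)
    tv = sum(1 for v in variants if v.vtype == "snp" and not v.is_transition)
    if tv == 0:
        return math.inf if ti else math.nan
    return ti / tv


def mutated_gene_set(
    effects: list[VariantEffect], classes: frozenset[str] = LARGE_IMPACT
) -> set[str]:
    """Genes with at least one large-impact consequence, each counted once."""
    return {e.gene_id for e in effects if e.gene_id and e.coding_effect in classes}


def variant_summaries(
    variants: list[Variant], effects: list[VariantEffect]
) -> dict:
    """Fig 2-style mutagenesis summary statistics."""
    per_chrom = Counter(v.chrom for v in variants)
    genes_per_chrom: dict[str, set[str]] = defaultdict(set)
    for e in effects:
        if e.gene_id and e.coding_effect in LARGE_IMPACT:
            genes_per_chrom[e.variant.chrom].add(e.gene_id)
    hist = Counter(
        (v.size if v.vtype == "insertion" else -v.size)
        for v in variants
        if v.vtype != "snp"
    )
    n = len(variants)
    het = sum(1 for v in variants if v.zygosity == "het") / n if n else 0.0
    region_counts = Counter(e.region for e in effects)
    total_eff = sum(region_counts.values())
    region_pct = {
        r: 100.0 * region_counts.get(r, 0) / total_eff if total_eff else 0.0
        for r in REGIONS
    }
    return {
        "n_variants": n,
        "per_chromosome": dict(per_chrom),
        "mutated_genes_per_chromosome": {c: len(s) for c, s in genes_per_chrom.items()},
        "indel_size_histogram": {int(k): int(v) for k, v in sorted(hist.items())},
        "het_fraction": het,
        "region_percent": region_pct,
        "titv": titv(variants) if any(v.vtype == "snp" for v in variants) else math.nan,
    }
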