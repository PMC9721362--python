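"""Seeded generator of a toy genome with matched variants, counts and methylomes.

The generator emulates the statistical structure of an EMS-mutagenised plant
line compared to its progenitor: transition-biased, mostly heterozygous SNPs
and sub-50-bp indels; two single-library RNA-seq conditions with planted
two-fold differentially expressed genes; and a bisulfite methylome with
context-dependent methylation, planted differentially methylated regions and
a small non-conversion error rate estimated from an unmethylated spike-in.

Every stage draws from an independent, stage-name-keyed substream of a single
master seed, so adding a stage never perturbs the output of earlier ones.
Truth labels for variant effects are produced by a brute-force oracle
(interval membership for the region; whole-protein re-translation and diff
for the coding consequence) that is deliberately independent of the
per-codon annotation logic in :mod:`emsomics.variants`.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .config import SimConfig
from .models import GeneModel, LayoutError, ValidationError, Variant, revcomp

CONTROL_SEQ_ID = "control_unmethylated"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream keyed by the master seed and a stage name."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


@dataclass
class TruthSet:
    """Ground truth of a simulation run, for scoring downstream calls."""

    de_gene_ids: list[str] = field(default_factory=list)
    de_directions: dict[str, str] = field(default_factory=dict)
    dmr_intervals: list[tuple[str, int, int, float, str]] = field(default_factory=list)
    variant_labels: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "de_gene_ids": self.de_gene_ids,
            "de_directions": self.de_directions,
            "dmr_intervals": [list(t) for t in self.dmr_intervals],
            "variant_labels": self.variant_labels,
        }


# ---------------------------------------------------------------------------
# genome


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _build_gene(rng: np.random.Generator) -> tuple[str, dict]:
    """One gene in local coordinates on its own (coding) strand."""
    u5_len = int(rng.integers(100, 301))
    n_codons = int(rng.integers(100, 301))
    u3_len = int(rng.integers(100, 301))
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    )
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    cds = "ATG" + body + stop
    transcript = _random_seq(rng, u5_len) + cds + _random_seq(rng, u3_len)
    t_len = len(transcript)

    n_exons = int(rng.integers(1, 5))
    while True:  # exon pieces of >= 50 bp each
        cuts = np.sort(rng.integers(50, t_len - 49, size=n_exons - 1))
        bounds = np.concatenate(([0], cuts, [t_len]))
        if np.all(np.diff(bounds) >= 50):
            break
    piece_lens = np.diff(bounds)

    parts: list[str] = []
    exon_ivals: list[tuple[int, int]] = []  # local 1-based
    tmaps: list[tuple[int, int, int]] = []  # (t_start, t_end, local_g_start)
    tpos = gpos = 0
    for k, plen in enumerate(piece_lens):
        plen = int(plen)
        parts.append(transcript[tpos : tpos + plen])
        exon_ivals.append((gpos + 1, gpos + plen))
        tmaps.append((tpos + 1, tpos + plen, gpos + 1))
        tpos += plen
        gpos += plen
        if k < n_exons - 1:
            ilen = int(rng.integers(200, 801))
            intron = _random_seq(rng, ilen)
            intron = "GT" + intron[2:-2] + "AG"
            parts.append(intron)
            gpos += ilen
    local_seq = "".join(parts)

    def map_range(a: int, b: int) -> list[tuple[int, int]]:
        out = []
        for ts, te, gs in tmaps:
            lo, hi = max(a, ts), min(b, te)
            if lo <= hi:
                out.append((gs + lo - ts, gs + hi - ts))
        return out

    features = {
        "exons": exon_ivals,
        "utr5": map_range(1, u5_len),
        "cds": map_range(u5_len + 1, u5_len + len(cds)),
        "utr3": map_range(u5_len + len(cds) + 1, t_len),
    }
    return local_seq, features


def _place(features: dict, offset: int, strand: str, local_len: int) -> dict:
    """Local 1-based intervals on the gene strand -> genomic intervals."""
    out = {}
    for name, ivals in features.items():
        mapped = []
        for s, e in ivals:
            if strand == "+":
                mapped.append((offset + s - 1, offset + e - 1))
            else:
                mapped.append((offset + local_len - e, offset + local_len - s))
        out[name] = sorted(mapped)
    return out


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping gene models and a spike-in control.

    Each gene has >= 1 exon, an ATG start, a single ORF ending in a stop
    codon, and annotated UTRs; genes are separated by at least
    ``config.gene_flank`` bp so that flank and intergenic region classes all
    occur. The returned genome includes one extra record named
    ``control_unmethylated`` used for non-conversion estimation.
    """
    config.validate()
    rng = substream(config.seed, "genome")
    flank = config.gene_flank
    max_gene = 300 + 3 * 302 + 300 + 3 * 800 + 100  # conservative bound
    per_chrom = -(-config.n_genes // config.n_chromosomes) if config.n_genes else 0
    if per_chrom and per_chrom * (max_gene + flank) + flank > config.chrom_length:
        raise LayoutError(
            f"{config.n_genes} genes cannot fit on {config.n_chromosomes} x "
            f"{config.chrom_length} bp with {flank} bp flanks"
        )

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"Chr{c + 1:02d}"
        seq = np.array(list(_random_seq(rng, config.chrom_length)))
        n_here = min(per_chrom, config.n_genes - c * per_chrom) if per_chrom else 0
        cursor = flank + 1
        for _ in range(max(0, n_here)):
            local_seq, features = _build_gene(rng)
            glen = len(local_seq)
            offset = cursor + int(rng.integers(0, 2000))
            if offset + glen - 1 + flank > config.chrom_length:
                raise LayoutError("gene layout exceeded chromosome length")
            strand = "+" if rng.random() < 0.5 else "-"
            placed_seq = local_seq if strand == "+" else revcomp(local_seq)
            seq[offset - 1 : offset - 1 + glen] = list(placed_seq)
            ivals = _place(features, offset, strand, glen)
            gene_idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gene_idx:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=offset,
                    end=offset + glen - 1,
                    exons=ivals["exons"],
                    cds=ivals["cds"],
                    utr5=ivals["utr5"],
                    utr3=ivals["utr3"],
                )
            )
            cursor = offset + glen + flank
        genome[chrom] = "".join(seq)
    genome[CONTROL_SEQ_ID] = _random_seq(rng, config.control_seq_length)
    return genome, genes


# ---------------------------------------------------------------------------
# brute-force truth oracle for variant effects


def _genic_point_class(pos: int, gene: GeneModel) -> tuple[str, str] | None:
    """(region, coding_subtype) for a position inside a gene span, else None."""
    if not gene.contains(pos):
        return None
    for s, e in gene.cds:
        if s <= pos <= e:
            return "exon", ""
    for s, e in gene.introns:
        if s <= pos <= e:
            if gene.strand == "+":
                donor = (s, s + 1)
                acceptor = (e - 1, e)
            else:
                donor = (e - 1, e)
                acceptor = (s, s + 1)
            if donor[0] <= pos <= donor[1]:
                return "splice_site", "splice_donor"
            if acceptor[0] <= pos <= acceptor[1]:
                return "splice_site", "splice_acceptor"
            return "intron", ""
    for s, e in gene.utr5:
        if s <= pos <= e:
            return "utr5", ""
    for s, e in gene.utr3:
        if s <= pos <= e:
            return "utr3", ""
    return "exon", ""  # exonic but unassigned; should not occur


def _affected_pos(variant: Variant) -> int:
    """First affected base: SNP/insertion anchor, first deleted base."""
    return variant.pos + 1 if variant.vtype == "deletion" else variant.pos


def oracle_region(
    variant: Variant, genes: list[GeneModel], flank_bp: int = 5000
) -> tuple[str | None, str, str]:
    """Brute-force (gene_id, region, splice_subtype) by exhaustive scan."""
    pos = _affected_pos(variant)
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        hit = _genic_point_class(pos, gene)
        if hit is not None:
            return gene.gene_id, hit[0], hit[1]
    best: tuple[int, str, str, str] | None = None
    for gene in genes:
        if gene.chrom != variant.chrom or gene.contains(pos):
            continue
        if pos < gene.start:
            dist, left = gene.start - pos, True
        else:
            dist, left = pos - gene.end, False
        if dist > flank_bp:
            continue
        upstream = left == (gene.strand == "+")
        region = "upstream_5kb" if upstream else "downstream_5kb"
        key = (dist, gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (dist, gene.gene_id, region, "")
    if best is not None:
        return best[1], best[2], best[3]
    return None, "intergenic", ""


def _mutate_chrom(seq: str, variant: Variant) -> str:
    i = variant.pos - 1
    assert seq[i : i + len(variant.ref)] == variant.ref
    return seq[:i] + variant.alt + seq[i + len(variant.ref) :]


def _utr5_atg_starts(seq: str, gene: GeneModel) -> set[tuple[int, int]]:
    starts = set()
    for s, e in gene.utr5:
        sub = seq[s - 1 : e]
        if gene.strand == "-":
            sub = revcomp(sub)
        for i in range(len(sub) - 2):
            if sub[i : i + 3] == "ATG":
                starts.add((s, i))
    return starts


def oracle_coding_effect(
    variant: Variant, gene: GeneModel, chrom_seq: str, region: str, subtype: str
) -> tuple[str, str]:
    """(coding_effect, aa_change) by whole-protein re-translation and diff."""
    if region == "splice_site":
        return subtype, ""
    if region == "exon":
        if variant.vtype != "snp":
            if variant.size % 3:
                return "frameshift", ""
            return (
                "codon_insertion" if variant.vtype == "insertion" else "codon_deletion",
                "",
            )
        mutated = _mutate_chrom(chrom_seq, variant)
        prot_ref = str(Seq(gene.cds_sequence(chrom_seq)).translate())
        prot_alt = str(Seq(gene.cds_sequence(mutated)).translate())
        if prot_ref == prot_alt:
            return "synonymous", ""
        i = next(k for k, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b)
        ra, aa = prot_ref[i], prot_alt[i]
        change = f"{seq3(ra)}{i + 1}{seq3(aa)}"
        if i == 0 and ra == "M":
            return "start_lost", change
        if aa == "*":
            return "stop_gained", change
        if ra == "*":
            return "stop_lost", change
        return "nonsynonymous", change
    if region == "utr5" and variant.vtype == "snp":
        mutated = _mutate_chrom(chrom_seq, variant)
        created = _utr5_atg_starts(mutated, gene) - _utr5_atg_starts(chrom_seq, gene)
        if created:
            return "start_gained", ""
    return "none", ""


def oracle_label(
    variant: Variant, genes: list[GeneModel], genome: dict[str, str], flank_bp: int = 5000
) -> dict:
    gene_id, region, subtype = oracle_region(variant, genes, flank_bp)
    effect, aa = "none", ""
    if gene_id is not None and region in ("exon", "splice_site", "utr5"):
        gene = next(g for g in genes if g.gene_id == gene_id)
        effect, aa = oracle_coding_effect(variant, gene, genome[variant.chrom], region, subtype)
    return {"region": region, "gene_id": gene_id, "coding_effect": effect, "aa_change": aa}


# ---------------------------------------------------------------------------
# variants


def simulate_variants(
    genome: dict[str, str], genes: list[GeneModel], config: SimConfig
) -> tuple[list[Variant], TruthSet]:
    """EMS-style SNPs and small indels with brute-force truth effect labels."""
    config.validate()
    rng = substream(config.seed, "variants")
    variants: list[Variant] = []
    for chrom in sorted(genome):
        if chrom == CONTROL_SEQ_ID:
            continue
        seq = genome[chrom]
        L = len(seq)
        n_snp = rng.binomial(L, config.snp_rate)
        n_ind = rng.binomial(L, config.indel_rate)
        n_tot = n_snp + n_ind
        if n_tot == 0:
            continue
        cand = np.sort(rng.choice(np.arange(100, L - 100), size=n_tot, replace=False))
        keep = np.concatenate(([True], np.diff(cand) >= 60))
        cand = cand[keep]
        is_indel = np.zeros(len(cand), dtype=bool)
        if n_ind:
            is_indel[rng.choice(len(cand), size=min(n_ind, len(cand)), replace=False)] = True
        for pos0, indel in zip(cand, is_indel):
            pos = int(pos0)  # 1-based (cand drawn over valid anchor positions)
            ref = seq[pos - 1]
            zyg = "het" if rng.random() < config.het_fraction else "hom"
            if not indel:
                if rng.random() < config.transition_fraction:
                    alt = _TRANSITION[ref]
                else:
                    alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
                variants.append(Variant(chrom, pos, ref, alt, zyg))
                continue
            size = min(int(rng.geometric(0.5)), config.max_indel)
            if rng.random() < 0.5:  # insertion after the anchor
                ins = _random_seq(rng, size)
                variants.append(Variant(chrom, pos, ref, ref + ins, zyg))
            else:  # deletion of pos+1 .. pos+size
                if pos + size > L - 2:
                    continue
                span = [
                    oracle_region(
                        Variant(chrom, p, seq[p - 1], "T" if seq[p - 1] == "A" else "A"),
                        genes,
                    )[:2]
                    for p in range(pos + 1, pos + size + 1)
                ]
                if len({s for s in span}) > 1:
                    continue  # ambiguous boundary-crossing deletion: skip
                variants.append(Variant(chrom, pos, seq[pos - 1 : pos + size], ref, zyg))
    truth = TruthSet(variant_labels=[oracle_label(v, genes, genome) for v in variants])
    return variants, truth


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(
    genes: list[GeneModel] | int, config: SimConfig
) -> tuple[pd.DataFrame, TruthSet]:
    """Two-library negative binomial count table with planted DE genes.

    ``genes`` may be gene models from :func:`simulate_genome` or a bare gene
    count (synthetic ids, lengths drawn uniformly on 1-3 kb), which is handy
    for large expression-only simulations.
    """
    config.validate()
    rng = substream(config.seed, "counts")
    if isinstance(genes, int):
        n = genes
        ids = [f"gene_{i + 1:05d}" for i in range(n)]
        lengths = rng.integers(1000, 3001, size=n)
    else:
        ids = [g.gene_id for g in genes]
        lengths = np.array([sum(e - s + 1 for s, e in g.exons) for g in genes], dtype=int)
        n = len(ids)
    if config.n_de_genes > n:
        raise ValidationError("n_de_genes exceeds number of genes")

    base = rng.lognormal(mean=np.log(config.mean_count) - 0.245, sigma=0.7, size=n)
    de_idx = rng.choice(n, size=config.n_de_genes, replace=False)
    direction = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    direction[de_idx] = signs
    mu_control = base
    mu_mutant = base * np.power(2.0, direction * config.de_log2fc) * config.library_size_ratio

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / config.nb_dispersion
        return rng.poisson(rng.gamma(shape=r, scale=mu / r))

    counts = pd.DataFrame(
        {
            "gene_id": ids,
            "length_bp": lengths,
            "count_control": draw(mu_control),
            "count_mutant": draw(mu_mutant),
        }
    )
    truth = TruthSet(
        de_gene_ids=[ids[i] for i in de_idx],
        de_directions={ids[i]: ("up" if s > 0 else "down") for i, s in zip(de_idx, signs)},
    )
    return counts, truth


# ---------------------------------------------------------------------------
# methylome


def cytosine_positions(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosines on both strands with CG/CHG/CHH context.

    Returns (pos 1-based, strand as '+'/'-', context) arrays. Context is read
    from the two bases downstream on the cytosine's own strand; cytosines
    within 2 bp of a sequence end fall back to CHH.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out_pos, out_strand, out_ctx = [], [], []
    # + strand: C at i; next bases arr[i+1], arr[i+2]
    isC = arr == b"C"
    idx = np.flatnonzero(isC)
    n1 = np.full(len(arr), b"N", dtype="S1")
    n2 = np.full(len(arr), b"N", dtype="S1")
    n1[:-1] = arr[1:]
    n2[:-2] = arr[2:]
    ctx = np.where(n1[idx] == b"G", "CG", np.where(n2[idx] == b"G", "CHG", "CHH"))
    out_pos.append(idx + 1)
    out_strand.append(np.full(len(idx), "+"))
    out_ctx.append(ctx)
    # - strand: C where forward base is G; own-strand downstream = arr[i-1], arr[i-2]
    idx = np.flatnonzero(arr == b"G")
    p1 = np.full(len(arr), b"N", dtype="S1")
    p2 = np.full(len(arr), b"N", dtype="S1")
    p1[1:] = arr[:-1]
    p2[2:] = arr[:-2]
    ctx = np.where(p1[idx] == b"C", "CG", np.where(p2[idx] == b"C", "CHG", "CHH"))
    out_pos.append(idx + 1)
    out_strand.append(np.full(len(idx), "-"))
    out_ctx.append(ctx)
    pos = np.concatenate(out_pos)
    strand = np.concatenate(out_strand)
    context = np.concatenate(out_ctx)
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], context[order]


def simulate_methylome(
    genome: dict[str, str], config: SimConfig
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Cytosine report tables for a control and a mutant sample.

    Outside planted DMRs the two samples share the same underlying per-site
    methylation state (only read sampling differs); inside a DMR the two
    samples have flat per-site MLs differing by ``dmr_delta``. A fraction
    ``nonconversion_rate`` of truly unconverted cytosines appears methylated
    everywhere, including on the unmethylated control sequence.
    """
    config.validate()
    rng = substream(config.seed, "methylome")
    levels = {
        "CG": config.meth_level_cg,
        "CHG": config.meth_level_chg,
        "CHH": config.meth_level_chh,
    }
    # plant DMR intervals on real chromosomes
    chroms = sorted(c for c in genome if c != CONTROL_SEQ_ID)
    dmr_intervals: list[tuple[str, int, int, float, str]] = []
    if config.n_dmrs and chroms:
        per = -(-config.n_dmrs // len(chroms))
        placed = 0
        for chrom in chroms:
            L = len(genome[chrom])
            n_here = min(per, config.n_dmrs - placed)
            if n_here <= 0:
                break
            slot = L // n_here
            if slot < config.dmr_length + 2000:
                raise LayoutError("chromosome too short for requested DMRs")
            for k in range(n_here):
                start = k * slot + int(rng.integers(1000, slot - config.dmr_length - 1000))
                direction = "hyper" if (placed + k) % 2 == 0 else "hypo"
                dmr_intervals.append(
                    (chrom, start, start + config.dmr_length - 1, config.dmr_delta, direction)
                )
            placed += n_here
    hi = config.dmr_base_ml + config.dmr_delta
    if hi > 1.0:
        warnings.warn("dmr_base_ml + dmr_delta > 1; clipping planted DMR levels")
        hi = 1.0

    tables = {"control": [], "mutant": []}
    for chrom in sorted(genome):
        seq = genome[chrom]
        pos, strand, context = cytosine_positions(seq)
        n = len(pos)
        if chrom == CONTROL_SEQ_ID:
            ml_control = np.zeros(n)
            ml_mutant = np.zeros(n)
        else:
            level = np.array([levels[c] for c in context])
            state = rng.random(n) < level
            ml_control = np.where(state, config.meth_ml, 0.0)
            ml_mutant = ml_control.copy()
            for dchrom, dstart, dend, _, ddir in dmr_intervals:
                if dchrom != chrom:
                    continue
                mask = (pos >= dstart) & (pos <= dend)
                if ddir == "hyper":
                    ml_control[mask] = config.dmr_base_ml
                    ml_mutant[mask] = hi
                else:
                    ml_control[mask] = hi
                    ml_mutant[mask] = config.dmr_base_ml
        r = config.nonconversion_rate
        for sample, ml in (("control", ml_control), ("mutant", ml_mutant)):
            depth = rng.poisson(config.read_depth, size=n)
            p_obs = ml + (1.0 - ml) * r
            meth = rng.binomial(depth, p_obs)
            tables[sample].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "count_methylated": meth,
                        "count_unmethylated": depth - meth,
                        "context": context,
                    }
                )
            )
    out = {s: pd.concat(parts, ignore_index=True) for s, parts in tables.items()}
    return out, TruthSet(dmr_intervals=dmr_intervals)
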