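# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `emsomics`.

## Design setting

The package addresses the "one mutant, one control" multi-omics design:
a chemically mutagenised (EMS) plant line and its progenitor, each with a
single re-sequenced genome, a single RNA-seq library, and a single
whole-genome bisulfite library. Nothing in the design permits estimating
biological dispersion, so all tests are exact and conditional, and all
multiple-testing control is Benjamini–Hochberg.

## Variant-effect annotation

Coordinates are 1-based inclusive (VCF/GFF3 convention) everywhere except
BED output (0-based half-open). Multi-allelic VCF records are split into
biallelic variants on reading.

Region assignment priority: CDS ("exon") > splice site > intron > UTR >
gene flank (≤ 5,000 bp, upstream/downstream by the gene's strand, nearest
gene; exact distance ties go to the lexicographically smaller gene id) >
intergenic. Insertions are classified by their anchor base and deletions
by the first deleted base, so every variant receives exactly one region
per overlapped gene.

Splice sites default to the first/last 2 bp of an intron — the convention
that matches the donor/acceptor class names. A configuration switch
(`splice_site_on="exon"`) instead takes the terminal 2 bp of exons
adjoining an intron, for compatibility with pipelines that annotate the
exon side.

CDS SNP consequences are computed per codon against the spliced, strand-
corrected CDS and double-checked in the test suite against an independent
whole-protein re-translation oracle. `start_gained` is deliberately
narrow: an SNP that creates a new ATG trinucleotide within the annotated
5′ UTR (within one UTR interval, on the gene strand). CDS indels use the
size-mod-3 rule (frameshift vs codon insertion/deletion); a deletion
spanning a feature boundary is classified by its first deleted base and
the same rule, a simplification documented here because its true effect
is structurally ambiguous.

The "large impact" class set used for the mutated-gene set R comprises
nonsynonymous, stop/start gained/lost, splice acceptor/donor, codon
insertion/deletion and frameshift; a nonsynonymous-only preset exists for
strict variant–expression integration.

## Differential expression

The two libraries are put on a common scale with a single trimmed-mean-of-
M-values factor (reference = control; 30% two-sided trim on M, 5% on A;
weights are the standard inverse asymptotic variances; genes with a zero
in either library are excluded from the factor). A pure depth shift
therefore yields factor 1 with the depth absorbed into the library sizes.

The test statistic is the exact conditional binomial: given a gene's
two-library total k, the mutant count is Binomial(k, p₀) under the null,
with p₀ the mutant share of the combined effective library size. Two-sided
p = min(1, 2·min(lower tail, upper tail)). Totals above 10,000 use a
continuity-corrected normal approximation for speed (the relative error
there is far below any decision threshold). Genes with k = 0 are removed
before testing and before the BH family size is fixed. Calls require
BH-adjusted p < 0.005 and |log₂FC| ≥ 1.

Fold changes are computed on FPKM with a pseudocount of 0.1 applied only
when one of the values is zero; a zero/zero pair with pseudocount 0 is an
error. The pseudocount makes zero-expression fold changes finite but
their magnitude is arbitrary by construction — published fold changes for
zero values are generally not recoverable without knowing the pseudocount
used, and such rows are excluded from desk checks.

The conditional test models technical (sampling) variation only. Under
negative binomial overdispersion it is anticonservative; the generator's
default `nb_dispersion = 0.01` encodes mild technical overdispersion, under
which realized FDR at the stated thresholds stays well below 10% in the
recovery tests, while type-I calibration checks are run in the Poisson
limit (`nb_dispersion = 0`), which is the test's own null.

## Methylome

Context (CG/CHG/CHH, H ∈ {A,C,T}) is read from the two bases downstream of
the cytosine on its own strand; cytosines within 2 bp of a sequence end
fall back to CHH. CG sites are not strand-collapsed by default.

The bisulfite non-conversion rate r is the methylated-read fraction over
an unmethylated spike-in control sequence (record `control_unmethylated`);
r ≥ 0.05 is rejected as implausible. ML correction is
(ML − r)/(1 − r), clamped to [0, 1]; it is monotone in ML and the identity
at r = 0.

Site calls: coverage ≥ 5 (sites below are excluded and counted in QC, not
errors), exact binomial upper-tail p at rate r, BH across sites,
FDR 0.05. Because the caller intentionally admits an FDR-level of false
discoveries, the called fraction of a rare context (CHH) is biased upward
by roughly coverage·r of the unmethylated sites; calibration tests
therefore separate the noiseless recovery of planted context levels from
the null false-call rate.

Windows: starts 1, 601, 1201, … (window 3,000 bp, step 600 bp,
per-chromosome); generation stops with the first window reaching the
chromosome end, which is truncated. Window ML is the ratio of summed
methylated to total read counts (not the mean of per-site MLs), matching
the count-sum definition of the windowing scheme. Windows with no covered
cytosine are omitted.

DMRs: per shared window a 2×2 exact test on the summed (methylated,
unmethylated) counts of the two samples (Fisher; chi-squared with
continuity correction above 10,000 total reads, where the exact test is
numerically pointless and slow); BH across windows; significant windows
need adjusted p < 0.05, |ΔML| ≥ 0.1 and ≥ 3 covered cytosines in each
sample; overlapping or abutting significant windows merge, and the merged
region is trimmed to the outermost covered cytosine — hence DMRs can be
much shorter than one window. The reported ΔML and p-value of a merged
DMR are recomputed from the site counts inside the final interval; the
adjusted p is the minimum over member windows (BH cannot be redone after
merging). Merging necessarily dilutes ΔML relative to a planted plateau
because boundary windows straddle the edge. DMR calling is antisymmetric
under sample swap.

## CpG islands

Gardiner-Garden & Frommer scan with the classic defaults (window 100 bp,
shift 1 bp, GC ≥ 50%, ObsCpG/ExpCpG ≥ 0.6 with Exp = nC·nG/length, merged
length ≥ 200 bp, merged regions re-tested region-wide; all five
parameters exposed in configuration). N bases count toward window length
but not toward C/G. The implementation is a vectorized cumulative-sum
scan, asserted identical to an exhaustive per-window oracle in the tests.

The search region of a gene runs from 2,000 bp upstream of the TSS to the
3′ UTR end (gene end when no UTR is annotated), clipped to the
chromosome. A gene may hold several islands; its methylation delta is the
mutant-minus-control count of methylated-called sites summed over its
islands (a ΔML-based alternative can be derived from the site tables).
Patterns: opposite ⇔ the expression change and the methylation delta have
opposite signs; flat ⇔ delta 0; else concordant.

## Integration

Set M assigns a DMR to a gene when the DMR overlaps the gene body or its
promoter (2,000 bp upstream, consistent with the CGI region convention;
configurable) by ≥ 1 bp. Whether a study's gene–DMR association includes
promoters is often unstated; the promoter-inclusive default is the
biologically safer superset and the body-only behaviour is obtained with
`promoter_bp = 0`. All seven Venn cells are emitted; the candidate table
reports both FPKM values, log₂FC, raw and adjusted p per intersection
gene, with an explicit "NA" marker for genes absent from the expression
table.

## Synthetic-data generator

The generator is first-class, tested code. One master seed; every stage
(genome, variants, counts, methylome) draws from an independent substream
keyed by the stage name, so adding stages never perturbs earlier outputs,
and identical configurations give byte-identical files.

*Genome*: uniform random sequence; genes are placed non-overlapping with
≥ 12 kb flanks (so flank and intergenic classes both occur), each with a
100–300 bp 5′ UTR, an ORF of 101–301 codons (ATG start, no internal stop,
one of TAA/TAG/TGA), a 100–300 bp 3′ UTR, 1–4 exons and 200–800 bp introns
with canonical GT…AG ends. An extra unmethylated record
(`control_unmethylated`) provides the non-conversion spike-in: the
standard mechanism for estimating r when the source of the estimate is
otherwise unspecified.

*Variants*: SNP and indel counts are binomial in the per-bp rates;
transitions occur with probability `transition_fraction` (default 0.7;
the emulation preset uses 0.589, giving Ti/Tv = 0.589/0.411 ≈ 1.43);
heterozygosity with probability `het_fraction` (default 0.946); indel
sizes are geometric, capped below 50 bp; anchors are kept ≥ 60 bp apart
and deletions never span a feature boundary, keeping truth labels
unambiguous. Every variant carries a truth label computed by the
brute-force oracle (exhaustive interval membership + whole-protein diff),
which the per-codon annotator must reproduce exactly.

*Counts*: per-gene baseline means are lognormal (σ = 0.7) around
`mean_count`; counts are gamma-Poisson (negative binomial) with dispersion
`nb_dispersion` (0 = Poisson limit); planted DE genes shift the mutant
mean by ±`de_log2fc` with random sign; a `library_size_ratio` parameter
(default 1) covers unequal depths.

*Methylome*: every cytosine on both strands is emitted. Outside planted
DMRs the two samples share one underlying per-site state — methylated
with context-dependent probability (defaults 0.576 / 0.328 / 0.026 for
CG/CHG/CHH, the emulated study levels) at within-site ML 0.8 — so only
read sampling differs between samples, and DMR false positives are
genuinely null. Inside a planted DMR both samples have flat per-site MLs
differing by `dmr_delta` (base 0.2), alternating hyper/hypo. Coverage is
Poisson(`read_depth`, default 10); observed methylated reads are
Binomial(coverage, ML + (1 − ML)·r) with r = 0.0004 by default (99.96%
conversion).

What the generator does **not** emulate: read-level errors and mapping
bias, paralogy/repeat structure, M-bias, CHH strand asymmetry, linked
variant phasing, and expression–methylation coupling outside planted
structure. Passing recovery tests therefore demonstrates the correctness
and calibration of the statistical machinery under the stated sampling
models, not robustness to alignment artefacts in real data.

## Problem sizes and defaults

Default simulations use 2 × 400 kb chromosomes with 40 genes — small
enough for interactive runs while every region class, context and planted
structure occurs. Recovery benchmarks use the sizes their statements
require: 5,000 genes with 10% planted DE at |log₂FC| = 2 and mean count 50
for the expression test, and a 2 Mb genome with 20 planted 4 kb DMRs
(ΔML = 0.4, depth 20) for the DMR test. The headline corpus counts of the
motivating study (tens of thousands of SNPs, hundreds of DEGs and DMRs)
arise from its raw sequencing data and are not reproducible from printed
values; the acceptance machinery therefore checks desk-computable
quantities and property-based recovery instead.

## Known limitations

- The conditional DE test cannot separate biological from technical
  variation; with true biological replication a dispersion-based test is
  strictly better.
- DMR boundaries are window-quantized before trimming; merged ΔML is
  diluted by boundary windows.
- `start_gained` ignores ATGs created across UTR–intron junctions or into
  the CDS; splice-region effects beyond the 2 bp dinucleotides are not
  classified.
- The CGI scan reproduces the classical algorithm, not the exact output
  formatting/trimming of any particular EMBOSS build.
- Unanchored scaffolds are treated like any other sequence; the package
  has no special handling for repeat-dominated contigs.
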