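"""Core domain records shared across the pipeline stages.

Coordinates are 1-based inclusive throughout the in-memory model, matching
VCF and GFF3. BED output alone is 0-based half-open (see :mod:`emsomics.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Input violates a documented precondition (bad file, bad parameter)."""


class LayoutError(ValidationError):
    """Requested simulation layout cannot fit on the genome."""


#: region labels, in annotation priority order (highest first)
REGIONS = (
    "exon",
    "splice_site",
    "intron",
    "utr5",
    "utr3",
    "upstream_5kb",
    "downstream_5kb",
    "intergenic",
)

#: coding-consequence classes considered "large impact" on protein function
LARGE_IMPACT = frozenset(
    {
        "nonsynonymous",
        "stop_gained",
        "stop_lost",
        "start_gained",
        "start_lost",
        "splice_acceptor",
        "splice_donor",
        "codon_insertion",
        "codon_deletion",
        "frameshift",
    }
)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class Variant:
    """A SNP or small (< 50 bp) insertion/deletion, VCF left-anchored."""

    chrom: str
    pos: int  # 1-based anchor position
    ref: str
    alt: str
    zygosity: str = "het"  # {"het", "hom"}

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.zygosity not in ("het", "hom"):
            raise ValidationError(f"bad zygosity {self.zygosity!r}")
        if not self.ref or not self.alt:
            raise ValidationError("empty allele")
        if self.size >= 50:
            raise ValidationError("indels must be < 50 bp")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def is_transition(self) -> bool:
        return self.vtype == "snp" and (self.ref, self.alt) in TRANSITIONS


@dataclass
class GeneModel:
    """Strand-aware gene with exon/CDS/UTR structure.

    Interval lists hold 1-based inclusive ``(start, end)`` tuples in genomic
    coordinates, sorted by start regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS on the coding strand."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class VariantEffect:
    """Predicted consequence of one variant against one gene model."""

    variant: Variant
    gene_id: str | None
    region: str
    coding_effect: str = "none"
    aa_change: str = ""


@dataclass
class DEGResult:
    gene_id: str
    log2fc: float
    pvalue: float
    padj: float
    status: str = "ns"  # {"up", "down", "ns"}


@dataclass
class DMR:
    """Differentially methylated region (mutant minus control)."""

    chrom: str
    start: int
    end: int
    delta_ml: float
    pvalue: float
    padj: float
    direction: str  # {"hyper", "hypo"}
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_percent: float
    obs_exp_cpg: float
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
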