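"""No-replicate differential expression between two count libraries.

With a single library per condition, dispersion cannot be estimated, so the
test is the exact conditional binomial: under the null of equal relative
expression, a gene's mutant count given its two-library total k follows
Binomial(k, N_mut / (N_ctrl + N_mut)) with effective library sizes adjusted
by a single trimmed-mean-of-M-values (TMM) scaling factor. Two-sided
p-values are BH-adjusted and genes are called differential at adjusted
p < 0.005 with at least a two-fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .models import ValidationError


def scaling_factor(
    counts_control: np.ndarray,
    counts_mutant: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM normalization factor of the mutant library vs the control reference.

    Genes with a zero in either library are excluded; per-gene log-ratios M
    and abundances A are doubly trimmed (30% on M, 5% on A by default) and
    averaged with inverse-asymptotic-variance weights. The factor multiplies
    the mutant library size to put both libraries on a common scale; equal
    libraries give 1.0.
    """
    k1 = np.asarray(counts_control, dtype=float)
    k2 = np.asarray(counts_mutant, dtype=float)
    n1, n2 = k1.sum(), k2.sum()
    if n1 == 0 or n2 == 0:
        raise ValidationError("cannot normalize an all-zero library")
    keep = (k1 > 0) & (k2 > 0)
    if keep.sum() < 2:
        raise ValidationError("need >= 2 genes expressed in both libraries")
    k1, k2 = k1[keep], k2[keep]
    p1, p2 = k1 / n1, k2 / n2
    m = np.log2(p2 / p1)
    a = 0.5 * np.log2(p2 * p1)
    if np.allclose(m, m[0]):  # pure depth shift: trimming would drop everything
        return float(2 ** m[0])
    m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
    a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
    sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not sel.any():
        sel = np.ones_like(m, dtype=bool)
    w = 1.0 / ((n1 - k1) / (n1 * k1) + (n2 - k2) / (n2 * k2))
    return float(2 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))


def fpkm(counts: np.ndarray, lengths: np.ndarray, library_total: float) -> np.ndarray:
    """Fragments per kilobase of gene model per million mapped reads."""
    if library_total <= 0:
        raise ValidationError("library total must be positive")
    return np.asarray(counts, dtype=float) * 1e9 / (np.asarray(lengths, dtype=float) * library_total)


def log2fc(control_value: float, mutant_value: float, pseudocount: float = 0.1) -> float:
    """log2(mutant/control); the pseudocount applies only when a value is zero."""
    c, m = float(control_value), float(mutant_value)
    if c < 0 or m < 0:
        raise ValidationError("expression values must be non-negative")
    if c == 0 or m == 0:
        if pseudocount == 0:
            raise ValidationError("undefined fold change: zero value with zero pseudocount")
        c += pseudocount
        m += pseudocount
    return float(np.log2(m / c))


def deg_test(
    count_control: np.ndarray,
    count_mutant: np.ndarray,
    n_control_total: float,
    n_mutant_total: float,
    normal_approx_above: int = 10_000,
) -> np.ndarray:
    """Two-sided exact conditional binomial p-values, vectorized over genes.

    p = min(1, 2 * min(lower tail, upper tail)) of Binomial(k, p0) at the
    mutant count, with k the gene's two-library total and p0 the mutant share
    of the combined effective library size. Totals above
    ``normal_approx_above`` use a continuity-corrected normal approximation.
    Genes with k = 0 get p = 1.
    """
    if n_control_total <= 0 or n_mutant_total <= 0:
        raise ValidationError("library totals must be positive")
    k1 = np.asarray(count_control, dtype=np.int64)
    k2 = np.asarray(count_mutant, dtype=np.int64)
    k = k1 + k2
    p0 = n_mutant_total / (n_control_total + n_mutant_total)
    p = np.ones(len(k), dtype=float)
    nz = k > 0
    exact = nz & (k <= normal_approx_above)
    if exact.any():
        lower = stats.binom.cdf(k2[exact], k[exact], p0)
        upper = stats.binom.sf(k2[exact] - 1, k[exact], p0)
        p[exact] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    big = nz & ~exact
    if big.any():
        mu = k[big] * p0
        sd = np.sqrt(k[big] * p0 * (1 - p0))
        lower = stats.norm.cdf(k2[big] + 0.5, mu, sd)
        upper = stats.norm.sf(k2[big] - 0.5, mu, sd)
        p[big] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(df: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Add the up/down/ns status column given log2fc and padj columns."""
    config = config or PipelineConfig()
    sig = df["padj"] < config.deg_padj
    up = sig & (df["log2fc"] >= config.deg_min_abs_log2fc)
    down = sig & (df["log2fc"] <= -config.deg_min_abs_log2fc)
    out = df.copy()
    out["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def run_deg(counts: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full DE pipeline on a (gene_id, length_bp, count_control, count_mutant) table.

    Genes with zero counts in both libraries are dropped before testing (and
    before the BH family size is fixed). Fold changes are computed on FPKM
    with the configured pseudocount applied only at zeros.
    """
    config = config or PipelineConfig()
    df = counts.copy()
    df = df[(df["count_control"] + df["count_mutant"]) > 0].reset_index(drop=True)
    if df.empty:
        raise ValidationError("no genes with nonzero counts")
    n1 = float(df["count_control"].sum())
    n2 = float(df["count_mutant"].sum())
    f = scaling_factor(df["count_control"].to_numpy(), df["count_mutant"].to_numpy())
    n2_eff = n2 * f
    df["fpkm_control"] = fpkm(df["count_control"].to_numpy(), df["length_bp"].to_numpy(), n1)
    df["fpkm_mutant"] = fpkm(df["count_mutant"].to_numpy(), df["length_bp"].to_numpy(), n2_eff)
    df["log2fc"] = [
        log2fc(c, m, config.pseudocount)
        for c, m in zip(df["fpkm_control"], df["fpkm_mutant"])
    ]
    df["pvalue"] = deg_test(
        df["count_control"].to_numpy(),
        df["count_mutant"].to_numpy(),
        n1,
        n2_eff,
        config.normal_approx_above,
    )
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    return call_degs(df, config)
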