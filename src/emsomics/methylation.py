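"""Bisulfite methylation levels, site calls, sliding windows and DMRs.

Per-site methylation level ML = m/(m+u) is corrected for bisulfite
non-conversion r (estimated from an unmethylated spike-in) as
ML_corrected = (ML - r)/(1 - r), clamped to [0, 1]. A site is called
methylated when its methylated read count is improbably high under
Binomial(coverage, r), after BH control of the FDR across sites. Counts are
aggregated in 3,000 bp windows sliding by 600 bp; windows whose 2x2 count
table differs between samples (exact test, BH) by at least ``dmr_min_delta``
in ML with enough covered cytosines are merged into DMRs and trimmed to the
outermost covered cytosine, so a DMR can be much shorter than one window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .models import DMR, ValidationError

CONTEXTS = ("CG", "CHG", "CHH")


class NotACytosineError(ValidationError):
    pass


@dataclass
class NonConversionEstimate:
    rate: float
    n_reads_used: int
    source: str


def context_of(seq: str, pos: int, strand: str) -> str:
    """CG/CHG/CHH context of the cytosine at 1-based ``pos`` on ``strand``.

    Read from the two downstream bases on the cytosine's own strand; within
    2 bp of a sequence end the context is undeterminable and falls back to
    CHH (the maximal-entropy class).
    """
    base = seq[pos - 1]
    if strand == "+":
        if base != "C":
            raise NotACytosineError(f"{pos}:+ is {base}, not C")
        n1 = seq[pos] if pos < len(seq) else None
        n2 = seq[pos + 1] if pos + 1 < len(seq) else None
    else:
        if base != "G":
            raise NotACytosineError(f"{pos}:- is {base}, not C on the minus strand")
        n1 = _comp(seq[pos - 2]) if pos >= 2 else None
        n2 = _comp(seq[pos - 3]) if pos >= 3 else None
    if n1 == "G":
        return "CG"
    if n1 is None:
        return "CHH"
    if n2 == "G":
        return "CHG"
    return "CHH"


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}.get(b, "N")


def estimate_nonconversion(
    control_sites: pd.DataFrame, source: str = "control_unmethylated"
) -> NonConversionEstimate:
    """Non-conversion rate = methylated / total reads on the unmethylated control."""
    meth = int(control_sites["count_methylated"].sum())
    total = meth + int(control_sites["count_unmethylated"].sum())
    if total == 0:
        raise ValidationError("control sequence has zero coverage; cannot estimate r")
    r = meth / total
    if r >= 0.05:
        raise ValidationError(
            f"non-conversion rate {r:.4f} >= 0.05 is implausible; check the control"
        )
    return NonConversionEstimate(rate=r, n_reads_used=total, source=source)


def correct_ml(ml, r: float):
    """(ML - r)/(1 - r), clamped to [0, 1]; identity at r = 0."""
    if r >= 1:
        raise ValidationError("non-conversion rate must be < 1")
    return np.clip((np.asarray(ml, dtype=float) - r) / (1.0 - r), 0.0, 1.0)


def site_pvalue(meth, coverage, r: float):
    """Exact upper-tail P(X >= meth), X ~ Binomial(coverage, r)."""
    meth = np.asarray(meth, dtype=np.int64)
    coverage = np.asarray(coverage, dtype=np.int64)
    return stats.binom.sf(meth - 1, coverage, r)


def call_sites(
    sites: pd.DataFrame, r: float, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-site methylation calls on a cytosine report table.

    Sites below ``min_coverage`` are excluded from testing (counted in the
    returned QC dict, not an error). Adds ml_raw, ml_corrected, pvalue, padj
    and the boolean ``methylated`` column to the retained rows.
    """
    config = config or PipelineConfig()
    cov = sites["count_methylated"] + sites["count_unmethylated"]
    kept = sites[cov >= config.min_coverage].copy()
    qc = {
        "n_total": int(len(sites)),
        "n_tested": int(len(kept)),
        "n_low_coverage": int(len(sites) - len(kept)),
    }
    coverage = (kept["count_methylated"] + kept["count_unmethylated"]).to_numpy()
    meth = kept["count_methylated"].to_numpy()
    with np.errstate(invalid="ignore"):
        kept["ml_raw"] = np.where(coverage > 0, meth / coverage, 0.0)
    kept["ml_corrected"] = correct_ml(kept["ml_raw"].to_numpy(), r)
    kept["pvalue"] = site_pvalue(meth, coverage, r)
    if len(kept):
        from .expression import bh_adjust

        kept["padj"] = bh_adjust(kept["pvalue"].to_numpy())
    else:
        kept["padj"] = np.array([], dtype=float)
    kept["methylated"] = kept["padj"] < config.site_fdr
    qc["n_methylated"] = int(kept["methylated"].sum())
    return kept, qc


def window_starts(chrom_length: int, window: int = 3000, step: int = 600) -> np.ndarray:
    """Window start positions 1, 1+step, ...; generation stops with the first
    window that reaches the chromosome end (that window is truncated)."""
    n = max(1, int(np.ceil((chrom_length - window) / step)) + 1)
    return 1 + step * np.arange(n)


def make_windows(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Sum methylated/unmethylated counts (total and per context) per window.

    Windows with zero covered cytosines are omitted. Overlapping windows
    (window > step) each count every site they contain.
    """
    config = config or PipelineConfig()
    w, s = config.window_size, config.step_size
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        L = chrom_lengths[chrom]
        starts = window_starts(L, w, s)
        n_win = len(starts)
        pos = sub["pos"].to_numpy()
        cov = (sub["count_methylated"] + sub["count_unmethylated"]).to_numpy()
        covered = cov > 0
        meth = sub["count_methylated"].to_numpy()
        unmeth = sub["count_unmethylated"].to_numpy()
        ctx = sub["context"].to_numpy()
        # window index range per site: j in [ceil((pos-w)/s), floor((pos-1)/s)]
        j_lo = np.maximum(0, np.ceil((pos - w) / s).astype(np.int64))
        j_hi = np.minimum(n_win - 1, (pos - 1) // s)
        agg_m = np.zeros(n_win)
        agg_u = np.zeros(n_win)
        agg_n = np.zeros(n_win, dtype=np.int64)
        per_ctx = {c: (np.zeros(n_win), np.zeros(n_win)) for c in CONTEXTS}
        valid = j_lo <= j_hi

        def scatter(site_mask: np.ndarray, m_target, u_target, n_target=None):
            mask = valid & site_mask
            lo, hi = j_lo[mask], j_hi[mask]
            reps = hi - lo + 1
            if reps.sum() == 0:
                return
            base = np.repeat(np.cumsum(reps) - reps, reps)
            idx = np.repeat(lo, reps) + (np.arange(reps.sum()) - base)
            np.add.at(m_target, idx, np.repeat(meth[mask], reps))
            np.add.at(u_target, idx, np.repeat(unmeth[mask], reps))
            if n_target is not None:
                np.add.at(n_target, idx, np.repeat(covered[mask].astype(np.int64), reps))

        scatter(np.ones(len(pos), dtype=bool), agg_m, agg_u, agg_n)
        for c in CONTEXTS:
            scatter(ctx == c, per_ctx[c][0], per_ctx[c][1])
        keep = agg_n > 0
        for j in np.flatnonzero(keep):
            start = int(starts[j])
            row = {
                "chrom": chrom,
                "start": start,
                "end": min(start + w - 1, L),
                "n_sites": int(agg_n[j]),
                "meth": int(agg_m[j]),
                "unmeth": int(agg_u[j]),
            }
            row["ml"] = row["meth"] / (row["meth"] + row["unmeth"]) if row["meth"] + row["unmeth"] else 0.0
            for c in CONTEXTS:
                row[f"meth_{c}"] = int(per_ctx[c][0][j])
                row[f"unmeth_{c}"] = int(per_ctx[c][1][j])
            rows.append(row)
    cols = ["chrom", "start", "end", "n_sites", "meth", "unmeth", "ml"] + [
        f"{p}_{c}" for c in CONTEXTS for p in ("meth", "unmeth")
    ]
    return pd.DataFrame(rows, columns=cols)


def _table_pvalue(m1: int, u1: int, m2: int, u2: int, exact_below: int = 10_000) -> float:
    """2x2 association p-value: Fisher exact, chi-squared for huge tables."""
    total = m1 + u1 + m2 + u2
    if total == 0:
        return 1.0
    if total <= exact_below:
        return float(stats.fisher_exact([[m1, u1], [m2, u2]])[1])
    obs = np.array([[m1, u1], [m2, u2]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(obs, correction=True)[1])


def call_dmrs(
    windows_control: pd.DataFrame,
    windows_mutant: pd.DataFrame,
    sites_control: pd.DataFrame | None = None,
    sites_mutant: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> list[DMR]:
    """Differentially methylated regions between two samples.

    Shared windows are tested on their (meth, unmeth) 2x2 table, BH-adjusted
    across windows; significant windows (padj < dmr_fdr, |delta ML| >=
    dmr_min_delta, >= dmr_min_sites covered cytosines in each sample) that
    overlap or abut are merged and, when site tables are supplied, trimmed
    to the outermost covered cytosine.
    """
    config = config or PipelineConfig()
    merged = windows_control.merge(
        windows_mutant, on=["chrom", "start"], suffixes=("_c", "_m"), how="inner"
    )
    if merged.empty:
        return []
    if (merged["end_c"] != merged["end_m"]).any():
        raise ValidationError("window grids of the two samples do not match")
    p = np.array(
        [
            _table_pvalue(r.meth_m, r.unmeth_m, r.meth_c, r.unmeth_c)
            for r in merged.itertuples()
        ]
    )
    from .expression import bh_adjust

    padj = bh_adjust(p)
    delta = merged["ml_m"].to_numpy() - merged["ml_c"].to_numpy()
    n_sites = np.minimum(merged["n_sites_c"].to_numpy(), merged["n_sites_m"].to_numpy())
    sig = (
        (padj < config.dmr_fdr)
        & (np.abs(delta) >= config.dmr_min_delta)
        & (n_sites >= config.dmr_min_sites)
    )
    sig_win = merged[sig].assign(padj=padj[sig]).sort_values(["chrom", "start"])
    if sig_win.empty:
        return []

    dmrs: list[DMR] = []
    cur: dict | None = None
    for r in sig_win.itertuples():
        if cur is not None and r.chrom == cur["chrom"] and r.start <= cur["end"] + 1:
            cur["end"] = max(cur["end"], int(r.end_c))
            cur["padj"] = min(cur["padj"], float(r.padj))
        else:
            if cur is not None:
                dmrs.append(_finalize_dmr(cur, sites_control, sites_mutant, config))
            cur = {
                "chrom": r.chrom,
                "start": int(r.start),
                "end": int(r.end_c),
                "padj": float(r.padj),
            }
    if cur is not None:
        dmrs.append(_finalize_dmr(cur, sites_control, sites_mutant, config))
    return [d for d in dmrs if d is not None]


def _region_counts(sites: pd.DataFrame, chrom: str, start: int, end: int):
    sub = sites[(sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] <= end)]
    cov = sub["count_methylated"] + sub["count_unmethylated"]
    covered = sub[cov > 0]
    return (
        int(sub["count_methylated"].sum()),
        int(sub["count_unmethylated"].sum()),
        covered["pos"].to_numpy(),
    )


def _finalize_dmr(
    region: dict,
    sites_control: pd.DataFrame | None,
    sites_mutant: pd.DataFrame | None,
    config: PipelineConfig,
) -> DMR | None:
    chrom, start, end = region["chrom"], region["start"], region["end"]
    if sites_control is not None and sites_mutant is not None:
        m1, u1, pos1 = _region_counts(sites_control, chrom, start, end)
        m2, u2, pos2 = _region_counts(sites_mutant, chrom, start, end)
        all_pos = np.union1d(pos1, pos2)
        if len(all_pos) == 0:
            return None
        start, end = int(all_pos.min()), int(all_pos.max())
        ml1 = m1 / (m1 + u1) if m1 + u1 else 0.0
        ml2 = m2 / (m2 + u2) if m2 + u2 else 0.0
        delta = ml2 - ml1
        pvalue = _table_pvalue(m2, u2, m1, u1)
        n_sites = int(min(len(pos1), len(pos2)))
    else:
        delta, pvalue, n_sites = np.nan, np.nan, -1
    return DMR(
        chrom=chrom,
        start=start,
        end=end,
        delta_ml=float(delta),
        pvalue=float(pvalue),
        padj=float(region["padj"]),
        direction="hyper" if delta > 0 else "hypo",
        n_sites=n_sites,
    )


def genome_summary(called_sites: pd.DataFrame) -> dict:
    """Per-context methylated fractions and the composition of methylated sites.

    Composition percentages sum to 100; with zero methylated sites they are
    reported as zeros with the ``undefined`` flag set.
    """
    out: dict = {"per_context_fraction": {}, "composition_percent": {}, "undefined": False}
    n_meth_total = int(called_sites["methylated"].sum())
    for c in CONTEXTS:
        sub = called_sites[called_sites["context"] == c]
        n = len(sub)
        n_meth = int(sub["methylated"].sum())
        out["per_context_fraction"][c] = n_meth / n if n else 0.0
        out["composition_percent"][c] = 100.0 * n_meth / n_meth_total if n_meth_total else 0.0
    out["undefined"] = n_meth_total == 0
    out["fraction_methylated_overall"] = (
        n_meth_total / len(called_sites) if len(called_sites) else 0.0
    )
    return out
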