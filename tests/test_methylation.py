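"""Methylation levels, site calls, windows and DMR detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emsomics import PipelineConfig, SimConfig, ValidationError
from emsomics import methylation as meth
from emsomics import simulate as sim

from .oracles import binom_upper_tail, trinucleotide_contexts


class TestContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 2, "+", "CG"),
            ("ACAGT", 2, "+", "CHG"),
            ("ACAAT", 2, "+", "CHH"),
            ("ACGT", 3, "-", "CG"),   # G at 3: minus-strand C followed by C->G
            ("TCTGA", 4, "-", "CHG"),
            ("AC", 2, "+", "CHH"),    # end fallback
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert meth.context_of(seq, pos, strand) == expected

    def test_not_a_cytosine_raises(self):
        with pytest.raises(meth.NotACytosineError):
            meth.context_of("ACGT", 1, "+")
        with pytest.raises(meth.NotACytosineError):
            meth.context_of("ACGT", 2, "-")

    def test_agrees_with_exhaustive_tabulation(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        expected = trinucleotide_contexts(seq)
        for (pos, strand), ctx in expected.items():
            assert meth.context_of(seq, pos, strand) == ctx


class TestNonConversion:
    def test_worked_rate(self):
        df = pd.DataFrame({"count_methylated": [4], "count_unmethylated": [9996]})
        est = meth.estimate_nonconversion(df)
        assert est.rate == pytest.approx(0.0004)
        assert est.n_reads_used == 10_000

    def test_zero_meth_reads(self):
        df = pd.DataFrame({"count_methylated": [0, 0], "count_unmethylated": [50, 70]})
        assert meth.estimate_nonconversion(df).rate == 0.0

    def test_no_coverage_and_implausible_rate_raise(self):
        empty = pd.DataFrame({"count_methylated": [0], "count_unmethylated": [0]})
        with pytest.raises(ValidationError):
            meth.estimate_nonconversion(empty)
        bad = pd.DataFrame({"count_methylated": [10], "count_unmethylated": [90]})
        with pytest.raises(ValidationError):
            meth.estimate_nonconversion(bad)


class TestCorrectML:
    def test_fixed_points_and_worked_value(self):
        assert meth.correct_ml(0.0004, 0.0004) == pytest.approx(0.0)
        assert meth.correct_ml(1.0, 0.3) == pytest.approx(1.0)
        assert float(meth.correct_ml(0.25, 0.0004)) == pytest.approx(0.2497, abs=5e-5)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=0.99),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotone_in_ml_and_identity_at_zero_r(self, ml1, ml2, r):
        lo, hi = sorted([ml1, ml2])
        assert meth.correct_ml(lo, r) <= meth.correct_ml(hi, r) + 1e-12
        assert meth.correct_ml(ml1, 0.0) == pytest.approx(ml1)

    def test_invalid_rate(self):
        with pytest.raises(ValidationError):
            meth.correct_ml(0.5, 1.0)


class TestSiteCalls:
    def test_worked_pvalue(self):
        p = float(meth.site_pvalue(5, 10, 0.01))
        assert p == pytest.approx(binom_upper_tail(5, 10, 0.01), abs=1e-12)
        assert p == pytest.approx(2.4e-8, rel=0.05)

    def test_zero_meth_is_p_one(self):
        assert float(meth.site_pvalue(0, 10, 0.01)) == 1.0

    def test_grid_matches_exact_tail_sums(self):
        for r in (0.0004, 0.004, 0.05):
            for cov in (1, 5, 17, 50):
                for m in range(0, cov + 1, max(1, cov // 5)):
                    got = float(meth.site_pvalue(m, cov, r))
                    assert got == pytest.approx(binom_upper_tail(m, cov, r), abs=1e-12)

    def test_low_coverage_sites_excluded_not_failed(self):
        df = pd.DataFrame(
            {
                "chrom": ["c"] * 3,
                "pos": [1, 2, 3],
                "strand": ["+"] * 3,
                "count_methylated": [2, 8, 0],
                "count_unmethylated": [1, 2, 9],
                "context": ["CG", "CG", "CHH"],
            }
        )
        called, qc = meth.call_sites(df, r=0.004)
        assert qc == {"n_total": 3, "n_tested": 2, "n_low_coverage": 1, "n_methylated": 1}
        assert set(called.pos) == {2, 3}

    def test_null_pvalues_dominate_uniform(self):
        rng = np.random.default_rng(17)
        r = 0.004
        cov = rng.poisson(10, size=30_000) + 1
        m = rng.binomial(cov, r)
        p = meth.site_pvalue(m, cov, r)
        for t in (0.01, 0.05, 0.2):
            frac = float((p <= t).mean())
            se = np.sqrt(t * (1 - t) / len(p))
            assert frac <= t + 3 * se


class TestWindows:
    def test_start_enumeration_examples(self):
        assert list(meth.window_starts(4200)) == [1, 601, 1201]
        assert list(meth.window_starts(4300)) == [1, 601, 1201, 1801]
        assert list(meth.window_starts(3000)) == [1]
        assert list(meth.window_starts(2000)) == [1]  # single truncated window

    def test_single_site_window_ml(self):
        df = pd.DataFrame(
            {
                "chrom": ["c"],
                "pos": [50],
                "strand": ["+"],
                "count_methylated": [3],
                "count_unmethylated": [1],
                "context": ["CG"],
            }
        )
        w = meth.make_windows(df, {"c": 3000})
        assert len(w) == 1
        assert w.ml[0] == 0.75 and w.n_sites[0] == 1 and w.meth_CG[0] == 3

    def test_overlap_factor_bound(self, methylome_data, small_cfg):
        tables, _ = methylome_data
        df = tables["control"]
        df = df[df.chrom == "Chr01"].iloc[:20_000]
        w = meth.make_windows(df, {"Chr01": small_cfg.chrom_length})
        covered = int(((df.count_methylated + df.count_unmethylated) > 0).sum())
        total = int(w.n_sites.sum())
        assert covered <= total <= 5 * covered


def _window_row(chrom, start, end, meth_n, unmeth_n, n_sites=10):
    total = meth_n + unmeth_n
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "n_sites": n_sites,
        "meth": meth_n,
        "unmeth": unmeth_n,
        "ml": meth_n / total if total else 0.0,
        **{f"meth_{c}": 0 for c in ("CG", "CHG", "CHH")},
        **{f"unmeth_{c}": 0 for c in ("CG", "CHG", "CHH")},
    }


class TestDMRs:
    def test_identical_samples_yield_no_dmrs(self):
        w = pd.DataFrame([_window_row("c", 1, 3000, 40, 60)])
        assert meth.call_dmrs(w, w) == []

    def test_extreme_table_is_hypo_with_delta_minus_one(self):
        wc = pd.DataFrame([_window_row("c", 1, 3000, 100, 0)])
        wm = pd.DataFrame([_window_row("c", 1, 3000, 0, 100)])
        sites_c = pd.DataFrame(
            {
                "chrom": ["c"] * 2,
                "pos": [100, 2900],
                "count_methylated": [50, 50],
                "count_unmethylated": [0, 0],
            }
        )
        sites_m = sites_c.assign(count_methylated=[0, 0], count_unmethylated=[50, 50])
        dmrs = meth.call_dmrs(wc, wm, sites_c, sites_m)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hypo" and d.delta_ml == pytest.approx(-1.0)
        assert (d.start, d.end) == (100, 2900)  # trimmed to outermost cytosines

    def test_mismatched_grids_raise(self):
        wc = pd.DataFrame([_window_row("c", 1, 3000, 10, 10)])
        wm = pd.DataFrame([_window_row("c", 1, 2500, 10, 10)])
        with pytest.raises(ValidationError):
            meth.call_dmrs(wc, wm)

    def test_antisymmetric_under_sample_swap(self, methylome_data, small_cfg):
        tables, truth = methylome_data
        lengths = {
            f"Chr{i:02d}": small_cfg.chrom_length
            for i in range(1, small_cfg.n_chromosomes + 1)
        }
        g_c = tables["control"][tables["control"].chrom != sim.CONTROL_SEQ_ID]
        g_m = tables["mutant"][tables["mutant"].chrom != sim.CONTROL_SEQ_ID]
        wc = meth.make_windows(g_c, lengths)
        wm = meth.make_windows(g_m, lengths)
        fwd = meth.call_dmrs(wc, wm, g_c, g_m)
        rev = meth.call_dmrs(wm, wc, g_m, g_c)
        assert len(fwd) == len(truth.dmr_intervals) > 0
        assert [(d.chrom, d.start, d.end) for d in fwd] == [
            (d.chrom, d.start, d.end) for d in rev
        ]
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [d.direction for d in rev] == [flip[d.direction] for d in fwd]
        for f, r in zip(fwd, rev):
            assert f.delta_ml == pytest.approx(-r.delta_ml)
            assert f.n_sites >= PipelineConfig().dmr_min_sites
            assert f.length >= 1


class TestGenomeSummary:
    def test_composition_sums_to_hundred(self, methylome_data):
        tables, _ = methylome_data
        df = tables["control"]
        called, _ = meth.call_sites(df[df.chrom != sim.CONTROL_SEQ_ID], r=0.0004)
        summary = meth.genome_summary(called)
        assert sum(summary["composition_percent"].values()) == pytest.approx(100.0, abs=1e-9)
        assert not summary["undefined"]

    def test_zero_methylated_flagged(self):
        df = pd.DataFrame(
            {
                "chrom": ["c"],
                "pos": [1],
                "strand": ["+"],
                "count_methylated": [0],
                "count_unmethylated": [20],
                "context": ["CG"],
            }
        )
        called, _ = meth.call_sites(df, r=0.0)
        summary = meth.genome_summary(called)
        assert summary["undefined"] and sum(summary["composition_percent"].values()) == 0.0

    def test_context_levels_recovered_without_noise(self):
        cfg = SimConfig(
            seed=19, n_genes=0, n_de_genes=0, n_dmrs=0, n_chromosomes=1,
            chrom_length=150_000, nonconversion_rate=0.0, read_depth=12.0,
            control_seq_length=5_000,
        )
        genome, _ = sim.simulate_genome(cfg)
        tables, _ = sim.simulate_methylome(genome, cfg)
        df = tables["mutant"]
        called, _ = meth.call_sites(df[df.chrom != sim.CONTROL_SEQ_ID], r=0.0)
        summary = meth.genome_summary(called)
        truth_levels = {"CG": 0.576, "CHG": 0.328, "CHH": 0.026}
        for ctx, level in truth_levels.items():
            n = int((called.context == ctx).sum())
            se = np.sqrt(level * (1 - level) / n)
            assert abs(summary["per_context_fraction"][ctx] - level) <= 3 * se + 1e-3
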