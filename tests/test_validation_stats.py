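"""Fisher exact OR/CI, trend test, BKY FDR, exact power, two-stage report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolgwas.validation_stats import (
    GenotypeTable,
    TwoStageValidation,
    bky_fdr,
    build_model_table,
    cochran_armitage,
    fisher_exact_p,
    fisher_or,
    fisher_power,
    orient_minor,
)

#: published first-cohort validation P-values (three models x four SNPs)
PUBLISHED_PVALS = [
    0.0168, 0.217, 0.0235, 0.0164, 0.4745, 0.0391,
    0.0397, 1.0, 0.0638, 0.1227, 0.0169, 0.0062,
]


def bky_oracle(p, q):
    """Literal transcription of the two-stage step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    qp = q / (1 + q)
    s = np.sort(p)

    def bh(level):
        hits = [i + 1 for i in range(m) if s[i] <= level * (i + 1) / m]
        return max(hits, default=0)

    r1 = bh(qp)
    if r1 == 0:
        return np.zeros(m, bool)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, bool)
    r2 = bh(qp * m / m0)
    return p <= s[r2 - 1] if r2 else np.zeros(m, bool)


class TestFisher:
    def test_symmetric_table(self):
        r = fisher_or(10, 10, 10, 10)
        assert r.or_hat == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_reference_table_or_ci_p(self):
        r = fisher_or(20, 5, 10, 15)
        assert r.or_hat == pytest.approx(6.0)
        # Woolf CI oracle: exp(ln 6 +/- 1.959964 * sqrt(1/20+1/5+1/10+1/15))
        assert r.ci_low == pytest.approx(1.6931795592741459, rel=1e-9)
        assert r.ci_high == pytest.approx(21.261773332199304, rel=1e-9)
        # exact-rational enumeration oracle value
        assert r.p == pytest.approx(0.008578508150469122, rel=1e-12)

    def test_zero_cell_reports_na_but_p(self):
        r = fisher_or(5, 0, 3, 4)
        assert np.isnan(r.or_hat) and np.isnan(r.ci_low)
        assert 0 < r.p <= 1

    def test_zero_margin_is_deterministic(self):
        assert fisher_exact_p(0, 5, 0, 7) == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            ours = fisher_exact_p(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_conditional_style_uses_conditional_mle(self):
        r = fisher_or(20, 5, 10, 15, or_style="conditional")
        ref = stats.contingency.odds_ratio([[20, 5], [10, 15]], kind="conditional")
        assert r.or_hat == pytest.approx(float(ref.statistic), rel=1e-9)


class TestCochranArmitage:
    def test_identical_rows_carry_no_trend(self):
        z2, p = cochran_armitage([[10, 20, 10], [10, 20, 10]])
        assert z2 == 0.0 and p == 1.0

    def test_matches_correlation_oracle(self):
        table = np.array([[10, 20, 10], [20, 15, 5]])
        z2, p = cochran_armitage(table)
        # independent oracle: trend chi-square equals N * r^2 where r is
        # the Pearson correlation of group indicator and genotype score
        # over expanded subjects
        g = np.repeat([0, 1, 2, 0, 1, 2], table.ravel())
        y = np.repeat([1, 1, 1, 0, 0, 0], table.ravel())
        r = np.corrcoef(g, y)[0, 1]
        assert z2 == pytest.approx(len(g) * r**2, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(len(g) * r**2, 1), rel=1e-9)

    def test_group_swap_invariance(self):
        t = np.array([[5, 9, 16], [12, 11, 4]])
        assert cochran_armitage(t)[1] == pytest.approx(
            cochran_armitage(t[::-1])[1], rel=1e-12
        )

    def test_orientation_reversal_invariance(self):
        t = np.array([[5, 9, 16], [12, 11, 4]])
        assert cochran_armitage(t)[0] == pytest.approx(
            cochran_armitage(t[:, ::-1])[0], rel=1e-12
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage([[0, 0, 0], [0, 0, 0]])

    def test_additive_risk_favours_trend_over_dominant(self, rng):
        """Per-allele effects: the trend test beats the dominant 2x2 test."""
        trend_p, dom_p = [], []
        f0 = 0.3
        # per-allele OR 1.8 on the logit scale
        f_case_geno = np.array([(1 - f0) ** 2, 2 * f0 * (1 - f0), f0**2])
        w = np.array([1.0, 1.8, 1.8**2])
        f_case_geno = f_case_geno * w / (f_case_geno * w).sum()
        f_ctrl_geno = np.array([(1 - f0) ** 2, 2 * f0 * (1 - f0), f0**2])
        for _ in range(500):
            case = rng.multinomial(100, f_case_geno)
            ctrl = rng.multinomial(100, f_ctrl_geno)
            trend_p.append(cochran_armitage(np.vstack([case, ctrl]))[1])
            a, b = case[1] + case[2], ctrl[1] + ctrl[2]
            dom_p.append(fisher_exact_p(int(a), int(b), int(case[0]), int(ctrl[0])))
        assert np.median(trend_p) < np.median(dom_p)


class TestBkyFdr:
    def test_all_ones_reject_nothing(self):
        res = bky_fdr([1.0] * 8, q=0.05)
        assert not res.rejected.any()
        assert res.m0_hat == 8

    def test_zero_pvalue_rejected_at_any_level(self):
        for q in (0.001, 0.05, 0.5):
            assert bky_fdr([0.0], q=q).rejected.all()

    @pytest.mark.parametrize("q", [0.05, 0.11])
    def test_published_pvalue_batch_matches_oracles(self, q):
        from statsmodels.stats.multitest import multipletests

        res = bky_fdr(PUBLISHED_PVALS, q=q, adjusted=False)
        oracle = bky_oracle(PUBLISHED_PVALS, q)
        assert (res.rejected == oracle).all()
        sm = multipletests(PUBLISHED_PVALS, alpha=q, method="fdr_tsbky")[0]
        assert (res.rejected == sm).all()

    def test_random_vectors_match_transcription_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(150):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            if rng.random() < 0.3:  # inject ties and extremes
                p = np.round(p, 1)
            q = float(rng.uniform(0.01, 0.3))
            res = bky_fdr(p, q=q, adjusted=False)
            assert (res.rejected == bky_oracle(p, q)).all()
            sm = multipletests(p, alpha=q, method="fdr_tsbky")[0]
            assert (res.rejected == sm).all()

    def test_adjusted_values_consistent_with_rejection(self, rng):
        p = rng.uniform(size=15)
        q = 0.08
        res = bky_fdr(p, q=q)
        # adjusted must be monotone in p and reproduce the rejection set
        order = np.argsort(p)
        assert (np.diff(res.adjusted[order]) >= -1e-12).all()
        assert ((res.adjusted <= q) == res.rejected).all()

    def test_adaptivity_beats_plain_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        gains = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            p = np.concatenate([r.uniform(0, 0.01, 6), r.uniform(size=14)])
            q = 0.05
            res = bky_fdr(p, q=q, adjusted=False)
            bh = multipletests(p, alpha=q, method="fdr_bh")[0]
            if res.rejected.sum() > 0:
                assert res.rejected.sum() >= bh.sum()
                gains += int(res.rejected.sum() > bh.sum())
        assert gains > 0  # strictly adaptive somewhere

    def test_empty_input(self):
        assert len(bky_fdr([], q=0.05).rejected) == 0


class TestFisherPower:
    def test_reference_enumeration_value(self):
        assert fisher_power(20, 20, 0.1, 0.6, 0.05) == pytest.approx(
            0.9084711646502219, rel=1e-9
        )

    def test_matches_independent_scipy_oracle(self):
        # oracle built from scipy's fisher_exact and binomial pmfs
        n1, n2, p1, p2, alpha = 12, 15, 0.2, 0.7, 0.05
        power = 0.0
        for x1 in range(n1 + 1):
            for x2 in range(n2 + 1):
                p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])[1]
                if p <= alpha:
                    power += stats.binom.pmf(x1, n1, p1) * stats.binom.pmf(x2, n2, p2)
        assert fisher_power(n1, n2, p1, p2, alpha) == pytest.approx(power, rel=1e-9)

    def test_size_never_exceeds_alpha(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 30, 2)
            p0 = float(rng.uniform(0.05, 0.95))
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            assert fisher_power(int(n1), int(n2), p0, p0, alpha) <= alpha + 1e-12

    def test_monotone_in_effect_and_sample_size(self):
        grid = [fisher_power(25, 25, 0.3, 0.3 + d, 0.05) for d in (0.1, 0.25, 0.4)]
        assert grid == sorted(grid)
        sizes = [fisher_power(n, n, 0.2, 0.55, 0.05) for n in (10, 25, 45)]
        assert sizes == sorted(sizes)


class TestModelTables:
    def test_counting_oracle(self, rng):
        codes = rng.choice([0.0, 1.0, 2.0, np.nan], size=60, p=[0.4, 0.3, 0.2, 0.1])
        status = rng.choice(["IR_POS", "IR_NEG", "INDETERMINATE"], size=60)
        for model in ("recessive", "dominant"):
            mt = build_model_table(codes, status, model)
            keep = ~np.isnan(codes) & np.isin(status, ["IR_POS", "IR_NEG"])
            exp = (codes == 2) if model == "recessive" else (codes >= 1)
            a = int((keep & exp & (status == "IR_POS")).sum())
            b = int((keep & exp & (status == "IR_NEG")).sum())
            c = int((keep & ~exp & (status == "IR_POS")).sum())
            d = int((keep & ~exp & (status == "IR_NEG")).sum())
            assert mt.abcd == (a, b, c, d)
        add = build_model_table(codes, status, "additive")
        assert add.counts.sum() == (~np.isnan(codes)
                                    & np.isin(status, ["IR_POS", "IR_NEG"])).sum()

    def test_balanced_toy_is_symmetric(self):
        codes = np.array([0.0, 1.0, 2.0] * 10)
        status = np.array((["IR_POS"] * 3 + ["IR_NEG"] * 3) * 5)
        mt = build_model_table(codes, status, "additive")
        assert (mt.counts[0] == mt.counts[1]).all()

    def test_monomorphic_snp_flags_degenerate(self):
        codes = np.zeros(20)
        status = np.array(["IR_POS"] * 10 + ["IR_NEG"] * 10)
        mt = build_model_table(codes, status, "dominant")
        assert mt.degenerate
        r = fisher_or(*mt.abcd)
        assert np.isnan(r.or_hat)  # the published tables print NA here


class TestOrientation:
    def test_major_alleles_are_flipped(self):
        codes = pd.DataFrame(
            {"snpA": [2.0, 2.0, 1.0, 2.0], "snpB": [0.0, 1.0, 0.0, 0.0]},
            index=list("wxyz"),
        )
        t = GenotypeTable(codes, pd.Series("IR_POS", index=list("wxyz")))
        (flipped,), flags = orient_minor([t])
        assert flags["snpA"] and not flags["snpB"]
        assert (flipped.codes["snpA"] == 2.0 - codes["snpA"]).all()

    def test_orientation_decided_on_combined_sample(self):
        c1 = pd.DataFrame({"s": [2.0, 2.0]}, index=["a", "b"])   # freq 1.0
        c2 = pd.DataFrame({"s": [0.0, 0.0, 0.0]}, index=["c", "d", "e"])
        t1 = GenotypeTable(c1, pd.Series("IR_POS", index=c1.index))
        t2 = GenotypeTable(c2, pd.Series("IR_NEG", index=c2.index))
        (f1, f2), flags = orient_minor([t1, t2])
        assert not flags["s"]  # combined frequency 0.4 -> already minor


class TestTwoStage:
    def _cohort(self, rng, n=60, effect=False):
        f = {"snpA": 0.3, "snpB": 0.4, "snpC": 0.25, "snpD": 0.45}
        rows, status = [], {}
        for grp, shift in (("IR_POS", 0.25 if effect else 0.0), ("IR_NEG", 0.0)):
            for i in range(n):
                sid = f"{grp}_{i}_{rng.integers(1e9)}"
                rows.append(
                    {s: float(rng.binomial(2, min(f[s] + (shift if s == "snpA" else 0), 1)))
                     for s in f}
                )
                status[sid] = grp
        codes = pd.DataFrame(rows, index=list(status))
        return GenotypeTable(codes, pd.Series(status))

    def test_doubling_keeps_or_and_shrinks_p(self, rng):
        c1 = self._cohort(rng, effect=True)
        c2 = GenotypeTable(c1.codes.copy(), c1.status.copy())
        res = TwoStageValidation({"c1": c1, "c2": c2}).fit(compute_power=False)
        t = res.table.set_index(["batch", "snp_id", "model"])
        for (snp, model) in {(s, m) for (_, s, m) in t.index}:
            p1 = t.loc[("c1", snp, model), "p"]
            pm = t.loc[("merged", snp, model), "p"]
            assert pm <= p1 + 1e-12
            or1 = t.loc[("c1", snp, model), "or_hat"]
            orm = t.loc[("merged", snp, model), "or_hat"]
            if not (np.isnan(or1) or np.isnan(orm)):
                assert orm == pytest.approx(or1, rel=1e-9)

    def test_merged_detects_recessive_effect_more_often(self):
        """A true recessive effect among 4 SNPs: merged beats single cohorts."""
        merged_hits = c1_hits = c2_hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            f = {"snpA": 0.45, "snpB": 0.3, "snpC": 0.4, "snpD": 0.35}
            tables = {}
            for name in ("c1", "c2"):
                rows, status = [], {}
                for grp in ("IR_POS", "IR_NEG"):
                    for i in range(60):
                        sid = f"{name}_{grp}_{i}"
                        row = {}
                        for s, fr in f.items():
                            if s == "snpA" and grp == "IR_POS":
                                # recessive risk genotype enriched in cases
                                hom = fr**2 * 1.8
                                het = 2 * fr * (1 - fr)
                                probs = np.array([max(1 - hom - het, 0), het, hom])
                                probs = probs / probs.sum()
                                row[s] = float(r.choice([0, 1, 2], p=probs))
                            else:
                                row[s] = float(r.binomial(2, fr))
                        rows.append(row)
                        status[sid] = grp
                tables[name] = GenotypeTable(
                    pd.DataFrame(rows, index=list(status)), pd.Series(status)
                )
            res = TwoStageValidation(tables).fit(compute_power=False)
            t = res.table
            sel = (t["snp_id"] == "snpA") & (t["model"] == "recessive")
            sig = t[sel].set_index("batch")["significant"]
            merged_hits += int(sig.get("merged", False))
            c1_hits += int(sig.get("c1", False))
            c2_hits += int(sig.get("c2", False))
        assert merged_hits > c1_hits
        assert merged_hits > c2_hits

    def test_fixed_threshold_flags(self, rng):
        c1 = self._cohort(rng)
        res = TwoStageValidation({"c1": c1}).fit(
            significance_threshold=0.0239, compute_power=False
        )
        assert (res.table["significant"] == (res.table["p"] < 0.0239)).all()

    def test_missing_snp_in_one_cohort_is_flagged(self, rng):
        c1 = self._cohort(rng)
        c2 = self._cohort(rng)
        c2 = GenotypeTable(c2.codes.drop(columns=["snpD"]), c2.status)
        res = TwoStageValidation({"c1": c1, "c2": c2}).fit(compute_power=False)
        t = res.table
        assert not t[t["snp_id"] == "snpD"]["in_all_cohorts"].any()
        merged = t[t["batch"] == "merged"]
        assert "snpD" not in set(merged["snp_id"])
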