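"""Individual-genotype validation statistics for the two-stage design.

After the pooled scan nominates candidate SNPs, each candidate is
genotyped individually in the discovery cohort and in an independent
replication cohort.  Association is tested under three genetic models
(minor-allele orientation fixed on the combined sample):

* recessive — homozygous minor (code 2) vs the rest,
* dominant — minor-allele carrier (code >= 1) vs non-carrier,
* additive — Cochran-Armitage trend over genotype codes 0/1/2.

2x2 models use Fisher's exact test (two-sided, minimum-likelihood rule)
with the sample cross-product odds ratio and a Woolf logit confidence
interval; post-hoc power of the exact test is computed by full binomial
enumeration.  The per-batch family of model P-values is adjusted with
the adaptive two-stage Benjamini-Krieger-Yekutieli (BKY) FDR step-up.

The exact-test P-value is computed in exact integer arithmetic
(hypergeometric numerators compared as integers), which makes tie
handling unambiguous — float implementations must resolve near-ties by
tolerance and can disagree with enumeration on adversarial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, exp, log, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeTable",
    "ModelTable",
    "FisherResult",
    "BkyResult",
    "ValidationResults",
    "TwoStageValidation",
    "build_model_table",
    "fisher_exact_p",
    "fisher_or",
    "cochran_armitage",
    "bky_fdr",
    "fisher_power",
    "two_stage_report",
    "orient_minor",
    "read_genotype_tsv",
    "read_genotype_vcf",
]

MODELS = ("recessive", "dominant", "additive")


# ---------------------------------------------------------------------------
# elementary statistics


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for a 2x2 table, exact integer arithmetic.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed table's
    (the minimum-likelihood rule).  Probabilities are compared through
    their integer numerators, so ties are exact.  A table with a zero
    margin is deterministic and yields P = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n1, n2, k = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or k == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, k - n2), min(n1, k)
    nums = [comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)]
    observed = nums[a - lo]
    tail = sum(v for v in nums if v <= observed)
    return min(1.0, tail / comb(n1 + n2, k))


@dataclass(frozen=True)
class FisherResult:
    """Odds ratio, 95% CI and two-sided exact P for a 2x2 table."""

    or_hat: float
    ci_low: float
    ci_high: float
    p: float


def fisher_or(
    a: int, b: int, c: int, d: int,
    alpha: float = 0.05,
    or_style: str = "sample",
) -> FisherResult:
    """Fisher exact test with odds ratio and CI for a 2x2 table.

    ``or_style="sample"`` (default) is the cross-product ratio a*d/(b*c)
    with the Woolf logit interval exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d));
    ``or_style="conditional"`` is the conditional MLE with its exact
    interval (via scipy).  Any zero cell makes the sample OR and CI
    undefined (reported as NaN); the P-value is always computed.
    """
    p = fisher_exact_p(a, b, c, d)
    if or_style == "conditional":
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        return FisherResult(float(res.statistic), float(ci.low), float(ci.high), p)
    if or_style != "sample":
        raise ValueError(f"unknown or_style {or_style!r}")
    if min(a, b, c, d) == 0:
        return FisherResult(np.nan, np.nan, np.nan, p)
    or_hat = (a * d) / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return FisherResult(
        or_hat, exp(log(or_hat) - z * se), exp(log(or_hat) + z * se), p
    )


def cochran_armitage(counts, weights=(0.0, 1.0, 2.0)) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    Rows are the two groups, columns the genotype codes scored by
    ``weights``.  Returns (Z^2, P) with Z^2 referred to chi-square(1).
    The statistic is invariant to swapping the group rows and to any
    affine rescoring of the weights (in particular reversing 0/1/2 to
    2/1/0).  A table with no genotype variation carries no trend
    information and returns (0, 1).
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    w = np.asarray(weights, dtype=float)
    r1 = t[0].sum()
    col = t.sum(axis=0)
    num = n * (w * t[0]).sum() - r1 * (w * col).sum()
    den = r1 * (n - r1) * (n * (w**2 * col).sum() - ((w * col).sum()) ** 2)
    if den <= 0:
        return 0.0, 1.0
    z2 = num**2 / den * n
    return float(z2), float(stats.chi2.sf(z2, df=1))


@dataclass
class BkyResult:
    """Two-stage BKY FDR outcome."""

    rejected: np.ndarray        # boolean, original order
    m0_hat: int                 # estimated number of true nulls
    adjusted: np.ndarray        # smallest q at which each p is rejected
    threshold: float            # largest rejected p (NaN if none)


def _bh_reject_count(p_sorted: np.ndarray, level: float) -> int:
    m = len(p_sorted)
    ok = np.nonzero(p_sorted <= level * np.arange(1, m + 1) / m)[0]
    return 0 if ok.size == 0 else int(ok[-1]) + 1


def _bky_rejected(p: np.ndarray, q: float) -> tuple[np.ndarray, int]:
    m = len(p)
    qp = q / (1 + q)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    r1 = _bh_reject_count(ps, qp)
    rejected = np.zeros(m, dtype=bool)
    if r1 == 0:
        return rejected, m
    m0 = m - r1
    if m0 == 0:
        rejected[:] = True
        return rejected, 0
    r2 = _bh_reject_count(ps, qp * m / m0)
    rejected[order[:r2]] = True
    return rejected, m0


def bky_fdr(pvals, q: float = 0.05, adjusted: bool = True) -> BkyResult:
    """Adaptive two-stage Benjamini-Krieger-Yekutieli FDR step-up.

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q); with r1 rejections
    the null count is estimated as m0 = m - r1 and, if r1 > 0, stage 2
    re-runs BH at q' * m/m0.  ``adjusted`` values are the smallest
    nominal q at which each p enters the rejection set (found by
    bisection, then made monotone in p; capped at 1); pass
    ``adjusted=False`` to skip their computation (NaN) when only the
    rejection set is needed.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if len(p) == 0:
        return BkyResult(np.zeros(0, bool), 0, np.zeros(0), np.nan)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    rejected, m0 = _bky_rejected(p, q)
    threshold = float(p[rejected].max()) if rejected.any() else np.nan
    if not adjusted:
        return BkyResult(rejected, int(m0), np.full(len(p), np.nan), threshold)

    # smallest q at which each p is rejected; rejection grows with q
    lo = np.zeros(len(p))
    hi = np.ones(len(p))
    for _ in range(60):
        mid = (lo + hi) / 2
        for qq in np.unique(mid):
            rej_q, _ = _bky_rejected(p, min(qq, 1 - 1e-12))
            sel = mid == qq
            lo[sel & ~rej_q] = qq
            hi[sel & rej_q] = qq
    adj = hi.copy()
    never = ~_bky_rejected(p, 1 - 1e-9)[0]
    adj[never] = 1.0
    order = np.argsort(p, kind="stable")
    adj[order] = np.maximum.accumulate(adj[order])
    return BkyResult(rejected, int(m0), adj, threshold)


def fisher_power(
    n1: int, n2: int, p1: float, p2: float, alpha: float = 0.05
) -> float:
    """Exact unconditional power of the two-sided Fisher test.

    Enumerates every outcome (x1, x2) of two independent binomials
    Binom(n1, p1), Binom(n2, p2) and sums the probability of those whose
    two-sided exact P does not exceed ``alpha``.  With p1 = p2 this is
    the attained size of the test, which never exceeds alpha.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pm1 = stats.binom.pmf(np.arange(n1 + 1), n1, p1)
    pm2 = stats.binom.pmf(np.arange(n2 + 1), n2, p2)
    power = 0.0
    # group outcomes by their exposure margin k = x1 + x2 so hypergeometric
    # numerators are computed once per margin; a sorted prefix sum gives the
    # minimum-likelihood tail of every outcome on that margin at once
    from bisect import bisect_right

    for k in range(n1 + n2 + 1):
        lo, hi = max(0, k - n2), min(n1, k)
        nums = [comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)]
        denom = comb(n1 + n2, k)
        srt = sorted(nums)
        prefix = [0]
        for v in srt:
            prefix.append(prefix[-1] + v)
        for x1 in range(lo, hi + 1):
            tail = prefix[bisect_right(srt, nums[x1 - lo])]
            if tail / denom <= alpha:
                power += float(pm1[x1] * pm2[k - x1])
    return min(power, 1.0)


# ---------------------------------------------------------------------------
# genotype containers


@dataclass
class GenotypeTable:
    """Subjects x SNPs minor-allele dosage codes with IR status.

    ``codes`` holds 0/1/2 (float, NaN = missing); ``status`` maps subject
    id to IR_POS / IR_NEG / INDETERMINATE.  Indeterminate subjects are
    carried but excluded from every test.
    """

    codes: pd.DataFrame
    status: pd.Series
    snps: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.status = self.status.reindex(self.codes.index)
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.codes.columns)

    def allele_freq(self) -> pd.Series:
        """Frequency of the counted allele per SNP (pairwise non-missing)."""
        return self.codes.mean(axis=0, skipna=True) / 2.0

    def flipped(self, snp_ids: Sequence[str]) -> "GenotypeTable":
        codes = self.codes.copy()
        cols = [s for s in snp_ids if s in codes.columns]
        codes[cols] = 2.0 - codes[cols]
        return GenotypeTable(codes, self.status, self.snps)


def orient_minor(
    tables: Sequence[GenotypeTable],
) -> tuple[list[GenotypeTable], pd.Series]:
    """Flip SNPs so the counted allele is the minor one in the combined sample.

    The orientation is decided once on the concatenation of all cohorts
    (frequency <= 0.5) so model definitions stay identical across
    cohorts.  Returns the re-oriented tables and a boolean Series of
    flipped SNPs.
    """
    combined = pd.concat([t.codes for t in tables], axis=0, ignore_index=True)
    freq = combined.mean(axis=0, skipna=True) / 2.0
    flip = freq > 0.5
    flipped_ids = list(flip.index[flip])
    return [t.flipped(flipped_ids) for t in tables], flip


def read_genotype_tsv(path, status: pd.Series | None = None) -> GenotypeTable:
    """Read a subjects x SNPs table of 0/1/2 codes (first column: subject id).

    Missing entries may be empty or 'NA'.  ``status`` (subject -> IR
    label) can be joined afterwards if not supplied.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    status = status if status is not None else pd.Series(index=df.index, dtype=object)
    return GenotypeTable(df.astype(float), status)


def read_genotype_vcf(path, status: pd.Series | None = None) -> GenotypeTable:
    """Read diploid genotypes from a VCF (GT field; unphased accepted).

    Codes count copies of the ALT allele; orientation to the minor
    allele is applied later via :func:`orient_minor`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        g = var.gt_types.astype(float)
        g[g == 2] = np.nan
        g[g == 3] = 2.0
        cols.append(g)
    codes = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)),
                         index=samples, columns=ids)
    status = status if status is not None else pd.Series(index=codes.index, dtype=object)
    return GenotypeTable(codes, status)


@dataclass
class ModelTable:
    """Contingency table for one SNP under one genetic model.

    For recessive/dominant: 2x2 with rows (exposed, unexposed) and
    columns (IR_POS, IR_NEG); ``a, b, c, d`` unpack row-wise.  For
    additive: 2x3 genotype counts with rows (IR_POS, IR_NEG).  A 2x2
    table with an empty exposure (or non-exposure) row is degenerate —
    its odds ratio is undefined and reported NA.
    """

    model: str
    counts: np.ndarray
    degenerate: bool = field(default=False)

    @property
    def abcd(self) -> tuple[int, int, int, int]:
        if self.counts.shape != (2, 2):
            raise ValueError("abcd is defined for 2x2 models only")
        return tuple(int(x) for x in self.counts.ravel())


def build_model_table(codes, status, model: str) -> ModelTable:
    """Contingency table from one SNP's codes and the IR labels.

    Missing codes and indeterminate subjects are dropped pairwise.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    g = np.asarray(codes, dtype=float)
    lab = np.asarray(status, dtype=object)
    keep = ~np.isnan(g) & np.isin(lab, ("IR_POS", "IR_NEG"))
    g, lab = g[keep], lab[keep]
    case, ctrl = lab == "IR_POS", lab == "IR_NEG"
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("need at least one subject per group")
    if model == "additive":
        counts = np.array(
            [[int(((g == c) & grp).sum()) for c in (0, 1, 2)] for grp in (case, ctrl)]
        )
        return ModelTable(model, counts)
    exposed = g == 2 if model == "recessive" else g >= 1
    counts = np.array(
        [
            [int((exposed & case).sum()), int((exposed & ctrl).sum())],
            [int((~exposed & case).sum()), int((~exposed & ctrl).sum())],
        ]
    )
    degenerate = counts[0].sum() == 0 or counts[1].sum() == 0
    return ModelTable(model, counts, degenerate)


# ---------------------------------------------------------------------------
# two-stage validation model


class TwoStageValidation:
    """Association testing of candidate SNPs across cohorts plus merged.

    Parameters
    ----------
    cohorts
        Ordered mapping of cohort name -> :class:`GenotypeTable`.  Minor
        allele orientation is fixed on the concatenated cohorts at
        construction.
    """

    def __init__(self, cohorts: Mapping[str, GenotypeTable]) -> None:
        if not cohorts:
            raise ValueError("need at least one cohort")
        names = list(cohorts)
        oriented, self.flipped = orient_minor([cohorts[n] for n in names])
        self.cohorts: dict[str, GenotypeTable] = dict(zip(names, oriented))

    def _merged(self) -> GenotypeTable:
        frames, statuses = [], []
        common = None
        for name, t in self.cohorts.items():
            common = set(t.snp_ids) if common is None else common & set(t.snp_ids)
        common = sorted(common)
        for name, t in self.cohorts.items():
            c = t.codes[common].copy()
            c.index = [f"{name}:{i}" for i in c.index]
            s = t.status.copy()
            s.index = c.index
            frames.append(c)
            statuses.append(s)
        return GenotypeTable(pd.concat(frames), pd.concat(statuses))

    def fit(
        self,
        q: float = 0.05,
        alpha: float = 0.05,
        models: Sequence[str] = MODELS,
        significance_threshold: float | None = None,
        merged_label: str = "merged",
        compute_power: bool = True,
    ) -> "ValidationResults":
        """Run all models per SNP per cohort and on the merged cohorts.

        The BKY adjustment is applied to the combined set of model
        P-values *within each analysis batch* (each cohort, and the
        merged analysis, separately).  ``significant`` flags use the
        threshold the procedure derives for the batch, unless an explicit
        ``significance_threshold`` overrides it.
        """
        batches: dict[str, GenotypeTable] = dict(self.cohorts)
        if len(self.cohorts) > 1:
            batches[merged_label] = self._merged()
        all_ids = sorted({s for t in self.cohorts.values() for s in t.snp_ids})
        in_all = {
            s: all(s in t.snp_ids for t in self.cohorts.values()) for s in all_ids
        }

        rows = []
        for batch, table in batches.items():
            lab = table.status
            for snp in table.snp_ids:
                codes = table.codes[snp]
                for model in models:
                    mt = build_model_table(codes, lab, model)
                    row = {
                        "batch": batch,
                        "snp_id": snp,
                        "model": model,
                        "in_all_cohorts": in_all.get(snp, True),
                        "degenerate": mt.degenerate,
                    }
                    if model == "additive":
                        z2, p = cochran_armitage(mt.counts)
                        row.update(
                            {f"case{j}": mt.counts[0, j] for j in range(3)}
                            | {f"ctrl{j}": mt.counts[1, j] for j in range(3)}
                        )
                        row.update(or_hat=np.nan, ci_low=np.nan, ci_high=np.nan, p=p)
                        if compute_power:
                            # post-hoc power of the trend test: observed
                            # statistic as the non-centrality of the 1-df
                            # chi-square
                            crit = stats.chi2.ppf(1 - alpha, 1)
                            row["power"] = (
                                float(stats.ncx2.sf(crit, 1, z2)) if z2 > 0 else alpha
                            )
                        else:
                            row["power"] = np.nan
                    else:
                        a, b, c, d = mt.abcd
                        fr = fisher_or(a, b, c, d, alpha=alpha)
                        row.update(a=a, b=b, c=c, d=d,
                                   or_hat=fr.or_hat, ci_low=fr.ci_low,
                                   ci_high=fr.ci_high, p=fr.p)
                        n1, n2 = a + c, b + d
                        row["power"] = (
                            fisher_power(n1, n2, a / n1, b / n2, alpha)
                            if compute_power
                            else np.nan
                        )
                    rows.append(row)
        df = pd.DataFrame(rows)

        df["q"] = np.nan
        df["significant"] = False
        thresholds = {}
        for batch in batches:
            sel = df["batch"] == batch
            res = bky_fdr(df.loc[sel, "p"].to_numpy(), q=q)
            df.loc[sel, "q"] = res.adjusted
            thresholds[batch] = res.threshold
            if significance_threshold is not None:
                df.loc[sel, "significant"] = df.loc[sel, "p"] < significance_threshold
            else:
                df.loc[sel, "significant"] = res.rejected
        return ValidationResults(
            table=df, q=q, thresholds=thresholds,
            significance_threshold=significance_threshold,
        )


@dataclass
class ValidationResults:
    """Per-batch association results; one row per (batch, SNP, model)."""

    table: pd.DataFrame
    q: float
    thresholds: dict[str, float]
    significance_threshold: float | None = None

    def batch(self, name: str) -> pd.DataFrame:
        return self.table[self.table["batch"] == name].reset_index(drop=True)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Two-stage genotype validation", "============================="]
        if self.significance_threshold is not None:
            lines.append(f"Significance: P < {self.significance_threshold} (fixed)")
        else:
            lines.append(f"Significance: BKY two-stage FDR at q = {self.q}")
        for batch in self.table["batch"].unique():
            sub = self.batch(batch)
            lines.append(f"\n[{batch}]")
            for _, r in sub.iterrows():
                orr = "NA" if np.isnan(r["or_hat"]) else f"{r['or_hat']:.3f}"
                ci = (
                    "NA"
                    if np.isnan(r["ci_low"])
                    else f"{r['ci_low']:.3f}-{r['ci_high']:.3f}"
                )
                star = " *" if r["significant"] else ""
                lines.append(
                    f"  {r['snp_id']:<12} {r['model']:<9} OR={orr:<8} "
                    f"95%CI={ci:<15} P={r['p']:.4f}  q={r['q']:.4f}  "
                    f"power={r['power']:.2f}{star}"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def two_stage_report(
    cohorts: Mapping[str, GenotypeTable],
    q: float = 0.05,
    **fit_kwargs,
) -> ValidationResults:
    """Convenience wrapper: orient, test per cohort and merged, adjust."""
    return TwoStageValidation(cohorts).fit(q=q, **fit_kwargs)
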