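"""Pooled case-control association scan with a two-component variance model.

For each SNP the scan compares the replicate-mean pooling allele
frequencies of the case and control pools.  The variance of the observed
difference has two parts:

* **sampling variance V** — the binomial variance of an allele-frequency
  estimate over the finite number of chromosomes in each pool,
  ``p_t(1-p_t)/(2 n_t) + p_c(1-p_c)/(2 n_c)`` for ``n`` individuals per
  pool;
* **replicate (pooling) variance** — the variance attributable to pool
  construction and array measurement, estimated from the technical
  replicates as ``s2_t/k_t + s2_c/k_c`` (unbiased replicate variance over
  a group's k replicate arrays, scaled to the variance of the replicate
  mean).

The test statistic ``chi2 = (pbar_t - pbar_c)^2 / (V + replicate
variance)`` is referred to a 1-df chi-square.  SNPs are then ranked by
increasing P-value, a mean rank over a sliding window of ``w``
genomically consecutive SNPs (default 10) is taken, normalised by the
number of tested SNPs and -log10 transformed into a window score; the
top-``k`` SNPs by window score are the discovery candidates.  The window
statistic deliberately rewards *regions* of consistently low ranks, the
footprint an associated locus leaves through local LD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pooled_array import PafMatrix

__all__ = [
    "sampling_variance",
    "replicate_variance",
    "rank_snps",
    "sliding_window",
    "select_top",
    "chi2_scan",
    "PooledScan",
    "PooledScanResults",
]

DEFAULT_WINDOW = 10
DEFAULT_TOP_K = 5


def sampling_variance(paf_t, paf_c, n_t: int, n_c: int):
    """Binomial sampling variance V of the case-control PAF difference.

    Each pool of n individuals carries 2n chromosomes, so the sampling
    variance of its allele-frequency estimate is p(1-p)/(2n); the two
    pools are independent.
    """
    if n_t < 1 or n_c < 1:
        raise ValueError("pool sizes must be >= 1")
    pt = np.asarray(paf_t, dtype=float)
    pc = np.asarray(paf_c, dtype=float)
    if np.any((pt < 0) | (pt > 1) | (pc < 0) | (pc > 1)):
        raise ValueError("PAF values must lie in [0, 1]")
    v = pt * (1 - pt) / (2 * n_t) + pc * (1 - pc) / (2 * n_c)
    return v if v.ndim else float(v)


def replicate_variance(case_reps, control_reps):
    """Variance of the difference of replicate-mean PAFs.

    s2_t/k_t + s2_c/k_c with s2 the unbiased sample variance across a
    group's technical replicates and k its replicate count.  This jointly
    captures pool-construction error and array error — the components the
    replicate design can identify.
    """
    ct = np.atleast_2d(np.asarray(case_reps, dtype=float))
    cc = np.atleast_2d(np.asarray(control_reps, dtype=float))
    if ct.shape[-1] < 2 or cc.shape[-1] < 2:
        raise ValueError("need at least 2 replicates per group")
    v = ct.var(axis=-1, ddof=1) / ct.shape[-1] + cc.var(axis=-1, ddof=1) / cc.shape[-1]
    v = np.squeeze(v)
    return v if v.ndim else float(v)


def rank_snps(p, order_index):
    """Ranks 1..M by increasing P-value; ties broken by genome order."""
    p = np.asarray(p, dtype=float)
    order_index = np.asarray(order_index)
    if np.any(np.isnan(p)):
        raise ValueError("all retained SNPs must have a P-value")
    perm = np.lexsort((order_index, p))
    ranks = np.empty(len(p), dtype=int)
    ranks[perm] = np.arange(1, len(p) + 1)
    return ranks


def sliding_window(ranks, chroms, w: int = DEFAULT_WINDOW, m_total: int | None = None):
    """Mean rank over a window of w consecutive SNPs, per chromosome.

    The window is centred with ceil((w-1)/2) SNPs to the left and the
    remainder to the right, shrinking at chromosome ends.  Returns
    (window_mean_rank, window_score) with
    score = -log10(window_mean_rank / M).

    ``ranks``/``chroms`` must already be in genome order.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    ranks = np.asarray(ranks, dtype=float)
    chroms = np.asarray(chroms)
    m = m_total if m_total is not None else len(ranks)
    left = math.ceil((w - 1) / 2)
    right = w - 1 - left
    means = np.empty(len(ranks))
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        r = ranks[idx]
        csum = np.concatenate(([0.0], np.cumsum(r)))
        n = len(r)
        starts = np.maximum(np.arange(n) - left, 0)
        stops = np.minimum(np.arange(n) + right + 1, n)
        means[idx] = (csum[stops] - csum[starts]) / (stops - starts)
    scores = -np.log10(means / m)
    return means, scores


def select_top(table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Top-k SNPs by window score; ties broken by genome order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        import warnings

        warnings.warn(f"k={k} exceeds {len(table)} SNPs; returning all")
        k = len(table)
    ordered = table.sort_values(
        ["window_score", "order_index"], ascending=[False, True], kind="stable"
    )
    return ordered.head(k)


def chi2_scan(
    matrix: PafMatrix,
    n_cases: int,
    n_controls: int,
    *,
    window: int = DEFAULT_WINDOW,
    case_group: str = "IR_POS",
    control_group: str = "IR_NEG",
) -> pd.DataFrame:
    """Per-SNP scan table in genome order (see :class:`PooledScan`)."""
    model = PooledScan(
        matrix, n_cases, n_controls,
        case_group=case_group, control_group=control_group,
    )
    return model.fit(window=window).table


class PooledScan:
    """Model object for the pooled-DNA association scan.

    Parameters
    ----------
    matrix
        Calibrated (and normally bead-filtered) :class:`PafMatrix`.
    n_cases, n_controls
        Number of individuals constituting the case and control pools
        (98 and 100 in the reference design).
    case_group, control_group
        Group labels in ``matrix.groups``.
    """

    def __init__(
        self,
        matrix: PafMatrix,
        n_cases: int,
        n_controls: int,
        *,
        case_group: str = "IR_POS",
        control_group: str = "IR_NEG",
    ) -> None:
        self.matrix = matrix
        self.n_cases = int(n_cases)
        self.n_controls = int(n_controls)
        self.case_samples = matrix.samples_of(case_group)
        self.control_samples = matrix.samples_of(control_group)
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise ValueError("need >= 2 replicates per group")

    def fit(self, window: int = DEFAULT_WINDOW) -> "PooledScanResults":
        """Run the scan and return results in genome order."""
        m = self.matrix
        snps = m.snps.sort_values("order_index")
        case = m.paf.loc[snps.index, self.case_samples].to_numpy()
        ctrl = m.paf.loc[snps.index, self.control_samples].to_numpy()
        pt, pc = case.mean(axis=1), ctrl.mean(axis=1)
        v_samp = sampling_variance(
            np.clip(pt, 0, 1), np.clip(pc, 0, 1), self.n_cases, self.n_controls
        )
        v_rep = np.atleast_1d(replicate_variance(case, ctrl))
        denom = v_samp + v_rep
        diff2 = (pt - pc) ** 2

        unstable = (denom == 0) & (diff2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(denom > 0, diff2 / denom, 0.0)
        p = stats.chi2.sf(chi2, df=1)
        p[denom == 0] = 1.0
        p[unstable] = np.nan

        table = pd.DataFrame(
            {
                "snp_id": snps.index,
                "chrom": snps["chrom"].to_numpy(),
                "pos": snps["pos"].to_numpy(),
                "order_index": snps["order_index"].to_numpy(),
                "paf_case": pt,
                "paf_control": pc,
                "v_sampling": v_samp,
                "v_replicate": v_rep,
                "chi2": chi2,
                "p": p,
            }
        )
        stable = table[~unstable].copy()
        stable["rank"] = rank_snps(stable["p"], stable["order_index"])
        wm, ws = sliding_window(
            stable["rank"].to_numpy(), stable["chrom"].to_numpy(), window
        )
        stable["window_mean_rank"] = wm
        stable["window_score"] = ws
        return PooledScanResults(
            model=self,
            table=stable.reset_index(drop=True),
            unstable=table[unstable].reset_index(drop=True),
            window=window,
        )


@dataclass
class PooledScanResults:
    """Results of :meth:`PooledScan.fit`.

    ``table`` holds one row per tested SNP in genome order with variance
    components, chi-square, P, rank, window mean rank and window score.
    SNPs with a zero variance estimate but non-zero frequency difference
    are segregated into ``unstable`` (P missing) and never ranked.
    """

    model: PooledScan
    table: pd.DataFrame
    unstable: pd.DataFrame
    window: int

    @property
    def m(self) -> int:
        """Number of tested (ranked) SNPs."""
        return len(self.table)

    def top(self, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
        """Top-k candidates by window score."""
        return select_top(self.table, k)

    def pairwise_diagnostics(self) -> pd.DataFrame:
        """Per-SNP chi-square for every case x control replicate pair.

        Mirrors the supplementary "nine comparisons" view of a 3x3
        replicate design: each single-replicate difference is tested
        against V (from the pair's own PAFs) plus the single-replicate
        pooling variance s2_t + s2_c.  Diagnostic only — the headline
        scan uses one test per SNP from replicate means.
        """
        mdl = self.model
        m = mdl.matrix
        snps = m.snps.sort_values("order_index")
        case = m.paf.loc[snps.index, mdl.case_samples].to_numpy()
        ctrl = m.paf.loc[snps.index, mdl.control_samples].to_numpy()
        s2t = case.var(axis=1, ddof=1)
        s2c = ctrl.var(axis=1, ddof=1)
        rows = []
        for i, cs in enumerate(mdl.case_samples):
            for j, xs in enumerate(mdl.control_samples):
                pt, pc = case[:, i], ctrl[:, j]
                v = sampling_variance(
                    np.clip(pt, 0, 1), np.clip(pc, 0, 1),
                    mdl.n_cases, mdl.n_controls,
                ) + s2t + s2c
                with np.errstate(divide="ignore", invalid="ignore"):
                    chi2 = np.where(v > 0, (pt - pc) ** 2 / v, 0.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "snp_id": snps.index,
                            "pair": f"{cs}|{xs}",
                            "chi2": chi2,
                            "p": stats.chi2.sf(chi2, df=1),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def summary(self, k: int = DEFAULT_TOP_K) -> str:
        """Human-readable scan summary with the top-k candidate list."""
        lines = [
            "Pooled-DNA association scan",
            "===========================",
            f"SNPs tested:        {self.m}",
            f"Pool sizes:         {self.model.n_cases} cases / "
            f"{self.model.n_controls} controls",
            f"Replicates:         {len(self.model.case_samples)} case / "
            f"{len(self.model.control_samples)} control",
            f"Window size:        {self.window}",
            f"Unstable SNPs:      {len(self.unstable)}",
            "",
            f"Top {min(k, self.m)} candidates by window score:",
        ]
        top = self.top(k)
        for _, r in top.iterrows():
            lines.append(
                f"  {r['snp_id']:<14} {r['chrom']}:{int(r['pos']):<10} "
                f"chi2={r['chi2']:8.3f}  P={r['p']:.3e}  rank={int(r['rank']):>5} "
                f"window_score={r['window_score']:.3f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = [
            "snp_id", "chrom", "pos", "paf_case", "paf_control",
            "v_sampling", "v_replicate", "chi2", "p", "rank",
            "window_mean_rank", "window_score",
        ]
        self.table[cols].to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        """4-column window-score track (chrom, pos-1, pos, score)."""
        bg = pd.DataFrame(
            {
                "chrom": self.table["chrom"],
                "start": self.table["pos"].astype(int) - 1,
                "end": self.table["pos"].astype(int),
                "score": self.table["window_score"],
            }
        )
        bg.to_csv(path, sep="\t", index=False, header=False)
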