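"""Calibration of two-channel pooled-array intensities into allele frequencies.

A pooled-DNA array experiment hybridises a DNA pool (here: ~100 subjects
per case/control group, three technical replicates each) to a two-channel
SNP bead array.  The red/green intensity ratio of a SNP estimates the
pool's B-allele frequency, but the two dyes are not on a common scale:
the red/green gain systematically differs between arrays and between the
physical strips of one array.  Calibration therefore rescales the red
channel per (strip, sample) so that the mean pooling allele frequency
(PAF) over the strip's SNPs equals 0.5, after which

    PAF = k * red / (k * red + green).

SNPs whose intensity is supported by fewer than four beads in any sample
are unreliable and are removed (``filter_beads``), and a PCA of the
calibrated PAF matrix checks that technical replicates cluster by group
(``PafMatrix.pca_qc``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.decomposition import PCA

__all__ = [
    "CalibrationError",
    "PafMatrix",
    "BeadFilterReport",
    "PcaQC",
    "calibrate_strip",
    "compute_paf",
    "filter_beads",
    "pca_qc",
    "read_intensity_tsv",
    "write_intensity_tsv",
    "genome_order",
]

#: required columns of the long intensity table
INTENSITY_COLUMNS = [
    "snp_id", "chrom", "pos", "strip", "sample_id", "group",
    "red", "green", "beads",
]

#: minimum beads supporting a SNP in every sample
DEFAULT_MIN_BEADS = 4


class CalibrationError(ValueError):
    """No red-channel scale can reach the mean-PAF 0.5 target."""


def _chrom_key(chrom: str) -> tuple[int, float, str]:
    """Natural chromosome sort key: 1..22 numerically, then X, Y, MT, rest."""
    c = re.sub(r"^chr", "", str(chrom), flags=re.IGNORECASE)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def genome_order(snps: pd.DataFrame) -> pd.Series:
    """0-based genome sort order over (chromosome natural order, position)."""
    key = snps.apply(lambda r: (_chrom_key(r["chrom"]), int(r["pos"])), axis=1)
    order = np.empty(len(snps), dtype=int)
    order[np.argsort(key.to_numpy(), kind="stable")] = np.arange(len(snps))
    return pd.Series(order, index=snps.index, name="order_index")


def calibrate_strip(red, green, *, tol: float = 1e-12) -> float:
    """Red-channel scale factor k for one (strip, sample).

    Finds the k > 0 with mean over the strip's SNPs of
    k*R/(k*R + G) = 0.5.  The mean is strictly increasing in k wherever
    it is not constant, so a bracketing root search is exact; the root is
    refined to machine precision.

    Raises
    ------
    CalibrationError
        If no k in (0, inf) reaches the target (e.g. all-red or
        all-green strips).
    """
    r = np.asarray(red, dtype=float)
    g = np.asarray(green, dtype=float)
    use = (r + g) > 0
    if not np.any((r > 0) & (g > 0)):
        raise CalibrationError("no SNP with both channels positive on strip")
    r, g = r[use], g[use]

    def mean_paf(k: float) -> float:
        return float(np.mean(k * r / (k * r + g))) - 0.5

    lo, hi = 1e-12, 1e12
    if mean_paf(lo) > 0 or mean_paf(hi) < 0:
        raise CalibrationError("mean PAF target 0.5 unreachable on strip")
    return float(brentq(mean_paf, lo, hi, xtol=tol, rtol=8.9e-16))


def compute_paf(red, green, k: float):
    """PAF = k*R / (k*R + G); zero total intensity yields NaN (missing)."""
    if not k > 0:
        raise ValueError("scale factor k must be positive")
    r = np.asarray(red, dtype=float)
    g = np.asarray(green, dtype=float)
    denom = k * r + g
    with np.errstate(invalid="ignore", divide="ignore"):
        paf = np.where(denom > 0, k * r / denom, np.nan)
    return paf if paf.ndim else float(paf)


@dataclass
class BeadFilterReport:
    """Outcome of the minimum-bead-count filter."""

    dropped: pd.DataFrame  # snp_id, reason, min_beads
    n_before: int
    n_dropped: int

    @property
    def fraction_dropped(self) -> float:
        return self.n_dropped / self.n_before if self.n_before else 0.0


@dataclass
class PcaQC:
    """Replicate-clustering QC of the PAF matrix."""

    coords: pd.DataFrame            # samples x components
    explained_variance_ratio: np.ndarray
    max_within: float
    min_between: float
    passed: bool

    @property
    def verdict(self) -> str:
        return "PASS" if self.passed else "FAIL"


@dataclass
class PafMatrix:
    """Calibrated pooling allele frequencies: SNPs x pool replicates.

    Attributes
    ----------
    snps : DataFrame indexed by snp_id with chrom, pos, strip, order_index.
    paf : DataFrame (snp_id x sample_id) of frequencies in [0, 1].
    beads : DataFrame of supporting bead counts, same shape as ``paf``.
    groups : Series mapping sample_id -> group label (IR_POS / IR_NEG).
    strip_scale : DataFrame (strip x sample_id) of calibration factors k.
    exclusions : SNPs removed before the matrix was formed (missing PAF).
    """

    snps: pd.DataFrame
    paf: pd.DataFrame
    beads: pd.DataFrame
    groups: pd.Series
    strip_scale: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    @classmethod
    def from_intensities(cls, records: pd.DataFrame) -> "PafMatrix":
        """Calibrate per (strip, sample) and assemble the PAF matrix.

        A SNP whose PAF is missing in any replicate (zero total
        intensity) is excluded so the replicate arithmetic of the scan
        stays balanced; exclusions are reported with reason ``missing``.
        """
        missing_cols = [c for c in INTENSITY_COLUMNS if c not in records.columns]
        if missing_cols:
            raise ValueError(f"intensity table missing columns: {missing_cols}")
        df = records.copy()
        df["paf"] = np.nan
        scales = {}
        for (strip, sample), idx in df.groupby(["strip", "sample_id"]).groups.items():
            sub = df.loc[idx]
            k = calibrate_strip(sub["red"].to_numpy(), sub["green"].to_numpy())
            scales[(strip, sample)] = k
            df.loc[idx, "paf"] = compute_paf(
                sub["red"].to_numpy(), sub["green"].to_numpy(), k
            )
        snps = (
            df[["snp_id", "chrom", "pos", "strip"]]
            .drop_duplicates("snp_id")
            .set_index("snp_id")
        )
        snps["order_index"] = genome_order(snps)
        snps = snps.sort_values("order_index")

        paf = df.pivot_table(index="snp_id", columns="sample_id", values="paf",
                             dropna=False).reindex(snps.index)
        beads = df.pivot_table(index="snp_id", columns="sample_id",
                               values="beads", dropna=False).reindex(snps.index)
        groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
        groups = groups.reindex(paf.columns)

        bad = paf.isna().any(axis=1)
        exclusions = pd.DataFrame(
            {"snp_id": paf.index[bad], "reason": "missing"}
        )
        strip_scale = (
            pd.Series(scales).rename_axis(["strip", "sample_id"]).unstack()
        )
        return cls(
            snps=snps.loc[~bad.to_numpy()],
            paf=paf.loc[~bad.to_numpy()],
            beads=beads.loc[~bad.to_numpy()],
            groups=groups,
            strip_scale=strip_scale,
            exclusions=exclusions,
        )

    # -- convenience -------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.paf.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.paf.columns)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    # -- QC ----------------------------------------------------------------

    def filter_beads(
        self, min_beads: int = DEFAULT_MIN_BEADS
    ) -> tuple["PafMatrix", BeadFilterReport]:
        """Drop SNPs supported by fewer than ``min_beads`` beads in any sample.

        Surviving PAF values are untouched; only membership changes.
        """
        worst = self.beads.min(axis=1)
        drop = worst < min_beads
        report = BeadFilterReport(
            dropped=pd.DataFrame(
                {
                    "snp_id": self.paf.index[drop],
                    "reason": "low_beads",
                    "min_beads": worst[drop].astype(int),
                }
            ).reset_index(drop=True),
            n_before=self.n_snps,
            n_dropped=int(drop.sum()),
        )
        keep = ~drop.to_numpy()
        filtered = PafMatrix(
            snps=self.snps.loc[keep],
            paf=self.paf.loc[keep],
            beads=self.beads.loc[keep],
            groups=self.groups,
            strip_scale=self.strip_scale,
            exclusions=self.exclusions,
        )
        return filtered, report

    def pca_qc(self, n_components: int = 2) -> PcaQC:
        """PCA of per-SNP-centred PAF columns; replicates must cluster.

        The verdict is PASS when, in the first two components, the
        largest within-group pairwise distance is smaller than the
        smallest between-group pairwise distance.
        """
        if self.paf.shape[1] < 2 or self.n_snps < 2:
            raise ValueError("PCA QC needs at least 2 samples and 2 SNPs")
        X = self.paf.to_numpy().T  # samples x snps; PCA centres per SNP
        n_components = min(n_components, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_components)
        coords = pca.fit_transform(X)
        coords_df = pd.DataFrame(
            coords,
            index=self.paf.columns,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        )
        two = coords[:, : min(2, coords.shape[1])]
        labels = self.groups.reindex(self.paf.columns).to_numpy()
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                d = float(np.linalg.norm(two[i] - two[j]))
                (within if labels[i] == labels[j] else between).append(d)
        max_within = max(within) if within else 0.0
        min_between = min(between) if between else np.inf
        return PcaQC(
            coords=coords_df,
            explained_variance_ratio=pca.explained_variance_ratio_,
            max_within=max_within,
            min_between=min_between,
            passed=max_within < min_between,
        )

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """SNP metadata columns followed by one PAF column per sample."""
        out = self.snps.join(self.paf)
        out.to_csv(path, sep="\t", index_label="snp_id")


def filter_beads(matrix: PafMatrix, min_beads: int = DEFAULT_MIN_BEADS):
    """Functional alias of :meth:`PafMatrix.filter_beads`."""
    return matrix.filter_beads(min_beads)


def pca_qc(matrix: PafMatrix, n_components: int = 2) -> PcaQC:
    """Functional alias of :meth:`PafMatrix.pca_qc`."""
    return matrix.pca_qc(n_components)


def read_intensity_tsv(path) -> pd.DataFrame:
    """Read the long intensity table (gzip-transparent, header required)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "strip": str, "sample_id": str}
    )
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity TSV missing columns: {missing}")
    return df


def write_intensity_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
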