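"""Synthetic cohorts, genotypes, pools and bead intensities with ground truth.

The generator emulates the statistical structure the pooled-GWAS analysis
assumes, end to end:

* two matched groups of ~100 obese subjects each, classified IR+/IR- from
  OGTT-derived indices (phenotypes are generated *backwards* from target
  HOMA-IR / WBISI values on a latent sensitivity scale, so the
  classification rules reproduce the generator's labels exactly);
* Hardy-Weinberg genotypes, with a handful of effect loci whose allele
  frequencies differ between groups by a configurable delta_f.  Each
  effect is a contiguous *region* of ``effect_region_size`` consecutive
  SNPs sharing the shift, centred on the named effect SNP — the regional
  footprint an associated locus leaves through local LD, which is what
  the sliding-window prioritisation is built to detect (between-SNP
  genotype correlation itself is not modelled);
* DNA pools per group: the pool's base frequency is the group's sample
  allele frequency; each technical replicate adds Gaussian
  pool-construction error on the frequency scale;
* two-channel bead-array intensities with per-strip red/green gain bias
  (corrected later by calibration), multiplicative channel noise, and
  Poisson-like bead counts with a controllable fraction of low-bead SNPs
  that the bead filter removes.

Every simulated observable is traceable to a recorded generating value
(:class:`GroundTruth`).  All functions are pure in (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype import (
    GLUCOSE_MGDL_PER_MMOL,
    INSULIN_PMOL_PER_UU,
    OgttCurve,
    Subject,
)
from .validation_stats import GenotypeTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "GenerationError",
    "simulate_genotypes",
    "simulate_cohort",
    "build_pools",
    "simulate_array",
    "simulate_study",
    "write_genotype_tsv",
    "write_genotype_vcf",
    "write_truth_json",
]


class GenerationError(RuntimeError):
    """Raised when an infeasible configuration defeats bounded retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pooled-GWAS experiment.

    Defaults mirror the reference design: ~100 subjects per group, three
    technical array replicates per pool, five effect loci with a
    frequency shift of 0.15, small Gaussian pool-construction error, a
    strip-dependent red/green gain in [0.7, 1.4], and a small low-bead
    dropout fraction so the bead filter is always exercised.  Dense chips
    can show far higher exclusion rates (the reference 4.3M-SNP design
    excluded 11.5% of SNPs); set ``dropout_bead_prob=0.115`` to emulate
    that regime.
    """

    seed: int
    n_per_group: int = 100
    m_snps: int = 5000
    n_effect_snps: int = 5
    delta_f: float = 0.15
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    replicates_per_pool: int = 3
    construction_error_sd: float = 0.01
    strip_count: int = 10
    channel_bias_range: tuple[float, float] = (0.7, 1.4)
    channel_noise_sd: float = 0.05
    total_intensity_mean: float = 2000.0
    total_intensity_log_sd: float = 0.3
    bead_count_mean: float = 15.0
    dropout_bead_prob: float = 0.005
    effect_region_size: int = 10
    n_chromosomes: int = 5

    def __post_init__(self) -> None:
        if self.n_effect_snps > self.m_snps:
            raise ValueError("n_effect_snps cannot exceed m_snps")
        if self.n_effect_snps and self.effect_region_size * self.n_effect_snps > self.m_snps:
            raise ValueError("effect regions do not fit into the SNP map")
        if not 0 <= self.dropout_bead_prob < 1:
            raise ValueError("dropout_bead_prob must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Complete generator bookkeeping for every simulated observable."""

    freq_case: np.ndarray
    freq_control: np.ndarray
    effect_snps: list[str]
    effect_members: dict[str, list[str]]
    strip_gamma: pd.Series
    pool_freqs: pd.DataFrame | None = None       # snps x replicate samples
    latent: pd.DataFrame | None = None           # per-subject index targets
    low_bead_snps: list[str] = field(default_factory=list)


def _snp_map(cfg: SimulationConfig) -> pd.DataFrame:
    """Genome map: m SNPs over n chromosomes, strips in genome-order blocks."""
    m = cfg.m_snps
    per = [m // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(m % cfg.n_chromosomes):
        per[i] += 1
    chroms, pos = [], []
    for c, n in enumerate(per, start=1):
        chroms += [str(c)] * n
        pos += list(10_000 + 5_000 * np.arange(n))
    ids = [f"snp{i:06d}" for i in range(m)]
    strips = (np.arange(m) * cfg.strip_count) // m
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": pos,
            "strip": [f"strip{s:02d}" for s in strips],
            "order_index": np.arange(m),
        }
    ).set_index("snp_id")


def _group_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator, snps: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, list[str]]]:
    m = cfg.m_snps
    lo, hi = cfg.base_freq_range
    base = rng.uniform(lo, hi, m)
    f_case, f_ctrl = base.copy(), base.copy()
    effect, members = [], {}
    if cfg.n_effect_snps:
        span = cfg.effect_region_size
        # non-overlapping region starts, away from chromosome boundaries
        starts = rng.choice(
            np.arange(0, m - span, span * 3), cfg.n_effect_snps, replace=False
        )
        half = cfg.delta_f / 2
        for s in np.sort(starts):
            idx = np.arange(s, s + span)
            sign = rng.choice([-1.0, 1.0])
            centre = rng.uniform(max(lo, half + 0.02), min(hi, 1 - half - 0.02), span)
            f_case[idx] = np.clip(centre + sign * half, 0.0, 1.0)
            f_ctrl[idx] = np.clip(centre - sign * half, 0.0, 1.0)
            centre_snp = snps.index[s + span // 2]
            effect.append(centre_snp)
            members[centre_snp] = list(snps.index[idx])
    return f_case, f_ctrl, effect, members


def simulate_genotypes(
    freqs, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg genotype codes: Binomial(2, f) per subject per SNP."""
    f = np.asarray(freqs, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    return rng.binomial(2, f, size=(n, len(f))).astype(np.int8)


# -- phenotype generation ----------------------------------------------------

# plausible OGTT excursion shapes (relative weights for 30/60/120 min)
_G_SHAPE = np.array([1.25, 1.10, 0.75])
_I_SHAPE = np.array([3.0, 2.5, 1.2])


def _draw_subject(
    rng: np.random.Generator, ir_positive: bool, sid: str, sex: str,
    age: float, bmi_sds: float, weight: float,
    max_tries: int = 1000,
) -> tuple[Subject, dict]:
    for _ in range(max_tries):
        if ir_positive:
            homa = rng.lognormal(np.log(4.2), 0.35)
            wbisi_t = rng.lognormal(np.log(2.2), 0.25)
            if not (homa > 2.5 and wbisi_t < 3):
                continue
            gbar = rng.normal(125.0, 10.0)
        else:
            homa = rng.lognormal(np.log(1.75), 0.35)
            wbisi_t = rng.lognormal(np.log(5.5), 0.30)
            if not (homa <= 2.5 and wbisi_t >= 3):
                continue
            gbar = rng.normal(110.0, 10.0)
        g0 = float(np.clip(rng.normal(5.0, 0.4), 3.8, 6.5))       # mmol/l
        g0_mg = g0 * GLUCOSE_MGDL_PER_MMOL
        i0_uU = homa * 22.5 / g0
        needed = (10_000.0 / wbisi_t) ** 2 / (g0_mg * i0_uU)      # Gbar*Ibar
        gbar = float(np.clip(gbar, g0_mg / 4 * 1.1, 250.0))
        ibar = needed / gbar
        g_rest = (4 * gbar - g0_mg) * _G_SHAPE / _G_SHAPE.sum()
        i_rest = (4 * ibar - i0_uU) * _I_SHAPE / _I_SHAPE.sum()
        if np.any(g_rest <= 0) or np.any(i_rest <= 0):
            continue
        glucose = (g0,) + tuple(g_rest / GLUCOSE_MGDL_PER_MMOL)
        insulin = (i0_uU * INSULIN_PMOL_PER_UU,) + tuple(
            i_rest * INSULIN_PMOL_PER_UU
        )
        subj = Subject(
            id=sid,
            sex=sex,
            age=age,
            bmi_sds=bmi_sds,
            weight=weight,
            ogtt=OgttCurve(glucose=glucose, insulin=insulin),
        )
        expected = "IR_POS" if ir_positive else "IR_NEG"
        if subj.ir_status.value == expected:
            return subj, {"id": sid, "target_homa": homa, "target_wbisi": wbisi_t}
    raise GenerationError(f"could not generate a consistent subject for {sid}")


def simulate_cohort(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    label: str = "c1",
) -> tuple[list[Subject], pd.DataFrame]:
    """Matched IR+ / IR- subjects with OGTT curves consistent with status.

    Groups are pair-matched: the i-th IR- subject inherits the i-th IR+
    subject's sex and gets their age/BMI-SDS/weight plus small jitter,
    mirroring the matched case/control design.  The index targets come
    from group-specific distributions whose means track the reference
    cohort (IR+ HOMA-IR around 4.6, WBISI around 2.2; IR- around 1.8 and
    5.6).
    """
    covariates = [
        {
            "sex": "male" if i % 2 == 0 else "female",
            "age": float(np.clip(rng.normal(13.5, 2.6), 8.0, 18.0)),
            "bmi_sds": float(2.0 + rng.lognormal(np.log(0.85), 0.4)),
            "weight": float(np.clip(rng.normal(78.0, 15.0), 40.0, None)),
        }
        for i in range(cfg.n_per_group)
    ]
    subjects, latent = [], []
    for group, flag in (("IR_POS", True), ("IR_NEG", False)):
        for i in range(cfg.n_per_group):
            cov = covariates[i]
            if group == "IR_NEG":  # matched partner with measurement-scale jitter
                cov = dict(
                    cov,
                    age=float(np.clip(cov["age"] + rng.normal(0, 0.3), 8.0, 18.0)),
                    bmi_sds=float(max(2.0 + 1e-6, cov["bmi_sds"] + rng.normal(0, 0.05))),
                    weight=float(max(40.0, cov["weight"] + rng.normal(0, 2.0))),
                )
            sid = f"{label}_{group}_{i:03d}"
            subj, lat = _draw_subject(
                rng, flag, sid, cov["sex"], cov["age"], cov["bmi_sds"], cov["weight"]
            )
            lat["group"] = group
            subjects.append(subj)
            latent.append(lat)
    return subjects, pd.DataFrame(latent).set_index("id")


def build_pools(
    codes: np.ndarray,
    construction_error_sd: float,
    replicates: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """True replicate pool frequencies from a group's genotype codes.

    The pool's base frequency per SNP is the group's sample allele
    frequency mean(code)/2; each replicate adds Gaussian construction
    error, clipped to [0, 1].  Returns (base, replicate matrix m x k).
    """
    if codes.size == 0:
        raise ValueError("empty genotype group")
    base = codes.mean(axis=0) / 2.0
    reps = base[:, None] + rng.normal(
        0.0, construction_error_sd, size=(len(base), replicates)
    )
    return base, np.clip(reps, 0.0, 1.0)


def simulate_array(
    pool_freqs: pd.DataFrame,
    groups: pd.Series,
    snps: pd.DataFrame,
    strip_gamma: pd.Series,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-channel bead intensities for every (SNP, replicate sample).

    red = gamma_strip * T * f * (1 + eps), green = T * (1 - f) * (1 + eps'),
    with T log-normal around the configured total intensity and eps
    Gaussian channel noise.  Bead counts are 4 + Poisson(mean - 4); a
    fraction ``dropout_bead_prob`` of SNPs receives a sub-threshold count
    (Uniform{0..3}) in one randomly chosen sample, so the bead filter
    removes that fraction of SNPs.

    Returns the long intensity table and the list of low-bead SNP ids.
    """
    m = len(snps)
    gamma = snps["strip"].map(strip_gamma).to_numpy(dtype=float)
    samples = list(pool_freqs.columns)

    beads_by_sample = {
        s: 4 + rng.poisson(max(cfg.bead_count_mean - 4, 0.0), m) for s in samples
    }
    low_idx = np.nonzero(rng.random(m) < cfg.dropout_bead_prob)[0]
    which = rng.integers(0, len(samples), size=len(low_idx))
    low_counts = rng.integers(0, 4, size=len(low_idx))
    for i, s_idx, cnt in zip(low_idx, which, low_counts):
        beads_by_sample[samples[s_idx]][i] = cnt

    frames = []
    for sample in samples:
        f = pool_freqs[sample].to_numpy(dtype=float)
        T = rng.lognormal(np.log(cfg.total_intensity_mean), cfg.total_intensity_log_sd, m)
        eps_r = rng.normal(0.0, cfg.channel_noise_sd, m)
        eps_g = rng.normal(0.0, cfg.channel_noise_sd, m)
        red = np.maximum(gamma * T * f * (1 + eps_r), 0.0)
        green = np.maximum(T * (1 - f) * (1 + eps_g), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snps.index,
                    "chrom": snps["chrom"].to_numpy(),
                    "pos": snps["pos"].to_numpy(),
                    "strip": snps["strip"].to_numpy(),
                    "sample_id": sample,
                    "group": groups[sample],
                    "red": red,
                    "green": green,
                    "beads": beads_by_sample[sample],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return records, list(snps.index[low_idx])


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SimulationConfig
    snps: pd.DataFrame
    intensities: pd.DataFrame
    cohort1: GenotypeTable
    cohort2: GenotypeTable
    subjects1: list[Subject]
    subjects2: list[Subject]
    truth: GroundTruth


def simulate_study(cfg: SimulationConfig, phenotypes: bool = True) -> SimulatedStudy:
    """Run the full generative model for a two-cohort study.

    Cohort 1 provides the pools (and later the first validation round);
    cohort 2 is an independent replication cohort drawn from the same
    group frequencies.  With ``phenotypes=False`` the (comparatively
    expensive) OGTT back-generation is skipped and statuses are assigned
    directly — genotype and array structure are unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    snps = _snp_map(cfg)
    f_case, f_ctrl, effect, members = _group_frequencies(cfg, rng, snps)

    codes = {}
    for cohort in ("c1", "c2"):
        codes[(cohort, "IR_POS")] = simulate_genotypes(f_case, cfg.n_per_group, rng)
        codes[(cohort, "IR_NEG")] = simulate_genotypes(f_ctrl, cfg.n_per_group, rng)

    reps = cfg.replicates_per_pool
    pool_cols, groups = {}, {}
    for group, tag in (("IR_POS", "IR+"), ("IR_NEG", "IR-")):
        _, rep_f = build_pools(
            codes[("c1", group)], cfg.construction_error_sd, reps, rng
        )
        for j in range(reps):
            name = f"{tag}_rep{j + 1}"
            pool_cols[name] = rep_f[:, j]
            groups[name] = group
    pool_freqs = pd.DataFrame(pool_cols, index=snps.index)
    groups = pd.Series(groups)

    gamma = pd.Series(
        rng.uniform(*cfg.channel_bias_range, cfg.strip_count),
        index=[f"strip{s:02d}" for s in range(cfg.strip_count)],
        name="gamma",
    )
    intensities, low_beads = simulate_array(pool_freqs, groups, snps, gamma, cfg, rng)

    latent_frames = []
    studies = {}
    for cohort in ("c1", "c2"):
        if phenotypes:
            subjects, latent = simulate_cohort(cfg, rng, label=cohort)
            latent_frames.append(latent)
            ids = [s.id for s in subjects]
            status = pd.Series({s.id: s.ir_status.value for s in subjects})
        else:
            subjects = []
            ids = [
                f"{cohort}_{g}_{i:03d}"
                for g in ("IR_POS", "IR_NEG")
                for i in range(cfg.n_per_group)
            ]
            status = pd.Series({i: i.split("_", 1)[1].rsplit("_", 1)[0] for i in ids})
        mat = np.vstack([codes[(cohort, "IR_POS")], codes[(cohort, "IR_NEG")]])
        table = GenotypeTable(
            pd.DataFrame(mat.astype(float), index=ids, columns=snps.index),
            status,
            snps=snps,
        )
        studies[cohort] = (subjects, table)

    truth = GroundTruth(
        freq_case=f_case,
        freq_control=f_ctrl,
        effect_snps=effect,
        effect_members=members,
        strip_gamma=gamma,
        pool_freqs=pool_freqs,
        latent=pd.concat(latent_frames) if latent_frames else None,
        low_bead_snps=low_beads,
    )
    return SimulatedStudy(
        config=cfg,
        snps=snps,
        intensities=intensities,
        cohort1=studies["c1"][1],
        cohort2=studies["c2"][1],
        subjects1=studies["c1"][0],
        subjects2=studies["c2"][0],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers


def write_genotype_tsv(table: GenotypeTable, path) -> None:
    table.codes.to_csv(path, sep="\t", index_label="subject_id", na_rep="NA")


def write_genotype_vcf(table: GenotypeTable, snps: pd.DataFrame, path) -> None:
    """Minimal uncompressed VCF 4.2 with GT-only genotype columns."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    subjects = list(table.codes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subjects)
            + "\n"
        )
        for snp in table.codes.columns:
            meta = snps.loc[snp]
            gts = [
                gt_map.get(float(v), "./.") if pd.notna(v) else "./."
                for v in table.codes[snp]
            ]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "effect_snps": truth.effect_snps,
        "effect_members": truth.effect_members,
        "strip_gamma": truth.strip_gamma.to_dict(),
        "freq_case": truth.freq_case.tolist(),
        "freq_control": truth.freq_control.tolist(),
        "low_bead_snps": truth.low_bead_snps,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain mapping (YAML/JSON); seed is mandatory."""
    if "seed" not in d:
        raise ValueError("simulation config requires an explicit seed")
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("base_freq_range", "channel_bias_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
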