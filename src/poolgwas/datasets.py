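"""Small bundled reference data.

``TOP_SNP_REPLICATE_PAF`` holds the published per-replicate pooling
allele frequencies (B allele) of the five top-ranked candidate SNPs from
the reference pooled-DNA study of insulin resistance in obese children
(three technical replicates per pool; IR+ pool of 98 subjects, IR- pool
of 100).  They serve as a worked example for the replicate-variance and
chi-square arithmetic and as a regression fixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: IR+ pool size (individuals) in the reference design
N_CASES = 98
#: IR- pool size (individuals) in the reference design
N_CONTROLS = 100

#: replicate PAFs: rows = SNPs, three IR+ then three IR- replicates
TOP_SNP_REPLICATE_PAF = pd.DataFrame(
    {
        "IR+_rep1": [0.358, 0.147, 0.922, 0.913, 0.477],
        "IR+_rep2": [0.352, 0.138, 0.895, 0.874, 0.462],
        "IR+_rep3": [0.355, 0.160, 0.944, 0.909, 0.493],
        "IR-_rep1": [0.476, 0.084, 0.828, 0.964, 0.570],
        "IR-_rep2": [0.451, 0.085, 0.774, 0.949, 0.541],
        "IR-_rep3": [0.457, 0.065, 0.865, 0.980, 0.545],
    },
    index=pd.Index(
        ["rs212540", "rs3218888", "rs252111", "rs9261108", "rs2258617"],
        name="snp_id",
    ),
)

CASE_REPLICATES = [c for c in TOP_SNP_REPLICATE_PAF.columns if c.startswith("IR+")]
CONTROL_REPLICATES = [c for c in TOP_SNP_REPLICATE_PAF.columns if c.startswith("IR-")]


def replicate_summary() -> pd.DataFrame:
    """Per-SNP replicate means and sample SDs per pool and combined.

    Columns: mean_case, sd_case, mean_control, sd_control, mean_all,
    sd_all — the per-pool "Average" rows, the combined mean, and the
    replicate dispersions as sample standard deviations.
    """
    case = TOP_SNP_REPLICATE_PAF[CASE_REPLICATES].to_numpy()
    ctrl = TOP_SNP_REPLICATE_PAF[CONTROL_REPLICATES].to_numpy()
    both = np.hstack([case, ctrl])
    return pd.DataFrame(
        {
            "mean_case": case.mean(axis=1),
            "sd_case": case.std(axis=1, ddof=1),
            "mean_control": ctrl.mean(axis=1),
            "sd_control": ctrl.std(axis=1, ddof=1),
            "mean_all": both.mean(axis=1),
            "sd_all": both.std(axis=1, ddof=1),
        },
        index=TOP_SNP_REPLICATE_PAF.index,
    )
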