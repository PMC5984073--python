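"""OGTT-based insulin-resistance phenotyping.

Case/control status in the pooled-GWAS design is defined from a standard
oral glucose tolerance test (OGTT): blood glucose and insulin sampled at
0, 30, 60 and 120 minutes after a weight-scaled glucose load.  Two indices
summarise the curves:

* **HOMA-IR** — homeostatic model assessment of insulin resistance,
  fasting glucose [mmol/l] x fasting insulin [uU/ml] / 22.5.  Higher
  values mean more resistance.
* **WBISI** (Matsuda index) — whole-body insulin sensitivity,
  10000 / sqrt(G0 * I0 * Gmean * Imean) with glucose in mg/dl and insulin
  in uU/ml, means taken unweighted over the four OGTT time points.  Lower
  values mean more resistance.

A subject is insulin-resistant (IR+) when HOMA-IR > 2.5 **and**
WBISI < 3, insulin-sensitive (IR-) when neither threshold is crossed, and
indeterminate otherwise (discordant indices; such subjects are excluded
from the association analysis rather than forced into a group).

Laboratory units are mmol/l for glucose and pmol/l for insulin; the index
formulas use the conventional mg/dl and uU/ml, so the module exposes the
conversion constants (18.016 mg/dl per mmol/l, 6.945 pmol/l per uU/ml)
as overridable parameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: glucose: mg/dl per mmol/l
GLUCOSE_MGDL_PER_MMOL = 18.016
#: insulin: pmol/l per uU/ml
INSULIN_PMOL_PER_UU = 6.945

#: OGTT sampling grid in minutes
OGTT_MINUTES = (0, 30, 60, 120)

#: HOMA-IR threshold; IR+ requires a value strictly above it
HOMA_IR_THRESHOLD = 2.5
#: WBISI threshold; IR+ requires a value strictly below it
WBISI_THRESHOLD = 3.0


class IRStatus(str, enum.Enum):
    """Insulin-resistance classification."""

    IR_POS = "IR_POS"
    IR_NEG = "IR_NEG"
    INDETERMINATE = "INDETERMINATE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def mmol_to_mgdl(glucose_mmol, factor: float = GLUCOSE_MGDL_PER_MMOL):
    """Convert glucose mmol/l -> mg/dl."""
    return np.asarray(glucose_mmol, dtype=float) * factor


def mgdl_to_mmol(glucose_mgdl, factor: float = GLUCOSE_MGDL_PER_MMOL):
    """Convert glucose mg/dl -> mmol/l."""
    return np.asarray(glucose_mgdl, dtype=float) / factor


def pmol_to_uU(insulin_pmol, divisor: float = INSULIN_PMOL_PER_UU):
    """Convert insulin pmol/l -> uU/ml."""
    return np.asarray(insulin_pmol, dtype=float) / divisor


@dataclass(frozen=True)
class OgttCurve:
    """Glucose (mmol/l) and insulin (pmol/l) at 0/30/60/120 min.

    Parameters
    ----------
    glucose, insulin
        Length-4 sequences ordered by sampling time.
    """

    glucose: tuple[float, float, float, float]
    insulin: tuple[float, float, float, float]
    minutes: tuple[int, ...] = OGTT_MINUTES

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.glucose)
        i = tuple(float(x) for x in self.insulin)
        if len(g) != 4 or len(i) != 4:
            raise ValueError("OGTT curve needs exactly four time points")
        if any(x < 0 for x in g + i):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(self.minutes, self.minutes[1:])):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "glucose", g)
        object.__setattr__(self, "insulin", i)


@dataclass
class Subject:
    """One study participant with phenotype and derived IR indices."""

    id: str
    sex: str
    age: float
    bmi_sds: float
    ogtt: OgttCurve
    weight: float | None = None
    homa_ir: float = field(init=False)
    wbisi: float = field(init=False)
    ir_status: IRStatus = field(init=False)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.homa_ir = homa_ir(self.ogtt.glucose[0], self.ogtt.insulin[0])
        self.wbisi = wbisi(self.ogtt)
        self.ir_status = classify_ir(self.homa_ir, self.wbisi)


def glucose_dose(weight: float) -> float:
    """OGTT glucose load in grams: 1.75 g per kg body weight, capped at 75 g."""
    if not weight > 0:
        raise ValueError("weight must be positive")
    return min(1.75 * weight, 75.0)


def homa_ir(
    glucose0: float,
    insulin0: float,
    *,
    insulin_pmol_per_uU: float = INSULIN_PMOL_PER_UU,
) -> float:
    """HOMA-IR from fasting glucose (mmol/l) and fasting insulin (pmol/l).

    glucose0[mmol/l] * insulin0[uU/ml] / 22.5, insulin converted from
    pmol/l first.
    """
    if glucose0 < 0 or insulin0 < 0:
        raise ValueError("fasting concentrations must be non-negative")
    return glucose0 * (insulin0 / insulin_pmol_per_uU) / 22.5


def wbisi(
    curve: OgttCurve,
    *,
    glucose_mgdl_per_mmol: float = GLUCOSE_MGDL_PER_MMOL,
    insulin_pmol_per_uU: float = INSULIN_PMOL_PER_UU,
) -> float:
    """Whole-body insulin sensitivity (Matsuda) index from an OGTT curve.

    10000 / sqrt(G0 * I0 * Gmean * Imean), glucose in mg/dl, insulin in
    uU/ml, means unweighted over the four time points.
    """
    g = np.asarray(curve.glucose, dtype=float) * glucose_mgdl_per_mmol
    i = np.asarray(curve.insulin, dtype=float) / insulin_pmol_per_uU
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("WBISI needs strictly positive concentrations")
    return 10000.0 / float(np.sqrt(g[0] * i[0] * g.mean() * i.mean()))


def classify_ir(homa: float, wbisi_value: float) -> IRStatus:
    """Assign IR status from both indices.

    IR+ requires HOMA-IR strictly above 2.5 *and* WBISI strictly below 3;
    IR- requires neither criterion; a discordant pair is indeterminate.
    Boundary values never classify as IR+.
    """
    if homa < 0 or wbisi_value <= 0:
        raise ValueError("homa must be >= 0 and wbisi > 0")
    high_homa = homa > HOMA_IR_THRESHOLD
    low_wbisi = wbisi_value < WBISI_THRESHOLD
    if high_homa and low_wbisi:
        return IRStatus.IR_POS
    if not high_homa and not low_wbisi:
        return IRStatus.IR_NEG
    return IRStatus.INDETERMINATE


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    # standardized mean difference with pooled (unweighted) SD; 0 when both
    # groups are constant and equal
    va, vb = np.var(a, ddof=1) if a.size > 1 else 0.0, np.var(b, ddof=1) if b.size > 1 else 0.0
    sd = np.sqrt((va + vb) / 2.0)
    diff = float(np.mean(a) - np.mean(b))
    if sd == 0:
        return 0.0 if diff == 0 else np.inf
    return diff / sd


def matching_report(
    group_a: Sequence[Subject],
    group_b: Sequence[Subject],
    *,
    smd_flag: float = 0.25,
) -> pd.DataFrame:
    """Covariate balance between two subject groups.

    Reports per-group means of age, BMI-SDS and male fraction together
    with the standardized mean difference (SMD); |SMD| above ``smd_flag``
    is flagged, mirroring the matched-cohort design (groups matched for
    BMI, sex and age).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name, getter in (
        ("age", lambda s: s.age),
        ("bmi_sds", lambda s: s.bmi_sds),
        ("male_fraction", lambda s: 1.0 if s.sex == "male" else 0.0),
    ):
        a = np.array([getter(s) for s in group_a], dtype=float)
        b = np.array([getter(s) for s in group_b], dtype=float)
        smd = _smd(a, b)
        rows.append(
            {
                "variable": name,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "smd": smd,
                "flagged": abs(smd) > smd_flag,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotype CSV interface

_PHENO_COLUMNS = [
    "id", "sex", "age", "weight", "bmi_sds",
    "glu0", "glu30", "glu60", "glu120",
    "ins0", "ins30", "ins60", "ins120",
]


def subjects_to_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Tabulate subjects with derived columns appended."""
    rows = []
    for s in subjects:
        row = {
            "id": s.id, "sex": s.sex, "age": s.age, "weight": s.weight,
            "bmi_sds": s.bmi_sds,
        }
        for t, g in zip(OGTT_MINUTES, s.ogtt.glucose):
            row[f"glu{t}"] = g
        for t, i in zip(OGTT_MINUTES, s.ogtt.insulin):
            row[f"ins{t}"] = i
        row.update(homa_ir=s.homa_ir, wbisi=s.wbisi, ir_status=s.ir_status.value)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_subjects(df: pd.DataFrame) -> list[Subject]:
    """Build :class:`Subject` records (re-deriving indices) from a table."""
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns and c != "weight"]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    subjects = []
    for _, r in df.iterrows():
        curve = OgttCurve(
            glucose=tuple(float(r[f"glu{t}"]) for t in OGTT_MINUTES),
            insulin=tuple(float(r[f"ins{t}"]) for t in OGTT_MINUTES),
        )
        weight = float(r["weight"]) if "weight" in df.columns and pd.notna(r.get("weight")) else None
        subjects.append(
            Subject(
                id=str(r["id"]), sex=str(r["sex"]), age=float(r["age"]),
                bmi_sds=float(r["bmi_sds"]), ogtt=curve, weight=weight,
            )
        )
    return subjects


def read_phenotypes(path) -> list[Subject]:
    """Read the phenotype CSV (one row per subject) and derive indices."""
    return frame_to_subjects(pd.read_csv(path))


def write_phenotypes(subjects: Iterable[Subject], path) -> None:
    """Write the phenotype CSV with homa_ir/wbisi/ir_status appended."""
    subjects_to_frame(subjects).to_csv(path, index=False)
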