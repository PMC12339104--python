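"""Derived metabolic indices: HOMA-IR and the continuous metabolic syndrome score.

HOMA-IR (homeostatic model assessment of insulin resistance) is
``insulin (mU/l) x glucose (mmol/l) / 22.5``; insulin reported in SI
units (pmol/l) is converted to conventional units by dividing by 6.

The continuous metabolic syndrome score (MtbS) combines central obesity,
glycemia, dyslipidemia and blood pressure into one severity number:

    MtbS = 2*waist/height + glucose/5.6 + triglycerides/1.7
           + systolic/130 - HDL/(40 if male else 50)

Higher is worse.  Each denominator is the dichotomous metabolic-syndrome
cut-off for that component, so a person sitting exactly at every cut-off
scores 3.0.  The HDL denominators are configurable: the printed pair
(40, 50) follows mg/dl conventions while HDL is often recorded in
mmol/l (cut-offs 0.9/1.1); both readings are supported and neither is
silently assumed (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Cutoffs",
    "convert_insulin_si",
    "homa_ir",
    "mtbs",
    "cutoff_flags",
    "MetabolicScores",
]


@dataclass(frozen=True)
class Cutoffs:
    """Component cut-offs; all comparisons are inclusive (>=, or < for HDL)."""

    bmi_overweight: float = 25.0
    bmi_obese: float = 30.0
    waist_m: float = 94.5
    waist_f: float = 89.5
    systolic: float = 130.0
    glucose: float = 5.6
    triglycerides: float = 1.7
    hdl_low_m: float = 0.9   # mmol/l
    hdl_low_f: float = 1.1
    # MtbS equation denominators (unit reading configurable, see module doc)
    mtbs_hdl_denom_m: float = 40.0
    mtbs_hdl_denom_f: float = 50.0


DEFAULT_CUTOFFS = Cutoffs()

_SI_TO_CONVENTIONAL = 6.0
_HOMA_DENOM = 22.5


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError(f"{name} must be strictly positive")
    return arr


def convert_insulin_si(insulin_si):
    """Convert insulin from SI units (pmol/l) to conventional mU/l (divide by 6)."""
    return _require_positive("insulin_si", insulin_si) / _SI_TO_CONVENTIONAL


def homa_ir(insulin, glucose):
    """HOMA-IR = insulin (mU/l) x glucose (mmol/l) / 22.5."""
    ins = _require_positive("insulin", insulin)
    glu = _require_positive("glucose", glucose)
    return ins * glu / _HOMA_DENOM


def mtbs(
    waist,
    height,
    glucose,
    triglycerides,
    systolic,
    hdl,
    sex,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
):
    """Continuous metabolic syndrome severity score (vectorized).

    ``sex`` is ``"M"``/``"F"`` (scalar or array); waist and height must share
    one length unit.  Raises on any missing or non-positive component.
    """
    comps = {
        "waist": waist, "height": height, "glucose": glucose,
        "triglycerides": triglycerides, "systolic": systolic, "hdl": hdl,
    }
    missing = [k for k, v in comps.items() if v is None or np.any(pd.isna(v))]
    if missing:
        raise ValueError(f"missing MtbS components: {missing}")
    arrs = {k: _require_positive(k, v) for k, v in comps.items()}
    sex_arr = np.asarray(sex, dtype=object)
    bad = set(np.unique(sex_arr)) - {"M", "F"}
    if bad:
        raise ValueError(f"sex must be 'M' or 'F', got {sorted(bad)}")
    hdl_denom = np.where(sex_arr == "M", cutoffs.mtbs_hdl_denom_m, cutoffs.mtbs_hdl_denom_f)
    score = (
        2.0 * arrs["waist"] / arrs["height"]
        + arrs["glucose"] / cutoffs.glucose
        + arrs["triglycerides"] / cutoffs.triglycerides
        + arrs["systolic"] / cutoffs.systolic
        - arrs["hdl"] / hdl_denom
    )
    return score if score.ndim else float(score)


def cutoff_flags(
    phenotypes: pd.DataFrame, cutoffs: Cutoffs = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Dichotomous metabolic-syndrome component flags (inclusive boundaries)."""
    is_m = phenotypes["sex"].to_numpy(dtype=object) == "M"
    return pd.DataFrame(
        {
            "overweight": phenotypes["bmi"] >= cutoffs.bmi_overweight,
            "obese": phenotypes["bmi"] >= cutoffs.bmi_obese,
            "high_waist": phenotypes["waist"]
            >= np.where(is_m, cutoffs.waist_m, cutoffs.waist_f),
            "high_systolic": phenotypes["systolic"] >= cutoffs.systolic,
            "high_glucose": phenotypes["glucose"] >= cutoffs.glucose,
            "high_triglycerides": phenotypes["triglycerides"] >= cutoffs.triglycerides,
            "low_hdl": phenotypes["hdl"]
            < np.where(is_m, cutoffs.hdl_low_m, cutoffs.hdl_low_f),
        },
        index=phenotypes.index,
    )


class MetabolicScores(TransformerMixin, BaseEstimator):
    """Attach derived metabolic columns to a phenotype table.

    Adds ``homa_ir`` and ``mtbs`` (and the cut-off flags when
    ``add_flags=True``).  If ``insulin_is_si=True`` the insulin column is
    first converted from pmol/l to mU/l.
    """

    def __init__(
        self,
        insulin_is_si: bool = False,
        add_flags: bool = False,
        cutoffs: Cutoffs = DEFAULT_CUTOFFS,
    ):
        self.insulin_is_si = insulin_is_si
        self.add_flags = add_flags
        self.cutoffs = cutoffs

    _required = ("insulin", "glucose", "waist", "height",
                 "triglycerides", "systolic", "hdl", "sex")

    def fit(self, X: pd.DataFrame, y=None):  # noqa: D102 — stateless
        missing = [c for c in self._required if c not in X.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:  # noqa: D102
        out = X.copy()
        insulin = out["insulin"].to_numpy(float)
        if self.insulin_is_si:
            insulin = convert_insulin_si(insulin)
            out["insulin"] = insulin
        out["homa_ir"] = homa_ir(insulin, out["glucose"].to_numpy(float))
        out["mtbs"] = mtbs(
            out["waist"], out["height"], out["glucose"], out["triglycerides"],
            out["systolic"], out["hdl"], out["sex"], self.cutoffs,
        )
        if self.add_flags:
            out = pd.concat([out, cutoff_flags(out, self.cutoffs)], axis=1)
        return out
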