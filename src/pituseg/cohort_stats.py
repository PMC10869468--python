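"""Cohort statistics: IQR outlier exclusion, sex group comparison, and
sex-adjusted linear regression of gland morphometrics on age.

The regression model is ordinary least squares,

    outcome ~ intercept + age + sex,

with sex coded 1 = male, 0 = female, so a negative sex coefficient means a
smaller male gland.  Before fitting, subjects whose brain size (count of
above-Otsu voxels in the head image) falls outside
``[Q1 - k*IQR, Q3 + k*IQR]`` are excluded (default k = 1.5, quartiles by
linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "iqr_exclude",
    "brain_size",
    "apply_brain_size_exclusion",
    "group_compare",
    "fit_age_regression",
]

SEX_CODING = {"female": 0, "male": 1}


def iqr_exclude(values, factor: float = 1.5) -> np.ndarray:
    """Boolean keep-flags under the interquartile-range outlier rule.

    A value is excluded iff it lies strictly outside
    ``[Q1 - factor*IQR, Q3 + factor*IQR]``; quartiles use linear
    interpolation.  Scale- and shift-equivariant for positive scalings.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 values for the IQR rule, got {values.size}")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation default
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return (values >= lo) & (values <= hi)


def brain_size(volume_data: np.ndarray) -> int:
    """Brain-size proxy: voxels above Otsu's threshold in the head image."""
    from skimage.filters import threshold_otsu

    data = np.asarray(volume_data)
    thr = threshold_otsu(data.astype(np.float64))
    return int(np.count_nonzero(data > thr))


def apply_brain_size_exclusion(table: pd.DataFrame, factor: float = 1.5) -> pd.DataFrame:
    """Flag rows whose ``brain_size`` is an IQR outlier.

    Adds/overwrites boolean ``excluded`` and string ``exclusion_reason``
    columns; does not drop rows.
    """
    table = table.copy()
    keep = iqr_exclude(table["brain_size"].to_numpy(), factor=factor)
    table["excluded"] = ~keep
    table["exclusion_reason"] = np.where(keep, "", "abnormal brain size (IQR rule)")
    return table


def _active(table: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in table.columns:
        return table.loc[~table["excluded"].astype(bool)]
    return table


def _sex_indicator(sex: pd.Series) -> np.ndarray:
    coded = sex.astype(str).str.lower().map(SEX_CODING)
    if coded.isna().any():
        bad = sorted(set(sex[coded.isna()]))
        raise ValueError(f"unrecognized sex labels: {bad}; expected female/male")
    return coded.to_numpy(dtype=float)


def group_compare(table: pd.DataFrame, outcome: str) -> dict:
    """Welch's unequal-variance t-test of ``outcome`` between sexes."""
    active = _active(table)
    sex = _sex_indicator(active["sex"])
    a = active.loc[sex == 0, outcome].to_numpy(dtype=float)  # female
    b = active.loc[sex == 1, outcome].to_numpy(dtype=float)  # male
    if a.size == 0 or b.size == 0:
        raise ValueError("both sexes must be present after exclusion")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return {
        "outcome": outcome,
        "test": "welch_t",
        "statistic": float(t),
        "p_value": float(p),
        "mean_female": float(a.mean()),
        "mean_male": float(b.mean()),
        "n_female": int(a.size),
        "n_male": int(b.size),
    }


@dataclass
class RegressionResult:
    """Sex-adjusted OLS of a morphometric outcome on age."""

    outcome: str
    coefficients: dict
    standard_errors: dict
    t_values: dict
    p_values: dict
    n_used: int
    r_squared: float
    sex_coding: dict = field(default_factory=lambda: dict(SEX_CODING))

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "n_used": self.n_used,
            "r_squared": self.r_squared,
            "sex_coding": self.sex_coding,
        }


def fit_age_regression(table: pd.DataFrame, outcome: str) -> RegressionResult:
    """OLS of ``outcome ~ intercept + age + sex`` on non-excluded rows."""
    active = _active(table)
    if len(active) < 4:
        raise ValueError(f"need >= 4 non-excluded rows, got {len(active)}")
    age = active["age"].to_numpy(dtype=float)
    sex = _sex_indicator(active["sex"])
    if np.ptp(age) == 0:
        raise ValueError("rank deficiency: column 'age' is constant")
    if np.ptp(sex) == 0:
        raise ValueError("rank deficiency: column 'sex' has a single level")
    X = sm.add_constant(
        pd.DataFrame({"age": age, "sex": sex}), has_constant="add"
    ).rename(columns={"const": "intercept"})
    fit = sm.OLS(active[outcome].to_numpy(dtype=float), X).fit()
    return RegressionResult(
        outcome=outcome,
        coefficients={k: float(v) for k, v in fit.params.items()},
        standard_errors={k: float(v) for k, v in fit.bse.items()},
        t_values={k: float(v) for k, v in fit.tvalues.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        n_used=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )
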