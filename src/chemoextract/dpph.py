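"""DPPH radical-scavenging assay: inhibition percentages and IC50.

The assay follows the absorbance of the DPPH radical at 516 nm. With t0
the blank absorbance of the working solution and t1 the (replicate-
averaged) absorbance after one hour of reaction with the extract, the
inhibition percentage is

    A_DPPH% = 100 * (t0 - t1) / t0.

IC50 — the extract concentration inhibiting 50% of the radical — is
interpolated from a straight least-squares line of mean inhibition on
concentration (the dose range studied here stays in the near-linear
regime, so no sigmoid model is fitted). The IC50 standard error comes
from first-order propagation of the OLS coefficient covariance.

For the antioxidant response-surface design the raw response is
Y = mean(t0) - t1, the absorbance drop itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "inhibition_percent",
    "ccd_response",
    "CalibrationLine",
    "fit_inhibition_line",
    "DpphCalibration",
]


def inhibition_percent(t0: float, t1) -> float | np.ndarray:
    """Percent absorbance decrease 100*(t0 - t1)/t0.

    May leave [0, 100] for noisy inputs (a warning, not an error):
    clipping would bias the calibration line.
    """
    t0 = float(t0)
    if t0 <= 0:
        raise ValueError(f"blank absorbance t0 must be positive, got {t0}")
    t1 = np.asarray(t1, float)
    pct = 100.0 * (t0 - t1) / t0
    if np.any(pct < 0) or np.any(pct > 100):
        warnings.warn("inhibition outside [0, 100]%: noisy t0/t1 inputs", UserWarning,
                      stacklevel=2)
    return float(pct) if pct.ndim == 0 else pct


def ccd_response(t0_mean: float, t1) -> float | np.ndarray:
    """Absorbance-drop response Y = mean(t0) - t1 used by the CCD."""
    if t0_mean <= 0:
        raise ValueError(f"blank absorbance t0 must be positive, got {t0_mean}")
    y = float(t0_mean) - np.asarray(t1, float)
    return float(y) if y.ndim == 0 else y


@dataclass
class CalibrationLine:
    """Inhibition-vs-concentration line with interpolated IC50."""

    slope: float                 # % per mg/mL
    intercept: float             # %
    r_squared: float
    ic50: float                  # mg dry material per mL; NaN if slope <= 0
    ic50_se: float
    n_points: int

    def predict(self, concentration) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(concentration, float)

    def summary(self) -> str:
        return (
            "DPPH calibration line\n"
            f"  inhibition% = {self.intercept:.3f} + {self.slope:.3f} * conc (mg/mL)\n"
            f"  R^2 = {self.r_squared:.4f}  (n = {self.n_points})\n"
            f"  IC50 = {self.ic50:.3f} +/- {self.ic50_se:.3f} mg/mL"
        )


def fit_inhibition_line(concentrations, inhibition_pct) -> CalibrationLine:
    """OLS of mean inhibition% on concentration; IC50 = (50 - b0)/b1.

    Requires >= 3 distinct concentrations. A non-positive slope (no
    scavenging trend) yields a warning and an undefined (NaN) IC50.
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(inhibition_pct, float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    X = sm.add_constant(c)
    res = sm.OLS(y, X).fit()
    b0, b1 = res.params
    if b1 <= 0:
        warnings.warn("non-positive slope: no scavenging trend, IC50 undefined",
                      UserWarning, stacklevel=2)
        ic50, se = float("nan"), float("nan")
    else:
        ic50 = (50.0 - b0) / b1
        grad = np.array([-1.0 / b1, -(50.0 - b0) / b1 ** 2])
        se = float(np.sqrt(grad @ res.cov_params() @ grad))
    return CalibrationLine(
        slope=float(b1),
        intercept=float(b0),
        r_squared=float(res.rsquared),
        ic50=float(ic50),
        ic50_se=se,
        n_points=len(c),
    )


class DpphCalibration:
    """Model object over raw assay records (statsmodels style).

    Parameters
    ----------
    records : DataFrame with columns ``concentration_mg_per_ml``, ``t0``,
        ``t1`` (long format, one row per replicate).
    average_replicates : average t1 within concentration before the
        regression (the conventional treatment); set False to fit on
        replicate-level points.
    """

    def __init__(self, records: pd.DataFrame, average_replicates: bool = True):
        need = {"concentration_mg_per_ml", "t0", "t1"}
        missing = need - set(records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.records = records.copy()
        self.average_replicates = average_replicates

    def fit(self) -> CalibrationLine:
        df = self.records
        t0 = df["t0"].mean()
        if self.average_replicates:
            t1 = df.groupby("concentration_mg_per_ml")["t1"].mean()
            conc = t1.index.to_numpy(float)
            pct = inhibition_percent(t0, t1.to_numpy())
        else:
            conc = df["concentration_mg_per_ml"].to_numpy(float)
            pct = inhibition_percent(t0, df["t1"].to_numpy())
        return fit_inhibition_line(conc, pct)
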