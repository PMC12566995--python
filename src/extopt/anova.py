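"""ANOVA with lack-of-fit decomposition for response-surface models.

Residual variation is split into *pure error* — variation among replicated
runs, which no model can explain — and *lack of fit*, the remainder, which
measures model inadequacy.  Two Fisher tests follow:

* regression:   F = MS_regression / MS_residual, significant when it
  exceeds the upper-tail critical value at the working level (default 10%);
* lack of fit:  F = MS_lof / MS_pure_error, where a *small* value (below
  the critical value) means the model's departures from the data are
  within replicate noise, i.e. the model is predictive.

R² is reported as SS_regression / SS_total and adjusted R² as
1 - (SS_residual/df_residual)/(SS_total/df_total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .exceptions import ExtoptError, InputError
from .model import QuadraticModel, build_model_matrix

__all__ = ["AnovaTable", "anova_decompose", "f_quantile", "model_verdict"]

VERDICTS = (
    "significant_and_predictive",
    "significant_not_predictive",
    "not_significant",
    "predictivity_undeterminable",
)


def f_quantile(prob: float, df1: int, df2: int) -> float:
    """Quantile of the F(df1, df2) distribution at cumulative probability ``prob``.

    The critical value tabulated at level p is ``f_quantile(1 - p, df1, df2)``;
    e.g. the 90% point for (8, 8) df is 2.59.
    """
    if not 0.0 < prob < 1.0:
        raise InputError(f"prob must be in (0, 1), got {prob}")
    if df1 < 1 or df2 < 1:
        raise InputError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    return float(stats.f.ppf(prob, df1, df2))


@dataclass
class AnovaTable:
    """Sums-of-squares decomposition with Fisher tests at a fixed level."""

    ss_regression: float
    df_regression: int
    ss_residual: float
    df_residual: int
    ss_lof: float
    df_lof: int
    ss_pure_error: float
    df_pure_error: int
    p_threshold: float = 0.1
    response_name: str = ""

    @property
    def ss_total(self) -> float:
        return self.ss_regression + self.ss_residual

    @property
    def df_total(self) -> int:
        return self.df_regression + self.df_residual

    @property
    def ms_regression(self) -> float:
        return self.ss_regression / self.df_regression if self.df_regression > 0 else float("nan")

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    @property
    def ms_lof(self) -> float:
        return self.ss_lof / self.df_lof if self.df_lof > 0 else float("nan")

    @property
    def ms_pure_error(self) -> float:
        return self.ss_pure_error / self.df_pure_error if self.df_pure_error > 0 else float("nan")

    @property
    def f_regression(self) -> float:
        if self.df_regression < 1:
            return 0.0  # intercept-only model: nothing to test
        return self.ms_regression / self.ms_residual if self.ms_residual > 0 else float("inf")

    @property
    def f_tab_regression(self) -> float:
        if self.df_regression < 1:
            return float("nan")
        return f_quantile(1.0 - self.p_threshold, self.df_regression, self.df_residual)

    @property
    def f_lof(self) -> float:
        ms_pe = self.ms_pure_error
        if not np.isfinite(ms_pe) or ms_pe == 0.0:
            return float("inf")
        return self.ms_lof / ms_pe

    @property
    def f_tab_lof(self) -> float:
        return f_quantile(1.0 - self.p_threshold, self.df_lof, self.df_pure_error)

    @property
    def r2(self) -> float:
        return self.ss_regression / self.ss_total if self.ss_total > 0 else float("nan")

    @property
    def adj_r2(self) -> float:
        if self.ss_total == 0 or self.df_residual == 0:
            return float("nan")
        return 1.0 - (self.ss_residual / self.df_residual) / (self.ss_total / self.df_total)

    @property
    def verdict(self) -> str:
        return model_verdict(self)

    def to_frame(self) -> pd.DataFrame:
        """Five-row table: Regression, Residue, Lack of fit, Pure error, Total."""
        rows = [
            ("Regression", self.ss_regression, self.df_regression, self.ms_regression,
             self.f_regression, self.f_tab_regression),
            ("Residue", self.ss_residual, self.df_residual, self.ms_residual, None, None),
            ("Lack of fit", self.ss_lof, self.df_lof, self.ms_lof, self.f_lof, self.f_tab_lof),
            ("Pure error", self.ss_pure_error, self.df_pure_error, self.ms_pure_error, None, None),
            ("Total", self.ss_total, self.df_total, None, None, None),
        ]
        return pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F_calc", "F_tab"])

    def to_dict(self) -> dict:
        d = {
            "response_name": self.response_name,
            "p_threshold": self.p_threshold,
            "verdict": self.verdict,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "f_regression": self.f_regression,
            "f_tab_regression": self.f_tab_regression,
            "f_lof": self.f_lof if np.isfinite(self.f_lof) else None,
            "f_tab_lof": self.f_tab_lof if self.df_lof > 0 and self.df_pure_error > 0 else None,
        }
        for name in ("regression", "residual", "lof", "pure_error"):
            d[f"ss_{name}"] = getattr(self, f"ss_{name}")
            d[f"df_{name}"] = getattr(self, f"df_{name}")
        d["ss_total"] = self.ss_total
        d["df_total"] = self.df_total
        return d


def model_verdict(table: AnovaTable) -> str:
    """Combined Fisher verdict.

    Significant requires strict ``F_regression > F_tab``; predictive requires
    strict ``F_lof < F_tab`` (a non-significant lack of fit).  Zero pure-error
    mean square leaves predictivity undeterminable.
    """
    if table.df_regression < 1:
        return "not_significant"
    if not table.f_regression > table.f_tab_regression:
        return "not_significant"
    ms_pe = table.ms_pure_error
    if not np.isfinite(ms_pe) or ms_pe == 0.0:
        return "predictivity_undeterminable"
    if table.f_lof < table.f_tab_lof:
        return "significant_and_predictive"
    return "significant_not_predictive"


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded coordinates (>= 2 members)."""
    keys: dict[tuple, list[int]] = {}
    for i, row in enumerate(np.round(coded, 10)):
        keys.setdefault(tuple(row), []).append(i)
    return [np.array(v) for v in keys.values() if len(v) >= 2]


def anova_decompose(
    model: QuadraticModel,
    design: DesignMatrix,
    y,
    p_threshold: float = 0.1,
) -> AnovaTable:
    """Decompose variation around the mean for a fitted model.

    Pure error comes from within-group deviations of replicated runs (the
    center replicates, for a standard CCRD); lack of fit is the residual
    remainder.  Requires at least one replicated group.
    """
    y = np.asarray(y, dtype=float)
    coded = design.coded_array()
    if y.shape[0] != coded.shape[0]:
        raise InputError(f"y has {y.shape[0]} entries for {coded.shape[0]} runs")
    groups = _replicate_groups(coded)
    if not groups:
        raise ExtoptError("pure error unavailable: design has no replicated runs")

    X = build_model_matrix(coded, model.terms)
    beta = np.array([t.coefficient for t in model.terms])
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_reg = ss_tot - ss_res
    n = y.shape[0]
    p = len(model.terms)

    ss_pe = sum(float(np.sum((y[g] - y[g].mean()) ** 2)) for g in groups)
    df_pe = int(sum(len(g) - 1 for g in groups))
    ss_lof = max(ss_res - ss_pe, 0.0)
    df_lof = (n - p) - df_pe

    return AnovaTable(
        ss_regression=ss_reg,
        df_regression=p - 1,
        ss_residual=ss_res,
        df_residual=n - p,
        ss_lof=ss_lof,
        df_lof=df_lof,
        ss_pure_error=ss_pe,
        df_pure_error=df_pe,
        p_threshold=p_threshold,
        response_name=model.response_name,
    )
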