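"""Quantile-anchored linear model coupling histone-tag change to
transcription change.

The line of best fit is anchored at three summary points — the (min,
median, max) of the tag-change values paired with the corresponding
order statistics of the transcription-change values — and fit by
ordinary least squares over those three anchors (a min–max chord mode,
which ignores the median anchor, is available). Genes whose residual
from the line lies within one standard deviation of all residuals are
"included", and Spearman correlations are computed on the included genes
separately for up- and down-regulated genes within strata (all BvCR vs
survivin-positive BvCR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def minmax_line(x, y, anchor_mode: str = "summary", fit_mode: str = "ols"):
    """Slope, intercept and the three quantile anchors for (x, y).

    ``anchor_mode="summary"`` pairs the (min, median, max) of x with the
    (min, median, max) of y; ``"argpoint"`` instead takes the actual
    (x_i, y_i) observations at the argmin/argmedian/argmax of x.
    ``fit_mode="ols"`` least-squares the three anchors; ``"chord"`` draws
    the exact line through the min and max anchors.

    Returns ``(slope, intercept, anchors)`` with anchors ordered by x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.min() == x.max():
        raise ValueError("x is constant; the anchor line is undefined")
    if anchor_mode == "summary":
        qx = np.array([x.min(), np.median(x), x.max()])
        qy = np.array([y.min(), np.median(y), y.max()])
    elif anchor_mode == "argpoint":
        order = np.argsort(x, kind="stable")
        idx = [order[0], order[x.size // 2], order[-1]]
        qx = x[idx]
        qy = y[idx]
    else:
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    anchors = list(zip(qx.tolist(), qy.tolist()))
    if fit_mode == "ols":
        slope, intercept = np.polyfit(qx, qy, 1)
    elif fit_mode == "chord":
        slope = (qy[2] - qy[0]) / (qx[2] - qx[0])
        intercept = qy[0] - slope * qx[0]
    else:
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    return float(slope), float(intercept), anchors


def residual_filter(x, y, slope: float, intercept: float, k: float = 1.0):
    """Inclusion flags and residual SD under the 1-SD rule.

    Residuals are ``y - (slope*x + intercept)``; the SD is the population
    SD over all genes and a gene is included iff |residual| <= k*SD.
    Returns ``(included, residuals, residual_sd)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    residuals = y - (slope * x + intercept)
    residual_sd = float(residuals.std(ddof=0))
    included = np.abs(residuals) <= k * residual_sd + 1e-12
    return included, residuals, residual_sd


def subgroup_spearman(
    x, y, included=None, strata: dict | None = None, min_n: int = 3,
    split_direction: bool = True,
) -> pd.DataFrame:
    """Spearman rho per (direction x stratum) cell over included genes.

    Direction labels genes up/down by the sign of the transcription
    change y (zeros fall in neither group); ``split_direction=False``
    reports a single "any" direction over all included genes instead.
    ``strata`` maps stratum name to a boolean mask (default a single
    "all" stratum). Cells with fewer than ``min_n`` genes report NaN.
    Ranks are tie-corrected and p is two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    included = np.ones_like(x, bool) if included is None else np.asarray(included, bool)
    strata = {"all": np.ones_like(x, bool)} if strata is None else strata
    if split_direction:
        directions = (("up", y > 0), ("down", y < 0))
    else:
        directions = (("any", np.ones_like(x, bool)),)
    rows = []
    for direction, dmask in directions:
        for name, smask in strata.items():
            mask = included & dmask & np.asarray(smask, bool)
            n = int(mask.sum())
            if n >= min_n:
                rho, p = stats.spearmanr(x[mask], y[mask])
                rho, p = float(rho), float(p)
            else:
                rho, p = np.nan, np.nan
            rows.append({"direction": direction, "stratum": name,
                         "n": n, "rho": rho, "p": p})
    return pd.DataFrame(rows)


class QuantileAnchoredLine(BaseEstimator, RegressorMixin):
    """Min–max quantile-anchored line with the 1-SD inclusion rule.

    Parameters
    ----------
    anchor_mode : "summary" or "argpoint"
        How the three anchors pair x and y order statistics.
    fit_mode : "ols" or "chord"
        Least squares over the three anchors, or the exact min–max chord.
    residual_direction : "y" or "x"
        Whether residuals (and the inclusion rule) are measured in the
        transcription variable y or back-projected through the line onto
        the tag-change variable x.
    k : float
        Inclusion half-width in residual standard deviations.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_ : the fitted line
    anchors_ : the three (x, y) anchor points, ordered by x
    residuals_, residual_sd_, included_ : the inclusion rule's outputs
    """

    def __init__(self, anchor_mode: str = "summary", fit_mode: str = "ols",
                 residual_direction: str = "y", k: float = 1.0):
        self.anchor_mode = anchor_mode
        self.fit_mode = fit_mode
        self.residual_direction = residual_direction
        self.k = k

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        self.slope_, self.intercept_, self.anchors_ = minmax_line(
            x, y, self.anchor_mode, self.fit_mode)
        if self.residual_direction == "y":
            self.included_, self.residuals_, self.residual_sd_ = residual_filter(
                x, y, self.slope_, self.intercept_, self.k)
        elif self.residual_direction == "x":
            if self.slope_ == 0:
                raise ValueError("zero slope: x-direction residuals undefined")
            inv_slope = 1.0 / self.slope_
            inv_intercept = -self.intercept_ / self.slope_
            self.included_, self.residuals_, self.residual_sd_ = residual_filter(
                y, x, inv_slope, inv_intercept, self.k)
        else:
            raise ValueError(f"unknown residual_direction {self.residual_direction!r}")
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def correlations(self, X, y, strata: dict | None = None,
                     split_direction: bool = True) -> pd.DataFrame:
        """Subgroup Spearman correlations over the included genes."""
        check_is_fitted(self, "included_")
        return subgroup_spearman(np.asarray(X, float).reshape(-1),
                                 np.asarray(y, float).reshape(-1),
                                 self.included_, strata,
                                 split_direction=split_direction)
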