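"""Weighted logistic exposure-response curve for %HSD versus Lnight.

The model for the proportion of highly sleep-disturbed respondents at a
5-dB noise class centered at NL dB is the two-parameter logistic

    p(NL) = 1 / (1 + exp(a - b * NL)),

fitted to the pooled class proportions p_i = hsd_sum_i / n_i with weights
equal to the class sample sizes n_i. Two estimation methods are provided:

* ``wnls`` (default): minimize sum_i n_i (p_i - p(NL_i))^2 by
  derivative-based least squares started from the weighted logit-linear
  closed form. This is the method that reproduces the published reference
  coefficients and is the documented default.
* ``binomial_glm``: maximize the binomial likelihood with successes
  round(hsd_sum_i) of n_i trials (a grouped logistic regression), via
  statsmodels GLM.

The results object carries the estimates, their covariance (local curvature
at the optimum), the n-weighted R^2, predictions on the percent scale, and
delta-method confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

METHODS = ("wnls", "binomial_glm")


class FitError(RuntimeError):
    pass


class InsufficientDataError(FitError):
    pass


def logistic_pct(nl, a: float, b: float):
    """Model curve on the percent scale: 100 / (1 + exp(a - b*nl))."""
    return 100.0 * special.expit(b * np.asarray(nl, dtype=float) - a)


class ExposureResponseModel:
    """Weighted logistic dose-response model on pooled class proportions.

    Parameters
    ----------
    nl : array-like
        Class centers, dB.
    proportion : array-like
        Observed HSD proportions per class, in [0, 1].
    weights : array-like
        Class sample sizes (fit weights).
    source : str, optional
        Label carried through to the results ("RT", "CR", "HR", ...).
    """

    def __init__(self, nl, proportion, weights, source: str | None = None):
        self.nl = np.asarray(nl, dtype=float)
        self.proportion = np.asarray(proportion, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self.source = source
        if not (len(self.nl) == len(self.proportion) == len(self.weights)):
            raise ValueError("nl, proportion and weights must have equal length")
        if len(self.nl) < 3:
            raise InsufficientDataError(
                f"need at least 3 classes to fit, got {len(self.nl)}"
            )
        if np.any((self.proportion < 0) | (self.proportion > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @classmethod
    def from_pooled(cls, pooled: pd.DataFrame, source: str) -> "ExposureResponseModel":
        """Build from a ``pool_by_source`` table, using only include_in_fit rows."""
        sub = pooled[(pooled["source"] == source) & pooled["include_in_fit"]]
        return cls(
            nl=sub["nl_center"],
            proportion=sub["hsd_sum"] / sub["n"],
            weights=sub["n"],
            source=source,
        )

    # -- estimation ---------------------------------------------------------

    def _start(self) -> np.ndarray:
        """Weighted logit-linear regression as the optimizer start."""
        eps = 1e-4
        y = special.logit(np.clip(self.proportion, eps, 1 - eps))
        X = np.column_stack([np.ones_like(self.nl), self.nl])
        sw = np.sqrt(self.weights)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return np.array([-beta[0], beta[1]])  # (a, b)

    def fit(self, method: str = "wnls", xtol: float = 1e-12) -> "ExposureResponseResults":
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if method == "wnls":
            params, cov = self._fit_wnls(xtol)
        else:
            params, cov = self._fit_glm()
        return ExposureResponseResults(model=self, method=method, params=params, cov_params=cov)

    def _fit_wnls(self, xtol: float) -> tuple[np.ndarray, np.ndarray]:
        sw = np.sqrt(self.weights)

        def resid(theta):
            a, b = theta
            return sw * (self.proportion - special.expit(b * self.nl - a))

        sol = optimize.least_squares(
            resid, x0=self._start(), method="lm", xtol=xtol, ftol=xtol, gtol=xtol
        )
        if not sol.success:
            raise FitError(f"least-squares fit did not converge: {sol.message}")
        m, k = len(self.nl), 2
        dof = m - k
        rss = float(np.sum(sol.fun**2))
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular curvature at the optimum: {exc}") from exc
        return sol.x, cov

    def _fit_glm(self) -> tuple[np.ndarray, np.ndarray]:
        import statsmodels.api as sm

        successes = np.round(self.proportion * self.weights)
        endog = np.column_stack([successes, self.weights - successes])
        exog = np.column_stack([np.ones_like(self.nl), self.nl])
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        if not res.converged:
            raise FitError("binomial GLM did not converge")
        beta = np.asarray(res.params)  # (intercept, slope) on the logit scale
        params = np.array([-beta[0], beta[1]])
        cov_beta = np.asarray(res.cov_params())
        # a = -intercept: flip the sign of the cross-covariance
        J = np.array([[-1.0, 0.0], [0.0, 1.0]])
        return params, J @ cov_beta @ J.T


@dataclass
class ExposureResponseResults:
    """Fitted exposure-response curve with uncertainty and diagnostics."""

    model: ExposureResponseModel
    method: str
    params: np.ndarray  # (a, b)
    cov_params: np.ndarray = field(repr=False)

    @property
    def intercept_a(self) -> float:
        return float(self.params[0])

    @property
    def slope_b(self) -> float:
        return float(self.params[1])

    @property
    def source(self) -> str | None:
        return self.model.source

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted proportions at the model's class centers."""
        return special.expit(self.slope_b * self.model.nl - self.intercept_a)

    @property
    def rsquared_weighted(self) -> float:
        """n-weighted coefficient of determination on class proportions."""
        return weighted_r2(
            self.model.proportion, self.fittedvalues, self.model.weights
        )

    # -- prediction ---------------------------------------------------------

    def predict_pct(self, nl):
        """Estimated %HSD at night level(s) ``nl``."""
        return logistic_pct(nl, self.intercept_a, self.slope_b)

    def conf_band_pct(self, nl, level: float = 0.95):
        """Delta-method confidence band on the percent scale.

        The normal interval is formed on the linear predictor
        eta = b*nl - a (gradient (-1, nl)) and mapped through the logistic,
        so lower < point < upper always holds.
        """
        nl = np.atleast_1d(np.asarray(nl, dtype=float))
        if not np.all(np.isfinite(self.cov_params)):
            raise FitError("covariance unavailable; cannot form a confidence band")
        grad = np.column_stack([-np.ones_like(nl), nl])
        var_eta = np.einsum("ij,jk,ik->i", grad, self.cov_params, grad)
        if np.any(var_eta < 0):
            raise FitError("covariance is not positive semi-definite")
        z = stats.norm.ppf(0.5 + level / 2.0)
        eta = self.slope_b * nl - self.intercept_a
        half = z * np.sqrt(var_eta)
        lo = 100.0 * special.expit(eta - half)
        hi = 100.0 * special.expit(eta + half)
        return lo, hi

    def prediction_table(self, start: float = 33, stop: float = 78, step: float = 5, level: float = 0.95) -> pd.DataFrame:
        """%HSD with confidence band on a dB grid (5-dB classes or 1-dB curve)."""
        grid = np.arange(start, stop + step / 2.0, step)
        lo, hi = self.conf_band_pct(grid, level)
        return pd.DataFrame(
            {
                "nl": grid,
                "pct_hsd": self.predict_pct(grid),
                "lci": lo,
                "uci": hi,
            }
        )

    # -- reporting ----------------------------------------------------------

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def summary(self) -> str:
        se = self.bse()
        lines = [
            f"Weighted logistic exposure-response fit"
            + (f" [{self.source}]" if self.source else ""),
            f"  method: {self.method}   classes: {len(self.model.nl)}   "
            f"total n: {self.model.weights.sum():.0f}",
            f"  %HSD(NL) = 100 / (1 + exp(a - b*NL))",
            f"  a = {self.intercept_a:.4f}  (SE {se[0]:.4f})",
            f"  b = {self.slope_b:.4f} per dB  (SE {se[1]:.4f})",
            f"  weighted R^2 = {self.rsquared_weighted:.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "method": self.method,
            "intercept_a": self.intercept_a,
            "slope_b": self.slope_b,
            "cov_params": self.cov_params.tolist(),
            "rsquared_weighted": self.rsquared_weighted,
        }

    def plot(self, ax=None, observed: bool = True, level: float = 0.95, step: float = 1.0):
        """Curve with confidence band (and observed class proportions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo_nl, hi_nl = float(self.model.nl.min()) - 2, float(self.model.nl.max()) + 2
        tab = self.prediction_table(lo_nl, hi_nl, step, level)
        ax.plot(tab["nl"], tab["pct_hsd"], "-", label=self.source or "fit")
        ax.plot(tab["nl"], tab["lci"], ":", color="gray")
        ax.plot(tab["nl"], tab["uci"], ":", color="gray")
        if observed:
            ax.scatter(self.model.nl, 100 * self.model.proportion, color="gray", zorder=3)
        ax.set_xlabel("Lnight class center, dB")
        ax.set_ylabel("%HSD")
        return ax


def weighted_r2(p_obs, p_fit, weights) -> float:
    """1 - sum w (p - p_hat)^2 / sum w (p - p_bar_w)^2 with weighted-mean null."""
    p_obs = np.asarray(p_obs, dtype=float)
    p_fit = np.asarray(p_fit, dtype=float)
    w = np.asarray(weights, dtype=float)
    p_bar = np.sum(w * p_obs) / np.sum(w)
    sst = float(np.sum(w * (p_obs - p_bar) ** 2))
    if sst == 0.0:
        raise FitError("zero weighted variance: R^2 undefined")
    return 1.0 - float(np.sum(w * (p_obs - p_fit) ** 2)) / sst


def fit_all_sources(pooled: pd.DataFrame, method: str = "wnls") -> dict[str, ExposureResponseResults]:
    """Fit one curve per source present in a pooled table."""
    out = {}
    for source in pd.unique(pooled["source"]):
        sub = pooled[(pooled["source"] == source) & pooled["include_in_fit"]]
        if len(sub) >= 3:
            out[source] = ExposureResponseModel.from_pooled(pooled, source).fit(method)
    return out
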