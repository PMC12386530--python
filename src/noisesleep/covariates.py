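"""Individual-level logistic regression of binarized HSD on exposure and demographics.

After the fractional HSD scores are binarized by the randomized split, a
maximum-likelihood logistic regression relates the binary label to the
continuous night level (per dB), gender (female vs male), age band (40-59
and 60+ vs under 40) and survey period (2010 onward vs before). The results
object reports Wald standard errors, two-sided p-values, odds ratios with
95% confidence intervals, the rank-based AUC of the fitted probabilities,
and the per-5-dB odds ratio exp(5b) conventionally quoted for exposure.

Records with "no answer" gender or age are dropped listwise by default
(n is reported); optionally they are kept as their own indicator levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PERIOD_BREAK_YEAR = 2010

#: design terms in reporting order (without optional no-answer levels)
BASE_TERMS = ("const", "nl", "female", "age_40to59", "age_60plus", "after_2010")


class DesignError(ValueError):
    pass


class SeparationError(RuntimeError):
    pass


def auc_rank(labels, scores) -> float:
    """Rank-based ROC area: Mann-Whitney U / (n1 * n0), ties counted half."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def fit_seed_ensemble(
    df: pd.DataFrame,
    score_col: str = "hsd_score",
    seeds=range(10),
    group_col: str = "dataset_id",
    **from_df_kwargs,
) -> pd.DataFrame:
    """Refit the covariate model under several binarization seeds.

    The randomized split injects extra randomness into the estimates; this
    reports its size. Returns a per-term table of the mean and SD of the
    coefficients across seeds.
    """
    from .scoring import binarize_hsd

    runs = []
    for seed in seeds:
        labels = binarize_hsd(df[score_col], seed=int(seed), group_keys=df[group_col])
        res = DisturbanceLogitModel.from_dataframe(
            df.assign(hsd=labels), **from_df_kwargs
        ).fit()
        runs.append(res.params)
    stacked = pd.concat(runs, axis=1)
    return pd.DataFrame({"mean": stacked.mean(axis=1), "sd": stacked.std(axis=1)})


class DisturbanceLogitModel:
    """Logistic regression of binary HSD labels on NL and demographic terms.

    Build it with :meth:`from_dataframe` from scored, binarized microdata, or
    directly from a design matrix (DataFrame of regressors incl. ``const``)
    and a label vector.
    """

    def __init__(self, exog: pd.DataFrame, endog: pd.Series, n_dropped: int = 0):
        if "const" not in exog.columns:
            raise DesignError("design matrix must include a 'const' column")
        self.exog = exog
        self.endog = endog.astype(int)
        self.n_dropped = int(n_dropped)
        for col in exog.columns:
            if col == "const":
                continue
            if exog[col].nunique() == 1 and col != "nl":
                raise DesignError(f"term {col!r} is constant (empty reference or level)")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "hsd",
        period_break: int = PERIOD_BREAK_YEAR,
        missing: str = "drop",
    ) -> "DisturbanceLogitModel":
        """Assemble the standard design from microdata with a binary label column.

        missing="drop": listwise-delete rows with no-answer gender or age;
        missing="category": keep them, adding gender_no_answer /
        age_no_answer indicator terms.
        """
        if missing not in ("drop", "category"):
            raise ValueError("missing must be 'drop' or 'category'")
        work = df
        n_dropped = 0
        if missing == "drop":
            keep = (df["gender"] != "no_answer") & (df["age_band"] != "no_answer")
            n_dropped = int((~keep).sum())
            work = df.loc[keep]
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "nl": work["lnight_db"].astype(float),
                "female": (work["gender"] == "female").astype(float),
                "age_40to59": (work["age_band"] == "40to59").astype(float),
                "age_60plus": (work["age_band"] == "60plus").astype(float),
                "after_2010": (work["survey_year"] >= period_break).astype(float),
            },
            index=work.index,
        )
        if missing == "category":
            exog["gender_no_answer"] = (work["gender"] == "no_answer").astype(float)
            exog["age_no_answer"] = (work["age_band"] == "no_answer").astype(float)
        return cls(exog, work[label_col], n_dropped=n_dropped)

    def fit(self) -> "DisturbanceLogitResults":
        import statsmodels.api as sm

        y = self.endog.to_numpy()
        if y.min() == y.max():
            raise DesignError("labels are all identical; nothing to fit")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, self.exog.to_numpy()).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise SeparationError("logistic fit did not converge (separation?)")
        return DisturbanceLogitResults(self, res)


@dataclass
class DisturbanceLogitResults:
    model: DisturbanceLogitModel
    _res: object

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.model.exog.columns)

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.params), index=self.terms)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.bse), index=self.terms)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.pvalues), index=self.terms)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """OR = exp(coef) with Wald confidence interval, per non-intercept term."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        rows = []
        for term in self.terms:
            if term == "const":
                continue
            beta, se = self.params[term], self.bse[term]
            rows.append(
                {
                    "term": term,
                    "estimate": beta,
                    "se": se,
                    "p": self.pvalues[term],
                    "or": np.exp(beta),
                    "lci": np.exp(beta - z * se),
                    "uci": np.exp(beta + z * se),
                }
            )
        return pd.DataFrame(rows).set_index("term")

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return np.asarray(self._res.predict())

    @property
    def auc(self) -> float:
        return auc_rank(self.model.endog.to_numpy(), self.fitted_probabilities)

    def or_per_5db(self) -> float:
        """Odds ratio for a 5-dB increase in night level: exp(5b)."""
        return float(np.exp(5.0 * self.params["nl"]))

    def summary(self) -> str:
        tab = self.odds_ratios()
        lines = [
            f"HSD logistic regression  (n = {self.nobs}, "
            f"dropped no-answer = {self.model.n_dropped})",
            f"  AUC = {self.auc:.3f}   OR per 5 dB = {self.or_per_5db():.2f}",
            f"  const = {self.params['const']:.3f}",
        ]
        for term, row in tab.iterrows():
            star = " *" if row["p"] < 0.05 else ""
            lines.append(
                f"  {term:<16} beta={row['estimate']:+.3f} SE={row['se']:.3f} "
                f"p={row['p']:.3f} OR={row['or']:.3f} "
                f"[{row['lci']:.3f}, {row['uci']:.3f}]{star}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Reporting table: term, estimate, SE, p, OR, LCI, UCI (+ const row)."""
        tab = self.odds_ratios().reset_index()
        const = pd.DataFrame(
            [
                {
                    "term": "const",
                    "estimate": self.params["const"],
                    "se": self.bse["const"],
                    "p": self.pvalues["const"],
                    "or": np.exp(self.params["const"]),
                    "lci": np.nan,
                    "uci": np.nan,
                }
            ]
        )
        out = pd.concat([tab, const], ignore_index=True)
        out["auc"] = self.auc
        out["n"] = self.nobs
        return out
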