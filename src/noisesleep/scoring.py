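"""Cutoff-standardized HSD scoring of ordinal sleep-disturbance responses.

Surveys rate sleep disturbance on 2-, 4- or 5-point ordinal scales. To pool
them, each scale is mapped onto the unit response continuum: category i of a
k-point scale occupies the interval [(i-1)/k, i/k]. With a "high disturbance"
cutoff at fraction ``c`` of the continuum (~0.72 by convention, following the
annoyance literature), category i receives the converted score

    score_i = |[(i-1)/k, i/k]  intersect  [c, 1]| / (1/k),

i.e. the fraction of the category lying above the cutoff. At c = 0.72 this
yields (0, 0, 0, 0.4, 1) for a 5-point scale and (0, 0.56) for a 2-point
scale. The single 4-point frequency scale instead counts only its top
category (effective cutoff 75%), flagged ``top_only``.

A respondent's HSD score is the converted score of their answer, averaged
(default) or maximized over the answered items. %HSD at an exposure level is
the sum of these fractional scores over respondents, divided by their count.

For individual-level logistic regression, fractional scores are turned into
binary labels by a seeded randomized split: within each group of identical
score value s, exactly round(s*m) of the m respondents are labeled highly
sleep-disturbed (so a score of 0.4 sends 40% of that category to the HSD
group, and 0.56 of 2-point "yes" answers likewise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import DatasetMeta, Registry, default_registry

DEFAULT_CUTOFF = 0.72
COMBINE_RULES = ("mean", "max")


class ScoringError(ValueError):
    pass


def cutoff_scores(n_points: int, cutoff: float = DEFAULT_CUTOFF, top_only: bool = False) -> tuple[float, ...]:
    """Converted HSD score for each category of a k-point scale.

    Parameters
    ----------
    n_points : int
        Number of scale categories, >= 2.
    cutoff : float
        High-disturbance cutoff as a fraction of the response continuum,
        in (0, 1].
    top_only : bool
        If True, ignore the overlap formula and count only the top category
        (score 1), all others 0.

    Examples
    --------
    >>> cutoff_scores(5, 0.72)
    (0.0, 0.0, 0.0, 0.4, 1.0)
    >>> cutoff_scores(2, 0.72)
    (0.0, 0.56)
    """
    if n_points < 2:
        raise ScoringError(f"n_points must be >= 2, got {n_points}")
    if not 0 < cutoff <= 1:
        raise ScoringError(f"cutoff must be in (0, 1], got {cutoff}")
    if top_only:
        return tuple(0.0 if i < n_points else 1.0 for i in range(1, n_points + 1))
    width = 1.0 / n_points
    scores = []
    for i in range(1, n_points + 1):
        lo, hi = (i - 1) * width, i * width
        overlap = max(0.0, min(hi, 1.0) - max(lo, cutoff))
        scores.append(round(overlap / width, 12))
    return tuple(scores)


@dataclass(frozen=True)
class ScaleScheme:
    """A response scale with its converted scores under a cutoff."""

    n_points: int
    cutoff: float = DEFAULT_CUTOFF
    top_only: bool = False
    converted_scores: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "converted_scores", cutoff_scores(self.n_points, self.cutoff, self.top_only)
        )

    @classmethod
    def for_dataset(cls, meta: DatasetMeta, cutoff: float = DEFAULT_CUTOFF) -> "ScaleScheme":
        return cls(meta.scale_points, cutoff, top_only=meta.top_only)

    def score_category(self, category: int) -> float:
        if not 1 <= category <= self.n_points:
            raise ScoringError(f"category {category} out of range 1..{self.n_points}")
        return self.converted_scores[category - 1]


def score_items(categories, scheme: ScaleScheme, combine: str = "mean") -> float:
    """Combine one respondent's item categories into a single HSD score.

    ``categories`` may contain None/NaN for unanswered items; at least one
    answered item is required. The worked reference case: categories (5, 4)
    on the 5-point scheme, mean combination -> (1 + 0.4)/2 = 0.7.
    """
    if combine not in COMBINE_RULES:
        raise ScoringError(f"combine must be one of {COMBINE_RULES}")
    vals = [scheme.score_category(int(c)) for c in categories if c is not None and not pd.isna(c)]
    if not vals:
        raise ScoringError("respondent has no answered items")
    return float(np.mean(vals) if combine == "mean" else np.max(vals))


def score_respondents(
    df: pd.DataFrame,
    registry: Registry | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    combine: str = "mean",
) -> pd.Series:
    """Vectorized HSD score for every microdata row.

    Returns a float Series aligned with ``df`` (name ``hsd_score``). Rows
    without any answered item get NaN; drop them via the analysis-set filter
    before aggregation.

    For two-point surveys with most-disturbing-source selection, respondents
    who did not select the target source are recorded in category 1 and thus
    score 0, which is exactly the intended "no disturbance by this source".
    """
    if combine not in COMBINE_RULES:
        raise ScoringError(f"combine must be one of {COMBINE_RULES}")
    registry = registry if registry is not None else default_registry()
    item_cols = [c for c in df.columns if c.startswith("item_")]
    out = pd.Series(np.nan, index=df.index, name="hsd_score", dtype=float)
    for dataset_id, grp in df.groupby("dataset_id", sort=False):
        scheme = ScaleScheme.for_dataset(registry[dataset_id], cutoff)
        lut = np.concatenate([[np.nan], scheme.converted_scores])  # 1-based lookup
        cats = grp[item_cols].to_numpy(dtype=float)
        scored = np.full_like(cats, np.nan)
        answered = ~np.isnan(cats)
        scored[answered] = lut[cats[answered].astype(int)]
        with np.errstate(invalid="ignore"):
            if combine == "mean":
                combined = np.nanmean(scored, axis=1)
            else:
                combined = np.nanmax(scored, axis=1)
        out.loc[grp.index] = combined
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def binarize_hsd(
    scores: pd.Series,
    seed: int,
    mode: str = "exact_split",
    group_keys: pd.Series | None = None,
) -> pd.Series:
    """Convert fractional HSD scores to binary labels by randomized split.

    Parameters
    ----------
    scores : Series of floats in [0, 1]
    seed : int
        Seeds the random assignment; the result is deterministic given it.
    mode : {"exact_split", "bernoulli"}
        ``exact_split`` labels exactly round(s*m) of each group of m
        respondents sharing score value s (seeded shuffle decides which);
        ``bernoulli`` labels each respondent independently with
        probability s.
    group_keys : Series, optional
        Grouping for the exact split (typically dataset_id, so each survey's
        response categories are split internally); default: one global group.

    Scores of exactly 0 or 1 always map to 0 or 1.
    """
    s = pd.to_numeric(scores, errors="raise").astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ScoringError("scores must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = pd.Series(0, index=s.index, dtype=int)
    if mode == "bernoulli":
        labels[:] = (rng.random(len(s)) < s.to_numpy()).astype(int)
        labels[s == 0.0] = 0
        labels[s == 1.0] = 1
        return labels
    if mode != "exact_split":
        raise ScoringError(f"unknown mode {mode!r}")
    keys = group_keys if group_keys is not None else pd.Series("all", index=s.index)
    frame = pd.DataFrame({"score": s, "key": keys})
    for (_, value), grp in frame.groupby(["key", "score"], sort=True):
        if value == 0.0:
            continue
        m = len(grp)
        k = m if value == 1.0 else min(m, _round_half_up(value * m))
        chosen = rng.permutation(grp.index.to_numpy())[:k]
        labels.loc[chosen] = 1
    return labels
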