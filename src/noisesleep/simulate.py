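"""Synthetic survey microdata with known dose-response structure.

The generator emulates the harmonized Japanese detached-house survey
collection: per-source exposure-class frequencies, the registry's mix of
2/4/5-point datasets, the observed gender/age composition, and a true
logistic dose-response on the HSD-probability scale,

    pi = expit(b * Lnight - a + demographic/period log-odds offsets).

Ordinal categories are drawn so that the *converted-score expectation*
equals pi under each dataset's scale scheme (the analysis consumes only
converted scores, so matching their expectation is the minimal faithful
structure): on 5-point scales the top category gets probability rho*pi and
category 4 gets (1-rho)*pi/0.4 (so P(top) + 0.4*P(4) = pi); on 2-point
scales the affirmative probability is pi/0.56 (capped at 1, with a warning);
on the top-only 4-point scale the top category gets probability pi. An
ordered-logit draw is available as a realism option; it does not preserve
the expectation identity and is never the tested default.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .aggregation import load_demographic_mix, load_nl_frequencies
from .registry import Registry, default_registry
from .survey import ITEM_COLUMNS, MANDATORY_COLUMNS

#: published reference dose-response parameters per source (a, b)
REFERENCE_PARAMS = {
    "RT": (5.6431, 0.0602),
    "CR": (5.6302, 0.0528),
    "HR": (6.3245, 0.0766),
}

#: how sub-cutoff probability mass is spread over the non-scoring categories
_LOW_CAT_SPLIT_5PT = (0.6, 0.3, 0.1)  # categories 1..3 of a 5-point scale
_LOW_CAT_SPLIT_4PT = (0.5, 0.3, 0.2)  # categories 1..3 of the 4-point scale


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults reproduce the observed study conditions for the chosen source:
    exposure-class mix and demographic mix from the packaged aggregate
    fixtures, dataset/scale mix proportional to the registry sample sizes,
    and the published dose-response parameters. Demographic and period
    effects default to zero.
    """

    n_respondents: int
    source: str = "RT"
    true_a: float | None = None
    true_b: float | None = None
    nl_distribution: dict[int, float] | None = None
    scale_mix: dict[int, float] | None = None
    beta_female: float = 0.0
    beta_age4059: float = 0.0
    beta_age60: float = 0.0
    beta_after2010: float = 0.0
    period_mix: float | None = None
    top_split: float = 0.5  # rho: share of pi carried by the top 5-pt category
    ordinal_model: str = "expectation"  # or "ordered_logit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_a is None:
            self.true_a = REFERENCE_PARAMS[self.source][0]
        if self.true_b is None:
            self.true_b = REFERENCE_PARAMS[self.source][1]
        if self.ordinal_model not in ("expectation", "ordered_logit"):
            raise ValueError("ordinal_model must be 'expectation' or 'ordered_logit'")
        if not 0 < self.top_split < 1:
            raise ValueError("top_split must be in (0, 1)")


def _normalized(d: dict) -> tuple[np.ndarray, np.ndarray]:
    keys = np.array(list(d.keys()))
    w = np.array([float(d[k]) for k in keys])
    return keys, w / w.sum()


def _default_nl_distribution(source: str) -> dict[int, float]:
    freq = load_nl_frequencies()
    sub = freq[freq["source"] == source]
    return dict(zip(sub["nl_center"].astype(int), sub["count"].astype(float)))


def _demographic_probs(source: str, kind: str) -> dict[str, float]:
    mix = load_demographic_mix()
    sub = mix[(mix["source"] == source) & (mix["kind"] == kind)]
    return dict(zip(sub["category"], sub["count"].astype(float)))


def _pick_datasets(cfg: SimConfig, registry: Registry, rng) -> list:
    """Per-respondent dataset metadata, by scale mix then sample-size weight."""
    metas = registry.for_source(cfg.source)
    if not metas:
        raise ValueError(f"no registry datasets for source {cfg.source!r}")
    if cfg.scale_mix is None:
        keys, p = _normalized({m.dataset_id: m.sample_size for m in metas})
        ids = rng.choice(keys, size=cfg.n_respondents, p=p)
    else:
        by_scale = {}
        for m in metas:
            by_scale.setdefault(m.scale_points, []).append(m)
        mix = {k: v for k, v in cfg.scale_mix.items() if k in by_scale}
        if not mix:
            raise ValueError("scale_mix has no scale available for this source")
        scales, p = _normalized(mix)
        drawn = rng.choice(scales, size=cfg.n_respondents, p=p)
        ids = np.empty(cfg.n_respondents, dtype=object)
        for k, group in by_scale.items():
            mask = drawn == k
            if mask.any():
                gk, gp = _normalized({m.dataset_id: m.sample_size for m in group})
                ids[mask] = rng.choice(gk, size=int(mask.sum()), p=gp)
    lookup = {m.dataset_id: m for m in registry}
    return [lookup[i] for i in ids]


def _category_matrix_expectation(pi: np.ndarray, meta, rho: float, rng) -> np.ndarray:
    """Draw one item's categories so E[converted score] = pi."""
    n = len(pi)
    k = meta.scale_points
    if k == 2:
        p_yes = pi / 0.56
        if np.any(p_yes > 1):
            warnings.warn(
                "pi/0.56 exceeds 1 for some respondents; affirmative probability capped",
                RuntimeWarning,
                stacklevel=3,
            )
            p_yes = np.minimum(p_yes, 1.0)
        return np.where(rng.random(n) < p_yes, 2, 1)
    if k == 4:  # top-only scoring: only category 4 counts
        probs = np.zeros((n, 4))
        probs[:, 3] = pi
        rest = 1.0 - pi
        for j, share in enumerate(_LOW_CAT_SPLIT_4PT):
            probs[:, j] = rest * share
        return _draw_rows(probs, rng)
    # 5-point: P(5) + 0.4 P(4) = pi
    p_top = rho * pi
    p_four = (1.0 - rho) * pi / 0.4
    over = p_top + p_four > 1.0
    # fallback split that still satisfies the identity (needs pi >= 0.4)
    p_top = np.where(over, (pi - 0.4) / 0.6, p_top)
    p_four = np.where(over, 1.0 - p_top, p_four)
    probs = np.zeros((n, 5))
    probs[:, 4] = p_top
    probs[:, 3] = p_four
    rest = 1.0 - p_top - p_four
    for j, share in enumerate(_LOW_CAT_SPLIT_5PT):
        probs[:, j] = rest * share
    return _draw_rows(probs, rng)


def _category_matrix_ordered_logit(pi: np.ndarray, meta, rng) -> np.ndarray:
    """Realism option: cumulative-logit draw around the latent predictor."""
    k = meta.scale_points
    eta = np.log(pi / (1 - pi))
    # thresholds relative to the top-category logit; top category keeps P = pi
    taus = {2: [0.0], 4: [-2.0, -1.0, 0.0], 5: [-3.0, -1.5, -0.5, 0.0]}[k]
    u = rng.random(len(pi))
    cat = np.ones(len(pi), dtype=int)
    for tau in taus:
        cat += (u < expit(eta - tau)).astype(int)
    return cat


def _draw_rows(probs: np.ndarray, rng) -> np.ndarray:
    """Vectorized categorical draw: one category (1-based) per row."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random((len(probs), 1)) * cum[:, -1:]
    return 1 + (u > cum[:, :-1]).sum(axis=1)


def generate_survey(cfg: SimConfig, registry: Registry | None = None):
    """Draw respondent microdata plus its ground truth.

    Returns ``(df, truth)``: a microdata DataFrame in the standard schema and
    a dict with the true parameters and the per-respondent HSD probability.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_respondents

    metas = _pick_datasets(cfg, registry, rng)
    dataset_ids = np.array([m.dataset_id for m in metas])

    nl_dist = cfg.nl_distribution or _default_nl_distribution(cfg.source)
    centers, p = _normalized(nl_dist)
    bin_center = rng.choice(centers, size=n, p=p).astype(float)
    lo = np.maximum(30.0, bin_center - 2.5)
    hi = bin_center + 2.5
    # round to 0.01 dB but keep strictly inside the class after rounding
    lnight = np.clip(np.round(lo + rng.random(n) * (hi - lo), 2), lo, hi - 0.01)

    gk, gp = _normalized(_demographic_probs(cfg.source, "gender"))
    gender = rng.choice(gk, size=n, p=gp)
    ak, ap = _normalized(_demographic_probs(cfg.source, "age_band"))
    age = rng.choice(ak, size=n, p=ap)

    if cfg.period_mix is None:
        y0 = np.array([m.year_start for m in metas])
        y1 = np.array([m.year_end for m in metas])
        year = y0 + rng.integers(0, y1 - y0 + 1)
    else:
        year = np.where(rng.random(n) < cfg.period_mix, 2015, 2005)

    eta = (
        cfg.true_b * lnight
        - cfg.true_a
        + cfg.beta_female * (gender == "female")
        + cfg.beta_age4059 * (age == "40to59")
        + cfg.beta_age60 * (age == "60plus")
        + cfg.beta_after2010 * (year >= 2010)
    )
    pi = expit(eta)

    items = np.full((n, len(ITEM_COLUMNS)), np.nan)
    for dataset_id in np.unique(dataset_ids):
        mask = dataset_ids == dataset_id
        meta = registry[dataset_id]
        k_items = len(meta.items)
        for j in range(k_items):
            if cfg.ordinal_model == "expectation":
                cats = _category_matrix_expectation(pi[mask], meta, cfg.top_split, rng)
            else:
                cats = _category_matrix_ordered_logit(pi[mask], meta, rng)
            items[mask, j] = cats

    df = pd.DataFrame(
        {
            "respondent_id": [f"R{i:07d}" for i in range(n)],
            "dataset_id": dataset_ids,
            "source": cfg.source,
            "dwelling": "detached",
            "gender": gender,
            "age_band": age,
            "survey_year": year.astype(int),
            "lnight_db": lnight,
            "lden_db": np.nan,
            "scale_points": [m.scale_points for m in metas],
        }
    )
    for j, col in enumerate(ITEM_COLUMNS):
        df[col] = items[:, j]
    df = df[list(MANDATORY_COLUMNS) + list(ITEM_COLUMNS)]

    truth = {
        "true_a": cfg.true_a,
        "true_b": cfg.true_b,
        "betas": {
            "female": cfg.beta_female,
            "age_40to59": cfg.beta_age4059,
            "age_60plus": cfg.beta_age60,
            "after_2010": cfg.beta_after2010,
        },
        "seed": cfg.seed,
        "source": cfg.source,
        "pi": pi.tolist(),
    }
    return df, truth


def write_survey(cfg: SimConfig, csv_path, truth_path=None, registry: Registry | None = None) -> pd.DataFrame:
    """Generate and write microdata CSV (+ optional ground-truth JSON)."""
    from .survey import write_microdata

    df, truth = generate_survey(cfg, registry)
    write_microdata(df, csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh)
    return df


def generate_pooled_bins(
    true_a: float,
    true_b: float,
    n_per_bin: dict[int, int] | None = None,
    seed: int = 0,
    source: str = "RT",
) -> pd.DataFrame:
    """Binomial pooled classes on a known curve, in ``pool_by_source`` layout.

    With ``n_per_bin=None`` the observed per-class sample sizes for the
    source are used (suppressed classes included, so the <50 exclusion rule
    is exercised too).
    """
    if n_per_bin is None:
        n_per_bin = {k: int(v) for k, v in _default_nl_distribution(source).items()}
    rng = np.random.default_rng(seed)
    rows = []
    for center, n in sorted(n_per_bin.items()):
        p = float(expit(true_b * center - true_a))
        hsd = int(rng.binomial(n, p)) if n > 0 else 0
        rows.append(
            {
                "source": source,
                "nl_center": int(center),
                "hsd_sum": float(hsd),
                "n": int(n),
                "pct_hsd": 100.0 * hsd / n if n else np.nan,
                "include_in_fit": n >= 50,
            }
        )
    return pd.DataFrame(rows)


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
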