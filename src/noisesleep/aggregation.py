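"""%HSD aggregation tables with small-sample suppression.

Builds the per-dataset %HSD-by-NL table (cells with fewer than 25 respondents
suppressed), the pooled per-source fitting input (classes with fewer than 50
respondents flagged out of the fit), and the demographic frequency table.
%HSD is computed from the fractional converted scores (summed scores / n),
not from the randomized binary labels, which exist only for the
individual-level regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exposure import NL_CENTERS
from .registry import _packaged

MIN_N_DATASET_CELL = 25
MIN_N_FIT = 50


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}; score and bin the data first")


def pct_hsd_by_dataset(df: pd.DataFrame, min_n: int = MIN_N_DATASET_CELL) -> pd.DataFrame:
    """Per-dataset %HSD by NL class, integer percent, suppressed below min_n.

    ``df`` must carry ``hsd_score`` and ``nl_center`` columns. Suppressed
    cells (and empty ones) are NaN.
    """
    _require(df, ("hsd_score", "nl_center", "dataset_id"))
    g = df.groupby(["dataset_id", "nl_center"])["hsd_score"].agg(["sum", "count"])
    pct = pd.Series(
        np.where(g["count"] >= min_n, _round_half_up(100.0 * g["sum"] / g["count"]), np.nan),
        index=g.index,
    )
    table = pct.unstack("nl_center")
    return table.reindex(columns=[c for c in NL_CENTERS if c in table.columns])


def pool_by_source(df: pd.DataFrame, min_n: int = MIN_N_FIT) -> pd.DataFrame:
    """Pooled fitting input: one row per (source, NL class).

    Columns: source, nl_center, hsd_sum (summed fractional scores), n,
    pct_hsd (unrounded, NaN when n is below ``min_n``), include_in_fit.
    """
    _require(df, ("hsd_score", "nl_center", "source"))
    g = (
        df.groupby(["source", "nl_center"])["hsd_score"]
        .agg(hsd_sum="sum", n="count")
        .reset_index()
    )
    g["n"] = g["n"].astype(int)
    g["include_in_fit"] = g["n"] >= min_n
    g["pct_hsd"] = np.where(g["include_in_fit"], 100.0 * g["hsd_sum"] / g["n"], np.nan)
    g["nl_center"] = g["nl_center"].astype(int)
    return g[["source", "nl_center", "hsd_sum", "n", "pct_hsd", "include_in_fit"]]


def demographic_table(df: pd.DataFrame) -> pd.DataFrame:
    """Gender and age-band frequencies (count and within-source percent) per source."""
    frames = []
    for kind in ("gender", "age_band"):
        counts = df.groupby(["source", kind]).size().rename("count").reset_index()
        counts = counts.rename(columns={kind: "category"})
        counts["kind"] = kind
        total = counts.groupby("source")["count"].transform("sum")
        counts["pct"] = 100.0 * counts["count"] / total
        frames.append(counts)
    out = pd.concat(frames, ignore_index=True)
    return out[["source", "kind", "category", "count", "pct"]]


def load_pooled_reference() -> pd.DataFrame:
    """The packaged pooled %HSD-by-NL aggregate for the Japanese detached-house
    survey collection (the published fitting input), in ``pool_by_source``
    layout. ``hsd_sum`` is reconstructed as pct_hsd * n / 100."""
    df = pd.read_csv(_packaged("pooled_hsd_by_nl.csv"), comment="#")
    df["pct_hsd"] = df["pct_hsd"].astype(float)
    df["hsd_sum"] = df["pct_hsd"] * df["n"] / 100.0
    df["include_in_fit"] = True
    return df[["source", "nl_center", "hsd_sum", "n", "pct_hsd", "include_in_fit"]]


def load_nl_frequencies() -> pd.DataFrame:
    """Packaged per-source NL class frequencies (all classes, incl. suppressed)."""
    return pd.read_csv(_packaged("nl_frequencies.csv"), comment="#")


def load_demographic_mix() -> pd.DataFrame:
    """Packaged demographic composition (gender, age band) per source."""
    return pd.read_csv(_packaged("demographic_mix.csv"), comment="#")
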