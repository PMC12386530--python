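"""Respondent microdata: CSV schema, validated loading, and analysis-set filters.

Microdata are held as a pandas DataFrame with one row per respondent x noise
source. Combined-exposure surveys therefore contribute two rows per person
(same respondent_id, different dataset_id). Mandatory columns:

    respondent_id, dataset_id, source, dwelling, gender, age_band,
    survey_year, lnight_db, lden_db, scale_points, item_1 .. item_k

Item columns hold 1-based ordinal categories; empty cells mean the item was
not asked / not answered. ``lnight_db`` is the A-weighted equivalent level
over the night window (22:00-07:00); it may be absent when only ``lden_db``
was supplied, in which case :mod:`noisesleep.exposure` resolves it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import Registry, RegistryError, default_registry

MAX_ITEMS = 5
ITEM_COLUMNS = tuple(f"item_{i}" for i in range(1, MAX_ITEMS + 1))
MANDATORY_COLUMNS = (
    "respondent_id",
    "dataset_id",
    "source",
    "dwelling",
    "gender",
    "age_band",
    "survey_year",
    "lnight_db",
    "lden_db",
    "scale_points",
)

DWELLINGS = ("detached", "apartment", "other", "unknown")
GENDERS = ("male", "female", "no_answer")
AGE_BANDS = ("under40", "40to59", "60plus", "no_answer")

#: analysis-set inclusion threshold on the night level, inclusive
MIN_LNIGHT_DB = 30.0


class SchemaError(ValueError):
    """A mandatory microdata column is missing."""


class ValidationError(ValueError):
    """A row violates the microdata contract (bad category, bad code, ...)."""


def load_microdata(path, registry: Registry | None = None) -> pd.DataFrame:
    """Read and validate a respondent microdata CSV.

    Parameters
    ----------
    path : str, Path or file-like
        CSV with the documented column schema; empty string = absent value.
    registry : Registry, optional
        Dataset registry used to validate dataset ids, source/scale
        consistency and response-category ranges. Defaults to the packaged
        registry.

    Returns
    -------
    DataFrame
        One validated row per respondent record.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the error names the column).
    ValidationError
        For an unparseable mandatory field or an out-of-range response
        category; the message carries the offending row index.
    RegistryError
        For a dataset_id absent from the registry.
    """
    df = pd.read_csv(
        path,
        dtype={"respondent_id": str, "dataset_id": str, "source": str},
        keep_default_na=False,
        na_values=[""],
    )
    return validate_microdata(df, registry)


def validate_microdata(df: pd.DataFrame, registry: Registry | None = None) -> pd.DataFrame:
    registry = registry if registry is not None else default_registry()
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")

    out = df.copy()
    for col in ("lnight_db", "lden_db"):
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {col!r} is not numeric: {exc}") from exc
    for col in ("survey_year", "scale_points"):
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {col!r} is not integer: {exc}") from exc

    for col, allowed in (("dwelling", DWELLINGS), ("gender", GENDERS), ("age_band", AGE_BANDS)):
        bad = ~out[col].isin(allowed)
        if bad.any():
            pos = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"row {out.index[pos]}: invalid {col} {out[col].iloc[pos]!r}")

    unknown = set(out["dataset_id"]) - {m.dataset_id for m in registry}
    if unknown:
        raise RegistryError(f"unknown dataset_id(s): {sorted(unknown)}")

    item_cols = [c for c in out.columns if c.startswith("item_")]
    for c in item_cols:
        out[c] = pd.to_numeric(out[c], errors="coerce")

    # per-dataset consistency and category bounds
    for dataset_id, grp in out.groupby("dataset_id", sort=False):
        meta = registry[dataset_id]
        if not (grp["source"] == meta.source).all():
            raise ValidationError(f"dataset {dataset_id}: source column disagrees with registry")
        if not (grp["scale_points"] == meta.scale_points).all():
            raise ValidationError(
                f"dataset {dataset_id}: scale_points column disagrees with registry"
            )
        k = meta.scale_points
        for c in item_cols:
            vals = grp[c].dropna()
            bad = vals[(vals < 1) | (vals > k) | (vals != vals.round())]
            if len(bad):
                i = int(bad.index[0])
                raise ValidationError(
                    f"row {i}: response category {bad.iloc[0]:g} out of range 1..{k} "
                    f"({c}, dataset {dataset_id})"
                )
    return out


def write_microdata(df: pd.DataFrame, path) -> None:
    """Write microdata so that ``load_microdata`` round-trips it."""
    out = df.copy()
    cols = [c for c in MANDATORY_COLUMNS] + [c for c in out.columns if c.startswith("item_")]
    out = out[cols]
    out.to_csv(path, index=False, na_rep="")


def has_any_response(df: pd.DataFrame) -> pd.Series:
    """True where a row has at least one answered sleep-disturbance item."""
    item_cols = [c for c in df.columns if c.startswith("item_")]
    if not item_cols:
        return pd.Series(False, index=df.index)
    return df[item_cols].notna().any(axis=1)


def filter_analysis_set(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analysis-set inclusion rules.

    Keeps respondents in detached houses with a resolved night level of at
    least 30 dB and at least one answered sleep-disturbance item. Returns the
    retained rows plus a per-reason exclusion tally (a row is counted once,
    under the first failing rule in the order below).
    """
    not_detached = df["dwelling"] != "detached"
    low_or_missing = ~(df["lnight_db"] >= MIN_LNIGHT_DB)  # NaN excluded too
    no_response = ~has_any_response(df)

    reason = np.select(
        [not_detached, low_or_missing, no_response],
        ["not_detached", "below_30db_or_missing", "no_response"],
        default="",
    )
    counts = {
        "not_detached": int((reason == "not_detached").sum()),
        "below_30db_or_missing": int((reason == "below_30db_or_missing").sum()),
        "no_response": int((reason == "no_response").sum()),
    }
    kept = df.loc[reason == ""]
    return kept, counts
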