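"""End-to-end orchestration: load -> filter -> exposure -> score -> aggregate -> fit -> regress.

``run_pipeline`` executes the whole analysis on a microdata CSV (or, in
fit-only mode, on the packaged pooled aggregate) and writes the standard
output bundle: demographic table, per-dataset %HSD table, pooled fitting
input, curve coefficients JSON, prediction tables with confidence bands,
covariate-regression table, and a run log carrying the seed and a config
hash so reruns are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregation, curve, exposure, scoring, survey
from .covariates import DisturbanceLogitModel
from .registry import default_registry

log = logging.getLogger("noisesleep")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage: {stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    microdata: str | None = None  # None => fit-only on the packaged aggregate
    outdir: str = "noisesleep_out"
    cutoff: float = scoring.DEFAULT_CUTOFF
    combine_rule: str = "mean"
    fit_method: str = "wnls"
    min_n_dataset: int = aggregation.MIN_N_DATASET_CELL
    min_n_fit: int = aggregation.MIN_N_FIT
    seed: int = 0
    exposure_configs: dict = field(default_factory=dict)
    regress: bool = True

    def __post_init__(self) -> None:
        if self.min_n_dataset <= 0 or self.min_n_fit <= 0:
            raise ValueError("suppression thresholds must be positive")

    def hash(self) -> str:
        # outdir does not affect the analysis; keep it out of the identity
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("exposure_configs", "outdir")
        }
        payload["exposure_configs"] = {
            k: repr(v) for k, v in sorted(self.exposure_configs.items())
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("load")
def _load(cfg, registry):
    return survey.load_microdata(cfg.microdata, registry)


@_stage("exposure")
def _exposure(cfg, df):
    return exposure.resolve_lnight(df, cfg.exposure_configs)


@_stage("filter")
def _filter(df):
    return survey.filter_analysis_set(df)


@_stage("score")
def _score(cfg, df, registry):
    df = df.copy()
    df["hsd_score"] = scoring.score_respondents(df, registry, cfg.cutoff, cfg.combine_rule)
    df["nl_center"] = exposure.nl_bins(df["lnight_db"])
    return df


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured analysis; returns the result bundle as a dict
    of DataFrames/objects and writes everything under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    meta = {"config_hash": cfg.hash(), "seed": cfg.seed}
    bundle: dict = {}

    if cfg.microdata is not None:
        df = _load(cfg, registry)
        df = _exposure(cfg, df)
        kept, removed = _filter(df)
        log.info("analysis set: %d kept, removed %s", len(kept), removed)
        scored = _score(cfg, kept, registry)

        bundle["demographics"] = aggregation.demographic_table(scored)
        bundle["pct_hsd_by_dataset"] = aggregation.pct_hsd_by_dataset(
            scored, cfg.min_n_dataset
        )
        pooled = aggregation.pool_by_source(scored, cfg.min_n_fit)
        bundle["removed"] = removed
        bundle["scored"] = scored
    else:
        pooled = aggregation.load_pooled_reference()
    bundle["pooled"] = pooled

    try:
        fits = curve.fit_all_sources(pooled, cfg.fit_method)
    except Exception as exc:
        raise PipelineError("fit", exc) from exc
    bundle["fits"] = fits

    predictions = []
    for source, res in fits.items():
        sub = pooled[(pooled["source"] == source) & pooled["include_in_fit"]]
        lo, hi = int(sub["nl_center"].min()), int(sub["nl_center"].max())
        for step in (5, 1):
            tab = res.prediction_table(lo, hi, step)
            tab.insert(0, "source", source)
            tab.insert(1, "step_db", step)
            predictions.append(tab)
    bundle["predictions"] = pd.concat(predictions, ignore_index=True)

    if cfg.regress and cfg.microdata is not None:
        try:
            scored = bundle["scored"]
            labels = scoring.binarize_hsd(
                scored["hsd_score"], seed=cfg.seed, group_keys=scored["dataset_id"]
            )
            tables = []
            for source, grp in scored.assign(hsd=labels).groupby("source"):
                res = DisturbanceLogitModel.from_dataframe(grp).fit()
                tab = res.to_frame()
                tab.insert(0, "source", source)
                tables.append(tab)
            bundle["covariate_model"] = pd.concat(tables, ignore_index=True)
        except Exception as exc:
            raise PipelineError("regress", exc) from exc

    _write_bundle(bundle, outdir, meta, cfg)
    return bundle


def _write_bundle(bundle: dict, outdir: Path, meta: dict, cfg: RunConfig) -> None:
    header = f"# config_hash={meta['config_hash']} seed={meta['seed']}\n"

    def write_csv(name, df, index=False):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=index)

    for name, key, index in (
        ("demographics.csv", "demographics", False),
        ("pct_hsd_by_dataset.csv", "pct_hsd_by_dataset", True),
        ("pooled_hsd.csv", "pooled", False),
        ("predictions.csv", "predictions", False),
        ("covariate_model.csv", "covariate_model", False),
    ):
        if key in bundle:
            write_csv(name, bundle[key], index)

    coeffs = {src: res.to_dict() for src, res in bundle.get("fits", {}).items()}
    with open(outdir / "curve_coefficients.json", "w") as fh:
        json.dump({**meta, "fits": coeffs}, fh, indent=2)

    runlog = dict(meta)
    runlog["config"] = {
        k: v
        for k, v in dataclasses.asdict(cfg).items()
        if k not in ("exposure_configs", "outdir")  # outdir = where this log sits
    }
    if "removed" in bundle:
        runlog["excluded"] = bundle["removed"]
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2)
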