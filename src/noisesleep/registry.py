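"""Dataset registry: metadata for the harmonized socio-acoustic survey collection.

Each entry describes one dataset (one noise source rated by one survey):
which source it targets (road traffic RT, conventional railway CR, or
high-speed/Shinkansen railway HR), the survey years, the ordinal response
scale used for the sleep-disturbance items, and the item list. Two-point
("yes/no") surveys that first asked respondents to pick the single most
disturbing source are flagged ``two_point_source_selection``: a respondent
who did not pick the target source is recorded as not disturbed by it.
The single 4-point (frequency-scale) dataset is flagged ``top_only``:
only its top category counts as highly sleep-disturbed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

SOURCES = ("RT", "CR", "HR")
VALID_SCALE_POINTS = (2, 4, 5)


class RegistryError(KeyError):
    """Raised for a dataset_id that is not in the registry."""


@dataclass(frozen=True)
class DatasetMeta:
    dataset_id: str
    source: str
    year_start: int
    year_end: int
    sample_size: int
    scale_points: int
    items: tuple[str, ...]
    two_point_source_selection: bool = False
    top_only: bool = False

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.scale_points not in VALID_SCALE_POINTS:
            raise ValueError(f"scale_points must be one of {VALID_SCALE_POINTS}")
        if not self.items:
            raise ValueError("items must be non-empty")


@dataclass(frozen=True)
class Registry:
    """Immutable mapping dataset_id -> :class:`DatasetMeta`."""

    entries: dict[str, DatasetMeta] = field(default_factory=dict)

    def __getitem__(self, dataset_id: str) -> DatasetMeta:
        try:
            return self.entries[dataset_id]
        except KeyError:
            raise RegistryError(f"dataset_id {dataset_id!r} not in registry") from None

    def __contains__(self, dataset_id: str) -> bool:
        return dataset_id in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def for_source(self, source: str) -> list[DatasetMeta]:
        return [m for m in self if m.source == source]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_id": m.dataset_id,
                "source": m.source,
                "year_start": m.year_start,
                "year_end": m.year_end,
                "sample_size": m.sample_size,
                "scale_points": m.scale_points,
                "items": ";".join(m.items),
                "two_point_source_selection": m.two_point_source_selection,
                "top_only": m.top_only,
            }
            for m in self
        ]
        return pd.DataFrame(rows)


def _packaged(name: str):
    return importlib.resources.files("noisesleep.data").joinpath(name)


def load_registry(path=None) -> Registry:
    """Load the dataset registry (packaged fixture by default)."""
    src = path if path is not None else _packaged("registry.csv")
    df = pd.read_csv(src, comment="#")
    entries = {}
    for row in df.itertuples(index=False):
        meta = DatasetMeta(
            dataset_id=row.dataset_id,
            source=row.source,
            year_start=int(row.year_start),
            year_end=int(row.year_end),
            sample_size=int(row.sample_size),
            scale_points=int(row.scale_points),
            items=tuple(str(row.items).split(";")),
            two_point_source_selection=_as_bool(row.two_point_source_selection),
            top_only=_as_bool(row.top_only),
        )
        entries[meta.dataset_id] = meta
    return Registry(entries)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)


def default_registry() -> Registry:
    """The packaged registry of the 22 harmonized survey datasets."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_registry()
    return _DEFAULT


_DEFAULT: Registry | None = None
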