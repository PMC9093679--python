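"""Survey data containers and CSV / config I/O."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SurveyDataset", "RunConfig", "read_survey_csv", "write_survey_csv"]

_FAMILIES = ("continuous", "binary", "count")


@dataclass
class SurveyDataset:
    """A rectangular respondent-by-item response matrix with its factor map.

    ``item_factor_map`` assigns every item (column) to exactly one factor
    (simple structure).  Categorical Likert codes are carried as integers and
    used as-is numerically downstream; ``category_range`` records the legal
    code range (inclusive).
    """

    responses: np.ndarray
    item_factor_map: np.ndarray
    family: str = "continuous"
    category_range: tuple[int, int] | None = None
    item_names: list[str] | None = None
    person_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if np.any(~np.isfinite(self.responses.astype(float))):
            raise ValueError("missing or non-finite cells are not supported")
        self.item_factor_map = np.asarray(self.item_factor_map, dtype=np.int64)
        if self.item_factor_map.shape != (self.responses.shape[1],):
            raise ValueError("item_factor_map must assign each item to one factor")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.category_range is not None:
            lo, hi = self.category_range
            if self.responses.min() < lo or self.responses.max() > hi:
                raise ValueError("responses outside the declared category range")
        if self.item_names is None:
            self.item_names = [f"item{j + 1}" for j in range(self.n_items)]
        if self.person_ids is None:
            self.person_ids = np.arange(self.n_persons)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_factors(self) -> int:
        return int(self.item_factor_map.max()) + 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_names)
        df.insert(0, "person_id", self.person_ids)
        return df


@dataclass
class RunConfig:
    """End-to-end run settings: data location, factor map, model and MCMC knobs."""

    data: str | None = None
    factors: dict[str, list[str]] = field(default_factory=dict)
    reverse_coded: list[str] = field(default_factory=list)
    family: str = "continuous"
    id_column: str | None = None
    chains: int = 3
    iterations: int = 12_000
    burnin: int = 6_000
    threshold: float = 0.5
    seed: int = 0
    standardize_indices: bool = True
    fit_baseline: bool = False
    priors: dict = field(default_factory=dict)
    out: str | None = None

    def __post_init__(self) -> None:
        mapped = [it for items in self.factors.values() for it in items]
        if len(mapped) != len(set(mapped)):
            raise ValueError("an item may be mapped to only one factor (simple structure)")
        extra = set(self.reverse_coded) - set(mapped)
        if extra:
            raise ValueError(f"reverse-coded items not in the factor map: {sorted(extra)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**payload)


def read_survey_csv(path: str | Path, config: RunConfig) -> SurveyDataset:
    """Read a respondent-by-item CSV and apply the config's factor map.

    Reverse-coded items are recoded as ``min + max - y`` on the item's observed
    code range.  Unmapped columns are ignored with a warning; missing cells are
    an error (missing data is unsupported).
    """
    df = pd.read_csv(path)
    person_ids = (df[config.id_column].to_numpy() if config.id_column
                  else np.arange(len(df)))
    mapped: list[str] = [it for items in config.factors.values() for it in items]
    missing_cols = [c for c in mapped if c not in df.columns]
    if missing_cols:
        raise ValueError(f"mapped items missing from the CSV header: {missing_cols}")
    ignored = [c for c in df.columns if c not in mapped and c != config.id_column]
    if ignored:
        warnings.warn(f"ignoring unmapped columns: {ignored}", stacklevel=2)

    sub = df[mapped]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing cells in rows {bad}; missing data is unsupported")

    responses = sub.to_numpy()
    lo, hi = responses.min(), responses.max()
    for item in config.reverse_coded:
        j = mapped.index(item)
        responses[:, j] = lo + hi - responses[:, j]

    fmap = np.concatenate([
        np.full(len(items), k) for k, items in enumerate(config.factors.values())
    ])
    cat_range = (int(lo), int(hi)) if config.family != "count" else None
    return SurveyDataset(
        responses=responses,
        item_factor_map=fmap,
        family=config.family,
        category_range=cat_range,
        item_names=mapped,
        person_ids=person_ids,
    )


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)
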