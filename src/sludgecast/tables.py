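"""Core tabular containers shared across the pipeline.

Count and abundance tables are plain :class:`pandas.DataFrame` objects
(samples as rows, taxa as columns); the environmental metadata table carries
per-factor annotations alongside its values and therefore gets a small
dataclass wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The five factor categories used to organise environmental metadata.
FACTOR_CATEGORIES = (
    "climate",
    "design/operation",
    "inflow",
    "effluent",
    "physicochemical",
)


@dataclass
class EnvTable:
    """Environmental metadata: samples x factors plus per-factor annotations.

    Parameters
    ----------
    values
        Samples as rows, factors as columns. Numeric columns are floats with
        NaN marking missing cells; binary columns hold string tokens until
        :func:`sludgecast.preprocess.encode_binary` maps them to {0, 1}.
    meta
        Indexed by factor id with columns ``category`` (one of
        :data:`FACTOR_CATEGORIES`) and ``is_binary`` (bool).
    normalized
        True once every factor has been mapped onto the 1-100 range.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("factor ids of values and meta disagree")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("sample and factor ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def factor_ids(self) -> list[str]:
        return list(self.values.columns)

    def binary_factors(self) -> list[str]:
        return list(self.meta.index[self.meta["is_binary"].astype(bool)])

    def copy_with(self, values: pd.DataFrame, **kw) -> "EnvTable":
        return replace(self, values=values, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic-data generators.

    ``driver_map`` maps a driven taxon id to a list of
    ``(factor_id, effect_size, link)`` tuples; ``group_map`` maps taxon id to
    a functional-group label.
    """

    seed: int
    migration_rate: float | None = None
    metacommunity_abundance: pd.Series | None = None
    driver_map: dict[str, list[tuple[str, float, str]]] = field(default_factory=dict)
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metacommunity_abundance is not None:
            total = float(self.metacommunity_abundance.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"metacommunity abundances sum to {total}, not 1")
        for taxon, drivers in self.driver_map.items():
            for _, effect, _ in drivers:
                if not np.isfinite(effect):
                    raise ValueError(f"non-finite effect size for {taxon}")


def check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a count table: non-negative integers, unique ids."""
    if counts.empty:
        raise ValueError("empty count table")
    if not counts.index.is_unique or not counts.columns.is_unique:
        raise ValueError("sample and taxon ids must be unique")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative counts")
    return counts


def check_abundance(abund: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Validate a relative-abundance table: rows sum to 1 within ``atol``."""
    sums = abund.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > atol]
    if len(bad):
        raise ValueError(f"rows not summing to 1: {list(bad.index[:5])}")
    return abund
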