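"""Tabular containers shared across the pipeline.

Thin, validated wrappers over pandas DataFrames: a ``SampleTable``
holds integer feature counts (OTUs or ESUs) with per-sample metadata,
and a ``DietMatrix`` holds per-sample prey proportions after predator
self-reads and non-prey taxa have been removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SampleTable", "DietMatrix", "REQUIRED_METADATA"]

#: metadata columns every sample must carry
REQUIRED_METADATA = ("predator_species", "period")

VALID_PERIODS = frozenset({"drift", "postdrift"})


@dataclass
class SampleTable:
    """Integer count table (samples x features) with sample metadata.

    ``counts`` rows and ``metadata`` rows are aligned on the sample
    index. Metadata must provide ``predator_species`` and ``period``
    (one of ``drift``/``postdrift``); ``date``, ``substrate`` and
    ``site`` are optional but carried through when present.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("sample and feature labels must be unique")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(REQUIRED_METADATA) - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if not counts.index.equals(self.metadata.index):
            if set(counts.index) != set(self.metadata.index):
                raise ValueError("counts and metadata sample sets differ")
            self.metadata = self.metadata.loc[counts.index]
        bad = set(self.metadata["period"]) - VALID_PERIODS
        if bad:
            raise ValueError(f"unknown periods: {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def features(self) -> pd.Index:
        return self.counts.columns

    def totals(self) -> pd.Series:
        """Per-sample total read counts."""
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "SampleTable":
        return SampleTable(
            counts=self.counts.loc[sample_ids],
            metadata=self.metadata.loc[sample_ids],
        )


@dataclass
class DietMatrix:
    """Per-sample prey-ESU proportions.

    Each row lies on the simplex over prey ESUs; ``prey_reads`` records
    the per-sample prey read count used as the denominator, and
    ``metadata`` is aligned on the sample index.
    """

    proportions: pd.DataFrame
    prey_reads: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        props = self.proportions.astype(float)
        if len(props):
            rows = props.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                bad = rows.index[~np.isclose(rows, 1.0, atol=1e-9)]
                raise ValueError(f"diet rows do not sum to 1: {list(bad)[:5]}")
            if (props.to_numpy() < 0).any():
                raise ValueError("diet proportions must be nonnegative")
        self.proportions = props
        self.prey_reads = self.prey_reads.loc[props.index]
        self.metadata = self.metadata.loc[props.index]

    @property
    def samples(self) -> pd.Index:
        return self.proportions.index

    @property
    def esus(self) -> pd.Index:
        return self.proportions.columns

    def counts(self) -> pd.DataFrame:
        """Back out prey read counts (proportions x denominator), rounded."""
        raw = self.proportions.mul(self.prey_reads, axis=0)
        return raw.round().astype(np.int64)
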