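"""Core tabular containers: relative-abundance and read-count matrices.

Both containers are thin wrappers around a pandas DataFrame indexed by taxon
(rows) and sample (columns).  The canonical abundance unit everywhere inside
the package is a *fraction* in [0, 1]; dialects that store percentages are
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "CountMatrix"]


def _check_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class AbundanceMatrix:
    """Taxa × samples table of relative abundances (fractions in [0, 1]).

    Parameters
    ----------
    data:
        DataFrame with taxon identifiers as the row index and sample
        identifiers as columns.  Values are fractions of each sample total.
    region_of:
        Optional mapping from sample identifier to region label, used for
        site-presence annotation of network nodes.
    label:
        Optional OTU-definition label carried over from mothur files
        (e.g. ``"0.03"``); not used by any algorithm.
    """

    data: pd.DataFrame
    region_of: Mapping[str, str] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if vals.size and (vals < -1e-12).any():
            bad = self.data.stack()[self.data.stack() < -1e-12].index[0]
            raise ValueError(f"negative abundance at {bad}")
        if vals.size and (vals > 1 + 1e-9).any():
            bad = self.data.stack()[self.data.stack() > 1 + 1e-9].index[0]
            raise ValueError(
                f"abundance above 1 at {bad}; values must be fractions, not percents"
            )
        if self.region_of is not None:
            samples = set(self.data.columns)
            unknown = set(self.region_of) - samples
            if unknown:
                raise ValueError(f"region_of refers to unknown samples: {sorted(unknown)}")

    # -- convenience ------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_for(self, taxon: str) -> np.ndarray:
        return self.data.loc[taxon].to_numpy()

    def max_abundance(self) -> pd.Series:
        """Per-taxon maximum relative abundance over all samples."""
        return self.data.max(axis=1)


@dataclass
class CountMatrix:
    """Taxa × samples table of non-negative integer read counts."""

    data: pd.DataFrame
    label: str | None = None

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        if arr.size and not np.issubdtype(np.asarray(arr).dtype, np.integer):
            flo = np.asarray(arr, dtype=float)
            if not np.allclose(flo, np.round(flo)):
                raise ValueError("counts must be integers")
        self.data = self.data.astype(np.int64)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def to_relative(self) -> AbundanceMatrix:
        """Convert counts to per-sample fractions (columns sum to 1)."""
        totals = self.sample_totals()
        if (totals == 0).any():
            empty = totals.index[totals == 0][0]
            raise ValueError(f"sample {empty!r} has zero reads")
        return AbundanceMatrix(self.data / totals)
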