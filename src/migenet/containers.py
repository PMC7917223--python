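"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIDES = ("microbe", "gene")


class AlignmentError(ValueError):
    """Sample columns of two matrices do not match (ids or order)."""


@dataclass
class OmicsMatrix:
    """A named feature x sample numeric matrix with a side tag.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns;
        values must be numeric and finite.
    side
        Which side of the bipartite system the features belong to:
        ``"microbe"`` or ``"gene"``.
    """

    data: pd.DataFrame
    side: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("matrix values must be numeric")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Column subset preserving the requested order."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[:, sample_ids], self.side)

    def check_aligned(self, other: "OmicsMatrix") -> None:
        """Raise AlignmentError unless sample id sequences are identical."""
        if self.sample_ids != other.sample_ids:
            raise AlignmentError(
                "sample columns differ between matrices "
                f"({self.n_samples} vs {other.n_samples} samples; "
                "ids and order must match exactly)"
            )
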