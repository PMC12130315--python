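"""Core pairwise-matrix containers shared across the pipeline.

A :class:`DistanceMatrix` is the interchange type between the modality
distance layer, harmonization and fusion: a square symmetric matrix of
non-negative dissimilarities over a fixed entity index, with ``NaN``
marking pairs for which a modality has no information (typically because
one of the two entities is not covered by that modality at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "FusedSimilarityMatrix"]

_SYM_TOL = 1e-9


def _as_ids(ids) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        raise ValueError("entity ids must be unique")
    return out


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with a missing-pair mask.

    Parameters
    ----------
    ids:
        Entity identifiers, one per row/column.
    values:
        Square float array; ``NaN`` marks missing pairs. Must be symmetric
        within ``1e-9`` with zero diagonal for non-missing entities.
    bounded:
        True if the metric is confined to ``[0, 1]`` (set-overlap and
        similarity-derived metrics); drives boundary handling during
        harmonization.
    """

    ids: list[str]
    values: np.ndarray
    bounded: bool = False

    def __post_init__(self) -> None:
        self.ids = _as_ids(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("values must be square and match the id index")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if np.isfinite(asym) and asym > _SYM_TOL:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3g})")
        # NaN patterns must be symmetric too
        if not np.array_equal(np.isnan(v), np.isnan(v.T)):
            raise ValueError("missing-value pattern is not symmetric")
        v = (v + v.T) / 2.0
        present = ~np.all(np.isnan(v) | np.eye(len(self.ids), dtype=bool), axis=1)
        diag = np.diag(v)
        bad = present & ~np.isnan(diag) & (np.abs(diag) > _SYM_TOL)
        if bad.any():
            raise ValueError("non-zero diagonal for present entities")
        d = v.copy()
        idx = np.arange(len(self.ids))
        d[idx, idx] = np.where(present, 0.0, np.nan)
        finite = d[~np.isnan(d)]
        if finite.size:
            if finite.min() < -_SYM_TOL:
                raise ValueError("distances must be non-negative")
            if self.bounded and finite.max() > 1.0 + _SYM_TOL:
                raise ValueError("bounded metric has values outside [0, 1]")
        if self.bounded:
            d = np.clip(d, 0.0, 1.0)
        self.values = d

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a pair has a value."""
        return ~np.isnan(self.values)

    @property
    def present(self) -> np.ndarray:
        """Boolean array over entities: has any off-diagonal value."""
        off = self.mask & ~np.eye(self.n, dtype=bool)
        return off.any(axis=1) | (self.n == 1)

    def condensed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i, j, value) including NaN entries."""
        iu = np.triu_indices(self.n, k=1)
        return iu[0], iu[1], self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bounded: bool = False) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column ids differ")
        return cls(list(df.index), df.to_numpy(dtype=float), bounded=bounded)


@dataclass
class FusedSimilarityMatrix:
    """Weighted-average similarity in [0, 1] per entity pair.

    ``weight_sums`` records, per pair, the total modality weight that
    contributed (pairs missing a modality are averaged over the rest).
    Diagonal similarity is 1 by convention.
    """

    ids: list[str]
    values: np.ndarray
    weight_sums: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = _as_ids(self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("values must be square and match the id index")
        if np.nanmax(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError("fused similarity not symmetric")
        v = (v + v.T) / 2.0
        if np.nanmin(v) < -_SYM_TOL or np.nanmax(v) > 1 + _SYM_TOL:
            raise ValueError("fused similarity outside [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        if self.weight_sums is None:
            self.weight_sums = np.full((n, n), np.nan)
        else:
            self.weight_sums = np.asarray(self.weight_sums, dtype=float)

    @property
    def n(self) -> int:
        return len(self.ids)

    def dissimilarity(self) -> np.ndarray:
        """1 - similarity, zero diagonal; input metric for the landscape."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
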