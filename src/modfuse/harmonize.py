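"""Distribution harmonization and weighted similarity fusion.

Modality distances differ wildly in range and shape, so before fusion
each modality's pairwise distances are mapped onto a common reference
distribution: an ordered-quantile (rank-based inverse normal) transform
to standard-normal scores, followed by the quantile function of a normal
distribution with mean 0.5 and spread sigma truncated to [0, 1]. Sigma
defaults to 0.194, chosen so the untruncated normal covers 99% of its
mass inside [0, 1]. For bounded metrics, values lying exactly at 0 or 1
(structural atoms: identical sets, disjoint sets, cross-universe
substrate pairs) are set aside before the transform and reintroduced at
exactly 0 or 1 afterwards. Harmonized dissimilarities are then
complemented to similarities and combined per pair as a weighted
average, renormalizing weights over the modalities that cover the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata, truncnorm
from sklearn.base import BaseEstimator, TransformerMixin

from .matrices import DistanceMatrix, FusedSimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationConfig",
    "DEFAULT_WEIGHTS",
    "sigma_for_coverage",
    "orq_normalize",
    "to_truncated_normal",
    "harmonize_modality",
    "correlate_dissimilarities",
    "fuse",
    "QuantileHarmonizer",
    "WeightedSimilarityFusion",
]

#: Integration weights: highest on structure and the three perturbation/
#: interaction readouts, medium on substrate annotation, lowest on the
#: annotation-derived context modalities.
DEFAULT_WEIGHTS: dict[str, float] = {
    "transcriptome": 3.0,
    "metabolome": 3.0,
    "interactome": 3.0,
    "structure": 3.0,
    "substrate": 2.0,
    "localization": 1.0,
    "tissue": 1.0,
    "disease": 1.0,
}


def sigma_for_coverage(coverage: float, halfwidth: float) -> float:
    """Spread such that N(mu, sigma) puts ``coverage`` mass in mu +/- halfwidth.

    ``sigma = halfwidth / z`` with ``Phi(z) = (1 + coverage) / 2``. With
    coverage 0.99 and halfwidth 0.5 this gives 0.194.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie strictly between 0 and 1")
    return float(halfwidth / ndtri((1.0 + coverage) / 2.0))


@dataclass
class HarmonizationConfig:
    """Target distribution for harmonized dissimilarities.

    The target is a normal(mean, sigma) truncated to ``bounds``; by
    default sigma is derived from the coverage fraction so that the
    untruncated normal covers 99% of its mass inside the bounds.
    """

    mean: float = 0.5
    sigma: float | None = None
    coverage: float = 0.99
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must be ordered")
        if self.sigma is None:
            self.sigma = sigma_for_coverage(self.coverage, (hi - lo) / 2.0)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def _ab(self) -> tuple[float, float]:
        lo, hi = self.bounds
        return (lo - self.mean) / self.sigma, (hi - self.mean) / self.sigma


def orq_normalize(values) -> np.ndarray:
    """Ordered-quantile normalization to standard-normal scores.

    ``z_i = Phi^-1((r_i - 0.5) / n)`` with average ranks for ties; a
    strictly monotone map of the input ordering.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("orq_normalize expects a 1-d array")
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate modality: all values identical")
    r = rankdata(x, method="average")
    return ndtri((r - 0.5) / x.size)


def to_truncated_normal(z, config: HarmonizationConfig | None = None) -> np.ndarray:
    """Map standard-normal scores onto the truncated-normal target.

    ``v = Q_trunc(Phi(z))``, strictly monotone, values inside the open
    target interval.
    """
    config = config or HarmonizationConfig()
    a, b = config._ab
    return truncnorm.ppf(ndtr(np.asarray(z, dtype=float)), a, b,
                         loc=config.mean, scale=config.sigma)


class QuantileHarmonizer(TransformerMixin, BaseEstimator):
    """Rank-based transformer onto a truncated-normal reference.

    Fit learns the empirical quantiles of a 1-d training sample;
    transform maps values through interpolated ranks, the inverse normal
    CDF and the truncated-normal quantile function. ``fit_transform`` on
    the training data itself reproduces the ordered-quantile transform
    with average ranks for ties.

    Parameters
    ----------
    mean, coverage, bounds:
        Target truncated normal; sigma derived from coverage (0.194 for
        99% coverage on [0, 1]).
    """

    def __init__(self, mean: float = 0.5, coverage: float = 0.99,
                 bounds: tuple[float, float] = (0.0, 1.0)):
        self.mean = mean
        self.coverage = coverage
        self.bounds = bounds

    def _config(self) -> HarmonizationConfig:
        return HarmonizationConfig(mean=self.mean, coverage=self.coverage,
                                   bounds=tuple(self.bounds))

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 3:
            raise ValueError("need at least 3 values to fit")
        if not np.isfinite(x).all():
            raise ValueError("training values must be finite")
        if np.ptp(x) == 0:
            raise ValueError("degenerate modality: all values identical")
        self.reference_ = np.sort(x)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_")
        x = np.asarray(X, dtype=float).ravel()
        ref = self.reference_
        n = ref.size
        lo = np.searchsorted(ref, x, side="left")
        hi = np.searchsorted(ref, x, side="right")
        ranks = (lo + hi + 1) / 2.0  # average rank, 1-based
        q = np.clip((ranks - 0.5) / n, 0.5 / n, 1.0 - 0.5 / n)
        return to_truncated_normal(ndtri(q), self._config())


def harmonize_modality(dm: DistanceMatrix,
                       config: HarmonizationConfig | None = None) -> DistanceMatrix:
    """Harmonize one modality's distance matrix to the target distribution.

    Upper-triangle non-missing entries (diagonal excluded) are the
    training sample. For bounded metrics, entries exactly at 0 or 1 are
    set aside and reintroduced unchanged after the transform; everything
    else passes through ordered-quantile normalization and the
    truncated-normal quantile map. Missing entries stay missing.
    """
    config = config or HarmonizationConfig()
    n = dm.n
    ri, ci, vals = dm.condensed()
    present = ~np.isnan(vals)
    if dm.bounded:
        at_lo = present & (vals == config.bounds[0])
        at_hi = present & (vals == config.bounds[1])
    else:
        at_lo = np.zeros_like(present)
        at_hi = np.zeros_like(present)
    core = present & ~at_lo & ~at_hi
    if core.sum() < 3:
        raise ValueError("fewer than 3 transformable values in modality")
    out = np.full(vals.shape, np.nan)
    out[core] = to_truncated_normal(orq_normalize(vals[core]), config)
    out[at_lo] = config.bounds[0]
    out[at_hi] = config.bounds[1]
    m = np.full((n, n), np.nan)
    m[ri, ci] = out
    m[ci, ri] = out
    present_diag = dm.present
    idx = np.arange(n)
    m[idx, idx] = np.where(present_diag, 0.0, np.nan)
    return DistanceMatrix(dm.ids, m, bounded=True)


def correlate_dissimilarities(harmonized: list[DistanceMatrix],
                              names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of modality dissimilarities.

    Computed over upper-triangle entries present in both matrices
    (pairwise-complete); fewer than 3 shared pairs leaves NaN.
    """
    if len(harmonized) < 2:
        raise ValueError("need at least 2 matrices")
    ids = harmonized[0].ids
    for dm in harmonized:
        if dm.ids != ids:
            raise ValueError("matrices must share the entity index")
    names = names or [f"modality_{i}" for i in range(len(harmonized))]
    tri = [dm.condensed()[2] for dm in harmonized]
    k = len(tri)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            shared = ~np.isnan(tri[i]) & ~np.isnan(tri[j])
            if shared.sum() < 3:
                continue
            a, b = tri[i][shared], tri[j][shared]
            if a.std() == 0 or b.std() == 0:
                continue
            out[i, j] = out[j, i] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(out, index=names, columns=names)


def fuse(harmonized: list[DistanceMatrix], weights: dict[str, float] | list[float],
         names: list[str] | None = None) -> FusedSimilarityMatrix:
    """Weighted-average fusion of harmonized dissimilarities.

    Per pair, similarity = sum_m w_m (1 - d_m) / sum_m w_m over the
    modalities where both entities are covered; the effective weight sum
    is recorded. A pair covered by no modality is an error (the
    complete-coverage modality prevents it).
    """
    if not harmonized:
        raise ValueError("no matrices to fuse")
    ids = harmonized[0].ids
    for dm in harmonized:
        if dm.ids != ids:
            raise ValueError("matrices must share the entity index")
    names = names or [f"modality_{i}" for i in range(len(harmonized))]
    if isinstance(weights, dict):
        w = np.array([float(weights[n]) for n in names])
    else:
        w = np.asarray(list(weights), dtype=float)
    if len(w) != len(harmonized):
        raise ValueError("one weight per matrix required")
    if (w < 0).any() or not (w > 0).any():
        raise ValueError("weights must be non-negative with at least one positive")
    n = len(ids)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for wm, dm in zip(w, harmonized):
        have = dm.mask
        sim = np.where(have, 1.0 - np.nan_to_num(dm.values), 0.0)
        num += wm * sim * have
        den += wm * have
    uncovered = (den == 0) & ~np.eye(n, dtype=bool)
    if uncovered.any():
        i, j = np.argwhere(uncovered)[0]
        raise ValueError(f"pair ({ids[i]}, {ids[j]}) covered by no modality")
    with np.errstate(invalid="ignore", divide="ignore"):
        fusedv = np.where(den > 0, num / np.where(den == 0, 1, den), np.nan)
    np.fill_diagonal(fusedv, 1.0)
    return FusedSimilarityMatrix(ids, fusedv, weight_sums=den)


class WeightedSimilarityFusion(TransformerMixin, BaseEstimator):
    """Estimator facade over :func:`harmonize_modality` + :func:`fuse`.

    ``transform`` takes a dict name -> :class:`DistanceMatrix` and
    returns the :class:`FusedSimilarityMatrix`; harmonization uses the
    configured truncated-normal target.
    """

    def __init__(self, weights: dict[str, float] | None = None,
                 mean: float = 0.5, coverage: float = 0.99):
        self.weights = weights
        self.mean = mean
        self.coverage = coverage

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X: dict[str, DistanceMatrix]) -> FusedSimilarityMatrix:
        cfg = HarmonizationConfig(mean=self.mean, coverage=self.coverage)
        names = list(X)
        weights = self.weights or {n: 1.0 for n in names}
        harmonized = [harmonize_modality(X[n], cfg) for n in names]
        self.harmonized_ = dict(zip(names, harmonized))
        self.correlations_ = correlate_dissimilarities(harmonized, names)
        return fuse(harmonized, weights, names)
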