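"""Modality-specific pairwise distance computations.

Each of the eight data modalities comes in its own native type —
continuous profiles, item sets, ontology-term annotations, fingerprints,
or a precomputed similarity matrix — and each gets a data-type-specific
distance:

==================  =============================================  ========
modality            distance                                       bounded
==================  =============================================  ========
transcriptome       Euclidean on standard-normalized profiles      no
metabolome          Euclidean on standard-normalized profiles      no
interactome         Jaccard distance of interactor sets            yes
localization        BMA over term-cooccurrence Jaccard distances   yes
structure           1 - similarity                                 yes
tissue expression   sqrt((1 - Spearman r_s) / 2)                   yes
substrate           BMA over fingerprint/element distances         yes
disease             BMA over Leacock term distances                yes
==================  =============================================  ========

Only the four set/annotation-derived metrics (interactome, localization,
substrate, disease) produce structural boundary atoms at exactly 0 or 1;
the harmonization layer treats those specially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrices import DistanceMatrix
from .ontology import OntologyGraph, TermDistanceCache, bma_aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "SubstrateCatalog",
    "profile_euclidean",
    "set_jaccard",
    "correlation_distance",
    "term_cooccurrence_distance",
    "structure_distance",
    "substrate_distance",
    "disease_distance",
    "jaccard_distance",
    "tanimoto_distance",
]


# ---------------------------------------------------------------- helpers
def jaccard_distance(a: set, b: set) -> float:
    """1 - |A n B| / |A u B|; requires both sets non-empty."""
    if not a or not b:
        raise ValueError("Jaccard distance undefined for empty sets")
    union = len(a | b)
    return 1.0 - len(a & b) / union


def tanimoto_distance(bits_a: set, bits_b: set) -> float:
    """1 - Tanimoto coefficient over set bits of two binary fingerprints."""
    return jaccard_distance(bits_a, bits_b)


def _empty(n: int) -> np.ndarray:
    return np.full((n, n), np.nan)


def _finish(ids, values, bounded) -> DistanceMatrix:
    return DistanceMatrix(list(ids), values, bounded=bounded)


def _bma_over_sets(ids, sets: dict[str, set], item_dist) -> np.ndarray:
    """Entity-level distances as best-match averages of item distances."""
    n = len(ids)
    items = {e: sorted(sets[e]) for e in ids if sets.get(e)}
    vals = _empty(n)
    for e in items:
        vals[ids.index(e), ids.index(e)] = 0.0
    idx = {e: i for i, e in enumerate(ids)}
    for a, b in combinations(items, 2):
        table = np.array([[item_dist(x, y) for y in items[b]] for x in items[a]])
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = bma_aggregate(table)
    return vals


# ---------------------------------------------------------------- profiles
def profile_euclidean(profiles: pd.DataFrame, standardize: str = "entity") -> DistanceMatrix:
    """Euclidean distance between standard-normalized profiles.

    Each entity profile is standardized to zero mean and unit variance
    across its features (``standardize="entity"``, the default) before
    pairwise Euclidean distances are taken; ``standardize="feature"``
    z-scores columns instead. Entities with constant (zero-variance)
    profiles are marked missing with a warning.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 entities")
    ids = [str(i) for i in profiles.index]
    X = profiles.to_numpy(dtype=float)
    n = len(ids)
    vals = _empty(n)
    if standardize == "entity":
        sd = X.std(axis=1, ddof=0)
        ok = np.isfinite(X).all(axis=1) & (sd > 0)
        if (~ok).any():
            logger.warning("profile_euclidean: %d constant/non-finite profiles marked missing",
                           int((~ok).sum()))
        Z = np.where(ok[:, None], (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None], np.nan)
    elif standardize == "feature":
        ok = np.isfinite(X).all(axis=1)
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        Z = (X - mu) / np.where(sd == 0, 1.0, sd)
        Z = np.where(ok[:, None], Z, np.nan)
    else:
        raise ValueError("standardize must be 'entity' or 'feature'")
    good = np.where(ok)[0]
    if len(good) >= 2:
        D = squareform(pdist(Z[good]))
        vals[np.ix_(good, good)] = D
    for i in good:
        vals[i, i] = 0.0
    return _finish(ids, vals, bounded=False)


def correlation_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """Spearman-based distance ``d = sqrt((1 - r_s) / 2)``.

    Rank correlation uses average ranks for ties and pairwise-complete
    features. Pairs with fewer than 3 shared features or zero rank
    variance are missing.
    """
    ids = [str(i) for i in profiles.index]
    X = profiles.to_numpy(dtype=float)
    n = len(ids)
    vals = _empty(n)
    np.fill_diagonal(vals, 0.0)
    from scipy.stats import rankdata

    finite = np.isfinite(X)
    for i, j in combinations(range(n), 2):
        shared = finite[i] & finite[j]
        if shared.sum() < 3:
            continue
        xi, xj = X[i, shared], X[j, shared]
        ri, rj = rankdata(xi), rankdata(xj)
        si, sj = ri.std(), rj.std()
        if si == 0 or sj == 0:
            continue
        rs = np.corrcoef(ri, rj)[0, 1]
        vals[i, j] = vals[j, i] = np.sqrt(max(0.0, (1.0 - rs) / 2.0))
    # entities with no finite data at all are fully missing
    dead = ~finite.any(axis=1)
    vals[dead, :] = np.nan
    vals[:, dead] = np.nan
    return _finish(ids, vals, bounded=True)


# ---------------------------------------------------------------- sets
def set_jaccard(sets: dict[str, set], ids=None) -> DistanceMatrix:
    """Jaccard distance between item sets; empty sets are missing."""
    ids = [str(i) for i in (ids if ids is not None else sorted(sets))]
    n = len(ids)
    vals = _empty(n)
    have = [i for i, e in enumerate(ids) if sets.get(e)]
    for i in have:
        vals[i, i] = 0.0
    for a, b in combinations(have, 2):
        vals[a, b] = vals[b, a] = jaccard_distance(sets[ids[a]], sets[ids[b]])
    return _finish(ids, vals, bounded=True)


def term_cooccurrence_distance(location_sets: dict[str, set], ids=None) -> DistanceMatrix:
    """Distance via term co-occurrence plus best-match averaging.

    Term-term distances are Jaccard distances of the entity sets each
    term annotates; entity-entity distances aggregate those with BMA
    over the two entities' term sets.
    """
    ids = [str(i) for i in (ids if ids is not None else sorted(location_sets))]
    carriers: dict[str, set] = {}
    for e in ids:
        for t in location_sets.get(e, ()):
            carriers.setdefault(t, set()).add(e)
    tdist: dict[tuple[str, str], float] = {}

    def term_d(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in tdist:
            tdist[key] = 0.0 if a == b else jaccard_distance(carriers[a], carriers[b])
        return tdist[key]

    vals = _bma_over_sets(ids, {e: location_sets.get(e, set()) for e in ids}, term_d)
    return _finish(ids, vals, bounded=True)


# ---------------------------------------------------------------- matrix
def structure_distance(similarities: pd.DataFrame) -> DistanceMatrix:
    """Distance = 1 - similarity for a precomputed similarity matrix.

    Input must be symmetric (tolerance 1e-9) with unit diagonal for
    present entities; values in [0, 1].
    """
    if list(similarities.index) != list(similarities.columns):
        raise ValueError("similarity matrix row/column ids differ")
    s = similarities.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        asym = np.nanmax(np.abs(s - s.T)) if s.size else 0.0
    if np.isfinite(asym) and asym > 1e-9:
        raise ValueError(f"similarity matrix asymmetric beyond tolerance ({asym:.3g})")
    if np.nanmin(s) < -1e-9 or np.nanmax(s) > 1 + 1e-9:
        raise ValueError("similarities must lie in [0, 1]")
    d = 1.0 - np.clip(s, 0.0, 1.0)
    present = ~np.all(np.isnan(d), axis=1)
    dg = np.full(len(d), np.nan)
    dg[present] = 0.0
    np.fill_diagonal(d, 0.0)
    d[~present, :] = np.nan
    d[:, ~present] = np.nan
    return _finish(list(similarities.index), d, bounded=True)


# ---------------------------------------------------------------- substrates
@dataclass
class SubstrateCatalog:
    """Per-substrate chemistry: molecular fingerprints or element embeddings.

    ``fingerprints`` maps molecular substrate id -> set of on-bits;
    ``embeddings`` maps elemental substrate id -> numeric vector. A
    substrate id belongs to exactly one universe. Embedding vectors are
    feature-standardized and the resulting elemental distances divided by
    their catalog-wide maximum, so every within-universe distance lies in
    [0, 1]; the molecular-elemental distance is 1 exactly.
    """

    fingerprints: dict[str, set] = field(default_factory=dict)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        both = set(self.fingerprints) & set(self.embeddings)
        if both:
            raise ValueError(f"substrates in both universes: {sorted(both)[:5]}")
        zero = [s for s, bits in self.fingerprints.items() if not bits]
        if zero:
            logger.warning("excluding %d all-zero fingerprints: %s", len(zero), zero[:5])
            for s in zero:
                del self.fingerprints[s]
        self._elem_dist = self._elemental_distances()

    def _elemental_distances(self) -> dict[tuple[str, str], float]:
        ids = sorted(self.embeddings)
        if len(ids) < 2:
            return {}
        M = np.array([np.asarray(self.embeddings[s], dtype=float) for s in ids])
        sd = M.std(axis=0, ddof=0)
        Z = (M - M.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        D = squareform(pdist(Z))
        dmax = D.max()
        if dmax > 0:
            D = D / dmax
        return {(ids[i], ids[j]): float(D[i, j])
                for i in range(len(ids)) for j in range(i, len(ids))}

    def known(self, substrate: str) -> bool:
        return substrate in self.fingerprints or substrate in self.embeddings

    def distance(self, a: str, b: str) -> float:
        if not (self.known(a) and self.known(b)):
            raise KeyError(f"substrate not in catalog: {a if not self.known(a) else b}")
        if a in self.fingerprints and b in self.fingerprints:
            return 0.0 if a == b else tanimoto_distance(self.fingerprints[a], self.fingerprints[b])
        if a in self.embeddings and b in self.embeddings:
            key = (a, b) if a <= b else (b, a)
            return 0.0 if a == b else self._elem_dist.get(key, 0.0)
        return 1.0  # cross-universe: maximal by construction


def substrate_distance(substrate_sets: dict[str, set], catalog: SubstrateCatalog,
                       ids=None) -> DistanceMatrix:
    """Entity distances as BMA over substrate-level chemical distances."""
    ids = [str(i) for i in (ids if ids is not None else sorted(substrate_sets))]
    cleaned: dict[str, set] = {}
    for e in ids:
        subs = {s for s in substrate_sets.get(e, ()) if catalog.known(s)}
        dropped = set(substrate_sets.get(e, ())) - subs
        if dropped:
            logger.warning("entity %s: %d substrates not in catalog dropped", e, len(dropped))
        cleaned[e] = subs
    vals = _bma_over_sets(ids, cleaned, catalog.distance)
    return _finish(ids, vals, bounded=True)


# ---------------------------------------------------------------- diseases
def disease_distance(disease_sets: dict[str, set], graph: OntologyGraph,
                     ids=None) -> DistanceMatrix:
    """Entity distances as BMA over Leacock term distances."""
    ids = [str(i) for i in (ids if ids is not None else sorted(disease_sets))]
    cache = TermDistanceCache(graph)
    cleaned: dict[str, set] = {}
    for e in ids:
        terms = {t for t in disease_sets.get(e, ()) if t in graph}
        dropped = set(disease_sets.get(e, ())) - terms
        if dropped:
            logger.warning("entity %s: unresolvable terms dropped: %s", e, sorted(dropped)[:5])
        cleaned[e] = terms
    vals = _bma_over_sets(ids, cleaned, cache)
    return _finish(ids, vals, bounded=True)
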