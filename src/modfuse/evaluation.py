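"""Statistical assessment of the landscape.

Cluster quality (silhouette on graph distances), coherence of distances
with discrete entity properties (ANOSIM permutation test), agreement
between partitions (adjusted mutual information), per-cluster property
enrichment (one-sided Fisher/hypergeometric with Benjamini-Hochberg
correction), multi-label annotation agreement (micro-averaged F1),
leave-one-modality-out cross-validation, and the skewness statistic
used to quantify publication asymmetry across gene groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from sklearn.metrics import adjusted_mutual_info_score, silhouette_samples
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnosimResult",
    "AgreementScore",
    "silhouette",
    "anosim",
    "adjusted_mutual_information",
    "enrichment",
    "micro_f1_agreement",
    "loo_modality_cv",
    "skewness",
    "pair_count",
]


def pair_count(n: int) -> int:
    """Number of unordered entity pairs, n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least 2 entities")
    return n * (n - 1) // 2


def skewness(counts) -> float:
    """Moment coefficient of skewness ``g1 = m3 / m2^(3/2)``."""
    x = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        raise ValueError("zero variance: skewness undefined")
    m3 = np.mean((x - x.mean()) ** 3)
    return float(m3 / m2 ** 1.5)


# ---------------------------------------------------------------- silhouette
def _cap_unreachable(d: np.ndarray) -> np.ndarray:
    """Replace unreachable (NaN/inf) off-diagonal pairs by max finite + 1.

    Rank-preserving: every unreachable pair becomes "farther than
    anything reachable", which is the exact semantics for rank-based
    statistics and a bounded proxy for silhouette on disconnected
    graphs.
    """
    out = d.copy()
    bad = ~np.isfinite(out)
    np.fill_diagonal(bad, False)
    if bad.any():
        cap = np.nanmax(np.where(np.isfinite(out), out, np.nan)) + 1.0
        logger.info("capping %d unreachable pairs at %.3g", int(bad.sum()) // 2, cap)
        out[bad] = cap
    return out


def silhouette(distances, labels, unreachable: str = "exclude"
               ) -> tuple[pd.Series, pd.Series]:
    """Per-entity silhouette values and per-cluster means.

    ``distances`` is a square precomputed distance matrix (a
    :class:`~modfuse.matrices.DistanceMatrix` or array); graph-based
    distances are the intended input. Entities with non-finite distances
    to any other scored entity are excluded with a logged count
    (``unreachable="exclude"``) or unreachable pairs are capped at the
    maximum finite distance plus one (``unreachable="cap"``, useful when
    the neighbor graph is disconnected); singleton clusters score 0 by
    convention.
    """
    from .matrices import DistanceMatrix

    if isinstance(distances, DistanceMatrix):
        ids, d = distances.ids, distances.values
    else:
        d = np.asarray(distances, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if unreachable == "cap":
        d = _cap_unreachable(d)
    elif unreachable != "exclude":
        raise ValueError("unreachable must be 'exclude' or 'cap'")
    finite = np.isfinite(d).all(axis=1)
    if (~finite).any():
        logger.warning("silhouette: excluding %d entities with non-finite distances",
                       int((~finite).sum()))
    d_f, lab_f = d[np.ix_(finite, finite)], labels[finite]
    ids_f = [i for i, keep in zip(ids, finite) if keep]
    if len(np.unique(lab_f)) < 2:
        raise ValueError("fewer than 2 clusters among finite-distance entities")
    s = silhouette_samples(d_f, lab_f, metric="precomputed")
    per_entity = pd.Series(s, index=ids_f, name="silhouette")
    per_cluster = per_entity.groupby(pd.Series(lab_f, index=ids_f)).mean()
    per_cluster.name = "mean_silhouette"
    return per_entity, per_cluster


# ---------------------------------------------------------------- ANOSIM
@dataclass
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation p-value."""

    r: float
    p_value: float
    permutations: int


def _anosim_r(rank_matrix: np.ndarray, within: np.ndarray) -> float:
    m = rank_matrix.size
    rw = rank_matrix[within].mean()
    rb = rank_matrix[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(distances, labels, permutations: int = 10000, seed: int = 0) -> AnosimResult:
    """Analysis of similarities: rank-based group-separation test.

    ``R = (mean rank between - mean rank within) / (M / 2)`` with
    ``M = n(n-1)/2`` distance ranks (average ranks for ties). The
    p-value is the add-one permutation estimate
    ``(1 + #{R_perm >= R_obs}) / (1 + permutations)``.
    """
    from .matrices import DistanceMatrix

    if isinstance(distances, DistanceMatrix):
        d = distances.values
    else:
        d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("one label per entity required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM requires >=2 groups with >=2 members each")
    iu, ju = np.triu_indices(n, k=1)
    vals = d[iu, ju]
    if not np.isfinite(vals).all():
        raise ValueError("ANOSIM requires finite distances")
    ranks = rankdata(vals, method="average")
    codes = np.unique(labels, return_inverse=True)[1]
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        w = perm[iu] == perm[ju]
        if _anosim_r(ranks, w) >= r_obs:
            count += 1
    p = (1 + count) / (1 + permutations)
    return AnosimResult(r=r_obs, p_value=p, permutations=permutations)


# ---------------------------------------------------------------- AMI
def adjusted_mutual_information(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement under the permutation model.

    ``AMI = (MI - E[MI]) / (mean(H_a, H_b) - E[MI])``; two single-class
    labelings are defined as agreement 1.0 (logged).
    """
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same entities")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        logger.info("AMI: both labelings single-class; defined as 1.0")
        return 1.0
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


# ---------------------------------------------------------------- enrichment
def _incidence(properties) -> list[tuple[str, str]]:
    pairs = []
    for entity, val in properties.items():
        if isinstance(val, (set, frozenset, list, tuple)):
            pairs.extend((str(entity), str(v)) for v in val)
        elif val is not None and not (isinstance(val, float) and np.isnan(val)):
            pairs.append((str(entity), str(val)))
    return pairs


def enrichment(clusters, properties, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster property over-representation (one-sided Fisher).

    ``clusters`` maps entity -> cluster id (or a
    :class:`~modfuse.landscape.ClusterAssignment`); ``properties`` maps
    entity -> label or -> set of labels (multi-label). For each
    (cluster, label) a 2x2 in/out-cluster x has/lacks-label table is
    tested for over-representation via the exact hypergeometric upper
    tail. Labels carried by fewer than two entities are dropped before
    testing; Benjamini-Hochberg adjustment runs across all tests
    performed.
    """
    from .landscape import ClusterAssignment

    if isinstance(clusters, ClusterAssignment):
        cluster_of = dict(zip(clusters.ids, clusters.labels))
    else:
        cluster_of = {str(k): v for k, v in dict(clusters).items()}
    universe = list(cluster_of)
    N = len(universe)
    carriers: dict[str, set] = {}
    for e, lab in _incidence(properties):
        if e in cluster_of:
            carriers.setdefault(lab, set()).add(e)
    carriers = {lab: c for lab, c in carriers.items() if len(c) >= 2}
    rows = []
    for cl in sorted(set(cluster_of.values()), key=str):
        members = {e for e in universe if cluster_of[e] == cl}
        n_cl = len(members)
        for lab in sorted(carriers):
            K = len(carriers[lab])
            k = len(carriers[lab] & members)
            p = float(hypergeom.sf(k - 1, N, K, n_cl))
            expected = K * n_cl / N
            rows.append({
                "cluster": cl,
                "label": lab,
                "count_in_cluster": k,
                "cluster_size": n_cl,
                "count_overall": K,
                "universe": N,
                "direction": "over" if k > expected else ("under" if k < expected else "even"),
                "p_value": p,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["p_adjusted"] = []
        table["significant"] = []
    return table


# ---------------------------------------------------------------- agreement
@dataclass
class AgreementScore:
    """Micro-averaged precision/recall/F1 over (entity, term) incidences."""

    precision: float
    recall: float
    f1: float


def micro_f1_agreement(annotations_a: dict[str, set],
                       annotations_b: dict[str, set]) -> AgreementScore:
    """Multi-label agreement pooled over all (entity, term) pairs.

    A is read as the prediction side, B as the reference:
    precision = TP/|A|, recall = TP/|B|, F1 their harmonic mean (0 when
    there is no overlap). Swapping A and B swaps precision and recall
    and leaves F1 unchanged.
    """
    pairs_a = {(e, t) for e, ts in annotations_a.items() for t in ts}
    pairs_b = {(e, t) for e, ts in annotations_b.items() for t in ts}
    if not pairs_a or not pairs_b:
        raise ValueError("empty annotation source")
    tp = len(pairs_a & pairs_b)
    prec = tp / len(pairs_a)
    rec = tp / len(pairs_b)
    f1 = 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)
    return AgreementScore(precision=prec, recall=rec, f1=f1)


# ---------------------------------------------------------------- LOO CV
def loo_modality_cv(world, weights=None, alpha: float = 0.05,
                    n_neighbors: int = 15, resolution: float = 1.0,
                    seed: int = 0) -> pd.DataFrame:
    """Leave-one-modality-out cross-validation on a synthetic world.

    The fusion -> graph -> Leiden pipeline is rerun once per modality
    with that modality excluded (plus a full-data baseline row),
    reporting cluster count, AMI against the planted labels, and the
    number of significantly enriched property labels (BH-adjusted
    p < alpha; planted labels and localization terms serve as the
    property sets). A run whose fusion fails (a pair left with zero
    covered modalities) is reported as failed, not fatal.
    """
    from .harmonize import DEFAULT_WEIGHTS, fuse, harmonize_modality
    from .landscape import FunctionalLandscape
    from .pipeline import modality_distance_matrices

    weights = weights or DEFAULT_WEIGHTS
    dms = modality_distance_matrices(world)
    harmonized = {name: harmonize_modality(dm) for name, dm in dms.items()}
    names = list(harmonized)
    rows = []
    for left_out in [None] + names:
        use = [n for n in names if n != left_out]
        try:
            fused = fuse([harmonized[n] for n in use], {n: weights[n] for n in use}, use)
            model = FunctionalLandscape(n_neighbors=n_neighbors, resolution=resolution,
                                        compute_embedding=False, random_state=seed)
            model.fit(fused)
            ami = adjusted_mutual_information(world.planted_labels, model.labels_)
            props = {e: set(world.locations.get(e, ())) |
                        {f"planted_{l}"} for e, l in
                     zip(world.entities, world.planted_labels)}
            table = enrichment(dict(zip(world.entities, model.labels_)), props, alpha=alpha)
            n_sig = int(table["significant"].sum()) if len(table) else 0
            rows.append({"left_out": left_out or "none", "status": "ok",
                         "n_clusters": len(np.unique(model.labels_)),
                         "ami_planted": ami, "n_enriched": n_sig})
        except ValueError as err:
            logger.warning("leave-out %s failed: %s", left_out, err)
            rows.append({"left_out": left_out or "none", "status": "failed",
                         "n_clusters": np.nan, "ami_planted": np.nan,
                         "n_enriched": np.nan})
    return pd.DataFrame(rows)
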