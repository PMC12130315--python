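"""Pipeline driver: configuration, stage sequencing and provenance.

The full run is distances -> harmonize -> fuse -> neighbor graph ->
embedding / graph distances / Leiden -> Ward tree -> evaluation, with
every stochastic stage seeded explicitly and a provenance record
(config hash, seeds, versions, per-artifact checksums) written next to
the outputs. Reruns with an identical configuration produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .distances import (correlation_distance, disease_distance, profile_euclidean,
                        set_jaccard, structure_distance, substrate_distance,
                        term_cooccurrence_distance)
from .evaluation import adjusted_mutual_information, anosim, enrichment, silhouette
from .harmonize import (DEFAULT_WEIGHTS, HarmonizationConfig,
                        correlate_dissimilarities, fuse, harmonize_modality)
from .landscape import (FunctionalLandscape, ward_tree)
from .matrices import DistanceMatrix
from .synthetic import MODALITIES, SyntheticWorld, read_world

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "modality_distance_matrices", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; every constant is overridable.

    ``world_dir`` points at a directory of modality tables in the
    layout written by :func:`modfuse.synthetic.write_world`.
    """

    world_dir: str = "."
    out_dir: str = "artifacts"
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    exclude_modalities: list = field(default_factory=list)
    harmonization_mean: float = 0.5
    harmonization_coverage: float = 0.99
    n_neighbors: int = 15
    n_epochs: int = 500
    min_dist: float = 0.1
    resolution: float = 1.0
    leiden_iterations: int = 100
    anosim_permutations: int = 1000
    seed: int = 0
    compute_embedding: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def modality_distance_matrices(world: SyntheticWorld,
                               exclude=()) -> dict[str, DistanceMatrix]:
    """All eight per-modality distance matrices on the shared entity index.

    Each matrix covers the full entity index; entities without data in a
    modality are missing (NaN) there.
    """
    ids = list(world.entities)
    out: dict[str, DistanceMatrix] = {}

    def reindex(dm: DistanceMatrix, bounded: bool) -> DistanceMatrix:
        df = dm.to_frame().reindex(index=ids, columns=ids)
        return DistanceMatrix(ids, df.to_numpy(), bounded=bounded)

    if "transcriptome" not in exclude:
        out["transcriptome"] = reindex(profile_euclidean(world.profiles["transcriptome"]), False)
    if "metabolome" not in exclude:
        out["metabolome"] = reindex(profile_euclidean(world.profiles["metabolome"]), False)
    if "interactome" not in exclude:
        out["interactome"] = set_jaccard(world.interactors, ids=ids)
    if "localization" not in exclude:
        out["localization"] = term_cooccurrence_distance(world.locations, ids=ids)
    if "structure" not in exclude:
        out["structure"] = structure_distance(world.structure_sim)
    if "tissue" not in exclude:
        out["tissue"] = reindex(correlation_distance(world.profiles["tissue"]), True)
    if "substrate" not in exclude:
        out["substrate"] = substrate_distance(world.substrates, world.catalog, ids=ids)
    if "disease" not in exclude:
        out["disease"] = disease_distance(world.diseases, world.disease_ontology, ids=ids)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the provenance record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        world = read_world(config.world_dir)
        modalities = [m for m in MODALITIES if m not in set(config.exclude_modalities)]

        stage = "distances"
        dms = modality_distance_matrices(world, exclude=set(config.exclude_modalities))

        stage = "harmonize"
        hcfg = HarmonizationConfig(mean=config.harmonization_mean,
                                   coverage=config.harmonization_coverage)
        harmonized = {m: harmonize_modality(dms[m], hcfg) for m in modalities}
        corr = correlate_dissimilarities([harmonized[m] for m in modalities], modalities)

        stage = "fuse"
        fused = fuse([harmonized[m] for m in modalities],
                     {m: config.weights[m] for m in modalities}, modalities)

        stage = "landscape"
        model = FunctionalLandscape(
            n_neighbors=config.n_neighbors, min_dist=config.min_dist,
            n_epochs=config.n_epochs, resolution=config.resolution,
            leiden_iterations=config.leiden_iterations,
            compute_embedding=config.compute_embedding,
            random_state=config.seed)
        model.fit(fused)

        stage = "tree"
        tree = ward_tree(dms["structure"]) if "structure" in dms else None

        stage = "evaluate"
        clusters = pd.Series(model.labels_, index=world.entities, name="cluster")
        gd = model.graph_distances_
        reports: dict = {"modularity": model.modularity_,
                         "n_clusters": int(len(np.unique(model.labels_)))}
        if world.planted_labels is not None:
            reports["ami_planted"] = adjusted_mutual_information(
                world.planted_labels, model.labels_)
            from .evaluation import _cap_unreachable

            res = anosim(_cap_unreachable(gd.values), world.planted_labels,
                         permutations=config.anosim_permutations, seed=config.seed)
            reports["anosim_planted"] = {"r": res.r, "p_value": res.p_value,
                                         "permutations": res.permutations}
        if len(np.unique(model.labels_)) >= 2:
            _, per_cluster = silhouette(gd, model.labels_, unreachable="cap")
            reports["mean_silhouette_per_cluster"] = per_cluster.to_dict()
        props = {e: set(world.locations.get(e, ())) for e in world.entities}
        enr = enrichment(dict(zip(world.entities, model.labels_)), props)
        reports["n_enriched_locations"] = int(enr["significant"].sum()) if len(enr) else 0

        stage = "write"
        artifacts: dict[str, str] = {}

        def emit(name: str, path: Path) -> None:
            artifacts[name] = path.name

        emit("fused", mio.write_matrix(fused.to_frame(), out / "fused_similarity.tsv"))
        emit("correlations", mio.write_matrix(corr, out / "modality_correlations.tsv"))
        edge_path = out / "graph_edges.tsv"
        model.graph_.edge_list().to_csv(edge_path, sep="\t", index=False,
                                        float_format="%.10g")
        emit("graph", edge_path)
        if model.embedding_ is not None:
            emit("embedding", mio.write_profiles(model.embedding_, out / "embedding.tsv"))
        emit("graph_distances", mio.write_matrix(gd.to_frame(), out / "graph_distances.tsv"))
        cl_path = out / "clusters.tsv"
        clusters.to_frame().to_csv(cl_path, sep="\t", index_label="id")
        emit("clusters", cl_path)
        if tree is not None:
            tree_path = out / "structure_tree.nwk"
            tree_path.write_text(tree.newick + "\n", encoding="utf-8")
            emit("tree", tree_path)
        emit("evaluation", mio.write_json(reports, out / "evaluation.json"))
        for m in modalities:
            emit(f"harmonized_{m}", mio.write_matrix(
                harmonized[m].to_frame(), out / f"harmonized_{m}.tsv"))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    import importlib.metadata as md

    versions = {}
    for pkg in ("numpy", "scipy", "pandas", "scikit-learn", "umap-learn", "leidenalg"):
        try:
            versions[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            pass
    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": versions,
        "artifacts": artifacts,
        "checksums": {name: _sha256(out / fname) for name, fname in artifacts.items()},
    }
    mio.write_json(provenance, out / "provenance.json")
    return provenance
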