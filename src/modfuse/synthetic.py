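"""Synthetic cohorts with planted cluster structure across all eight
modalities.

The generator emulates the statistical structure the fusion pipeline
assumes, not real biology: K latent cluster centers on a hypersphere
drive every modality, so that at low noise the same planted partition
is recoverable from each data layer. Per modality the noise knob means:

* profile modalities (transcriptome, metabolome, tissue) — Gaussian
  noise of that standard deviation around the projected cluster center;
* interactome — probability that a drawn interactor is replaced by a
  random one from the global pool (contamination);
* localization / substrate / disease terms — probability that a term is
  swapped for a random term of the whole vocabulary or ontology;
* fingerprints — per-bit flip probability relative to the cluster
  prototype;
* structure — relative Gaussian jitter of the latent positions before
  the monotone similarity transform.

Entities are dropped from a modality independently with probability
1 - coverage; the structure modality always covers everyone, so fusion
never meets a pair with zero shared modalities. Default coverages
mirror an eight-modality study in which 447 of 447 entities carry
structural data but only about half carry disease annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .distances import SubstrateCatalog
from .ontology import OntologyGraph, write_obo

__all__ = [
    "MODALITIES",
    "PROFILE_MODALITIES",
    "SET_MODALITIES",
    "DEFAULT_COVERAGE",
    "ConfigurationError",
    "GeneratorConfig",
    "SyntheticWorld",
    "generate_world",
    "write_world",
    "read_world",
    "build_toy_ontology",
]

MODALITIES = ("transcriptome", "metabolome", "interactome", "localization",
              "structure", "tissue", "substrate", "disease")
PROFILE_MODALITIES = ("transcriptome", "metabolome", "tissue")
SET_MODALITIES = ("interactome", "localization", "substrate", "disease")

#: Fraction of entities covered per modality (counts out of 447 entities:
#: 441, 378, 396, 418, 447, 443, 329 and 226 respectively).
DEFAULT_COVERAGE: dict[str, float] = {
    "transcriptome": 441 / 447,
    "metabolome": 378 / 447,
    "interactome": 396 / 447,
    "localization": 418 / 447,
    "structure": 1.0,
    "tissue": 443 / 447,
    "substrate": 329 / 447,
    "disease": 226 / 447,
}

DEFAULT_PROFILE_DIMS: dict[str, int] = {
    "transcriptome": 60,
    "metabolome": 30,
    "tissue": 50,
}


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _per_modality(value, name: str, lo: float, hi: float,
                  keys=MODALITIES, base=None) -> dict[str, float]:
    if isinstance(value, dict):
        base = base or {}
        out = {k: float(value.get(k, base.get(k, 0.0))) for k in keys}
        unknown = set(value) - set(keys)
        if unknown:
            raise ConfigurationError(f"{name}: unknown modalities {sorted(unknown)}")
    else:
        out = {k: float(value) for k in keys}
    for k, v in out.items():
        if not lo <= v <= hi:
            raise ConfigurationError(f"{name}[{k}] = {v} outside [{lo}, {hi}]")
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic world.

    ``noise_level`` and ``coverage`` may be a single float or a
    per-modality mapping. The structure modality must keep coverage 1.0
    (the complete-coverage guarantee fusion relies on).
    """

    n_entities: int = 120
    n_clusters: int = 4
    noise_level: float | dict = 0.1
    coverage: float | dict = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    profile_dims: dict = field(default_factory=lambda: dict(DEFAULT_PROFILE_DIMS))
    interactor_pool_size: int = 200
    n_compartments: int = 10
    ontology_spec: dict = field(default_factory=lambda: {"depth": 3, "branching": 3})
    fingerprint_bits: int = 128
    elemental_fraction: float = 0.25
    min_center_angle_deg: float = 60.0
    latent_dim: int = 8
    cross_modality_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if self.n_entities < 2 * self.n_clusters:
            raise ConfigurationError("n_entities must be >= 2 * n_clusters")
        self.noise_level = _per_modality(self.noise_level, "noise_level", 0.0, 1.0,
                                         base={m: 0.1 for m in MODALITIES})
        cov = self.coverage
        if not isinstance(cov, dict):
            cov = {m: cov for m in MODALITIES}
            cov["structure"] = 1.0
        self.coverage = _per_modality(cov, "coverage", 0.0, 1.0, base=DEFAULT_COVERAGE)
        for m, c in self.coverage.items():
            if c <= 0:
                raise ConfigurationError(f"coverage[{m}] must be in (0, 1]")
        if self.coverage["structure"] != 1.0:
            raise ConfigurationError("coverage[structure] must be 1.0")
        for m in PROFILE_MODALITIES:
            if self.profile_dims.get(m, 0) < 3:
                raise ConfigurationError(f"profile_dims[{m}] must be >= 3")
        if self.interactor_pool_size < 10 * self.n_clusters:
            raise ConfigurationError("interactor_pool_size too small (< 10 per cluster)")
        if self.n_compartments < 2:
            raise ConfigurationError("n_compartments must be >= 2")
        if not (self.ontology_spec.get("depth", 0) >= 2
                and self.ontology_spec.get("branching", 0) >= 2):
            raise ConfigurationError("ontology_spec needs depth >= 2 and branching >= 2")
        if self.fingerprint_bits < 16:
            raise ConfigurationError("fingerprint_bits must be >= 16")
        if not 0.0 <= self.elemental_fraction < 1.0:
            raise ConfigurationError("elemental_fraction must be in [0, 1)")
        if self.latent_dim < 2:
            raise ConfigurationError("latent_dim must be >= 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")


@dataclass
class SyntheticWorld:
    """Generated entities with planted labels and all modality tables."""

    config: GeneratorConfig
    entities: list[str]
    planted_labels: np.ndarray
    profiles: dict[str, pd.DataFrame]          # transcriptome/metabolome/tissue
    interactors: dict[str, set]
    locations: dict[str, set]
    substrates: dict[str, set]
    diseases: dict[str, set]
    structure_sim: pd.DataFrame
    catalog: SubstrateCatalog
    substrate_ontology: OntologyGraph
    disease_ontology: OntologyGraph
    disease_areas: list[str]

    def covered(self, modality: str) -> list[str]:
        """Entities with data in a modality."""
        if modality in PROFILE_MODALITIES:
            return [str(i) for i in self.profiles[modality].index]
        if modality == "structure":
            return list(self.entities)
        sets = {"interactome": self.interactors, "localization": self.locations,
                "substrate": self.substrates, "disease": self.diseases}[modality]
        return [e for e in self.entities if sets.get(e)]


def build_toy_ontology(prefix: str, n_branches: int, depth: int, branching: int,
                       root_label: str = "root") -> tuple[OntologyGraph, list[list[str]]]:
    """Balanced toy ontology: a root, ``n_branches`` direct children, and
    under each a complete is_a tree of the given depth and branching.

    Returns the graph and the leaf terms per branch. One role term with
    ``has_role`` edges from each branch's first leaf exercises typed
    relations.
    """
    counter = [0]

    def new_term() -> str:
        counter[0] += 1
        return f"{prefix}:{counter[0]:07d}"

    root = new_term()
    edges: list[tuple[str, str, str]] = []
    labels = {root: root_label}
    branch_leaves: list[list[str]] = []
    branch_roots = []
    for b in range(n_branches):
        t = new_term()
        labels[t] = f"{root_label} branch {b}"
        edges.append((t, root, "is_a"))
        branch_roots.append(t)
    for b, broot in enumerate(branch_roots):
        frontier = [broot]
        for level in range(depth - 1):
            nxt = []
            for parent in frontier:
                for _ in range(branching):
                    t = new_term()
                    labels[t] = f"b{b} d{level + 1} term {t.split(':')[1]}"
                    edges.append((t, parent, "is_a"))
                    nxt.append(t)
            frontier = nxt
        branch_leaves.append(frontier)
    role = new_term()
    labels[role] = f"{root_label} role"
    for leaves in branch_leaves:
        edges.append((leaves[0], role, "has_role"))
    return OntologyGraph.from_edges(edges, labels), branch_leaves


def _cluster_centers(rng: np.random.Generator, k: int, dim: int,
                     min_angle_deg: float) -> np.ndarray:
    """Unit vectors with pairwise angular separation >= the minimum.

    Rejection sampling with an orthonormal fallback (QR), which
    guarantees 90-degree separation whenever k <= dim.
    """
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    for _ in range(200):
        c = rng.normal(size=(k, dim))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        gram = c @ c.T
        if (gram[~np.eye(k, dtype=bool)] <= cos_max + 1e-12).all():
            return c
    q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    if k > dim:
        raise ConfigurationError("latent_dim too small for the requested separation")
    return q[:, :k].T


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Deterministically generate a world from (config, seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_entities, cfg.n_clusters
    entities = [f"E{i:04d}" for i in range(n)]
    labels = np.arange(n) % k
    rng.shuffle(labels)
    noise = cfg.noise_level
    centers = _cluster_centers(rng, k, cfg.latent_dim, cfg.min_center_angle_deg)

    # --- profile modalities ----------------------------------------
    profiles: dict[str, pd.DataFrame] = {}
    for mod in PROFILE_MODALITIES:
        d = cfg.profile_dims[mod]
        w = rng.normal(size=(cfg.latent_dim, d))
        base = centers @ w  # cluster centers in feature space
        x = base[labels] + noise[mod] * rng.normal(size=(n, d))
        prefix = {"transcriptome": "tx", "metabolome": "mb", "tissue": "ts"}[mod]
        profiles[mod] = pd.DataFrame(
            x, index=entities, columns=[f"{prefix}_{j:03d}" for j in range(d)])

    # --- interactome ------------------------------------------------
    pool = [f"P{i:04d}" for i in range(cfg.interactor_pool_size)]
    chunk = cfg.interactor_pool_size // k
    cluster_pool = [pool[c * chunk:(c + 1) * chunk] for c in range(k)]
    core = [cp[:6] for cp in cluster_pool]
    interactors: dict[str, set] = {}
    for i, e in enumerate(entities):
        c = labels[i]
        extra = rng.choice(cluster_pool[c], size=rng.integers(5, 12), replace=False)
        items = set(core[c]) | set(extra.tolist())
        contaminated = {
            (rng.choice(pool) if rng.random() < noise["interactome"] else it)
            for it in items}
        interactors[e] = contaminated

    # --- localization ----------------------------------------------
    # overlapping 3-compartment home sets (stride 2): neighboring clusters
    # share one compartment, so term co-occurrence distances are not all 0/1
    comps = [f"C{j:02d}" for j in range(cfg.n_compartments)]
    home = [{comps[(2 * c) % cfg.n_compartments],
             comps[(2 * c + 1) % cfg.n_compartments],
             comps[(2 * c + 2) % cfg.n_compartments]} for c in range(k)]
    locations: dict[str, set] = {}
    for i, e in enumerate(entities):
        terms = {
            (rng.choice(comps) if rng.random() < noise["localization"] else t)
            for t in home[labels[i]]}
        locations[e] = terms

    # --- substrate ontology, terms and catalog ----------------------
    spec = cfg.ontology_spec
    sub_onto, sub_leaves = build_toy_ontology(
        "SUB", k, spec["depth"], spec["branching"], root_label="substance")
    all_sub_leaves = [t for leaves in sub_leaves for t in leaves]
    n_elem_clusters = int(round(cfg.elemental_fraction * k))
    elemental_clusters = set(range(n_elem_clusters))
    proto = {c: rng.random(cfg.fingerprint_bits) < 0.3 for c in range(k)}
    elem_proto = {c: rng.normal(size=10) * 3.0 for c in range(k)}
    fingerprints: dict[str, set] = {}
    embeddings: dict[str, np.ndarray] = {}
    for c, leaves in enumerate(sub_leaves):
        for t in leaves:
            if c in elemental_clusters:
                embeddings[t] = elem_proto[c] + noise["substrate"] * rng.normal(size=10)
            else:
                flips = rng.random(cfg.fingerprint_bits) < noise["substrate"]
                bits = np.where(flips, ~proto[c], proto[c])
                fingerprints[t] = set(np.flatnonzero(bits).tolist())
                if not fingerprints[t]:  # pathological all-zero draw
                    fingerprints[t] = {int(rng.integers(cfg.fingerprint_bits))}
    substrates: dict[str, set] = {}
    for i, e in enumerate(entities):
        own = rng.choice(sub_leaves[labels[i]], size=rng.integers(1, 4), replace=True)
        terms = {
            (rng.choice(all_sub_leaves) if rng.random() < noise["substrate"] else t)
            for t in own.tolist()}
        substrates[e] = terms
    catalog = SubstrateCatalog(fingerprints=fingerprints, embeddings=embeddings)

    # --- disease ontology and terms ---------------------------------
    dis_onto, dis_leaves = build_toy_ontology(
        "DIS", k, spec["depth"], spec["branching"], root_label="disease")
    areas = sorted({t for t in dis_onto.graph.nodes
                    if any(kk == "is_a" and p == "DIS:0000001"
                           for _, p, kk in dis_onto.graph.out_edges(t, keys=True))})
    all_dis_leaves = [t for leaves in dis_leaves for t in leaves]
    diseases: dict[str, set] = {}
    for i, e in enumerate(entities):
        own = rng.choice(dis_leaves[labels[i]], size=rng.integers(1, 4), replace=True)
        terms = {
            (rng.choice(all_dis_leaves) if rng.random() < noise["disease"] else t)
            for t in own.tolist()}
        diseases[e] = terms

    # --- structure similarity ---------------------------------------
    latent = centers[labels] + noise["structure"] * rng.normal(size=(n, cfg.latent_dim))
    diff = latent[:, None, :] - latent[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    dmax = d.max() if d.max() > 0 else 1.0
    sim = 1.0 - d / dmax
    np.fill_diagonal(sim, 1.0)
    structure_sim = pd.DataFrame(np.clip(sim, 0.0, 1.0), index=entities, columns=entities)

    # --- missingness -------------------------------------------------
    for mod in PROFILE_MODALITIES:
        keep = rng.random(n) < cfg.coverage[mod]
        profiles[mod] = profiles[mod].loc[keep]
    for mod, table in (("interactome", interactors), ("localization", locations),
                       ("substrate", substrates), ("disease", diseases)):
        keep = rng.random(n) < cfg.coverage[mod]
        for i, e in enumerate(entities):
            if not keep[i]:
                table.pop(e, None)

    return SyntheticWorld(
        config=cfg, entities=entities, planted_labels=labels,
        profiles=profiles, interactors=interactors, locations=locations,
        substrates=substrates, diseases=diseases, structure_sim=structure_sim,
        catalog=catalog, substrate_ontology=sub_onto, disease_ontology=dis_onto,
        disease_areas=areas)


# ------------------------------------------------------------------ files
_SET_FILES = {"interactome": ("interactome.tsv", "interactor"),
              "localization": ("localization.tsv", "location"),
              "substrate": ("substrate.tsv", "substrate"),
              "disease": ("disease.tsv", "disease_term")}


def write_world(world: SyntheticWorld, directory) -> dict:
    """Write every modality table, the toy ontologies and the planted
    labels; returns the file manifest (also written as manifest.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for mod in PROFILE_MODALITIES:
        manifest[mod] = mio.write_profiles(world.profiles[mod], directory / f"{mod}.tsv").name
    for mod, (fname, col) in _SET_FILES.items():
        sets = getattr(world, {"interactome": "interactors", "localization": "locations",
                               "substrate": "substrates", "disease": "diseases"}[mod])
        manifest[mod] = mio.write_sets(sets, directory / fname, columns=("id", col)).name
    manifest["structure"] = mio.write_matrix(world.structure_sim, directory / "structure.tsv").name
    manifest["substrate_ontology"] = write_obo(
        world.substrate_ontology, directory / "substrate_ontology.obo", "toy-substances").name
    manifest["disease_ontology"] = write_obo(
        world.disease_ontology, directory / "disease_ontology.obo", "toy-diseases").name
    pd.DataFrame({"id": world.entities, "planted": world.planted_labels}).to_csv(
        directory / "planted_labels.tsv", sep="\t", index=False)
    manifest["planted_labels"] = "planted_labels.tsv"
    fp_rows = [(s, ",".join(map(str, sorted(bits))))
               for s, bits in sorted(world.catalog.fingerprints.items())]
    pd.DataFrame(fp_rows, columns=["substrate", "bits"]).to_csv(
        directory / "fingerprints.tsv", sep="\t", index=False)
    manifest["fingerprints"] = "fingerprints.tsv"
    emb = pd.DataFrame({s: world.catalog.embeddings[s]
                        for s in sorted(world.catalog.embeddings)}).T
    emb.columns = [f"v{j:02d}" for j in range(emb.shape[1])] if emb.shape[1] else []
    emb.to_csv(directory / "elements.tsv", sep="\t", float_format="%.10g",
               index_label="substrate")
    manifest["elements"] = "elements.tsv"
    meta = {
        "entities": world.entities,
        "disease_areas": world.disease_areas,
        "files": manifest,
        "n_clusters": int(world.config.n_clusters),
        "seed": int(world.config.seed),
    }
    mio.write_json(meta, directory / "manifest.json")
    manifest["manifest"] = "manifest.json"
    return manifest


def read_world(directory) -> SyntheticWorld:
    """Read a written world back; inverse of :func:`write_world` up to
    float formatting precision."""
    from .ontology import load_obo

    directory = Path(directory)
    meta = json.loads((directory / "manifest.json").read_text())
    files = meta["files"]
    entities = [str(e) for e in meta["entities"]]
    labels_df = pd.read_csv(directory / files["planted_labels"], sep="\t", dtype={"id": str})
    labels = labels_df.set_index("id").loc[entities, "planted"].to_numpy()
    profiles = {m: mio.read_profiles(directory / files[m]) for m in PROFILE_MODALITIES}
    sets = {m: mio.read_sets(directory / files[m]) for m in _SET_FILES}
    structure = mio.read_matrix(directory / files["structure"])
    fp_df = pd.read_csv(directory / files["fingerprints"], sep="\t", dtype=str)
    fingerprints = {row["substrate"]: {int(b) for b in row["bits"].split(",")}
                    for _, row in fp_df.iterrows()}
    emb_df = pd.read_csv(directory / files["elements"], sep="\t", index_col=0)
    embeddings = {str(s): emb_df.loc[s].to_numpy(dtype=float) for s in emb_df.index}
    catalog = SubstrateCatalog(fingerprints=fingerprints, embeddings=embeddings)
    cfg = GeneratorConfig(n_entities=len(entities), n_clusters=meta["n_clusters"],
                          seed=meta["seed"])
    return SyntheticWorld(
        config=cfg, entities=entities, planted_labels=labels,
        profiles=profiles, interactors=sets["interactome"],
        locations=sets["localization"], substrates=sets["substrate"],
        diseases=sets["disease"], structure_sim=structure, catalog=catalog,
        substrate_ontology=load_obo(directory / files["substrate_ontology"]),
        disease_ontology=load_obo(directory / files["disease_ontology"]),
        disease_areas=[str(a) for a in meta["disease_areas"]])
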