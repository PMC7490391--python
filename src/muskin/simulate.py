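"""Synthetic study-bundle generator with planted, quantified structure.

Generates paired DNA/RNA count tables for one wild population spread over
spatially distributed farms and three laboratory facilities, with:

* shared core taxa present in every group,
* group-specific core taxa (core in exactly one group),
* a wild-only rare biosphere (many very-low-abundance taxa),
* "carry-over" taxa present at the DNA level but transcriptionally silent,
* spatially autocorrelated farm effects (exponential covariance,
  sigma2_farm * exp(-d/rho)) that plant a distance-decay signal,
* reagent contaminants whose expected relative frequency is inversely
  proportional to the sample's nucleic-acid concentration, plus negative
  extraction controls,
* microsatellite genotypes and D-loop haplotypes whose genetic distances
  correlate with geography through spatially clustered demes.

The composition model is logistic-normal -> multinomial: per sample the
expected log relative abundance is group profile + farm effect +
individual noise, exponentiated and renormalized, then counts are drawn
multinomially at the sample's depth.  All truth needed by recovery tests
is returned as :class:`TruthLabels`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import seed_sequence
from .types import (
    DNA,
    RNA,
    FeatureTable,
    GenotypeTable,
    SampleMetadata,
    SequenceSet,
    TaxonomyTable,
)
from .io import StudyBundle

logger = logging.getLogger(__name__)

WILD = "wild"
LAB_GROUPS = ("HL-Lab", "MPI-Lab", "C57BL/6J")
CONTROL_GROUP = "control"

_PHYLA = ("Firmicutes", "Actinobacteria", "Proteobacteria", "Bacteroidetes")


@dataclass
class SimulationConfig:
    """Desk-scale defaults keep the full pipeline in the minutes range;
    ``paper_scale()`` restores the study's group sizes."""

    n_per_group: dict = field(default_factory=lambda: {
        WILD: 60, "HL-Lab": 20, "MPI-Lab": 10, "C57BL/6J": 8})
    n_farms: int = 12
    target_mean_site_distance_km: float = 10.0
    site_distance_sd_km: float = 6.0
    site_tolerance: float = 0.15
    site_max_retries: int = 500

    n_shared_core: int = 30
    n_group_specific: int = 8
    n_carryover: int = 4
    # rare biosphere, two tiers: a subdominant tier present in every group
    # (counts in the low single digits) and an ultra-rare wild-only tier
    # that surfaces as per-sample singletons
    n_subdominant: int = 12
    n_wild_subdominant: int = 6         # wild-only low-abundance taxa
    subdominant_log_range: tuple = (-1.5, -0.5)
    n_rare_tail: int = 80
    rare_tail_log_mean: float = -7.6
    rare_tail_shape: float = 2.0        # Exp scale of extra log-depression
    core_log_mean: float = 2.0
    core_log_sd: float = 0.5

    rho_km: float = 5.0                 # spatial decay length of farm effects
    sigma2_farm: float = 1.0
    sigma2_individual: float = 0.25
    activity_log_sd: float = 0.75       # RNA activity multiplier spread

    n_contaminants: int = 20
    ambient_load_range: tuple = (0.5, 2.0)   # expected freq = load / concentration
    concentration_log_mean: float = 1.0
    concentration_log_sd: float = 1.0
    n_controls: int = 4
    control_depth: int = 300
    crosstalk_reads: int = 20

    depth_log_mean: float = 9.1         # ~ 9000 reads
    depth_log_sd: float = 0.25
    depth_min: int = 4500

    n_genetic_clusters: int = 3
    n_loci: int = 18
    n_alleles_per_locus: int = 8
    dloop_length: int = 300
    cluster_mutation_rate: float = 0.03
    individual_mutation_rate: float = 0.003

    @staticmethod
    def paper_scale() -> "SimulationConfig":
        return SimulationConfig(
            n_per_group={WILD: 203, "HL-Lab": 225, "MPI-Lab": 29, "C57BL/6J": 13},
            n_farms=34, n_shared_core=60, n_group_specific=20,
            n_rare_tail=600,
        )

    def validate(self) -> None:
        if any(v < 0 for v in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        if self.rho_km <= 0:
            raise ValueError("rho_km must be > 0")
        if self.sigma2_farm < 0 or self.sigma2_individual < 0:
            raise ValueError("variances must be >= 0")
        if self.n_farms < 2:
            raise ValueError("need at least 2 farms")


@dataclass
class TruthLabels:
    contaminants: set = field(default_factory=set)
    shared_core: set = field(default_factory=set)
    group_specific: dict = field(default_factory=dict)   # group -> set
    carryover: set = field(default_factory=set)
    rare_tail: set = field(default_factory=set)
    rho_km: float = 0.0
    sigma2_farm: float = 0.0
    sigma2_individual: float = 0.0
    cluster_of: dict = field(default_factory=dict)       # individual -> cluster

    def frames(self) -> dict:
        rows = []
        for fid in sorted(self.contaminants):
            rows.append((fid, "contaminant", ""))
        for fid in sorted(self.shared_core):
            rows.append((fid, "shared_core", ""))
        for group, taxa in sorted(self.group_specific.items()):
            for fid in sorted(taxa):
                rows.append((fid, "group_specific", group))
        for fid in sorted(self.carryover):
            rows.append((fid, "carryover", ""))
        for fid in sorted(self.rare_tail):
            rows.append((fid, "rare_tail", ""))
        features = pd.DataFrame(rows, columns=["feature_id", "role", "group"])
        params = pd.DataFrame(
            [("rho_km", self.rho_km), ("sigma2_farm", self.sigma2_farm),
             ("sigma2_individual", self.sigma2_individual)],
            columns=["parameter", "value"])
        clusters = pd.DataFrame(sorted(self.cluster_of.items()),
                                columns=["individual_id", "cluster"])
        return {"truth_features.tsv": features, "truth_params.tsv": params,
                "truth_clusters.tsv": clusters}


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

def simulate_sites(config: SimulationConfig, seed) -> pd.DataFrame:
    """Farm coordinates whose realized mean pairwise distance falls within
    ``site_tolerance`` of the target; rejection-resampled, deterministic
    given the seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    target = config.target_mean_site_distance_km
    # E[pairwise distance] for an isotropic 2D normal with per-axis sd s
    # is s * sqrt(pi)
    scale = target / np.sqrt(np.pi)
    for _ in range(config.site_max_retries):
        xy = rng.normal(0.0, scale, size=(config.n_farms, 2))
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        iu = np.triu_indices(config.n_farms, k=1)
        mean_d = dist[iu].mean()
        if abs(mean_d - target) <= config.site_tolerance * target:
            farms = [f"F{i+1:02d}" for i in range(config.n_farms)]
            return pd.DataFrame({"x_km": xy[:, 0], "y_km": xy[:, 1]},
                                index=pd.Index(farms, name="farm_id"))
    raise ValueError(
        f"could not reach mean site distance {target} km within "
        f"{config.site_max_retries} resamples")


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _feature_universe(config: SimulationConfig) -> tuple[list, TruthLabels]:
    truth = TruthLabels(rho_km=config.rho_km, sigma2_farm=config.sigma2_farm,
                        sigma2_individual=config.sigma2_individual)
    features: list[str] = []
    truth.shared_core = {f"SH_{i+1:03d}" for i in range(config.n_shared_core)}
    features += sorted(truth.shared_core)
    for group in [WILD, *LAB_GROUPS]:
        tag = group.replace("/", "").replace("-", "")
        taxa = {f"GS_{tag}_{i+1:03d}" for i in range(config.n_group_specific)}
        truth.group_specific[group] = taxa
        features += sorted(taxa)
    truth.carryover = {f"CO_{i+1:03d}" for i in range(config.n_carryover)}
    features += sorted(truth.carryover)
    subdominant = {f"SD_{i+1:03d}" for i in range(config.n_subdominant)}
    wild_sub = {f"SW_{i+1:03d}" for i in range(config.n_wild_subdominant)}
    ultra_rare = {f"RT_{i+1:03d}" for i in range(config.n_rare_tail)}
    truth.rare_tail = subdominant | wild_sub | ultra_rare
    features += sorted(subdominant) + sorted(wild_sub) + sorted(ultra_rare)
    truth.contaminants = {f"CONT_{i+1:03d}" for i in range(config.n_contaminants)}
    features += sorted(truth.contaminants)
    return features, truth


def _group_profiles(config: SimulationConfig, features: list,
                    truth: TruthLabels, rng) -> dict:
    """Per-group expected log relative abundance (unnormalized);
    -inf marks structural absence."""
    groups = [WILD, *LAB_GROUPS]
    profiles = {g: np.full(len(features), -np.inf) for g in groups}
    index = {f: i for i, f in enumerate(features)}

    for fid in sorted(truth.shared_core | truth.carryover):
        base = rng.normal(config.core_log_mean, config.core_log_sd)
        for g in groups:
            profiles[g][index[fid]] = base + rng.normal(0.0, 0.2)
    for g in groups:
        for fid in sorted(truth.group_specific[g]):
            profiles[g][index[fid]] = rng.normal(config.core_log_mean,
                                                 config.core_log_sd)
    lo, hi = config.subdominant_log_range
    for fid in sorted(truth.rare_tail):
        if fid.startswith("SD_"):
            base = rng.uniform(lo, hi)
            for g in groups:
                profiles[g][index[fid]] = base + rng.normal(0.0, 0.1)
        elif fid.startswith("SW_"):
            profiles[WILD][index[fid]] = rng.uniform(lo, hi)
        else:
            profiles[WILD][index[fid]] = (
                config.rare_tail_log_mean
                - rng.exponential(config.rare_tail_shape))
    return profiles


def _spatial_farm_effects(config: SimulationConfig, sites: pd.DataFrame,
                          n_features: int, rng) -> np.ndarray:
    """(n_features, n_farms) effects with across-farm covariance
    sigma2_farm * exp(-d_ij / rho)."""
    xy = sites[["x_km", "y_km"]].to_numpy()
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    cov = config.sigma2_farm * np.exp(-dist / config.rho_km)
    if config.sigma2_farm == 0:
        return np.zeros((n_features, len(sites)))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(sites)))
    z = rng.standard_normal((n_features, len(sites)))
    return z @ chol.T


def simulate_communities(config: SimulationConfig, sites: pd.DataFrame, seed
                         ) -> tuple[FeatureTable, FeatureTable, SampleMetadata,
                                    TaxonomyTable, TreeNode, TruthLabels]:
    """Generate paired DNA/RNA tables, metadata, taxonomy, a random
    bifurcating feature tree and the truth labels.  Contaminant features
    are allocated (zero counts) but only filled in by
    :func:`simulate_contamination`."""
    config.validate()
    seeds = seed_sequence(seed).spawn(6)
    rng_profile = np.random.default_rng(seeds[0])
    rng_farm = np.random.default_rng(seeds[1])
    rng_sample = np.random.default_rng(seeds[2])
    rng_meta = np.random.default_rng(seeds[3])
    rng_activity = np.random.default_rng(seeds[4])
    rng_tree = np.random.default_rng(seeds[5])

    features, truth = _feature_universe(config)
    index = {f: i for i, f in enumerate(features)}
    profiles = _group_profiles(config, features, truth, rng_profile)
    farm_effects = _spatial_farm_effects(config, sites, len(features), rng_farm)

    # RNA activity multipliers: lognormal per taxon; carry-over taxa silent
    log_activity = rng_activity.normal(0.0, config.activity_log_sd, len(features))
    activity = np.exp(log_activity)
    for fid in truth.carryover:
        activity[index[fid]] = 0.0

    farms = list(sites.index)
    sample_rows = []
    columns_dna = []
    columns_rna = []
    sample_ids = []

    for group in [WILD, *LAB_GROUPS]:
        n = config.n_per_group.get(group, 0)
        tag = group.replace("/", "").replace("-", "")
        for k in range(n):
            sid = f"{tag}_{k+1:03d}"
            sample_ids.append(sid)
            if group == WILD:
                farm = farms[int(rng_meta.integers(len(farms)))]
                x, y = sites.loc[farm, ["x_km", "y_km"]]
                farm_idx = farms.index(farm)
            else:
                farm, x, y, farm_idx = f"{tag}_facility", np.nan, np.nan, None

            eta = profiles[group].copy()
            if farm_idx is not None:
                eta = eta + farm_effects[:, farm_idx]
            eta = eta + rng_sample.normal(
                0.0, np.sqrt(config.sigma2_individual), len(features))

            with np.errstate(over="ignore"):
                weights = np.exp(eta - np.nanmax(eta[np.isfinite(eta)]))
            weights[~np.isfinite(weights)] = 0.0
            p_dna = weights / weights.sum()

            w_rna = p_dna * activity
            p_rna = w_rna / w_rna.sum()

            depth_dna = _draw_depth(config, rng_sample)
            depth_rna = _draw_depth(config, rng_sample)
            columns_dna.append(rng_sample.multinomial(depth_dna, p_dna))
            columns_rna.append(rng_sample.multinomial(depth_rna, p_rna))

            sex = "F" if rng_meta.random() < 0.5 else "M"
            sample_rows.append({
                "sample_id": sid, "group": group, "farm_id": farm,
                "x_km": x, "y_km": y, "sex": sex,
                "weight_g": float(np.round(rng_meta.normal(20.0, 3.0), 2)),
                "body_length_mm": float(np.round(rng_meta.normal(80.0, 5.0), 1)),
                "tail_length_mm": float(np.round(rng_meta.normal(70.0, 5.0), 1)),
                "pregnant": bool(sex == "F" and rng_meta.random() < 0.2),
                "concentration_dna": float(np.round(rng_meta.lognormal(
                    config.concentration_log_mean, config.concentration_log_sd), 4)),
                "concentration_rna": float(np.round(rng_meta.lognormal(
                    config.concentration_log_mean, config.concentration_log_sd), 4)),
                "is_negative_control": False,
            })

    metadata = SampleMetadata(
        pd.DataFrame(sample_rows).set_index("sample_id"))
    table_dna = FeatureTable(features, list(sample_ids),
                             np.array(columns_dna, dtype=np.int64).T, DNA)
    table_rna = FeatureTable(features, list(sample_ids),
                             np.array(columns_rna, dtype=np.int64).T, RNA)
    taxonomy = _random_taxonomy(features, rng_tree)
    tree = _random_tree(features, rng_tree)
    logger.info("simulated %d samples x %d features", len(sample_ids),
                len(features))
    return table_dna, table_rna, metadata, taxonomy, tree, truth


def _draw_depth(config: SimulationConfig, rng) -> int:
    depth = int(rng.lognormal(config.depth_log_mean, config.depth_log_sd))
    return max(depth, config.depth_min)


def _random_taxonomy(features: list, rng) -> TaxonomyTable:
    rows = {}
    for fid in features:
        phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
        cls = f"{phylum}_c{int(rng.integers(3)) + 1}"
        order = f"{cls}_o{int(rng.integers(3)) + 1}"
        family = f"{order}_f{int(rng.integers(3)) + 1}"
        genus = f"g_{fid}" if rng.random() > 0.1 else "Unclassified"
        rows[fid] = dict(zip(("phylum", "class", "order", "family", "genus"),
                             (phylum, cls, order, family, genus)))
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


def _random_tree(features: list, rng) -> TreeNode:
    """Random bifurcating tree over the features with exponential branch
    lengths, built by sequential random joins."""
    nodes = [TreeNode(name=f, length=float(rng.exponential(0.1)))
             for f in features]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right],
                          length=float(rng.exponential(0.1)))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def simulate_contamination(table_dna: FeatureTable, table_rna: FeatureTable,
                           metadata: SampleMetadata, config: SimulationConfig,
                           truth: TruthLabels, seed
                           ) -> tuple[FeatureTable, FeatureTable, SampleMetadata]:
    """Fill in contaminant counts (ambient load independent of biomass, so
    expected relative frequency ~ load / concentration) and append negative
    extraction controls carrying contaminants plus trace cross-talk."""
    if config.n_contaminants == 0:
        return table_dna, table_rna, metadata
    rng = np.random.default_rng(seed)
    cont_ids = sorted(truth.contaminants)
    loads = rng.uniform(*config.ambient_load_range, size=len(cont_ids))
    loads = loads / loads.sum() * 0.04
    # loads sum to 0.04: ~4% expected contaminant reads at concentration 1

    out_tables = []
    for table in (table_dna, table_rna):
        table = table.copy()
        conc = metadata.concentrations(table.dataset_label)
        rows = [table.feature_ids.index(f) for f in cont_ids]
        for j, sid in enumerate(table.sample_ids):
            c = float(conc.loc[sid])
            depth = table.counts[:, j].sum()
            lam = loads * depth / c
            table.counts[rows, j] = rng.poisson(lam)
        out_tables.append(table)
    table_dna, table_rna = out_tables

    # negative controls: ambient contaminants at a tiny pseudo-concentration
    # plus trace cross-talk from a typical real sample
    control_rows = []
    for k in range(config.n_controls):
        sid = f"CTRL_{k+1:02d}"
        control_rows.append({
            "sample_id": sid, "group": CONTROL_GROUP, "farm_id": None,
            "x_km": np.nan, "y_km": np.nan, "sex": None,
            "weight_g": np.nan, "body_length_mm": np.nan,
            "tail_length_mm": np.nan, "pregnant": None,
            "concentration_dna": float(np.round(rng.uniform(0.01, 0.05), 4)),
            "concentration_rna": float(np.round(rng.uniform(0.01, 0.05), 4)),
            "is_negative_control": True,
        })
    control_meta = pd.DataFrame(control_rows).set_index("sample_id")
    new_meta = SampleMetadata(pd.concat([metadata.frame, control_meta]))

    out_tables = []
    for table in (table_dna, table_rna):
        n_feat = len(table.feature_ids)
        rows = [table.feature_ids.index(f) for f in cont_ids]
        real_mean = table.relative_abundance().mean(axis=1)
        cols = []
        for row in control_rows:
            col = np.zeros(n_feat, dtype=np.int64)
            n_ambient = max(config.control_depth - config.crosstalk_reads, 0)
            col[rows] = rng.multinomial(n_ambient, loads / loads.sum())
            col += rng.multinomial(config.crosstalk_reads,
                                   real_mean / real_mean.sum())
            cols.append(col)
        counts = np.column_stack([table.counts] + cols)
        out_tables.append(FeatureTable(
            list(table.feature_ids),
            list(table.sample_ids) + [r["sample_id"] for r in control_rows],
            counts, table.dataset_label))
    table_dna, table_rna = out_tables
    logger.info("planted %d contaminants and %d negative controls",
                len(cont_ids), config.n_controls)
    return table_dna, table_rna, new_meta


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------

def simulate_genetics(config: SimulationConfig, sites: pd.DataFrame,
                      metadata: SampleMetadata, truth: TruthLabels, seed
                      ) -> tuple[GenotypeTable, SequenceSet]:
    """Microsatellite genotypes and D-loop haplotypes for the wild
    individuals.  Farms are clustered spatially (nearest of k seed farms),
    allele frequencies differ per cluster, and D-loop haplotypes mutate
    along a star of cluster branches -- so genetic distance correlates with
    geography by construction."""
    rng = np.random.default_rng(seed)
    wild = metadata.frame[(metadata.frame["group"] == WILD)
                          & ~metadata.is_control()]
    individuals = list(wild.index)
    if not individuals:
        return GenotypeTable([], [f"L{i+1:02d}" for i in range(config.n_loci)]), \
            SequenceSet({}, aligned=True)

    farms = list(sites.index)
    k = min(config.n_genetic_clusters, len(farms))
    centers = rng.choice(len(farms), size=k, replace=False)
    xy = sites[["x_km", "y_km"]].to_numpy()
    d_to_center = np.sqrt(((xy[:, None, :] - xy[centers][None, :, :]) ** 2
                           ).sum(axis=2))
    cluster_of_farm = dict(zip(farms, d_to_center.argmin(axis=1)))

    loci = [f"L{i+1:02d}" for i in range(config.n_loci)]
    freqs = {}
    for ci in range(k):
        for locus in loci:
            alpha = np.full(config.n_alleles_per_locus, 0.3)
            freqs[(ci, locus)] = rng.dirichlet(alpha)

    genotypes = GenotypeTable(individuals, loci)
    for ind in individuals:
        farm = wild.loc[ind, "farm_id"]
        cluster = cluster_of_farm[farm]
        truth.cluster_of[ind] = int(cluster)
        for locus in loci:
            p = freqs[(cluster, locus)]
            a1, a2 = rng.choice(config.n_alleles_per_locus, size=2, p=p) + 100
            genotypes.set_call(ind, locus, (int(a1), int(a2)))

    # D-loop: root sequence, one mutated branch per cluster, then
    # individual-level mutations on top
    bases = np.array(list("ACGT"))
    root = rng.choice(4, size=config.dloop_length)
    cluster_seq = {}
    for ci in range(k):
        seq = root.copy()
        hits = rng.random(config.dloop_length) < config.cluster_mutation_rate
        seq[hits] = (seq[hits] + rng.integers(1, 4, hits.sum())) % 4
        cluster_seq[ci] = seq
    sequences = {}
    for ind in individuals:
        seq = cluster_seq[truth.cluster_of[ind]].copy()
        hits = rng.random(config.dloop_length) < config.individual_mutation_rate
        seq[hits] = (seq[hits] + rng.integers(1, 4, hits.sum())) % 4
        sequences[ind] = "".join(bases[seq])
    return genotypes, SequenceSet(sequences, aligned=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig | None = None, seed: int = 0
                    ) -> tuple[StudyBundle, TruthLabels]:
    """Full bundle: sites -> communities -> contamination -> genetics."""
    config = config or SimulationConfig()
    seeds = seed_sequence(seed).spawn(4)
    sites = simulate_sites(config, seeds[0])
    table_dna, table_rna, metadata, taxonomy, tree, truth = \
        simulate_communities(config, sites, seeds[1])
    table_dna, table_rna, metadata = simulate_contamination(
        table_dna, table_rna, metadata, config, truth, seeds[2])
    genotypes, sequences = simulate_genetics(config, sites, metadata, truth,
                                             seeds[3])
    bundle = StudyBundle(
        table_dna=table_dna, table_rna=table_rna, metadata=metadata,
        taxonomy=taxonomy, tree=tree, sequences=sequences,
        genotypes=genotypes,
    )
    return bundle, truth


def write_truth(truth: TruthLabels, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in truth.frames().items():
        frame.to_csv(directory / name, sep="\t", index=False)
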