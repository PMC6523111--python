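"""Synthetic study systems: trees, niche traits, communities, isotopes.

Generates data with the statistical structure the analysis pipeline
assumes, at the scale of a three-site tropical-forest termite survey:
a ~32-species regional pool on an ultrametric Yule phylogeny, feeding
groups evolving as a sparse Markov jump process (so clades share groups),
δ15N/δ13C signatures evolving by Brownian motion (phylogenetic signal),
15 plots in 3 sites of 5, and per-site community assembly that is random,
environmentally filtered (trait-matched species co-occur, clustering
relatives) or competitively structured (phylogenetically close species
excluded, overdispersing relatives).  Environment covariates follow
per-site means with noise; in the paper-like profile the driest site is
the competitive one, tying assembly mode to the rainfall gradient.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .tree_core import Phylogeny, patristic_distances, write_newick
from .phylo_community import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_communities",
    "simulate_isotope_table",
    "simulate_study",
    "paper_like_config",
]

FEEDING_GROUPS = ("I", "II", "III", "IV")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system (defaults = paper-like scale)."""

    n_species: int = 32
    n_sites: int = 3
    plots_per_site: int = 5
    # per-site assembly: mode in {random, filtering, competition}
    assembly_modes: tuple = ("filtering", "random", "competition")
    assembly_strength: float = 1.0
    birth_rate: float = 1.0
    sigma_d15N: float = 2.0  # Brownian rate (per mil per sqrt branch unit)
    sigma_d13C: float = 1.0
    root_d15N: float = 6.0
    root_d13C: float = -27.0
    feeding_jump_rate: float = 0.4  # Markov jumps per branch-length unit
    richness_mean: float = 8.0  # truncated-Poisson mean per plot
    # per-site environment means: wet/high to dry/low gradient
    site_rainfall_mm: tuple = (1500.0, 1100.0, 700.0)
    site_elevation_m: tuple = (300.0, 180.0, 50.0)
    site_temperature_C: tuple = (26.5, 27.0, 27.7)
    env_noise_frac: float = 0.03  # SD of plot noise as fraction of site mean
    isotope_residual_sd: float = 0.8  # per mil, termite replicates
    litter_site_offsets: tuple = (0.0, 0.0, 1.5)  # per mil, added per site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_sites < 1 or self.plots_per_site < 1:
            raise ValueError("counts must be >= 1 (n_species >= 2)")
        if self.assembly_strength < 0:
            raise ValueError("assembly_strength must be >= 0")
        if len(self.assembly_modes) != self.n_sites:
            raise ValueError("need one assembly mode per site")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default three-site profile: 32 species, 3 x 5 plots, richness 8,
    filtering at the wettest site and competition at the driest."""
    return SimulationConfig(seed=seed, **overrides)


# --------------------------------------------------------------------------
# tree
# --------------------------------------------------------------------------
def simulate_tree(
    n_species: int, birth_rate: float = 1.0, seed: int = 0
) -> Phylogeny:
    """Ultrametric Yule (pure-birth) tree with ``n_species`` tips.

    Exponential waiting times between speciation events; the lineage that
    splits is chosen uniformly.  Tip labels are sp01, sp02, ...
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    # grow the tree forward in time: active lineages accumulate pendant
    # length; a split replaces one lineage by two children
    next_id = 0

    class _N:
        __slots__ = ("children", "length")

        def __init__(self):
            self.children = []
            self.length = 0.0

    root = _N()
    active = [root]
    while len(active) < n_species:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.length += wait
        i = rng.integers(k)
        node = active.pop(int(i))
        left, right = _N(), _N()
        node.children = [left, right]
        active.extend([left, right])
    # final segment so tips are contemporaneous but not zero-length
    wait = rng.exponential(1.0 / (birth_rate * n_species))
    for node in active:
        node.length += wait

    labels = iter(f"sp{i + 1:02d}" for i in range(n_species))
    taxon_ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxon_ns)

    def build(src: _N, dst: dendropy.Node) -> None:
        dst.edge.length = src.length
        if not src.children:
            dst.taxon = taxon_ns.new_taxon(next(labels))
            return
        for ch in src.children:
            build(ch, dst.new_child())

    build(root, dtree.seed_node)
    dtree.seed_node.edge.length = None
    dtree.is_rooted = True
    return Phylogeny(dtree)


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------
def simulate_traits(
    tree: Phylogeny,
    sigma_d15N: float = 2.0,
    sigma_d13C: float = 1.0,
    root_d15N: float = 6.0,
    root_d13C: float = -27.0,
    feeding_jump_rate: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve δ15N/δ13C by Brownian motion and feeding group by a sparse
    Markov jump process along the tree.

    A branch of length t adds N(0, sigma^2 t) to each isotope value and
    Poisson(rate * t) uniform jumps to the feeding group, so clades share
    groups when the rate is low.  Returns a trait table:
    species, feeding_group, d15N, d13C.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def walk(node, d15, d13, grp):
        bl = node.edge.length or 0.0
        if bl > 0:
            d15 = d15 + rng.normal(0.0, sigma_d15N * np.sqrt(bl))
            d13 = d13 + rng.normal(0.0, sigma_d13C * np.sqrt(bl))
            n_jumps = rng.poisson(feeding_jump_rate * bl)
            for _ in range(n_jumps):
                others = [g for g in FEEDING_GROUPS if g != grp]
                grp = others[rng.integers(len(others))]
        if node.is_leaf():
            rows.append(
                {
                    "species": node.taxon.label,
                    "feeding_group": grp,
                    "d15N": d15,
                    "d13C": d13,
                }
            )
            return
        for ch in node.child_nodes():
            walk(ch, d15, d13, grp)

    walk(tree.tree.seed_node, root_d15N, root_d13C, "II")
    order = {lbl: i for i, lbl in enumerate(tree.tip_labels)}
    rows.sort(key=lambda r: order[r["species"]])
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# communities + environment
# --------------------------------------------------------------------------
def _truncated_poisson(rng, mean: float, low: int, high: int) -> int:
    for _ in range(1000):
        k = rng.poisson(mean)
        if low <= k <= high:
            return int(k)
    return int(min(max(low, round(mean)), high))


def _sample_plot(
    rng,
    mode: str,
    strength: float,
    richness: int,
    species: list[str],
    trait: np.ndarray,
    site_optimum: float,
    dist: np.ndarray,
    dist_scale: float,
) -> list[int]:
    n = len(species)
    if mode == "random" or strength == 0:
        return list(rng.choice(n, size=richness, replace=False))
    if mode == "filtering":
        w = np.exp(-strength * np.abs(trait - site_optimum))
        w = w / w.sum()
        return list(rng.choice(n, size=richness, replace=False, p=w))
    if mode == "competition":
        # sequentially admit species at least tau apart on the tree
        tau = 0.5 * strength * dist_scale
        order = rng.permutation(n)
        chosen: list[int] = []
        for cand in order:
            if len(chosen) >= richness:
                break
            if not chosen or dist[cand, chosen].min() >= tau:
                chosen.append(int(cand))
        if len(chosen) < richness:
            logger.warning(
                "competition: richness truncated %d -> %d", richness,
                len(chosen),
            )
        return chosen
    raise ValueError(f"unknown assembly mode {mode!r}")


def simulate_communities(
    tree: Phylogeny,
    traits: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Assemble plot communities and their environment table.

    Per plot: richness ~ truncated Poisson; species drawn per the site's
    assembly mode (random / filtering on δ15N / competition by minimum
    patristic distance); abundances i.i.d. geometric.  Environment values
    are site means plus Gaussian noise.  Returns ``(community, env)`` with
    env columns plot, site, rainfall_mm, elevation_m, temperature_C.
    """
    rng = np.random.default_rng(config.seed + 1)
    species = tree.tip_labels
    dist = patristic_distances(tree).loc[species, species].to_numpy()
    dist_scale = float(np.median(dist[np.triu_indices(len(species), k=1)]))
    trait = (
        traits.set_index("species")["d15N"].reindex(species).to_numpy()
    )
    t_lo, t_hi = trait.min(), trait.max()
    ab_rows, env_rows, sites = [], [], {}
    plot_ids = []
    for s in range(config.n_sites):
        site = f"site{s + 1}"
        mode = config.assembly_modes[s]
        # site trait optimum spread along the observed trait range
        frac = 0.5 if config.n_sites == 1 else s / (config.n_sites - 1)
        optimum = t_lo + frac * (t_hi - t_lo)
        for p in range(config.plots_per_site):
            plot = f"{site}_p{p + 1}"
            richness = _truncated_poisson(
                rng, config.richness_mean, 2, len(species)
            )
            chosen = _sample_plot(
                rng, mode, config.assembly_strength, richness, species,
                trait, optimum, dist, dist_scale,
            )
            counts = np.zeros(len(species), dtype=int)
            counts[chosen] = rng.geometric(0.25, size=len(chosen))
            ab_rows.append(counts)
            plot_ids.append(plot)
            sites[plot] = site
            env_rows.append(
                {
                    "plot": plot,
                    "site": site,
                    "rainfall_mm": rng.normal(
                        config.site_rainfall_mm[s],
                        config.env_noise_frac * config.site_rainfall_mm[s],
                    ),
                    "elevation_m": rng.normal(
                        config.site_elevation_m[s],
                        config.env_noise_frac * config.site_elevation_m[s],
                    ),
                    "temperature_C": rng.normal(
                        config.site_temperature_C[s],
                        config.env_noise_frac * config.site_temperature_C[s],
                    ),
                }
            )
    abundance = pd.DataFrame(ab_rows, index=plot_ids, columns=species)
    community = CommunityMatrix(
        abundance=abundance, sites=pd.Series(sites).reindex(plot_ids)
    )
    return community, pd.DataFrame(env_rows)


# --------------------------------------------------------------------------
# isotopes
# --------------------------------------------------------------------------
def simulate_isotope_table(
    traits: pd.DataFrame,
    community: CommunityMatrix,
    residual_sd: float = 0.8,
    litter_site_offsets: tuple | None = None,
    seed: int = 0,
    litter_per_site: int = 15,
    soil_per_site: int = 5,
) -> pd.DataFrame:
    """Per-sample isotope measurements mirroring the field design.

    Termite rows: species trait mean + N(0, residual_sd), three replicates
    per species per occupied site.  Litter: ``litter_per_site`` rows per
    site around litter baselines (d15N 2.0, d13C -28.5 per mil) plus a
    configurable per-site offset on both elements.  Soil:
    ``soil_per_site`` rows per site with no site effect (baselines d15N
    5.0, d13C -26.0).
    """
    rng = np.random.default_rng(seed)
    site_list = list(pd.unique(community.sites))
    if litter_site_offsets is None:
        litter_site_offsets = tuple(0.0 for _ in site_list)
    tr = traits.set_index("species")
    rows = []
    k = 0
    pres = community.presence()
    for site in site_list:
        plots = [p for p in community.plot_ids if community.sites[p] == site]
        occupied = sorted(
            s for s in community.species if pres.loc[plots, s].any().any()
        )
        for spp in occupied:
            for _ in range(3):
                k += 1
                rows.append(
                    {
                        "sample_id": f"T{k:04d}",
                        "type": "termite",
                        "site": site,
                        "plot": plots[int(rng.integers(len(plots)))],
                        "species": spp,
                        "d15N": tr.loc[spp, "d15N"]
                        + rng.normal(0, residual_sd),
                        "d13C": tr.loc[spp, "d13C"]
                        + rng.normal(0, residual_sd),
                    }
                )
    for si, site in enumerate(site_list):
        off = litter_site_offsets[si]
        for _ in range(litter_per_site):
            k += 1
            rows.append(
                {
                    "sample_id": f"L{k:04d}",
                    "type": "litter",
                    "site": site,
                    "plot": None,
                    "species": None,
                    "d15N": 2.0 + off + rng.normal(0, 0.8),
                    "d13C": -28.5 + off + rng.normal(0, 0.8),
                }
            )
        for _ in range(soil_per_site):
            k += 1
            rows.append(
                {
                    "sample_id": f"S{k:04d}",
                    "type": "soil",
                    "site": site,
                    "plot": None,
                    "species": None,
                    "d15N": 5.0 + rng.normal(0, 0.6),
                    "d13C": -26.0 + rng.normal(0, 0.6),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# whole-study convenience
# --------------------------------------------------------------------------
@dataclass
class StudyData:
    tree: Phylogeny
    traits: pd.DataFrame
    community: CommunityMatrix
    environment: pd.DataFrame
    isotopes: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    """Generate one full synthetic study from a config (deterministic)."""
    cfg = config or SimulationConfig()
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, cfg.seed)
    traits = simulate_traits(
        tree,
        sigma_d15N=cfg.sigma_d15N,
        sigma_d13C=cfg.sigma_d13C,
        root_d15N=cfg.root_d15N,
        root_d13C=cfg.root_d13C,
        feeding_jump_rate=cfg.feeding_jump_rate,
        seed=cfg.seed + 10,
    )
    community, env = simulate_communities(tree, traits, cfg)
    offsets = cfg.litter_site_offsets[: cfg.n_sites]
    isotopes = simulate_isotope_table(
        traits,
        community,
        residual_sd=cfg.isotope_residual_sd,
        litter_site_offsets=offsets,
        seed=cfg.seed + 20,
    )
    return StudyData(tree, traits, community, env, isotopes, cfg)


def write_study(data: StudyData, out_dir) -> None:
    """Write tree.nwk, community.csv, traits.csv, isotopes.csv,
    environment.csv and a provenance JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(data.tree, out / "tree.nwk")
    comm = data.community.abundance.copy()
    comm.insert(0, "site", data.community.sites)
    comm.index.name = "plot"
    comm.reset_index().to_csv(out / "community.csv", index=False)
    data.traits.to_csv(out / "traits.csv", index=False)
    data.isotopes.to_csv(out / "isotopes.csv", index=False)
    data.environment.to_csv(out / "environment.csv", index=False)
    prov = {"config": asdict(data.config) if data.config else None,
            "version": "0.1.0"}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                    default=list))
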