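"""Synthetic community data with a planted conservatism signal.

The generator produces everything the analysis consumes: a Yule tree over
OTUs, environment-affinity vectors whose latent trait diffuses along the
tree under a mean-reverting (Ornstein–Uhlenbeck) process — the conservatism
rate sigma sets how fast lineages forget their ancestral niche while the
stationary variance pins the magnitude of niche differentiation —
environment/project-stratified samples with multinomial read counts,
a taxonomy obtained by cutting the tree at fixed heights, and seasonal
time series with phylogenetically correlated phases.

All randomness flows from one seed; outputs are byte-identical for a
fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import OtuTable, Taxonomy, RANKS
from .timeseries import TimeSeriesTable
from .trees import PhyloTree
from .util import ENV_ORDER, as_rng

#: Raw metadata keywords emitted per canonical environment (exercises the
#: keyword lexicon downstream: 'ocean' and 'sea' must map back to marine).
ENV_SYNONYMS: dict[str, tuple[str, ...]] = {
    "animal": ("animal",),
    "marine": ("marine", "ocean", "sea"),
    "freshwater": ("freshwater", "lake", "river"),
    "plant": ("plant",),
    "soil": ("soil",),
}

#: Softmax input spread after latent standardization: sets how peaked the
#: realized environment affinities are (at sharpness 1 the latent trait is
#: rescaled to this stationary spread before the softmax).
TARGET_NICHE_SPREAD: float = 3.0

DEFAULT_RANK_CUTS: dict[str, float] = {
    "species": 0.04,
    "genus": 0.16,
    "family": 0.28,
    "order": 0.40,
    "class": 0.55,
    "phylum": 0.70,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_otus: int = 300
    n_samples: int = 2000
    n_projects: int = 40
    env_labels: tuple[str, ...] = ENV_ORDER
    #: Sampling probability per environment.  Uniform by default so every
    #: environment-combination baseline is well estimated at desk scale; a
    #: corpus-like skew (host-associated samples dominating) can be configured.
    env_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: Brownian rate of niche-trait evolution per unit branch length.
    conservatism_rate: float = 0.5
    #: Reads per sample: a fixed int or an inclusive (lo, hi) range.
    depth: int | tuple[int, int] = 10_000
    base_abundance_sdlog: float = 1.0
    #: Expected fraction of OTUs present per sample (before affinity weighting).
    occupancy_scale: float = 0.2
    rank_cut_heights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_CUTS)
    )
    coarse_cut_height: float = 0.10
    #: Softmax gain on the latent niche trait: > 1 sharpens affinities
    #: (specialists), < 1 flattens them (generalists).
    affinity_sharpness: float = 1.0
    #: Stationary standard deviation of the latent niche trait; together with
    #: the conservatism rate it sets the niche decorrelation rate
    #: θ = σ²/(2·niche_sd²) per unit branch length.
    niche_sd: float = 0.22

    def __post_init__(self):
        if self.conservatism_rate < 0:
            raise ConfigError("conservatism_rate must be >= 0")
        if len(self.env_labels) != len(self.env_probs):
            raise ConfigError("env_labels and env_probs must have equal length")
        if abs(sum(self.env_probs) - 1.0) > 1e-9:
            raise ConfigError("env_probs must sum to 1")
        ranks_fine_to_coarse = ("species", "genus", "family", "order", "class", "phylum")
        heights = [self.rank_cut_heights[r] for r in ranks_fine_to_coarse]
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise ConfigError("rank_cut_heights must be strictly increasing")

    @property
    def n_environments(self) -> int:
        return len(self.env_labels)


@dataclass
class SyntheticDataset:
    """A generated dataset plus the truth that generated it."""

    tree: PhyloTree
    table: OtuTable           # fine level, metadata attached, child_to_parent set
    taxonomy: Taxonomy
    affinities: np.ndarray    # n_otus × K, rows aligned with tree.leaves
    latents: np.ndarray
    config: SyntheticConfig
    shuffled: bool = False

    @property
    def truth_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.affinities,
            index=pd.Index(self.tree.leaves, name="otu_id"),
            columns=[f"affinity_{e}" for e in self.config.env_labels],
        )
        frame["sigma"] = self.config.conservatism_rate
        return frame


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_leaves: int, seed: int | np.random.Generator | None = None) -> PhyloTree:
    """Yule pure-birth tree with ``n_leaves`` tips, rescaled to root height 1.

    Leaves are labelled ``otu_0001``... in birth order.  The root is the
    first split, so a two-leaf tree is a cherry with tip distance 2.0.
    """
    if n_leaves < 2:
        raise ConfigError("a tree needs at least 2 leaves to form pairs")
    rng = as_rng(seed)
    parent = [-1, 0, 0]          # node 0 = root, nodes 1,2 = its children
    birth = [0.0, 0.0, 0.0]
    tips = [1, 2]
    t = 0.0
    while len(tips) < n_leaves:
        t += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(len(tips)))
        node = tips[k]
        a, b = len(parent), len(parent) + 1
        parent.extend([node, node])
        birth.extend([t, t])
        tips[k] = a
        tips.append(b)
    t += rng.exponential(1.0 / len(tips))
    height = t
    names = {node: f"otu_{i + 1:04d}" for i, node in enumerate(sorted(tips))}
    children: dict[int, list[int]] = {}
    for node, par in enumerate(parent):
        if par >= 0:
            children.setdefault(par, []).append(node)

    def newick(node: int) -> str:
        end = birth[children[node][0]] if node in children else height
        length = (end - birth[node]) / height
        if node in children:
            inner = ",".join(newick(c) for c in children[node])
            return f"({inner}):{length:.10f}"
        return f"{names[node]}:{length:.10f}"

    inner = ",".join(newick(c) for c in children[0])
    return PhyloTree.from_newick(f"({inner});")


# ---------------------------------------------------------------------------
# niche evolution
# ---------------------------------------------------------------------------

def evolve_niche(
    tree: PhyloTree,
    sigma: float,
    K: int,
    seed: int | np.random.Generator | None = None,
    sharpness: float = 1.0,
    niche_sd: float = 0.22,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-reverting niche traits on the tree; leaf affinities are softmax.

    A K-dimensional latent trait starts at 0 at the root and evolves along
    each branch as an Ornstein–Uhlenbeck process with Brownian diffusion
    rate ``sigma`` (variance σ²·branch length per coordinate) and fixed
    stationary standard deviation ``niche_sd``, i.e. mean-reversion rate
    θ = σ²/(2·niche_sd²).  The stationary variance pins the *magnitude* of
    niche differentiation, so the conservatism rate sigma controls only how
    fast lineages forget their ancestral niche: the between-leaf trait
    correlation decays as exp(−θ·d) with patristic distance d.  Small sigma
    therefore means strong conservatism (niche similarity persists across
    deep splits); large sigma decorrelates niches already between close
    relatives.  With sigma = 0 the trait never moves and every leaf has the
    uniform affinity vector.

    Returns (affinities, latents), both n_leaves × K in ``tree.leaves``
    order.  Affinities are softmax rows summing to 1; the softmax input is
    the latent trait standardized to spread ``TARGET_NICHE_SPREAD`` and
    multiplied by ``sharpness``, so the realized niche peakedness does not
    depend on ``niche_sd``.
    """
    rng = as_rng(seed)
    theta = 0.0 if sigma == 0 else sigma * sigma / (2.0 * niche_sd * niche_sd)
    dtree = tree.dendropy_tree()
    latent: dict[int, np.ndarray] = {id(dtree.seed_node): np.zeros(K)}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        parent = latent[id(node.parent_node)]
        length = node.edge.length
        if theta == 0:
            latent[id(node)] = parent
            continue
        shrink = np.exp(-theta * length)
        step_sd = niche_sd * np.sqrt(max(0.0, 1.0 - shrink * shrink))
        latent[id(node)] = parent * shrink + rng.normal(0.0, step_sd, size=K)
    leaves = {lf.taxon.label: latent[id(lf)] for lf in dtree.leaf_node_iter()}
    latents = np.array([leaves[name] for name in tree.leaves])
    z = sharpness * (TARGET_NICHE_SPREAD / niche_sd) * latents
    z = z - z.max(axis=1, keepdims=True)
    aff = np.exp(z)
    aff /= aff.sum(axis=1, keepdims=True)
    return aff, latents


# ---------------------------------------------------------------------------
# sample simulation
# ---------------------------------------------------------------------------

def simulate_samples(
    tree: PhyloTree,
    affinities: np.ndarray,
    config: SyntheticConfig,
    seed: int | np.random.Generator | None = None,
) -> OtuTable:
    """Draw environment/project-stratified samples with multinomial counts.

    Each sample draws an environment from the configured probabilities and a
    project uniformly; each OTU enters with probability
    ``clip(occupancy_scale · K · affinity[env], 0, 1)`` and, if present, gets
    expected relative abundance proportional to
    ``base_abundance(otu) · affinity[env]``.
    """
    rng = as_rng(seed if seed is not None else config.seed)
    n, k = affinities.shape
    if n != tree.n_leaves:
        raise ValidationError("affinities rows must match tree leaves")
    env_idx = rng.choice(k, size=config.n_samples, p=np.asarray(config.env_probs))
    projects = rng.integers(config.n_projects, size=config.n_samples)
    base = rng.lognormal(mean=0.0, sigma=config.base_abundance_sdlog, size=n)
    occ_prob = np.clip(config.occupancy_scale * k * affinities, 0.0, 1.0)
    present = rng.random((config.n_samples, n)) < occ_prob[:, env_idx].T
    weights = (base[None, :] * affinities[:, env_idx].T) * present
    if isinstance(config.depth, tuple):
        depths = rng.integers(config.depth[0], config.depth[1] + 1, size=config.n_samples)
    else:
        depths = np.full(config.n_samples, int(config.depth))
    counts = np.zeros((config.n_samples, n), dtype=np.int64)
    for i in range(config.n_samples):
        tot = weights[i].sum()
        if tot > 0:
            counts[i] = rng.multinomial(depths[i], weights[i] / tot)
    sample_ids = [f"s{i + 1:05d}" for i in range(config.n_samples)]
    keywords = []
    for e in env_idx:
        options = ENV_SYNONYMS[config.env_labels[e]]
        keywords.append([options[int(rng.integers(len(options)))]])
    meta = pd.DataFrame(
        {
            "project_id": [f"proj{p + 1:03d}" for p in projects],
            "env_keywords": keywords,
            "environments": [frozenset({config.env_labels[e]}) for e in env_idx],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    groups = tree.leaf_groups_at_age(config.coarse_cut_height)
    child_to_parent = {
        leaf: f"otu90_{groups[leaf] + 1:04d}" for leaf in tree.leaves
    }
    return OtuTable(
        counts,
        sample_ids,
        list(tree.leaves),
        level="99",
        meta=meta,
        child_to_parent=child_to_parent,
    )


# ---------------------------------------------------------------------------
# taxonomy simulation
# ---------------------------------------------------------------------------

def simulate_taxonomy(
    tree: PhyloTree, rank_cut_heights: Mapping[str, float] | None = None
) -> Taxonomy:
    """Taxonomy from tree-height cuts so ranks track phylogenetic distance.

    For each rank threshold, leaves are grouped into the maximal clades whose
    stem crosses that height; finer thresholds nest within coarser ones by
    construction.  All leaves share one domain label.
    """
    cuts = dict(DEFAULT_RANK_CUTS if rank_cut_heights is None else rank_cut_heights)
    group_maps = {
        rank: tree.leaf_groups_at_age(cuts[rank])
        for rank in ("species", "genus", "family", "order", "class", "phylum")
    }
    prefixes = dict(
        species="s", genus="g", family="f", order="o", class_="c", phylum="p"
    )
    lineages = {}
    for leaf in tree.leaves:
        lin = {"domain": "d__0001"}
        for rank, groups in group_maps.items():
            pref = prefixes["class_" if rank == "class" else rank]
            lin[rank] = f"{pref}__{groups[leaf] + 1:04d}"
        lineages[leaf] = tuple(lin[r] for r in RANKS)
    return Taxonomy(lineages)


# ---------------------------------------------------------------------------
# time series simulation
# ---------------------------------------------------------------------------

def simulate_timeseries(
    tree: PhyloTree,
    affinities: np.ndarray | None = None,
    T: int = 48,
    period: float = 12.0,
    amplitude: float = 0.5,
    phase_rate: float = 1.0,
    depth: int = 10_000,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    env_index: int | None = None,
    return_intensity: bool = False,
) -> TimeSeriesTable | tuple[TimeSeriesTable, np.ndarray]:
    """Seasonal abundance profiles with phylogenetically correlated phases.

    Per-OTU expected abundance at timepoint t is
    ``base · max(0, 1 + amplitude · sin(2πt/period + φ))`` (optionally times
    a multiplicative lognormal noise term), with the phase φ evolving along
    the tree by Brownian motion at ``phase_rate``; counts are multinomial at
    ``depth``.  With ``phase_rate = 0`` all OTUs share the root phase.  If
    ``affinities`` and ``env_index`` are given, base abundances are weighted
    by the affinity for that environment (a marine station, say).

    With ``return_intensity`` the underlying T × n expected-abundance matrix
    is returned alongside the count table.  Note that a seasonal factor
    shared by *all* OTUs cancels when counts are renormalized per timepoint
    (compositional closure), so planted co-fluctuation is only recoverable
    from counts when phases differ between OTUs.
    """
    rng = as_rng(seed)
    n = tree.n_leaves
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    if affinities is not None and env_index is not None:
        base = base * affinities[:, env_index]
    root_phase = rng.uniform(0.0, 2 * np.pi)
    dtree = tree.dendropy_tree()
    phase: dict[int, float] = {id(dtree.seed_node): root_phase}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        step = rng.normal(0.0, phase_rate * np.sqrt(node.edge.length))
        phase[id(node)] = phase[id(node.parent_node)] + step
    leaf_phase = np.array(
        [phase[id(lf)] for lf in dtree.leaf_node_iter()]
    )
    # dendropy leaf order matches tree.leaves construction order
    times = np.arange(T, dtype=float)
    counts = np.zeros((T, n), dtype=np.int64)
    intensities = np.zeros((T, n))
    for t in range(T):
        intensity = base * np.maximum(
            0.0, 1.0 + amplitude * np.sin(2 * np.pi * times[t] / period + leaf_phase)
        )
        if noise_sd > 0:
            intensity = intensity * rng.lognormal(0.0, noise_sd, size=n)
        intensities[t] = intensity
        tot = intensity.sum()
        if tot > 0:
            counts[t] = rng.multinomial(depth, intensity / tot)
    table = TimeSeriesTable(times, counts, list(tree.leaves))
    if return_intensity:
        return table, intensities
    return table


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def make_dataset(
    config: SyntheticConfig, shuffle_affinities: bool = False
) -> SyntheticDataset:
    """Generate tree, niches, samples and taxonomy from one configuration.

    With ``shuffle_affinities=True`` the leaf↔affinity assignment is permuted
    before sampling: environment structure is preserved but decoupled from
    the phylogeny, giving a conservatism-free null dataset.
    """
    rng = as_rng(config.seed)
    tree = simulate_tree(config.n_otus, rng)
    aff, latents = evolve_niche(
        tree,
        config.conservatism_rate,
        config.n_environments,
        rng,
        sharpness=config.affinity_sharpness,
        niche_sd=config.niche_sd,
    )
    if shuffle_affinities:
        perm = rng.permutation(config.n_otus)
        aff = aff[perm]
        latents = latents[perm]
    table = simulate_samples(tree, aff, config, rng)
    taxonomy = simulate_taxonomy(tree, config.rank_cut_heights)
    return SyntheticDataset(
        tree=tree,
        table=table,
        taxonomy=taxonomy,
        affinities=aff,
        latents=latents,
        config=config,
        shuffled=shuffle_affinities,
    )
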