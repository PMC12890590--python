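import numpy as np
import pytest
from scipy import stats

from ccons.errors import ConfigError
from ccons.io import qc_filter_samples, write_otu_table
from ccons.simulate import (
    SyntheticConfig,
    evolve_niche,
    make_dataset,
    simulate_samples,
    simulate_taxonomy,
    simulate_timeseries,
    simulate_tree,
)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def test_cherry_has_tip_distance_two():
    tree = simulate_tree(2, seed=0)
    a, b = tree.leaves
    assert tree.distance(a, b) == pytest.approx(2.0)
    assert tree.height == pytest.approx(1.0)


def test_tree_is_deterministic():
    assert simulate_tree(40, seed=7).to_newick() == simulate_tree(40, seed=7).to_newick()


def test_single_leaf_is_error():
    with pytest.raises(ConfigError):
        simulate_tree(1, seed=0)


def test_tree_is_ultrametric_with_unit_height():
    tree = simulate_tree(50, seed=3)
    d = tree.distance_matrix()
    root_to_tip = d.max() / 2
    assert root_to_tip == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# niche evolution
# ---------------------------------------------------------------------------

def test_sigma_zero_gives_uniform_affinities():
    tree = simulate_tree(20, seed=1)
    aff, _ = evolve_niche(tree, sigma=0.0, K=5, seed=2)
    assert np.allclose(aff, 0.2, atol=1e-12)


def test_affinities_are_probability_vectors():
    tree = simulate_tree(50, seed=2)
    aff, _ = evolve_niche(tree, sigma=0.8, K=5, seed=3)
    assert np.allclose(aff.sum(axis=1), 1.0, atol=1e-12)
    assert aff.min() >= 0


def test_affinity_divergence_grows_with_distance():
    """Planted conservatism: |affinity difference| rises with tree distance."""
    tree = simulate_tree(200, seed=4)
    aff, _ = evolve_niche(tree, sigma=0.5, K=5, seed=5)
    d = tree.distance_matrix()
    rng = np.random.default_rng(0)
    ii = rng.integers(200, size=1000)
    jj = rng.integers(200, size=1000)
    keep = ii != jj
    dist = d[ii[keep], jj[keep]]
    l1 = np.abs(aff[ii[keep]] - aff[jj[keep]]).sum(axis=1)
    rho, p = stats.spearmanr(dist, l1)
    assert rho > 0 and p < 1e-6


# ---------------------------------------------------------------------------
# sample simulation
# ---------------------------------------------------------------------------

def test_fixed_depth_is_conserved():
    config = SyntheticConfig(seed=1, n_otus=40, n_samples=60, depth=10_000)
    ds = make_dataset(config)
    totals = ds.table.totals()
    nonzero = totals[totals > 0]
    assert np.all(nonzero == 10_000)


def test_zero_occupancy_yields_table_qc_rejects():
    config = SyntheticConfig(seed=1, n_otus=30, n_samples=40, occupancy_scale=0.0)
    tree = simulate_tree(30, seed=1)
    aff, _ = evolve_niche(tree, 0.5, 5, seed=1)
    table = simulate_samples(tree, aff, config, seed=1)
    kept, report = qc_filter_samples(table)
    assert kept.n_samples == 0
    assert report.n_passed == 0


def test_no_planted_preference_at_sigma_zero():
    """σ = 0: per-environment mean relative abundances stay within noise."""
    config = SyntheticConfig(seed=3, n_otus=40, n_samples=600,
                             conservatism_rate=0.0)
    ds = make_dataset(config)
    rel = ds.table.relative_abundance()
    envs = [next(iter(e)) for e in ds.table.meta["environments"]]
    labels = sorted(set(envs))
    z_count = total = 0
    for j in range(ds.table.n_otus):
        groups = {
            lab: rel[[i for i, e in enumerate(envs) if e == lab], j]
            for lab in labels
        }
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                ga, gb = groups[labels[a]], groups[labels[b]]
                se = np.hypot(ga.std(ddof=1) / np.sqrt(len(ga)),
                              gb.std(ddof=1) / np.sqrt(len(gb)))
                total += 1
                if abs(ga.mean() - gb.mean()) > 3 * se:
                    z_count += 1
    # 3-SE exceedances are rare under the null (a few in hundreds of contrasts)
    assert z_count / total < 0.03


def test_dataset_is_byte_identical_under_fixed_seed(tmp_path):
    config = SyntheticConfig(seed=11, n_otus=40, n_samples=80)
    a, b = make_dataset(config), make_dataset(config)
    assert a.tree.to_newick() == b.tree.to_newick()
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_otu_table(a.table, pa)
    write_otu_table(b.table, pb)
    assert pa.read_bytes() == pb.read_bytes()
    assert np.array_equal(a.affinities, b.affinities)


def test_metadata_keywords_canonicalize_back():
    ds = make_dataset(SyntheticConfig(seed=5, n_otus=30, n_samples=120))
    for envs, kws in zip(ds.table.meta["environments"], ds.table.meta["env_keywords"]):
        assert len(envs) == 1
        # the emitted raw keyword (possibly a synonym) maps onto the drawn env
        from ccons.io import canonicalize_environments

        assert canonicalize_environments(kws) == envs


# ---------------------------------------------------------------------------
# taxonomy simulation
# ---------------------------------------------------------------------------

def test_cherry_below_species_threshold_shares_species():
    tree = simulate_tree(100, seed=6)
    tax = simulate_taxonomy(tree)
    d = tree.distance_matrix()
    i, j = np.unravel_index(np.argmin(d + np.eye(100) * 9), d.shape)
    if d[i, j] < 2 * 0.04:
        a, b = tree.leaves[i], tree.leaves[j]
        assert tax.rank(a, "species") == tax.rank(b, "species")


def test_opposite_sides_of_root_share_only_domain():
    tree = simulate_tree(100, seed=6)
    tax = simulate_taxonomy(tree)
    d = tree.distance_matrix()
    i, j = np.unravel_index(np.argmax(d), d.shape)
    lin_a, lin_b = tax.lineage(tree.leaves[i]), tax.lineage(tree.leaves[j])
    assert lin_a[0] == lin_b[0]          # domain
    assert lin_a[1] != lin_b[1]          # phylum differs (distance ≈ 2)


def test_rank_groups_nest():
    """Every species group sits inside exactly one genus group, and so on."""
    tree = simulate_tree(100, seed=9)
    tax = simulate_taxonomy(tree)
    ranks = ["species", "genus", "family", "order", "class", "phylum"]
    for fine, coarse in zip(ranks, ranks[1:]):
        mapping: dict[str, str] = {}
        for leaf in tree.leaves:
            f, c = tax.rank(leaf, fine), tax.rank(leaf, coarse)
            assert mapping.setdefault(f, c) == c


def test_config_validation():
    with pytest.raises(ConfigError):
        SyntheticConfig(conservatism_rate=-1)
    with pytest.raises(ConfigError):
        SyntheticConfig(env_probs=(0.5, 0.5, 0.2, 0.2, 0.2))
    with pytest.raises(ConfigError):
        SyntheticConfig(rank_cut_heights=dict(
            species=0.2, genus=0.1, family=0.3, order=0.4, phylum=0.7,
            **{"class": 0.5},
        ))


# ---------------------------------------------------------------------------
# time series simulation
# ---------------------------------------------------------------------------

def test_timeseries_same_seed_identical():
    tree = simulate_tree(20, seed=2)
    a = simulate_timeseries(tree, T=24, seed=3)
    b = simulate_timeseries(tree, T=24, seed=3)
    assert np.array_equal(a.counts, b.counts)


def test_shared_phase_intensities_are_perfectly_correlated():
    """phase_rate = 0, no noise: every intensity profile is the same sinusoid
    up to amplitude scaling (Pearson 1)."""
    tree = simulate_tree(30, seed=2)
    _, intensity = simulate_timeseries(
        tree, T=48, period=12.0, amplitude=0.5, phase_rate=0.0, noise_sd=0.0,
        seed=4, return_intensity=True,
    )
    corr = np.corrcoef(intensity, rowvar=False)
    assert corr.min() > 0.9


def test_zero_amplitude_intensities_are_constant():
    tree = simulate_tree(10, seed=2)
    _, intensity = simulate_timeseries(
        tree, T=24, amplitude=0.0, noise_sd=0.0, seed=1, return_intensity=True
    )
    assert np.allclose(intensity, intensity[0], atol=1e-12)
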