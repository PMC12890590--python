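import math

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis

from ccons.errors import ValidationError
from ccons.io import collapse_to_level, qc_filter_samples
from ccons.pairs import OtuPair
from ccons.similarity import (
    BcsEngine,
    BcsSummary,
    bray_curtis_similarity,
    compute_pair_bcs,
    enumerate_comparisons,
    log_transform,
    pair_bcs,
    rarefy,
    restrict_richness,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# the BCS formula
# ---------------------------------------------------------------------------

def test_bcs_identity_and_disjoint():
    assert bray_curtis_similarity({"a": 3, "b": 7}, {"a": 3, "b": 7}) == 1.0
    assert bray_curtis_similarity({"a": 1}, {"b": 1}) == 0.0


def test_bcs_half_overlap():
    assert bray_curtis_similarity({"a": 2, "b": 2}, {"a": 2, "c": 2}) == pytest.approx(0.5)


def test_bcs_zero_total_is_error():
    with pytest.raises(ValidationError):
        bray_curtis_similarity({"a": 0}, {"a": 1})


def test_bcs_scale_invariant_and_symmetric():
    u, v = {"a": 3, "b": 9}, {"a": 5, "b": 1, "c": 4}
    s = bray_curtis_similarity(u, v)
    assert bray_curtis_similarity(v, u) == pytest.approx(s)
    assert bray_curtis_similarity({k: 10 * c for k, c in u.items()}, v) == pytest.approx(s)
    assert 0.0 <= s <= 1.0


def test_batched_bcs_matches_scipy_oracle():
    """Engine min-sum equals 1 − scipy Bray–Curtis on relative abundances."""
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 50, size=(60, 25))
    counts[counts < 10] = 0
    counts[:, 0] += 1  # keep totals positive
    table = make_table(
        {f"s{i}": {f"o{j}": int(counts[i, j]) for j in range(25) if counts[i, j]}
         for i in range(60)}
    )
    engine = BcsEngine(table)
    x = rng.integers(0, 60, size=500)
    y = rng.integers(0, 60, size=500)
    got = engine.bcs_many(x, y)
    rel = table.relative_abundance()
    want = np.array([1.0 - braycurtis(rel[i], rel[j]) for i, j in zip(x, y)])
    assert np.max(np.abs(got - want)) < 1e-12


# ---------------------------------------------------------------------------
# comparison plans
# ---------------------------------------------------------------------------

def worked_engine(projects=None):
    counts = {
        "A": {"otu1": 5, "otu2": 5, "x": 10},
        "B": {"otu1": 3, "x": 10},
        "C": {"otu2": 2, "x": 10},
        "D": {"otu2": 8, "x": 10},
    }
    table = make_table(counts, projects=projects)
    return BcsEngine(table), table


def test_enumerate_comparisons_cross_sets():
    """S_a × S_b minus identical samples: B–A is a valid cross comparison."""
    engine, table = worked_engine()
    plan = enumerate_comparisons("otu1", "otu2", engine)
    got = {(table.sample_ids[i], table.sample_ids[j]) for i, j in zip(plan.x, plan.y)}
    assert got == {("A", "C"), ("A", "D"), ("B", "A"), ("B", "C"), ("B", "D")}
    assert plan.n_total == 5


def test_enumerate_comparisons_same_project_excluded():
    engine, table = worked_engine(
        projects={"A": "p1", "B": "p2", "C": "p2", "D": "p3"}
    )
    plan = enumerate_comparisons("otu1", "otu2", engine)
    got = {(table.sample_ids[i], table.sample_ids[j]) for i, j in zip(plan.x, plan.y)}
    assert ("B", "C") not in got  # same project
    assert plan.n_total == len(plan) == 4


def test_single_shared_sample_gives_empty_plan():
    table = make_table({"A": {"otu1": 1, "otu2": 1}})
    engine = BcsEngine(table)
    plan = enumerate_comparisons("otu1", "otu2", engine)
    assert plan.n_total == 0 and len(plan) == 0


def test_count_identity_on_synthetic_pairs(small_dataset):
    """n_total = |S_a|·|S_b| − |S_a∩S_b| − (cross same-project count), exactly."""
    table, _ = qc_filter_samples(small_dataset.table)
    coarse = collapse_to_level(table)
    engine = BcsEngine(coarse, occupancy_table=table)
    rng = np.random.default_rng(0)
    otus = table.otu_ids
    proj = engine.project_codes
    checked = 0
    for _ in range(120):
        a, b = rng.choice(len(otus), size=2, replace=False)
        sa = set(engine.occupancy(otus[a]).tolist())
        sb = set(engine.occupancy(otus[b]).tolist())
        if not sa or not sb:
            continue
        same_proj = sum(
            1 for x in sa for y in sb if x != y and proj[x] == proj[y]
        )
        expected = len(sa) * len(sb) - len(sa & sb) - same_proj
        plan = enumerate_comparisons(otus[a], otus[b], engine,
                                     max_comparisons=10**9)
        assert plan.n_total == expected
        assert len(plan) == expected
        checked += 1
    assert checked >= 100


def test_subsampling_is_flagged_and_seeded():
    rng = np.random.default_rng(3)
    table = make_table(
        {f"s{i}": {"otu1": 1, "x": int(rng.integers(1, 9))} for i in range(30)}
        | {f"t{i}": {"otu2": 1, "x": int(rng.integers(1, 9))} for i in range(30)}
    )
    engine = BcsEngine(table)
    p1 = enumerate_comparisons("otu1", "otu2", engine, max_comparisons=50, seed=7)
    p2 = enumerate_comparisons("otu1", "otu2", engine, max_comparisons=50, seed=7)
    assert p1.subsampled and len(p1) == 50
    assert np.array_equal(p1.x, p2.x) and np.array_equal(p1.y, p2.y)
    assert p1.n_total == 900


# ---------------------------------------------------------------------------
# per-pair summaries
# ---------------------------------------------------------------------------

def test_pair_bcs_aggregation_of_known_values():
    """Mean/median of the values {0.5, 0.2, 0.8, 0.1} → 0.4 and 0.35."""

    class StubEngine(BcsEngine):
        def __init__(self):
            table = make_table(
                {"A": {"otu1": 1}, "B": {"otu1": 1}, "C": {"otu2": 1}, "D": {"otu2": 1}}
            )
            super().__init__(table)

        def bcs_many(self, x, y):
            return np.array([0.5, 0.2, 0.8, 0.1][: len(x)])

    pair = OtuPair("otu1", "otu2", distance=0.5)
    summary = pair_bcs(pair, StubEngine())
    assert summary.n_comparisons == 4
    assert summary.mean == pytest.approx(0.4)
    assert summary.quantiles[0.5] == pytest.approx(0.35)


def test_empty_plan_is_flagged_not_dropped():
    table = make_table({"A": {"otu1": 2, "otu2": 3}})
    engine = BcsEngine(table)
    pair = OtuPair("otu1", "otu2", distance=0.1)
    summary = pair_bcs(pair, engine)
    assert summary.n_comparisons == 0
    assert math.isnan(summary.mean)
    assert "empty_plan" in summary.flags
    assert pair.flags == "empty_plan"


def test_identical_compositions_across_projects_give_mean_one():
    table = make_table(
        {"A": {"o1": 10, "o2": 30}, "B": {"o1": 10, "o2": 30}},
        projects={"A": "p1", "B": "p2"},
    )
    engine = BcsEngine(table)
    pair = OtuPair("o1", "o2", distance=0.2)
    summary = pair_bcs(pair, engine)
    assert summary.mean == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# robustness variants
# ---------------------------------------------------------------------------

def test_rarefy_preserves_depth_and_is_seeded():
    counts = {"a": 500, "b": 300, "c": 200}
    out = rarefy(counts, 100, seed=5)
    assert sum(out.values()) == 100
    assert out == rarefy(counts, 100, seed=5)
    assert rarefy(counts, 1000, seed=5) == counts  # total == depth


def test_rarefy_below_depth_is_error():
    with pytest.raises(ValidationError):
        rarefy({"a": 10}, 100)


def test_restrict_richness():
    counts = {f"o{i:02d}": 100 - i for i in range(60)}
    out = restrict_richness(counts, k=50)
    assert sum(1 for v in out.values() if v > 0) == 50
    small = {"a": 1, "b": 2}
    assert restrict_richness(small, k=50) == small
    # tie at the cut: lexicographically smaller id kept
    tied = {"z": 5, "a": 5, "m": 9}
    out = restrict_richness(tied, k=2)
    assert out["a"] == 5 and out["z"] == 0


def test_log_transform_is_monotone_and_damps_dominance():
    u, v = {"a": 1000, "b": 1}, {"a": 1, "b": 1000}
    raw = bray_curtis_similarity(u, v)
    logv = bray_curtis_similarity(log_transform(u), log_transform(v))
    assert logv > raw
    vals = log_transform({"a": 1, "b": 10, "c": 100})
    assert vals["a"] < vals["b"] < vals["c"]


def test_log_variant_self_similarity_is_one():
    u = {"a": 7, "b": 7, "c": 7}
    assert bray_curtis_similarity(log_transform(u), log_transform(u)) == 1.0


def test_depth_invariance_of_relative_bcs(small_dataset):
    """Mean pair BCS barely moves between rarefaction depths (compositional)."""
    table, _ = qc_filter_samples(small_dataset.table)
    coarse = collapse_to_level(table)
    pairs_spec = [("otu_0001", "otu_0005"), ("otu_0010", "otu_0020")]
    means = {}
    for depth in (10_000, 2_000):
        engine = BcsEngine(coarse, variant="rarefied", depth=depth, seed=0,
                           occupancy_table=table)
        vals = []
        for a, b in pairs_spec:
            pair = OtuPair(a, b, 0.1)
            s = pair_bcs(pair, engine, max_comparisons=200, seed=1)
            if not math.isnan(s.mean):
                vals.append(s.mean)
        means[depth] = np.mean(vals)
    assert abs(means[10_000] - means[2_000]) < 0.02
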