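import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ccons.errors import ConfigError, ValidationError
from ccons.pairs import OtuPair
from ccons.ranks import (
    RankWindows,
    bh_adjust,
    bin_by_rank,
    classify_outliers,
    cohens_d,
    compare_groups,
    conservatism_ratios,
    derive_rank_windows,
    generalism_scores,
    mann_whitney,
    matched_controls,
    phylum_generalism_vs_steepness,
    rank_tests,
    select_extremes,
)

from conftest import make_table


def pair(d, bcs=0.1, rank="species", n=20_000):
    p = OtuPair("a", "b", distance=d, shared_rank=rank)
    p.bcs_mean = bcs
    p.n_comparisons = n
    return p


# ---------------------------------------------------------------------------
# rank bins and the statistics toolbox
# ---------------------------------------------------------------------------

def test_bin_by_rank_sizes():
    pairs = [pair(0.1, rank="species")] * 3 + [pair(0.2, rank="genus")] * 2
    bins = bin_by_rank(pairs)
    assert bins.sizes() == {"species": 3, "genus": 2}


def test_bin_by_rank_empty_and_none():
    assert bin_by_rank([]).sizes() == {}
    bins = bin_by_rank([pair(0.5, rank="none")])
    assert bins.sizes() == {"none": 1}


def test_mann_whitney_exact_small_samples():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_mann_whitney_identical_bins():
    rng = np.random.default_rng(0)
    a = rng.normal(size=200)
    u, p = mann_whitney(a, a)
    assert p > 0.9
    assert cohens_d(a, a) == 0.0


def test_bh_adjust_step_up():
    out = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(out, [0.03, 0.03, 0.03])
    assert np.all(out >= [0.01, 0.02, 0.03])


def test_rank_tests_adjacent_and_vs_none():
    rng = np.random.default_rng(1)
    pairs = (
        [pair(0.05, bcs=v, rank="species") for v in rng.normal(0.3, 0.05, 40)]
        + [pair(0.2, bcs=v, rank="genus") for v in rng.normal(0.2, 0.05, 40)]
        + [pair(1.0, bcs=v, rank="none") for v in rng.normal(0.1, 0.05, 40)]
    )
    bins = bin_by_rank(pairs)
    frame = rank_tests(bins)
    adj = frame[frame.family == "adjacent"]
    assert list(adj.rank_a) == ["species"]
    assert (frame.p_adj >= frame.p - 1e-12).all()
    assert (frame[frame.family == "vs_none"].d > 0).all()


# ---------------------------------------------------------------------------
# rank windows and ratios
# ---------------------------------------------------------------------------

def test_windows_of_uniform_distances():
    rng = np.random.default_rng(3)
    pairs = [pair(d, rank="species") for d in rng.uniform(0, 1, 1000)]
    pairs += [pair(d + 1, rank="genus") for d in rng.uniform(0, 1, 1000)]
    pairs += [pair(d + 2, rank="phylum") for d in rng.uniform(0, 1, 1000)]
    win = derive_rank_windows(pairs)
    lo, hi = win["species"]
    assert lo == pytest.approx(0.2, abs=0.05)
    assert hi == pytest.approx(0.8, abs=0.05)
    assert win.ordered


def test_windows_need_enough_pairs():
    with pytest.raises(ValidationError, match="more"):
        derive_rank_windows([pair(0.1, rank="species")] * 5)


def test_conservatism_ratio_arithmetic():
    windows = RankWindows({"species": (0.0, 0.1), "genus": (0.2, 0.3),
                           "phylum": (0.8, 1.0)})
    pairs = (
        [pair(0.05, bcs=0.08)] * 10
        + [pair(0.25, bcs=0.05)] * 10
        + [pair(0.9, bcs=0.02)] * 10
    )
    ratio = conservatism_ratios(pairs, windows)
    assert ratio.sg_ratio == pytest.approx(1.6)
    assert ratio.sp_ratio == pytest.approx(4.0)


def test_conservatism_ratio_equal_means_is_one():
    windows = RankWindows({"species": (0.0, 0.1), "genus": (0.2, 0.3),
                           "phylum": (0.8, 1.0)})
    pairs = [pair(d, bcs=0.05) for d in (0.05, 0.25, 0.9)]
    ratio = conservatism_ratios(pairs, windows)
    assert ratio.sg_ratio == pytest.approx(1.0)
    assert ratio.sp_ratio == pytest.approx(1.0)


def test_conservatism_ratio_empty_window_is_flagged():
    windows = RankWindows({"species": (0.0, 0.1), "genus": (0.2, 0.3),
                           "phylum": (0.8, 1.0)})
    pairs = [pair(0.05, bcs=0.08)] * 5 + [pair(0.9, bcs=0.02)] * 5
    ratio = conservatism_ratios(pairs, windows)
    assert math.isnan(ratio.sg_ratio)
    assert "empty_window_genus" in ratio.flags


def test_baseline_normalization_rescales_means_not_ratios():
    windows = RankWindows({"species": (0.0, 0.1), "genus": (0.2, 0.3),
                           "phylum": (0.8, 1.0)})
    pairs = [pair(0.05, bcs=0.08)] * 5 + [pair(0.25, bcs=0.04)] * 5 + [
        pair(0.9, bcs=0.02)] * 5
    raw = conservatism_ratios(pairs, windows)
    norm = conservatism_ratios(pairs, windows, baseline=0.04)
    assert norm.window_means["genus"] == pytest.approx(1.0)
    assert norm.sg_ratio == pytest.approx(raw.sg_ratio)


# ---------------------------------------------------------------------------
# generalism
# ---------------------------------------------------------------------------

def generalism_table():
    return make_table(
        {
            "s_an": {"gen": 10, "spec": 90},
            "s_ma": {"gen": 10, "filler": 90},
            "s_fr": {"gen": 10, "filler": 90},
            "s_pl": {"gen": 10, "filler": 90},
        },
        envs={"s_an": {"animal"}, "s_ma": {"marine"}, "s_fr": {"freshwater"},
              "s_pl": {"plant"}},
    )


def test_entropy_extremes():
    scores = generalism_scores(generalism_table())
    assert scores["gen"].entropy == pytest.approx(math.log(4), abs=1e-9)
    assert scores["spec"].entropy == 0.0


def test_entropy_two_even_environments():
    table = make_table(
        {"s1": {"o": 50, "f": 50}, "s2": {"o": 50, "f": 50}},
        envs={"s1": {"animal"}, "s2": {"soil"}},
    )
    assert generalism_scores(table)["o"].entropy == pytest.approx(math.log(2))


def test_entropy_requires_environment():
    table = make_table({"s1": {"o": 5}})
    with pytest.raises(ValidationError):
        generalism_scores(table)


@given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=5))
def test_entropy_bounds(weights):
    p = np.array(weights) / np.sum(weights)
    h = float(-(p * np.log(p)).sum())
    assert -1e-12 <= h <= math.log(len(p)) + 1e-12


def test_select_extremes_sizes_and_disjoint():
    table = generalism_table()
    scores = generalism_scores(table)
    more = {f"o{i}": type(scores["gen"])(f"o{i}", 0.5 + 0.001 * i, {})
            for i in range(97)}
    scores.update(more)  # 100 scored OTUs in total (gen, spec, filler, o0..o96)
    gen, spec = select_extremes(scores, fraction=0.10)
    assert len(gen) == len(spec) == 10
    assert not gen & spec
    assert "spec" in spec and "gen" in gen
    half_g, half_s = select_extremes(scores, fraction=0.5)
    assert len(half_g) == len(half_s) == 50 and not half_g & half_s


def test_phylum_generalism_correlation():
    import pandas as pd

    frame = pd.DataFrame(
        {"mean_entropy": [0.2, 0.5, 0.9, 1.2], "sg_ratio": [3.0, 2.0, 1.5, 1.1]}
    )
    r, p = phylum_generalism_vs_steepness(frame, method="spearman")
    assert r == pytest.approx(-1.0)
    r2, _ = phylum_generalism_vs_steepness(frame, method="pearson")
    assert r2 < -0.9
    with pytest.raises(ValidationError):
        phylum_generalism_vs_steepness(frame.iloc[:2])


# ---------------------------------------------------------------------------
# outliers, matched controls and group comparisons
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d,bcs,n,expected",
    [
        (0.1, 0.02, 20_000, "related_divergent"),
        (0.9, 0.10, 15_000, "distant_similar"),
        (0.5, 0.02, 20_000, "none"),
        (0.5, 0.10, 20_000, "none"),
        (0.1, 0.02, 9_999, "none"),     # too few comparisons
        (0.1, 0.05, 20_000, "none"),    # related but not divergent enough
    ],
)
def test_classify_outliers_rules(d, bcs, n, expected):
    calls = classify_outliers([pair(d, bcs=bcs, n=n)])
    assert calls[0].cls == expected


def test_classify_outliers_is_order_invariant():
    rng = np.random.default_rng(5)
    pairs = [pair(rng.uniform(0, 1.5), bcs=rng.uniform(0, 0.15)) for _ in range(200)]
    calls = {id(c.pair): c.cls for c in classify_outliers(pairs)}
    shuffled = list(pairs)
    rng.shuffle(shuffled)
    calls2 = {id(c.pair): c.cls for c in classify_outliers(shuffled)}
    assert calls == calls2


def test_matched_controls_window_and_self_exclusion():
    focal = [OtuPair("f1", "f2", 0.50)]
    candidates = [OtuPair("f1", "f2", 0.50), OtuPair("c1", "c2", 0.51),
                  OtuPair("c3", "c4", 0.90)]
    controls, unmatched = matched_controls(focal, candidates, window=0.025, seed=0)
    assert unmatched == []
    assert controls[0].key() == ("c1", "c2")  # itself excluded, 0.90 outside


def test_matched_controls_unmatched_reported():
    focal = [OtuPair("f1", "f2", 0.50)]
    candidates = [OtuPair("c1", "c2", 0.90)]
    controls, unmatched = matched_controls(focal, candidates, window=0.025, seed=0)
    assert controls == [None] and unmatched == [0]


def test_compare_groups_signs_and_exact_p():
    frame = compare_groups([5, 6, 7], [1, 2, 3], [1, 2, 3])
    assert (frame.U == 9).all()
    assert np.allclose(frame.p, 0.1)
    assert (frame.d > 0).all()
    same = compare_groups([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4])
    assert np.allclose(same.d, 0.0)
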