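"""Expected-BCS baselines: global, per environment combination, and
phylum-weighted mixtures, plus normalization of signals against them.

The null model asks: how similar are two random communities drawn under the
same exclusion rules as the signal computation (distinct samples, distinct
projects), optionally conditioned on the unordered environment combination
of the two samples?  Per-group (e.g. per-phylum) expectations re-weight the
combination baselines by the group's observed combination frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError
from .pairs import OtuPair
from .similarity import BcsEngine
from .util import ENV_ORDER, UNASSIGNED, as_rng, combo_key

logger = logging.getLogger("ccons.nulls")


@dataclass
class BaselineEntry:
    mean: float
    n: int
    values: np.ndarray | None = None  # retained draws, for bootstrap bands

    @property
    def se(self) -> float:
        if self.values is None or len(self.values) < 2:
            return math.nan
        return float(self.values.std(ddof=1) / math.sqrt(len(self.values)))


@dataclass
class BaselineTable:
    """Mean expected BCS per unordered environment combination, plus global."""

    entries: dict[str, BaselineEntry] = field(default_factory=dict)
    global_: BaselineEntry | None = None

    def value(self, combo: str) -> float:
        if combo not in self.entries:
            raise KeyError(f"no baseline for environment combination {combo!r}")
        return self.entries[combo].mean


@dataclass
class WeightedBaseline:
    """Mixture of combination baselines by empirical combo frequencies."""

    weights: dict[str, float]
    value: float
    table: BaselineTable | None = None


# ---------------------------------------------------------------------------
# random sample-pair draws
# ---------------------------------------------------------------------------

def _random_cross_project_pairs(
    engine: BcsEngine,
    set_a: np.ndarray,
    set_b: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw up to n_pairs (x, y) with x≠y and different projects."""
    proj = engine.project_codes
    xs, ys = [], []
    have = 0
    attempts = 0
    while have < n_pairs and attempts < 50:
        attempts += 1
        m = int((n_pairs - have) * 1.5) + 16
        x = set_a[rng.integers(len(set_a), size=m)]
        y = set_b[rng.integers(len(set_b), size=m)]
        keep = (x != y) & (proj[x] != proj[y])
        xs.append(x[keep])
        ys.append(y[keep])
        have += int(keep.sum())
    if have == 0:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    return np.concatenate(xs)[:n_pairs], np.concatenate(ys)[:n_pairs]


def global_baseline(
    engine: BcsEngine, n_pairs: int = 50_000, seed=None
) -> BaselineEntry:
    """Mean BCS over uniformly drawn distinct cross-project sample pairs."""
    rng = as_rng(seed)
    valid = np.flatnonzero(engine.valid)
    if len(valid) < 2:
        raise ValidationError("need at least 2 valid samples for a baseline")
    x, y = _random_cross_project_pairs(engine, valid, valid, n_pairs, rng)
    if len(x) == 0:
        raise ValidationError("no eligible cross-project sample pairs")
    values = engine.bcs_many(x, y)
    return BaselineEntry(float(values.mean()), len(values), values)


def verify_baseline(
    engine: BcsEngine,
    set_size: int = 2150,
    n_reps: int = 1000,
    comparisons_per_rep: int = 500,
    seed=None,
) -> tuple[float, float]:
    """Baseline cross-check: mean of repeated two-random-set cross BCS means.

    Each rep draws two random sample sets of ``set_size`` and averages the
    BCS of up to ``comparisons_per_rep`` cross comparisons; returns the mean
    of rep means and its standard error.  Estimates the same expectation as
    :func:`global_baseline`.
    """
    rng = as_rng(seed)
    valid = np.flatnonzero(engine.valid)
    if len(valid) < 2:
        raise ValidationError("need at least 2 valid samples")
    size = min(set_size, len(valid))
    rep_means = np.empty(n_reps)
    for r in range(n_reps):
        sa = rng.choice(valid, size=size, replace=len(valid) < set_size)
        sb = rng.choice(valid, size=size, replace=len(valid) < set_size)
        x, y = _random_cross_project_pairs(engine, sa, sb, comparisons_per_rep, rng)
        rep_means[r] = engine.bcs_many(x, y).mean() if len(x) else math.nan
    rep_means = rep_means[np.isfinite(rep_means)]
    if len(rep_means) == 0:
        raise ValidationError("no rep produced eligible comparisons")
    se = float(rep_means.std(ddof=1) / math.sqrt(len(rep_means))) if len(rep_means) > 1 else math.nan
    return float(rep_means.mean()), se


def environment_baselines(
    engine: BcsEngine,
    n_per_combo: int = 10_000,
    seed=None,
    include_unassigned: bool = True,
    aquatic_merge: bool = False,
) -> BaselineTable:
    """Per-environment-combination baselines (soil–soil, animal–soil, ...).

    A sample belongs to the class of every environment label it carries;
    combinations with no eligible cross-project pairs yield a missing entry
    with a warning.  ``aquatic_merge`` pools marine and freshwater into one
    ``aquatic`` class.
    """
    rng = as_rng(seed)
    meta_envs = list(engine.table.meta["environments"])
    labels = list(ENV_ORDER)
    if aquatic_merge:
        labels = ["animal", "aquatic", "plant", "soil"]

    def sample_labels(envs) -> set[str]:
        if not envs:
            return {UNASSIGNED} if include_unassigned else set()
        if aquatic_merge:
            return {"aquatic" if e in ("marine", "freshwater") else e for e in envs}
        return set(envs)

    class_members: dict[str, list[int]] = {lab: [] for lab in labels}
    if include_unassigned:
        class_members[UNASSIGNED] = []
    valid = engine.valid
    for i, envs in enumerate(meta_envs):
        if not valid[i]:
            continue
        for lab in sample_labels(envs):
            class_members[lab].append(i)
    arrays = {lab: np.array(v, dtype=np.intp) for lab, v in class_members.items()}

    out = BaselineTable()
    all_labels = sorted(arrays)
    for i, la in enumerate(all_labels):
        for lb in all_labels[i:]:
            key = combo_key(la, lb)
            sa, sb = arrays[la], arrays[lb]
            if len(sa) == 0 or len(sb) == 0:
                logger.warning("no eligible samples for combination %s", key)
                continue
            x, y = _random_cross_project_pairs(engine, sa, sb, n_per_combo, rng)
            if len(x) == 0:
                logger.warning("no eligible pairs for combination %s", key)
                continue
            values = engine.bcs_many(x, y)
            out.entries[key] = BaselineEntry(float(values.mean()), len(values), values)
    out.global_ = global_baseline(engine, n_pairs=n_per_combo, seed=rng)
    return out


# ---------------------------------------------------------------------------
# weighted baselines and normalization
# ---------------------------------------------------------------------------

def phylum_weighted_baseline(
    pairs: list[OtuPair], baselines: BaselineTable
) -> WeightedBaseline:
    """Mixture baseline for a pair group, weighted by its combo frequencies.

    Every pair must carry an env_combo and every observed combo must have a
    baseline entry; a missing entry is an error naming the combination.
    """
    combos: dict[str, int] = {}
    for p in pairs:
        if p.env_combo is None:
            raise ValidationError(f"pair {p.otu_a}/{p.otu_b} has no env_combo")
        combos[p.env_combo] = combos.get(p.env_combo, 0) + 1
    if not combos:
        raise ValidationError("cannot build a weighted baseline from zero pairs")
    total = sum(combos.values())
    weights = {c: k / total for c, k in combos.items()}
    assert abs(sum(weights.values()) - 1.0) < 1e-9
    missing = [c for c in weights if c not in baselines.entries]
    if missing:
        raise ValidationError(f"no baseline entry for combination(s): {missing}")
    value = sum(w * baselines.entries[c].mean for c, w in weights.items())
    return WeightedBaseline(weights=weights, value=float(value), table=baselines)


def normalize_signal(values, baseline_value: float):
    """Divide signal values by a baseline expectation; 1.0 means at-baseline."""
    if baseline_value == 0 or not math.isfinite(baseline_value):
        raise ConfigError("cannot normalize by a zero or non-finite baseline")
    return np.asarray(values, dtype=float) / baseline_value


def weighted_baseline_band(
    weighted: WeightedBaseline,
    bin_size: int,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """Bootstrap band for the mean of ``bin_size`` null pairs.

    Each bootstrap pair draws an environment combination from the weight
    mixture and one BCS value from that combination's baseline draws; the
    band is the central ``level`` interval of the resulting bin means.
    Treating a null pair as a single comparison-level draw upper-bounds the
    spread of true pair means, so the band is conservative.
    """
    if weighted.table is None:
        raise ValidationError("weighted baseline lacks its underlying table")
    rng = as_rng(seed)
    combos = list(weighted.weights)
    probs = np.array([weighted.weights[c] for c in combos])
    pools = [weighted.table.entries[c].values for c in combos]
    if any(p is None or len(p) == 0 for p in pools):
        raise ValidationError("baseline entries lack stored draws for the band")
    means = np.empty(n_boot)
    for b in range(n_boot):
        picks = rng.choice(len(combos), size=bin_size, p=probs)
        vals = np.array([pools[c][rng.integers(len(pools[c]))] for c in picks])
        means[b] = vals.mean()
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


def null_bin_coverage(
    pairs: list[OtuPair],
    weighted: WeightedBaseline,
    n_bins: int = 20,
    n_boot: int = 500,
    level: float = 0.95,
    seed=None,
) -> float:
    """Fraction of distance bins whose mean pair BCS sits in the null band.

    Pairs are split into ``n_bins`` equal-width distance bins; each bin's
    mean BCS is compared with the bootstrap band of a same-sized mean under
    the weighted baseline.  On conservatism-free data the coverage should
    be near the band level.
    """
    rng = as_rng(seed)
    finite = [p for p in pairs if math.isfinite(p.bcs_mean)]
    if not finite:
        raise ValidationError("no finite pair values to bin")
    d = np.array([p.distance for p in finite])
    y = np.array([p.bcs_mean for p in finite])
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    inside = total = 0
    for b in range(n_bins):
        mask = which == b
        m = int(mask.sum())
        if m == 0:
            continue
        lo, hi = weighted_baseline_band(
            weighted, bin_size=m, n_boot=n_boot, level=level, seed=rng
        )
        total += 1
        if lo <= y[mask].mean() <= hi:
            inside += 1
    return inside / total if total else math.nan
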