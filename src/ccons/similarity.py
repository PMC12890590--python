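"""Bray–Curtis community similarity between the sample sets of OTU pairs.

BCS = 1 − Bray–Curtis dissimilarity, computed on relative abundances at the
coarse OTU level so that it is invariant to sequencing depth.  For a pair
(otu_a, otu_b) every sample containing otu_a is compared with every sample
containing otu_b, excluding identical samples and same-project pairs; the
per-pair statistic is the mean BCS over those comparisons (quantiles are
recorded alongside).  Robustness variants: log-transformed counts,
rarefaction to fixed depth, and richness restriction to the top-k OTUs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .io import OtuTable
from .pairs import OtuPair
from .util import as_rng

logger = logging.getLogger("ccons.similarity")

QUANTILES: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)
VARIANTS: tuple[str, ...] = ("raw", "log", "rarefied", "top_k")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _to_arrays(u, v) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(u, Mapping) or isinstance(v, Mapping):
        keys = sorted(set(u) | set(v))
        return (
            np.array([float(u.get(k, 0)) for k in keys]),
            np.array([float(v.get(k, 0)) for k in keys]),
        )
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("count vectors must have equal length")
    return u, v


def bray_curtis_similarity(u, v, relative: bool = True) -> float:
    """BCS = 2·Σ min(ũ, ṽ) / (Σũ + Σṽ) on relative abundances (default).

    Equals 1 for identical compositions and 0 for disjoint supports.  With
    ``relative=False`` the raw counts are compared instead.
    """
    u, v = _to_arrays(u, v)
    if u.min(initial=0) < 0 or v.min(initial=0) < 0:
        raise ValidationError("counts must be non-negative")
    su, sv = u.sum(), v.sum()
    if su <= 0 or sv <= 0:
        raise ValidationError("zero-total count vector in BCS")
    if relative:
        u, v, su, sv = u / su, v / sv, 1.0, 1.0
    return float(2.0 * np.minimum(u, v).sum() / (su + sv))


def rarefy(counts, depth: int, seed=None):
    """Subsample a count vector to exactly ``depth`` reads.

    Multivariate-hypergeometric (without replacement); a vector whose total
    is below ``depth`` is an error — such samples are discarded upstream.
    """
    rng = as_rng(seed)
    if isinstance(counts, Mapping):
        keys = sorted(counts)
        vec = np.array([int(counts[k]) for k in keys])
        out = rarefy(vec, depth, rng)
        return {k: int(c) for k, c in zip(keys, out)}
    vec = np.asarray(counts, dtype=np.int64)
    total = int(vec.sum())
    if total < depth:
        raise ValidationError(f"total {total} below rarefaction depth {depth}")
    if total == depth:
        return vec.copy()
    return rng.multivariate_hypergeometric(vec, depth)


def restrict_richness(counts, k: int = 50, otu_ids: Sequence[str] | None = None):
    """Keep the k largest counts, zero the rest; ties keep the smaller OTU id."""
    if isinstance(counts, Mapping):
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        keep = {key for key, _ in items[:k]}
        return {key: (val if key in keep else 0) for key, val in counts.items()}
    vec = np.asarray(counts)
    if vec.size <= k:
        return vec.copy()
    ids = np.asarray(otu_ids if otu_ids is not None else np.arange(vec.size))
    order = np.lexsort((ids, -vec))
    out = np.zeros_like(vec)
    out[order[:k]] = vec[order[:k]]
    return out


def log_transform(counts):
    """log(1 + c), applied before relative-abundance normalization."""
    if isinstance(counts, Mapping):
        return {k: math.log1p(v) for k, v in counts.items()}
    return np.log1p(np.asarray(counts, dtype=float))


# ---------------------------------------------------------------------------
# batched engine
# ---------------------------------------------------------------------------

class BcsEngine:
    """Precomputed relative-abundance matrix for fast batched BCS.

    Applies the chosen variant transform to every sample once, then answers
    BCS queries for arbitrary sample-index pairs with vectorized min-sums.
    """

    def __init__(
        self,
        table: OtuTable,
        variant: str = "raw",
        depth: int = 10_000,
        top_k: int = 50,
        seed=None,
        occupancy_table: OtuTable | None = None,
    ):
        if variant not in VARIANTS:
            raise ConfigError(f"unknown BCS variant {variant!r}")
        if occupancy_table is not None and occupancy_table.sample_ids != table.sample_ids:
            raise ValidationError(
                "occupancy table must hold the same samples in the same order"
            )
        self.table = table
        self.occupancy_table = occupancy_table
        self.variant = variant
        rng = as_rng(seed)
        dense = np.asarray(table.counts.todense(), dtype=np.int64)
        totals = dense.sum(axis=1)
        valid = totals > 0
        work = dense.astype(float)
        if variant == "log":
            work = np.log1p(work)
        elif variant == "rarefied":
            valid = totals >= depth
            for i in np.flatnonzero(valid):
                if totals[i] > depth:
                    work[i] = rng.multivariate_hypergeometric(dense[i], depth)
        elif variant == "top_k":
            ids = np.array(table.otu_ids)
            for i in np.flatnonzero(valid):
                work[i] = restrict_richness(work[i], top_k, otu_ids=ids)
        tot = work.sum(axis=1, keepdims=True)
        np.divide(work, tot, out=work, where=tot > 0)
        self.rel = work
        self.valid = valid
        self.project_codes = table.project_codes()

    def bcs_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """BCS for each (sample index, sample index) comparison, chunked."""
        x = np.asarray(x, dtype=np.intp)
        y = np.asarray(y, dtype=np.intp)
        out = np.empty(len(x))
        chunk = max(1, 2_000_000 // max(1, self.rel.shape[1]))
        for s in range(0, len(x), chunk):
            e = s + chunk
            out[s:e] = np.minimum(self.rel[x[s:e]], self.rel[y[s:e]]).sum(axis=1)
        return out

    def occupancy(self, otu_id: str) -> np.ndarray:
        """Indices of valid samples containing the OTU.

        When an ``occupancy_table`` was given (the fine-level table whose
        OTU ids the pairs use), presence is looked up there; compositions
        are still compared at this engine's (coarse) level.
        """
        source = self.occupancy_table if self.occupancy_table is not None else self.table
        try:
            idx = source.presence_samples(otu_id)
        except KeyError:
            # an OTU absent from every retained sample occupies no samples
            return np.empty(0, dtype=np.intp)
        return idx[self.valid[idx]]


# ---------------------------------------------------------------------------
# comparison plans
# ---------------------------------------------------------------------------

@dataclass
class ComparisonPlan:
    """Sample comparisons for one OTU pair under the exclusion rules.

    ``n_total`` is the closed-form count |S_a|·|S_b| − |S_a∩S_b| − (number of
    cross same-project pairs); ``x``/``y`` hold the comparisons actually
    retained (a seeded uniform subsample when n_total exceeds the cap).
    """

    x: np.ndarray
    y: np.ndarray
    n_total: int
    subsampled: bool = False

    def __len__(self) -> int:
        return len(self.x)


def _plan_total(sa: np.ndarray, sb: np.ndarray, proj: np.ndarray) -> int:
    # |S_a|·|S_b| − Σ_p a_p·b_p  ==  |S_a|·|S_b| − |S_a∩S_b| − same-project cross
    pa = np.bincount(proj[sa], minlength=proj.max() + 1 if len(proj) else 1)
    pb = np.bincount(proj[sb], minlength=len(pa))
    return int(len(sa) * len(sb) - (pa * pb).sum())


def enumerate_comparisons(
    otu_a: str,
    otu_b: str,
    engine: BcsEngine,
    max_comparisons: int = 250_000,
    seed=None,
) -> ComparisonPlan:
    """All cross-set sample comparisons for one OTU pair.

    Every sample containing otu_a is paired with every sample containing
    otu_b, excluding identical samples and pairs from the same project.
    Beyond ``max_comparisons`` a seeded uniform subsample is taken (flagged).
    """
    rng = as_rng(seed)
    sa = engine.occupancy(otu_a)
    sb = engine.occupancy(otu_b)
    proj = engine.project_codes
    if len(sa) == 0 or len(sb) == 0:
        return ComparisonPlan(np.empty(0, np.intp), np.empty(0, np.intp), 0)
    n_total = _plan_total(sa, sb, proj)
    if n_total == 0:
        return ComparisonPlan(np.empty(0, np.intp), np.empty(0, np.intp), 0)
    grid = len(sa) * len(sb)
    if grid <= max(4 * max_comparisons, 500_000):
        x = np.repeat(sa, len(sb))
        y = np.tile(sb, len(sa))
        keep = (x != y) & (proj[x] != proj[y])
        x, y = x[keep], y[keep]
        if len(x) > max_comparisons:
            pick = rng.choice(len(x), size=max_comparisons, replace=False)
            return ComparisonPlan(x[pick], y[pick], n_total, subsampled=True)
        return ComparisonPlan(x, y, n_total)
    # huge grids: sample comparisons directly instead of materializing them
    want = min(n_total, max_comparisons)
    xs, ys = [], []
    have = 0
    while have < want:
        m = int((want - have) * 1.5) + 16
        x = sa[rng.integers(len(sa), size=m)]
        y = sb[rng.integers(len(sb), size=m)]
        keep = (x != y) & (proj[x] != proj[y])
        xs.append(x[keep])
        ys.append(y[keep])
        have += int(keep.sum())
    x = np.concatenate(xs)[:want]
    y = np.concatenate(ys)[:want]
    return ComparisonPlan(x, y, n_total, subsampled=True)


# ---------------------------------------------------------------------------
# per-pair summaries
# ---------------------------------------------------------------------------

@dataclass
class BcsSummary:
    mean: float
    quantiles: dict[float, float]
    n_comparisons: int           # closed-form plan size
    n_used: int                  # comparisons actually averaged
    flags: str = ""


def pair_bcs(
    pair: OtuPair,
    engine: BcsEngine,
    max_comparisons: int = 250_000,
    seed=None,
) -> BcsSummary:
    """Mean and quantiles of BCS over a pair's comparison plan.

    Pairs with empty plans are returned with n_comparisons = 0 and flagged,
    not dropped.  The pair's bcs fields are filled in place.
    """
    rng = as_rng(seed)
    plan = enumerate_comparisons(
        pair.otu_a, pair.otu_b, engine, max_comparisons=max_comparisons, seed=rng
    )
    if len(plan) == 0:
        summary = BcsSummary(math.nan, {q: math.nan for q in QUANTILES}, 0, 0,
                             flags="empty_plan")
    else:
        values = engine.bcs_many(plan.x, plan.y)
        quants = {q: float(np.quantile(values, q)) for q in QUANTILES}
        summary = BcsSummary(
            float(values.mean()),
            quants,
            plan.n_total,
            len(values),
            flags="subsampled" if plan.subsampled else "",
        )
    pair.bcs_mean = summary.mean
    pair.bcs_quantiles = summary.quantiles
    pair.n_comparisons = summary.n_comparisons
    pair.flags = summary.flags
    return summary


def compute_pair_bcs(
    pairs: list[OtuPair],
    engine: BcsEngine,
    max_comparisons: int = 250_000,
    seed=None,
) -> list[BcsSummary]:
    """pair_bcs over a list of pairs with one seeded stream."""
    rng = as_rng(seed)
    return [pair_bcs(p, engine, max_comparisons=max_comparisons, seed=rng)
            for p in pairs]
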