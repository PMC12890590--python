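"""OTU pair selection: uniform-over-distance sampling with usage caps.

Pairs of tree leaves are drawn so that their patristic distances cover the
retained range uniformly: the furthest ``trim_fraction`` of distances is
discarded, the rest is split into equal-width bins, and each bin is filled
by seeded rejection sampling while no OTU exceeds its comparison cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import OtuTable, Taxonomy, RANKS
from .trees import PhyloTree, tree_distance
from .util import as_rng, combo_key

logger = logging.getLogger("ccons.pairs")

#: Ranks from most to least specific, as used by shared_rank.
RANKS_FINE_FIRST: tuple[str, ...] = tuple(reversed(RANKS))


@dataclass
class OtuPair:
    """One tested OTU pair with its annotations and (optional) BCS summary."""

    otu_a: str
    otu_b: str
    distance: float
    shared_rank: str = "none"
    env_combo: str | None = None
    shared_sample_fraction: float | None = None
    bcs_mean: float = math.nan
    bcs_quantiles: dict[float, float] = field(default_factory=dict)
    n_comparisons: int = 0
    flags: str = ""

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.otu_a, self.otu_b)))


def pairs_to_frame(pairs: list[OtuPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {
            "otu_a": p.otu_a,
            "otu_b": p.otu_b,
            "distance": p.distance,
            "shared_rank": p.shared_rank,
            "env_combo": p.env_combo,
            "shared_sample_fraction": p.shared_sample_fraction,
            "bcs_mean": p.bcs_mean,
            "n_comparisons": p.n_comparisons,
            "flags": p.flags,
        }
        for q, v in p.bcs_quantiles.items():
            row[f"bcs_q{int(round(q * 100)):02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared taxonomic rank
# ---------------------------------------------------------------------------

def shared_rank(
    lineage_a: tuple[str | None, ...], lineage_b: tuple[str | None, ...]
) -> str:
    """Most specific rank at which both lineages are filled and equal.

    Scans species → domain; returns ``"none"`` if the lineages differ (or
    are missing) at every rank including domain.
    """
    for rank in RANKS_FINE_FIRST:
        idx = RANKS.index(rank)
        a, b = lineage_a[idx], lineage_b[idx]
        if a is not None and b is not None and a == b:
            return rank
    return "none"


# ---------------------------------------------------------------------------
# sample overlap
# ---------------------------------------------------------------------------

def fraction_shared_samples(
    a: str, b: str, table: OtuTable, denominator: str = "union"
) -> float:
    """Occupancy-set overlap of two OTUs: Jaccard by default, min-denominator
    as an option.  Returns 0 when either OTU occupies no samples."""
    sa = set(table.presence_samples(a).tolist())
    sb = set(table.presence_samples(b).tolist())
    inter = len(sa & sb)
    if denominator == "union":
        denom = len(sa | sb)
    elif denominator == "min":
        denom = min(len(sa), len(sb))
    else:
        raise ConfigError(f"unknown denominator {denominator!r}")
    return inter / denom if denom else 0.0


# ---------------------------------------------------------------------------
# uniform-over-distance pair sampling
# ---------------------------------------------------------------------------

def sample_uniform_pairs(
    tree: PhyloTree,
    taxonomy: Taxonomy | None = None,
    n_pairs: int = 1000,
    n_bins: int = 50,
    trim_fraction: float = 0.03,
    max_use: int = 9,
    max_use_small: int | None = None,
    small_pool: int = 3000,
    seed: int | np.random.Generator | None = None,
    main_env: dict[str, str | None] | None = None,
    max_candidate_pairs: int = 2_000_000,
) -> list[OtuPair]:
    """Draw OTU pairs uniformly over phylogenetic distance.

    The candidate range is [0, q] with q the (1 − trim_fraction) distance
    quantile (estimated from up to ``max_candidate_pairs`` random pairs);
    the range is split into ``n_bins`` equal-width bins with quota
    ⌈n_pairs/n_bins⌉ each, trimmed to ``n_pairs`` total, and filled by
    seeded rejection sampling that never uses an OTU more than ``max_use``
    times.  When ``max_use_small`` is set and the leaf pool is smaller than
    ``small_pool``, the relaxed cap applies instead.  Exhausted bins are
    underfilled with a logged warning.
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    if not (0.0 <= trim_fraction < 1.0):
        raise ConfigError("trim_fraction must be in [0, 1)")
    rng = as_rng(seed)
    n = tree.n_leaves
    if n < 2:
        raise ConfigError("tree must have at least 2 leaves")
    n_bins = min(n_bins, max(1, n_pairs))  # degenerate requests: 1 pair per bin
    cap = max_use
    if max_use_small is not None and n < small_pool:
        cap = max_use_small

    n_all = n * (n - 1) // 2
    enumerate_all = n_all <= max_candidate_pairs
    dmat = tree.distance_matrix()
    if enumerate_all:
        iu = np.triu_indices(n, k=1)
        all_d = dmat[iu]
        q = float(np.quantile(all_d, 1.0 - trim_fraction))
    else:
        m = min(100_000, max_candidate_pairs)
        ii = rng.integers(n, size=m)
        jj = rng.integers(n, size=m)
        keep = ii != jj
        q = float(np.quantile(dmat[ii[keep], jj[keep]], 1.0 - trim_fraction))

    edges = np.linspace(0.0, q, n_bins + 1)
    quota = np.full(n_bins, math.ceil(n_pairs / n_bins), dtype=int)
    excess = int(quota.sum() - n_pairs)
    for k in range(excess):  # trim from the last bins
        quota[n_bins - 1 - (k % n_bins)] -= 1

    usage = np.zeros(n, dtype=int)
    chosen: list[tuple[int, int, float]] = []
    taken: set[tuple[int, int]] = set()

    if enumerate_all:
        in_range = all_d <= q
        bin_of = np.minimum(
            np.searchsorted(edges, all_d, side="right") - 1, n_bins - 1
        )
        per_bin: list[np.ndarray] = []
        for b in range(n_bins):
            members = np.flatnonzero(in_range & (bin_of == b))
            rng.shuffle(members)
            per_bin.append(members)
        cursor = np.zeros(n_bins, dtype=int)
        filled = np.zeros(n_bins, dtype=int)
        progress = True
        while progress:
            progress = False
            for b in range(n_bins):
                if filled[b] >= quota[b]:
                    continue
                while cursor[b] < len(per_bin[b]):
                    k = per_bin[b][cursor[b]]
                    cursor[b] += 1
                    i, j = int(iu[0][k]), int(iu[1][k])
                    if usage[i] < cap and usage[j] < cap:
                        usage[i] += 1
                        usage[j] += 1
                        chosen.append((i, j, float(all_d[k])))
                        filled[b] += 1
                        progress = True
                        break
    else:
        # batched rejection sampling for trees too large to enumerate
        filled = np.zeros(n_bins, dtype=int)
        attempts_cap = 10_000 * int(quota.sum())
        attempts = 0
        batch = 50_000
        while filled.sum() < quota.sum() and attempts < attempts_cap:
            attempts += batch
            ii = rng.integers(n, size=batch)
            jj = rng.integers(n, size=batch)
            lo = np.minimum(ii, jj)
            hi = np.maximum(ii, jj)
            d = dmat[lo, hi]
            ok = (lo != hi) & (d <= q)
            bins_of = np.clip(
                np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1
            )
            ok &= filled[bins_of] < quota[bins_of]
            for i, j, dd, b in zip(lo[ok], hi[ok], d[ok], bins_of[ok]):
                if filled[b] >= quota[b]:
                    continue
                key = (int(i), int(j))
                if key in taken or usage[i] >= cap or usage[j] >= cap:
                    continue
                taken.add(key)
                usage[i] += 1
                usage[j] += 1
                chosen.append((int(i), int(j), float(dd)))
                filled[b] += 1

    short = int(quota.sum() - len(chosen))
    if short:
        logger.warning(
            "pair sampler underfilled by %d pairs (exhausted bins)", short
        )

    pairs = []
    for i, j, d in chosen:
        a, b = tree.leaves[i], tree.leaves[j]
        rank = "none"
        if taxonomy is not None and a in taxonomy and b in taxonomy:
            rank = shared_rank(taxonomy.lineage(a), taxonomy.lineage(b))
        combo = None
        if main_env is not None:
            combo = combo_key(main_env.get(a), main_env.get(b))
        pairs.append(
            OtuPair(otu_a=a, otu_b=b, distance=d, shared_rank=rank, env_combo=combo)
        )
    return pairs


def annotate_env_combos(
    pairs: list[OtuPair], main_env: dict[str, str | None]
) -> list[OtuPair]:
    """Fill env_combo on pairs from a per-OTU main-environment map."""
    for p in pairs:
        p.env_combo = combo_key(main_env.get(p.otu_a), main_env.get(p.otu_b))
    return pairs
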