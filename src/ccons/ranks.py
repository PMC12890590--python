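"""Taxonomic-rank statistics, conservatism ratios, generalism scores,
outlier pairs and phylogeny-matched controls.

Pairs are binned by the most specific taxonomic rank they share; adjacent
rank bins are compared with two-sided Mann–Whitney U tests (BH-corrected,
with Cohen's d effect sizes).  Because many OTUs lack full taxonomy, rank
*windows* — the middle 60% of each rank's pair-distance distribution — bin
pairs by distance instead, and the species/genus and species/phylum window
mean ratios quantify curve steepness.  Generalism is the Shannon entropy of
an OTU's normalized mean relative abundances across environments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .io import OtuTable
from .pairs import OtuPair
from .util import ENV_ORDER, as_rng

logger = logging.getLogger("ccons.ranks")

#: Bin order from most to least specific shared rank.
RANK_BIN_ORDER: tuple[str, ...] = (
    "species", "genus", "family", "order", "class", "phylum", "domain", "none",
)


# ---------------------------------------------------------------------------
# rank bins and tests
# ---------------------------------------------------------------------------

@dataclass
class RankBins:
    values: dict[str, np.ndarray]          # rank → pair bcs_mean values
    tests: pd.DataFrame | None = None

    def sizes(self) -> dict[str, int]:
        return {r: len(v) for r, v in self.values.items()}


def bin_by_rank(pairs: list[OtuPair]) -> RankBins:
    """Group pair mean-BCS values by the most specific shared rank."""
    values: dict[str, list[float]] = {}
    for p in pairs:
        values.setdefault(p.shared_rank or "none", []).append(p.bcs_mean)
    return RankBins({r: np.asarray(v, dtype=float) for r, v in values.items()})


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact when both n ≤ 8 (no ties), otherwise
    the normal approximation with tie correction."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    exact = (
        len(a) <= 8 and len(b) <= 8
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def cohens_d(a, b) -> float:
    """Cohen's d with pooled (Bessel-corrected) standard deviation."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return math.nan
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_tests(bins: RankBins, min_n: int = 2) -> pd.DataFrame:
    """Adjacent-rank Mann–Whitney tests plus each rank against the 'none' bin.

    BH adjustment is applied within each family (adjacent; vs-none)
    separately.  The result is also stored on ``bins.tests``.
    """
    present = [r for r in RANK_BIN_ORDER if len(bins.values.get(r, ())) >= min_n]
    rows = []
    for ra, rb in zip(present, present[1:]):
        if ra == "none" or rb == "none":
            continue
        u, p = mann_whitney(bins.values[ra], bins.values[rb])
        rows.append(
            dict(rank_a=ra, rank_b=rb, family="adjacent", U=u, p=p,
                 d=cohens_d(bins.values[ra], bins.values[rb]),
                 n_a=len(bins.values[ra]), n_b=len(bins.values[rb]))
        )
    if "none" in bins.values and len(bins.values["none"]) >= min_n:
        for r in present:
            if r == "none":
                continue
            u, p = mann_whitney(bins.values[r], bins.values["none"])
            rows.append(
                dict(rank_a=r, rank_b="none", family="vs_none", U=u, p=p,
                     d=cohens_d(bins.values[r], bins.values["none"]),
                     n_a=len(bins.values[r]), n_b=len(bins.values["none"]))
            )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adj"] = np.nan
        for fam in frame["family"].unique():
            mask = frame["family"] == fam
            frame.loc[mask, "p_adj"] = bh_adjust(frame.loc[mask, "p"])
    bins.tests = frame
    return frame


# ---------------------------------------------------------------------------
# rank windows and conservatism ratios
# ---------------------------------------------------------------------------

@dataclass
class RankWindows:
    """Distance interval per rank: the middle 60% of that rank's distances."""

    windows: dict[str, tuple[float, float]]
    ordered: bool = True

    def __getitem__(self, rank: str) -> tuple[float, float]:
        return self.windows[rank]


def derive_rank_windows(
    pairs: list[OtuPair],
    ranks: tuple[str, ...] = ("species", "genus", "phylum"),
    min_pairs: int = 10,
    lo_q: float = 0.20,
    hi_q: float = 0.80,
) -> RankWindows:
    """[20th, 80th] distance percentiles of the pairs sharing exactly each rank."""
    windows = {}
    for rank in ranks:
        dists = np.array([p.distance for p in pairs if p.shared_rank == rank])
        if len(dists) < min_pairs:
            raise ValidationError(
                f"only {len(dists)} pairs share rank {rank!r}; "
                f"need at least {min_pairs} — provide more annotated pairs"
            )
        windows[rank] = (float(np.quantile(dists, lo_q)),
                         float(np.quantile(dists, hi_q)))
    mids = [np.mean(windows[r]) for r in ranks]
    ordered = bool(np.all(np.diff(mids) > 0))
    if not ordered:
        logger.warning("rank windows are not ordered by midpoint: %s", windows)
    return RankWindows(windows, ordered=ordered)


@dataclass
class ConservatismRatio:
    """Window mean BCS per rank and the species/genus, species/phylum ratios."""

    group: str
    window_means: dict[str, float]
    window_n: dict[str, int]
    sg_ratio: float
    sp_ratio: float
    flags: list[str] = field(default_factory=list)


def conservatism_ratios(
    pairs: list[OtuPair],
    windows: RankWindows,
    baseline: float | None = None,
    group: str = "all",
) -> ConservatismRatio:
    """Curve steepness of a pair group from its rank-window means.

    Each window's mean is taken over the pairs whose distance falls inside
    it (windows may overlap; membership is interval-wise, as for distance
    bins).  With a baseline, means are divided by it first — the ratios are
    unchanged but the reported means become baseline-normalized.
    """
    means: dict[str, float] = {}
    ns: dict[str, int] = {}
    flags: list[str] = []
    for rank, (lo, hi) in windows.windows.items():
        vals = np.array(
            [p.bcs_mean for p in pairs
             if lo <= p.distance <= hi and math.isfinite(p.bcs_mean)]
        )
        ns[rank] = len(vals)
        if len(vals) == 0:
            means[rank] = math.nan
            flags.append(f"empty_window_{rank}")
            continue
        m = float(vals.mean())
        means[rank] = m / baseline if baseline else m

    def ratio(num: str, den: str) -> float:
        a, b = means.get(num, math.nan), means.get(den, math.nan)
        if not (math.isfinite(a) and math.isfinite(b)) or b <= 0:
            flags.append(f"undefined_{num}_{den}_ratio")
            return math.nan
        return a / b

    return ConservatismRatio(
        group=group,
        window_means=means,
        window_n=ns,
        sg_ratio=ratio("species", "genus"),
        sp_ratio=ratio("species", "phylum"),
        flags=flags,
    )


def window_tests(pairs: list[OtuPair], windows: RankWindows) -> pd.DataFrame:
    """Mann–Whitney contrasts between adjacent rank windows (BH-corrected).

    Pairs are assigned to windows by distance; adjacent windows (in the
    order given by ``windows.windows``) are compared on their pair mean-BCS
    values.
    """
    names = list(windows.windows)
    values = {}
    for rank in names:
        lo, hi = windows[rank]
        values[rank] = np.array(
            [p.bcs_mean for p in pairs
             if lo <= p.distance <= hi and math.isfinite(p.bcs_mean)]
        )
    rows = []
    for ra, rb in zip(names, names[1:]):
        if len(values[ra]) < 2 or len(values[rb]) < 2:
            continue
        u, p = mann_whitney(values[ra], values[rb])
        rows.append(
            dict(rank_a=ra, rank_b=rb, U=u, p=p,
                 d=cohens_d(values[ra], values[rb]),
                 n_a=len(values[ra]), n_b=len(values[rb]))
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adj"] = bh_adjust(frame["p"])
    return frame


# ---------------------------------------------------------------------------
# generalism scores
# ---------------------------------------------------------------------------

@dataclass
class GeneralismScore:
    otu_id: str
    entropy: float
    proportions: dict[str, float]


def generalism_scores(
    table: OtuTable, otu_ids: list[str] | None = None
) -> dict[str, GeneralismScore]:
    """Shannon-entropy habitat generalism score per OTU.

    Per environment, the OTU's mean relative abundance over that
    environment's samples (absences contribute 0) is computed; the
    per-environment means are normalized to sum to 1 and scored with
    H = −Σ p·ln p (0·ln 0 = 0).  H ranges from 0 (specialist) to ln K.
    """
    if otu_ids is None:
        otu_ids = table.otu_ids
    rel = table.relative_abundance()
    env_masks = {
        e: np.array([e in envs for envs in table.meta["environments"]])
        for e in ENV_ORDER
    }
    env_means = {
        e: (rel[mask].mean(axis=0) if mask.any() else np.zeros(table.n_otus))
        for e, mask in env_masks.items()
    }
    out: dict[str, GeneralismScore] = {}
    for otu in otu_ids:
        j = table.otu_index(otu)
        vec = np.array([env_means[e][j] for e in ENV_ORDER])
        tot = vec.sum()
        if tot <= 0:
            raise ValidationError(
                f"OTU {otu!r} occurs in no sample with an assigned environment"
            )
        p = vec / tot
        nz = p[p > 0]
        h = float(-(nz * np.log(nz)).sum())
        out[otu] = GeneralismScore(otu, h, dict(zip(ENV_ORDER, p)))
    return out


def generalism_score(otu_id: str, table: OtuTable) -> GeneralismScore:
    return generalism_scores(table, [otu_id])[otu_id]


def select_extremes(
    scores: dict[str, GeneralismScore], fraction: float = 0.10
) -> tuple[set[str], set[str]]:
    """(generalists, specialists): top/bottom ``fraction`` by entropy.

    Ties break by OTU id; the sets are disjoint by construction.
    """
    if not (0 < fraction <= 0.5):
        raise ConfigError("fraction must be in (0, 0.5]")
    ranked = sorted(scores.values(), key=lambda s: (s.entropy, s.otu_id))
    n = int(len(ranked) * fraction)
    if n == 0:
        raise ValidationError("too few scored OTUs for the requested fraction")
    if ranked[0].entropy == ranked[-1].entropy:
        logger.warning("all generalism scores equal; split is tie-broken by id")
    specialists = {s.otu_id for s in ranked[:n]}
    generalists = {s.otu_id for s in ranked[-n:]}
    return generalists, specialists


def phylum_generalism_vs_steepness(
    per_phylum: pd.DataFrame, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation across phyla between mean generalism H and curve steepness.

    ``per_phylum`` needs columns ``mean_entropy`` and ``sg_ratio`` (one row
    per phylum, already filtered to phyla with enough OTUs).
    """
    if len(per_phylum) < 3:
        raise ValidationError("need at least 3 phyla for a correlation")
    x = per_phylum["mean_entropy"].to_numpy(dtype=float)
    y = per_phylum["sg_ratio"].to_numpy(dtype=float)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ConfigError(f"unknown method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

@dataclass
class OutlierCall:
    pair: OtuPair
    cls: str          # related_divergent | distant_similar | none
    eligible: bool


def classify_outliers(
    pairs: list[OtuPair],
    d_low: float = 0.2,
    bcs_low: float = 0.04,
    d_high: float = 0.8,
    bcs_high: float = 0.08,
    min_n: int = 10_000,
) -> list[OutlierCall]:
    """Flag ecologically informative extreme pairs.

    related_divergent: closely related (distance < d_low) yet dissimilar
    communities (mean BCS < bcs_low); distant_similar: distantly related
    (distance > d_high) yet similar communities (mean BCS > bcs_high).
    Both require at least ``min_n`` sample comparisons.
    """
    calls = []
    for p in pairs:
        eligible = p.n_comparisons >= min_n and math.isfinite(p.bcs_mean)
        cls = "none"
        if eligible and p.distance < d_low and p.bcs_mean < bcs_low:
            cls = "related_divergent"
        elif eligible and p.distance > d_high and p.bcs_mean > bcs_high:
            cls = "distant_similar"
        calls.append(OutlierCall(pair=p, cls=cls, eligible=eligible))
    return calls


# ---------------------------------------------------------------------------
# phylogeny-matched controls and group comparisons
# ---------------------------------------------------------------------------

def matched_controls(
    focal_pairs: list[OtuPair],
    candidate_pairs: list[OtuPair],
    window: float = 0.025,
    seed=None,
) -> tuple[list[OtuPair | None], list[int]]:
    """One distance-matched control per focal pair, drawn without replacement.

    For each focal pair a uniformly drawn candidate with
    |distance − focal distance| ≤ window is selected; candidates identical
    to a focal pair are never their own match.  Returns the aligned control
    list (None where unmatched) and the indices of unmatched focal pairs.
    """
    rng = as_rng(seed)
    cand_d = np.array([c.distance for c in candidate_pairs])
    used = np.zeros(len(candidate_pairs), dtype=bool)
    keys = [c.key() for c in candidate_pairs]
    controls: list[OtuPair | None] = []
    unmatched: list[int] = []
    for i, focal in enumerate(focal_pairs):
        ok = np.flatnonzero(
            (~used)
            & (np.abs(cand_d - focal.distance) <= window)
            & np.array([k != focal.key() for k in keys])
        )
        if len(ok) == 0:
            controls.append(None)
            unmatched.append(i)
            continue
        pick = int(ok[rng.integers(len(ok))])
        used[pick] = True
        controls.append(candidate_pairs[pick])
    if unmatched:
        logger.warning("%d focal pairs had no control in ±%.3f", len(unmatched), window)
    return controls, unmatched


def compare_groups(focal_values, random_values, matched_values) -> pd.DataFrame:
    """Focal vs random and focal vs distance-matched Mann–Whitney/Cohen's d."""
    rows = []
    for name, other in (("random", random_values), ("matched", matched_values)):
        u, p = mann_whitney(focal_values, other)
        rows.append(
            dict(comparison=f"focal_vs_{name}", U=u, p=p,
                 d=cohens_d(focal_values, other),
                 n_focal=len(focal_values), n_other=len(other))
        )
    frame = pd.DataFrame(rows)
    frame["p_adj"] = bh_adjust(frame["p"])
    return frame
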