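"""Temporal consistency check: do related OTUs fluctuate together over time?

Mirrors a station time-series analysis: OTU relative-abundance profiles over
dated samples are correlated pairwise (Pearson), and profile correlation is
related to phylogenetic distance and to globally computed community
similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .trees import PhyloTree

logger = logging.getLogger("ccons.timeseries")


@dataclass
class TimeSeriesTable:
    """Ordered timepoints × OTUs count matrix.

    ``timepoints`` must be strictly increasing.  Multiple samples at one
    timepoint should be averaged (after relative-abundance conversion)
    before constructing the table; :func:`from_samples` does this.
    """

    timepoints: np.ndarray  # shape (T,)
    counts: np.ndarray      # shape (T, n_otus), non-negative
    otu_ids: list[str]

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if self.counts.shape != (len(self.timepoints), len(self.otu_ids)):
            raise ValidationError("counts shape does not match timepoints/otu_ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative counts in time series")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def prevalence(self) -> np.ndarray:
        """Fraction of timepoints in which each OTU is detected."""
        return (self.counts > 0).mean(axis=0)

    def relative_abundance(self, otus: list[str] | None = None) -> pd.DataFrame:
        """Per-timepoint relative abundances over the retained OTU set.

        Normalization uses each timepoint's total *retained* reads, so it is
        applied after any prevalence filtering.
        """
        if otus is None:
            otus = self.otu_ids
        idx = [self.otu_ids.index(o) for o in otus]
        sub = self.counts[:, idx]
        tot = sub.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(tot > 0, sub / tot, 0.0)
        return pd.DataFrame(rel, index=self.timepoints, columns=otus)


def from_samples(
    counts: np.ndarray, dates: np.ndarray, otu_ids: list[str]
) -> TimeSeriesTable:
    """Build a table from per-sample counts, averaging replicate timepoints.

    Replicates (equal dates) are averaged after relative-abundance
    conversion, then re-expressed on a common unit total.
    """
    dates = np.asarray(dates, dtype=float)
    order = np.argsort(dates, kind="stable")
    counts = np.asarray(counts, dtype=float)[order]
    dates = dates[order]
    uniq, inverse = np.unique(dates, return_inverse=True)
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(tot > 0, counts / tot, 0.0)
    merged = np.zeros((len(uniq), counts.shape[1]))
    for t in range(len(uniq)):
        merged[t] = rel[inverse == t].mean(axis=0)
    return TimeSeriesTable(uniq, merged, otu_ids)


def filter_prevalence(ts: TimeSeriesTable, min_prevalence: float = 0.10) -> list[str]:
    """OTUs present in strictly more than ``min_prevalence`` of timepoints."""
    prev = ts.prevalence()
    return [o for o, p in zip(ts.otu_ids, prev) if p > min_prevalence]


def profile_correlations(
    ts: TimeSeriesTable, otus: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix of relative-abundance profiles.

    Returns the correlation matrix over OTUs with nonzero profile variance,
    plus the list of constant-profile OTUs that were flagged and excluded.
    """
    rel = ts.relative_abundance(otus)
    spread = rel.std(axis=0, ddof=0)
    scale = rel.abs().mean(axis=0) + 1e-30
    is_constant = spread <= 1e-9 * scale  # tolerate float residue
    constant = [o for o in rel.columns if is_constant[o]]
    if constant:
        logger.warning("%d constant profiles excluded from correlation", len(constant))
    kept = [o for o in rel.columns if not is_constant[o]]
    if not kept:
        return pd.DataFrame(index=[], columns=[], dtype=float), constant
    mat = np.corrcoef(rel[kept].to_numpy(), rowvar=False)
    mat = np.atleast_2d(mat)
    return pd.DataFrame(mat, index=kept, columns=kept), constant


def correlation_vs_distance(
    correlations: pd.DataFrame, tree: PhyloTree
) -> tuple[pd.DataFrame, dict]:
    """Join profile correlations with tree distances; summarize with Pearson r.

    Returns (pair table, summary).  With fewer than 3 OTU pairs the summary
    correlation is refused (``r`` is None) but the table is still emitted.
    """
    otus = [o for o in correlations.index if tree.has_leaf(o)]
    rows = []
    dmat = tree.distance_matrix()
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            a, b = otus[i], otus[j]
            rows.append(
                (a, b, float(correlations.loc[a, b]),
                 dmat[tree.leaf_index(a), tree.leaf_index(b)])
            )
    table = pd.DataFrame(rows, columns=["otu_a", "otu_b", "profile_r", "distance"])
    if len(table) < 3:
        return table, {"r": None, "p": None, "n": len(table), "flag": "too_few_pairs"}
    r, p = stats.pearsonr(table["profile_r"], table["distance"])
    return table, {"r": float(r), "p": float(p), "n": len(table), "flag": None}


def correlation_vs_global_bcs(
    correlations: pd.DataFrame, pair_bcs: pd.DataFrame
) -> dict:
    """Pearson r between profile correlation and global mean BCS per pair.

    ``pair_bcs`` needs columns otu_a, otu_b, bcs_mean.  Pairs are matched
    unordered; an empty intersection is an error; a constant BCS column is
    flagged as undefined.
    """
    lookup = {}
    for a in correlations.index:
        for b in correlations.columns:
            if a < b:
                lookup[(a, b)] = float(correlations.loc[a, b])
    xs, ys = [], []
    for _, row in pair_bcs.iterrows():
        key = tuple(sorted((row["otu_a"], row["otu_b"])))
        if key in lookup and np.isfinite(row["bcs_mean"]):
            xs.append(lookup[key])
            ys.append(float(row["bcs_mean"]))
    if not xs:
        raise ValidationError("no overlap between time-series pairs and BCS pairs")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.ptp(ys) == 0 or np.ptp(xs) == 0:
        return {"r": None, "p": None, "n": len(xs), "flag": "constant_column"}
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n": len(xs), "flag": None}
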