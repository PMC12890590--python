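"""End-to-end orchestration: dataset → QC → pairs → BCS → trends → ratios.

Glue for running the whole community-conservatism analysis on one dataset
with a single seed, as the tests and the reproduction script do.  Every
step is the public API of the corresponding module; this file adds no
science of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable, collapse_to_level, main_environments, qc_filter_samples
from .nulls import BaselineTable, WeightedBaseline, environment_baselines, phylum_weighted_baseline
from .pairs import OtuPair, sample_uniform_pairs
from .ranks import (
    ConservatismRatio,
    RankWindows,
    conservatism_ratios,
    derive_rank_windows,
    window_tests,
)
from .similarity import BcsEngine, compute_pair_bcs
from .simulate import SyntheticConfig, SyntheticDataset, make_dataset
from .trends import TrendCurve, expdecay_fit, lowess_fit
from .util import as_rng


@dataclass
class ConservatismResult:
    """Everything the main analysis produces for one dataset."""

    pairs: list[OtuPair]
    valid_pairs: list[OtuPair]
    engine: BcsEngine
    table_coarse: OtuTable
    main_env: dict[str, str | None]
    lowess: TrendCurve | None
    expdecay: TrendCurve | None
    windows: RankWindows | None
    ratios: ConservatismRatio | None
    window_tests: pd.DataFrame | None
    baselines: BaselineTable | None = None
    weighted_baseline: WeightedBaseline | None = None

    @property
    def lowess_spearman(self) -> float:
        """Spearman correlation between the lowess fit and distance."""
        rho, _ = stats.spearmanr(self.lowess.grid_x, self.lowess.grid_y)
        return float(rho)


def run_conservatism(
    dataset: SyntheticDataset,
    n_pairs: int = 1200,
    n_bins: int = 50,
    max_use: int = 9,
    max_use_small: int | None = 30,
    max_comparisons: int = 200,
    variant: str = "raw",
    with_baselines: bool = False,
    n_per_combo: int = 2000,
    fit_expdecay: bool = False,
    seed: int | np.random.Generator | None = None,
) -> ConservatismResult:
    """Run the full analysis on a (synthetic) dataset.

    QC-filters samples, collapses counts to the coarse OTU level, assigns
    main environments, samples distance-uniform OTU pairs, computes mean
    BCS per pair, derives rank windows and conservatism ratios, and fits
    the distance→similarity trend.  ``max_comparisons`` caps the seeded
    subsample of sample comparisons per pair.
    """
    rng = as_rng(seed)
    table_qc, _report = qc_filter_samples(dataset.table)
    main_env = main_environments(table_qc)
    coarse = collapse_to_level(table_qc, new_level="90")
    engine = BcsEngine(coarse, variant=variant, seed=rng, occupancy_table=table_qc)
    pairs = sample_uniform_pairs(
        dataset.tree,
        dataset.taxonomy,
        n_pairs=n_pairs,
        n_bins=n_bins,
        max_use=max_use,
        max_use_small=max_use_small,
        seed=rng,
        main_env=main_env,
    )
    compute_pair_bcs(pairs, engine, max_comparisons=max_comparisons, seed=rng)
    valid = [p for p in pairs if np.isfinite(p.bcs_mean)]

    lowess = expdecay = windows = ratios = wtests = None
    if len(valid) >= 10:
        x = np.array([p.distance for p in valid])
        y = np.array([p.bcs_mean for p in valid])
        lowess = lowess_fit(x, y)
        if fit_expdecay:
            expdecay = expdecay_fit(x, y)
        try:
            windows = derive_rank_windows(valid)
            ratios = conservatism_ratios(valid, windows)
            wtests = window_tests(valid, windows)
        except Exception:  # too few annotated pairs at some rank
            windows = ratios = wtests = None

    baselines = weighted = None
    if with_baselines:
        baselines = environment_baselines(engine, n_per_combo=n_per_combo, seed=rng)
        if valid:
            weighted = phylum_weighted_baseline(valid, baselines)

    return ConservatismResult(
        pairs=pairs,
        valid_pairs=valid,
        engine=engine,
        table_coarse=coarse,
        main_env=main_env,
        lowess=lowess,
        expdecay=expdecay,
        windows=windows,
        ratios=ratios,
        window_tests=wtests,
        baselines=baselines,
        weighted_baseline=weighted,
    )


def run_planted(
    sigma: float,
    seed: int,
    n_otus: int = 300,
    n_samples: int = 2000,
    sharpness: float = 1.0,
    niche_sd: float | None = None,
    shuffle: bool = False,
    **kwargs,
) -> tuple[SyntheticDataset, ConservatismResult]:
    """Generate a planted-conservatism dataset and analyse it in one call."""
    extra = {} if niche_sd is None else {"niche_sd": niche_sd}
    config = SyntheticConfig(
        seed=seed,
        n_otus=n_otus,
        n_samples=n_samples,
        conservatism_rate=sigma,
        affinity_sharpness=sharpness,
        **extra,
    )
    dataset = make_dataset(config, shuffle_affinities=shuffle)
    result = run_conservatism(dataset, seed=seed, **kwargs)
    return dataset, result
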