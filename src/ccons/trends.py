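"""Distance→similarity trend fitting: lowess, exponential decay, bootstrap bands.

The headline visualization of the analysis is mean BCS against phylogenetic
distance.  Two fits are provided: a lowess smoother with fixed span
(frac = 1/5, tricube weights, locally linear, 3 robustness iterations) and a
parametric exponential decay y = a·exp(k·x) + c whose coefficient k is the
"decay coefficient".  Confidence bands come from case-resampled bootstrap
lowess fits (pointwise mean ± z·SD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .errors import ValidationError
from .util import as_rng

logger = logging.getLogger("ccons.trends")


@dataclass
class TrendCurve:
    """A fitted distance→similarity curve with optional bootstrap band."""

    kind: str                     # "lowess" | "expdecay"
    grid_x: np.ndarray            # strictly increasing
    grid_y: np.ndarray
    params: tuple[float, float, float] | None = None  # (a, k, c) for expdecay
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def decay_coefficient(self) -> float | None:
        return None if self.params is None else self.params[1]


def _check_xy(x, y, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < min_points:
        raise ValidationError(f"need at least {min_points} finite points, got {len(x)}")
    return x, y


def lowess_fit(x, y, frac: float = 1 / 5, it: int = 3) -> TrendCurve:
    """Locally weighted scatterplot smoothing on the sorted-x grid."""
    x, y = _check_xy(x, y, 10)
    fitted = sm.nonparametric.lowess(y, x, frac=frac, it=it, return_sorted=True)
    gx, gy = fitted[:, 0], fitted[:, 1]
    # average duplicate x so the grid is strictly increasing
    ux, inverse = np.unique(gx, return_inverse=True)
    uy = np.bincount(inverse, weights=gy) / np.bincount(inverse)
    return TrendCurve(kind="lowess", grid_x=ux, grid_y=uy)


def _expdecay(x, a, k, c):
    return a * np.exp(k * x) + c


def expdecay_fit(
    x, y, fix_c: bool = False, grid_points: int = 200
) -> TrendCurve:
    """Least-squares fit of y = a·exp(k·x) + c; k is the decay coefficient.

    Initialization: a = max(y) − min(y), k = −1, c = min(y).  Degenerate or
    non-converging inputs yield a flagged curve rather than an exception;
    a fitted k > 0 carries a monotonicity warning flag.
    """
    x, y = _check_xy(x, y, 4)
    a0 = float(y.max() - y.min())
    c0 = float(y.min())
    flags: list[str] = []
    try:
        if fix_c:
            popt, _ = curve_fit(
                lambda xx, a, k: _expdecay(xx, a, k, 0.0), x, y,
                p0=(max(a0, 1e-6), -1.0), maxfev=20_000,
            )
            a, k, c = float(popt[0]), float(popt[1]), 0.0
        else:
            popt, _ = curve_fit(
                _expdecay, x, y, p0=(max(a0, 1e-6), -1.0, c0), maxfev=20_000
            )
            a, k, c = (float(v) for v in popt)
    except (RuntimeError, ValueError) as exc:
        logger.warning("exponential fit did not converge: %s", exc)
        flags.append("no_convergence")
        a, k, c = math.nan, math.nan, math.nan
    if math.isfinite(a) and abs(a) < 1e-8:
        flags.append("amplitude_degenerate")
    if math.isfinite(k) and k > 0:
        flags.append("increasing_trend")
    gx = np.linspace(x.min(), x.max(), grid_points)
    gy = _expdecay(gx, a, k, c) if math.isfinite(k) else np.full_like(gx, math.nan)
    return TrendCurve(
        kind="expdecay", grid_x=gx, grid_y=gy, params=(a, k, c), flags=flags
    )


def _interp_extrapolate(grid, xs, ys):
    """Linear interpolation that extends the end slopes beyond the data range
    (case resamples may not reach the grid edges)."""
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]
    out = np.interp(grid, xs, ys)
    if len(xs) >= 2:
        left = grid < xs[0]
        if left.any():
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[left] = ys[0] + slope * (grid[left] - xs[0])
        right = grid > xs[-1]
        if right.any():
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[right] = ys[-1] + slope * (grid[right] - xs[-1])
    return out


def bootstrap_lowess(
    x,
    y,
    B: int = 30,
    frac: float = 1 / 5,
    z: float = 1.96,
    seed=None,
    grid_points: int = 200,
) -> TrendCurve:
    """Mean of B case-resampled lowess fits with a ±z·SD pointwise band."""
    x, y = _check_xy(x, y, 10)
    rng = as_rng(seed)
    grid = np.linspace(x.min(), x.max(), grid_points)
    fits = np.empty((B, grid_points))
    for b in range(B):
        idx = rng.integers(len(x), size=len(x))
        fitted = sm.nonparametric.lowess(y[idx], x[idx], frac=frac, it=3,
                                         return_sorted=True)
        fits[b] = _interp_extrapolate(grid, fitted[:, 0], fitted[:, 1])
    mean = fits.mean(axis=0)
    sd = fits.std(axis=0, ddof=0)
    return TrendCurve(
        kind="lowess",
        grid_x=grid,
        grid_y=mean,
        band_lo=mean - z * sd,
        band_hi=mean + z * sd,
    )


def curve_steepness(pairs, windows, baseline=None):
    """Rank-window conservatism ratios; see :func:`ccons.ranks.conservatism_ratios`."""
    from .ranks import conservatism_ratios

    return conservatism_ratios(pairs, windows, baseline=baseline)


def plot_trend(pairs_x, pairs_y, curves: list[TrendCurve], path, title: str = ""):
    """Scatter of pairs plus fitted curves, written to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(pairs_x, pairs_y, s=6, alpha=0.3, color="grey", label="OTU pairs")
    for curve in curves:
        ax.plot(curve.grid_x, curve.grid_y, lw=2, label=curve.kind)
        if curve.band_lo is not None:
            ax.fill_between(curve.grid_x, curve.band_lo, curve.band_hi, alpha=0.2)
    ax.set_xlabel("phylogenetic distance (tree branch length)")
    ax.set_ylabel("mean Bray–Curtis similarity")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
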