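"""Results-level summaries of the smoothed selection surfaces.

All functions are pure: they take 365 x 24 surfaces (days as rows, hours as
columns) and return numbers or new surfaces.  Conventions:

* relative selection strength RSS = exp(beta);
* "preference" means beta > 0, "avoidance" beta <= 0 (ties count as
  non-preference);
* the cumulative selectivity index at a grid point is the sum of |beta|
  over the five habitat-dummy models (the distance models are on a
  different scale and are excluded);
* fold differences are marginal max/min ratios: the diel fold compares
  hourly means (across days), the seasonal fold daily means (across
  hours).  The input surface must be strictly positive, so per-habitat
  surfaces are compared on the RSS scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from temposelect.synthetic_data import MODELED_HABITATS
from temposelect.temporal_smoothing import SmoothModel, fit_gam, year_coord_from_day

#: Display threshold above which cumulative selectivity counts as "high".
HIGH_SELECTIVITY_THRESHOLD = 3.5


def rss(beta):
    """Relative selection strength exp(beta)."""
    return np.exp(beta)


def preference_share(surface: np.ndarray) -> dict[str, float]:
    """Share of day-hour cells with preference, and RSS medians by side.

    Returns ``share_positive`` = #{beta > 0} / n_cells plus the median RSS
    among preferred (beta > 0) and among avoided (beta <= 0) cells (NaN
    when a side is empty).
    """
    s = np.asarray(surface, dtype=float)
    pos = s > 0
    n = s.size
    return {
        "share_positive": float(pos.sum()) / n,
        "median_rss_positive": float(np.median(np.exp(s[pos]))) if pos.any() else np.nan,
        "median_rss_negative": float(np.median(np.exp(s[~pos]))) if (~pos).any() else np.nan,
    }


def cumulative_surface(surfaces: dict[str, np.ndarray]) -> np.ndarray:
    """Pointwise sum of |beta| over the five habitat-model surfaces."""
    missing = [h for h in MODELED_HABITATS if h not in surfaces]
    if missing:
        raise ValueError(f"missing habitat surfaces: {missing}")
    shapes = {surfaces[h].shape for h in MODELED_HABITATS}
    if len(shapes) != 1:
        raise ValueError(f"misaligned surface grids: {shapes}")
    out = np.zeros(shapes.pop())
    for h in MODELED_HABITATS:
        out += np.abs(np.asarray(surfaces[h], dtype=float))
    return out


def high_selectivity_mask(
    cumulative: np.ndarray, threshold: float = HIGH_SELECTIVITY_THRESHOLD
) -> np.ndarray:
    """Grid cells whose cumulative selectivity exceeds the display threshold."""
    return np.asarray(cumulative, dtype=float) > threshold


def fit_gam8(
    cumulative: np.ndarray, k_hour: int = 5, k_year: int = 10, **kwargs
) -> tuple[SmoothModel, np.ndarray]:
    """Smooth the cumulative selectivity surface over day and hour.

    Applies the same cyclic-spline machinery as the per-habitat smooths,
    with day-of-year mapped onto the 26-period year cycle.  Returns the
    fitted model and the smoothed 365 x 24 surface.
    """
    c = np.asarray(cumulative, dtype=float)
    if c.shape != (365, 24):
        raise ValueError("cumulative surface must be 365 x 24")
    days, hours = np.meshgrid(np.arange(1, 366), np.arange(24), indexing="ij")
    model = fit_gam(
        hours.ravel().astype(float),
        year_coord_from_day(days.ravel()),
        c.ravel(),
        k_hour=k_hour,
        k_year=k_year,
        **kwargs,
    )
    from temposelect.temporal_smoothing import predict_surface

    return model, predict_surface(model)


def fold_differences(surface: np.ndarray) -> tuple[float, float]:
    """(diel_fold, seasonal_fold) of a strictly positive surface.

    diel fold = max over hours / min over hours of the hourly mean across
    days; seasonal fold likewise on the daily means across hours.
    """
    s = np.asarray(surface, dtype=float)
    hour_marginal = s.mean(axis=0)
    day_marginal = s.mean(axis=1)
    if hour_marginal.min() <= 0 or day_marginal.min() <= 0:
        raise ValueError("fold differences need a strictly positive surface")
    return (
        float(hour_marginal.max() / hour_marginal.min()),
        float(day_marginal.max() / day_marginal.min()),
    )


@dataclass
class RepeatabilityResult:
    """Pairwise correlations of per-cell selection profiles."""

    n_cells: int
    n_pairs: int
    correlations: np.ndarray  # one r per unordered cell pair
    proportion_negative: float
    n_excluded: int  # pairs dropped for zero-variance profiles


def repeatability(
    surfaces: dict[str, np.ndarray],
    cells: pd.DataFrame | None = None,
    method: str = "pearson",
) -> RepeatabilityResult:
    """Temporal repeatability of selection across the temporal grid.

    For every cell of the grid, the selection profile is the vector of
    predicted beta over all supplied models (normally the seven GAM1-7
    surfaces, unscaled), evaluated at the cell's period-midpoint day and
    hour.  All unordered pairs of cells are correlated; an increasing
    correlation means the animal ranks habitats more consistently across
    time windows.  Cells default to the full 26 x 24 grid.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if cells is None:
        periods, hours = np.meshgrid(np.arange(1, 27), np.arange(24), indexing="ij")
        cells = pd.DataFrame({"period": periods.ravel(), "hour": hours.ravel()})
    model_ids = list(surfaces)
    # period-midpoint day, clipped into the 365-day surface for period 26
    mid_day = np.minimum((cells["period"].to_numpy() - 1) * 14 + 7, 365)
    hour = cells["hour"].to_numpy()
    profiles = np.column_stack(
        [np.asarray(surfaces[m])[mid_day - 1, hour] for m in model_ids]
    )
    if method == "spearman":
        profiles = stats.rankdata(profiles, axis=1)
    n_cells = profiles.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    iu = np.triu_indices(n_cells, k=1)
    r = corr[iu]
    n_all = len(r)
    finite = np.isfinite(r)
    r = r[finite]
    return RepeatabilityResult(
        n_cells=n_cells,
        n_pairs=n_all,
        correlations=r,
        proportion_negative=float((r < 0).mean()) if len(r) else np.nan,
        n_excluded=int(n_all - finite.sum()),
    )
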