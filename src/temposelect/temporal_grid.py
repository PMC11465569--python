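"""The 14-day x 1-hour temporal grid and the per-cell model fits.

Step pairs are assigned to temporal cells by the observed step's end
timestamp: 26 fourteen-day periods counted from 1 January (days 365-366
absorbed into period 26, since 26 x 14 = 364) crossed with the 24 clock
hours, giving the 624-cell grid.  Within each cell the pair count is
standardized by sampling whole pairs without replacement (863 pairs = 1,726
locations by default), and the seven single-covariate conditional-logit
models are fitted, i.e. 624 x 7 = 4,368 fits on a fully covered year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from temposelect.ssf_core import SubsetFit, fit_from_differences
from temposelect.synthetic_data import MODEL_COVARIATES

N_PERIODS = 26
PERIOD_DAYS = 14
N_HOURS = 24

#: Default cell standardization: 863 pairs = 1,726 locations per cell.
DEFAULT_TARGET_PAIRS = 863


@dataclass(frozen=True)
class TemporalCell:
    period: int  # 1..26, 14-day blocks from 1 January
    hour: int  # 0..23


@dataclass
class SubsetSpec:
    """How cell sample sizes are standardized."""

    target_pairs: int = DEFAULT_TARGET_PAIRS
    seed: int = 0
    min_pairs_policy: str = "warn_keep_all"  # or "error"

    def __post_init__(self) -> None:
        if self.min_pairs_policy not in ("warn_keep_all", "error"):
            raise ValueError("min_pairs_policy must be 'warn_keep_all' or 'error'")


def assign_cell(timestamps) -> pd.DataFrame:
    """Map timestamps to (period, hour) cells.

    period = min(26, floor((day_of_year - 1) / 14) + 1); hour is the integer
    clock hour.  Accepts a scalar or a sequence; returns a DataFrame with
    ``period`` and ``hour`` columns (single-row for a scalar).
    """
    if np.isscalar(timestamps) or isinstance(timestamps, pd.Timestamp):
        ts = pd.DatetimeIndex([timestamps])
    else:
        ts = pd.DatetimeIndex(timestamps)
    doy = ts.dayofyear.to_numpy()
    period = np.minimum((doy - 1) // PERIOD_DAYS + 1, N_PERIODS)
    return pd.DataFrame({"period": period, "hour": ts.hour.to_numpy()})


def partition(pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach (period, hour) cell labels to the long pairs table.

    Every pair lands in exactly one cell (assignment by the pair's end
    timestamp, which both members share).  Returns a copy with ``period``
    and ``hour`` columns.
    """
    out = pairs.copy()
    cells = assign_cell(out["t_end"])
    out["period"] = cells["period"].to_numpy()
    out["hour"] = cells["hour"].to_numpy()
    return out


def cell_counts(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pairs per non-empty cell (one row per cell)."""
    cases = pairs[pairs["case"] == 1]
    return (
        cases.groupby(["period", "hour"], sort=True)
        .size()
        .rename("n_pairs")
        .reset_index()
    )


def _cell_rng(seed: int, period: int, hour: int) -> np.random.Generator:
    # child seed from hashing (master, period, hour): cell draws do not
    # depend on iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, period, hour]))


def standardize_subset(
    pairs: pd.DataFrame,
    spec: SubsetSpec,
    period: int,
    hour: int,
) -> pd.DataFrame:
    """Subsample one cell's pairs to the target count, whole pairs only.

    Uniform sampling of strata without replacement, deterministic given
    ``(spec.seed, period, hour)``.  Cells already at or below target are
    handled per ``min_pairs_policy``: ``error`` raises naming the cell,
    ``warn_keep_all`` keeps everything with a warning.
    """
    strata = pairs.loc[pairs["case"] == 1, "stratum_id"].to_numpy()
    if len(strata) < spec.target_pairs:
        if spec.min_pairs_policy == "error":
            raise ValueError(
                f"cell (period={period}, hour={hour}) has {len(strata)} pairs "
                f"< target {spec.target_pairs}"
            )
        warnings.warn(
            f"cell (period={period}, hour={hour}): {len(strata)} pairs below "
            f"target {spec.target_pairs}; keeping all",
            stacklevel=2,
        )
        return pairs
    if len(strata) == spec.target_pairs:
        return pairs
    rng = _cell_rng(spec.seed, period, hour)
    chosen = rng.choice(strata, size=spec.target_pairs, replace=False)
    return pairs[pairs["stratum_id"].isin(chosen)]


def standardize_all(pairs: pd.DataFrame, spec: SubsetSpec) -> pd.DataFrame:
    """Apply per-cell standardization across the whole partitioned table."""
    out = []
    for (period, hour), cell in pairs.groupby(["period", "hour"], sort=True):
        out.append(standardize_subset(cell, spec, int(period), int(hour)))
    return pd.concat(out, ignore_index=True)


def fit_all(
    pairs: pd.DataFrame,
    covariates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Run the seven conditional-logit models in every non-empty cell.

    ``pairs`` must be partitioned (period/hour columns) and carry the
    z-scored distance columns.  Per-fit problems (non-estimable models,
    separation) are recorded as flags, never abort the grid.  Returns the
    fits table with one row per (cell, model).
    """
    if covariates is None:
        covariates = MODEL_COVARIATES
    # distance models are fitted on the globally z-scored columns but keep
    # their plain model_id
    columns = {
        c: (c + "_z" if c.startswith("dist_") and c + "_z" in pairs.columns else c)
        for c in covariates
    }
    rows = []
    for (period, hour), cell in pairs.groupby(["period", "hour"], sort=True):
        cs = cell.sort_values(["stratum_id", "case"], ascending=[True, False])
        obs = cs[cs["case"] == 1]
        rand = cs[cs["case"] == 0]
        if len(obs) != len(rand) or not np.array_equal(
            obs["stratum_id"].to_numpy(), rand["stratum_id"].to_numpy()
        ):
            raise ValueError(
                f"cell (period={period}, hour={hour}) has broken pairs"
            )
        for cov in covariates:
            col = columns[cov]
            d = obs[col].to_numpy(dtype=float) - rand[col].to_numpy(dtype=float)
            fit = fit_from_differences(d, cov)
            fit.period = int(period)
            fit.hour = int(hour)
            rows.append(fit)
    return fits_to_frame(rows)


def fits_to_frame(fits: list[SubsetFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "period": [f.period for f in fits],
            "hour": [f.hour for f in fits],
            "model_id": [f.model_id for f in fits],
            "beta": [f.beta for f in fits],
            "se": [f.se for f in fits],
            "n_pairs": [f.n_pairs for f in fits],
            "n_informative": [f.n_informative for f in fits],
            "converged": [f.converged for f in fits],
            "separation": [f.separation for f in fits],
            "estimable": [f.estimable for f in fits],
        }
    )


def usable_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Rows whose beta may enter the second-stage smoothing."""
    return fits[fits["estimable"] & fits["converged"] & ~fits["separation"]]
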