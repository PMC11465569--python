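"""Movement kernels, matched random steps, covariates, and conditional logit.

This module holds the statistical core of the step-selection analysis:

* maximum-likelihood gamma (step length) and von Mises (turning angle)
  movement kernels, fitted to the observed steps;
* generation of one random step per observed step by drawing a length and a
  turn from those kernels relative to the previous bearing;
* endpoint covariate extraction from the landscape (habitat dummy variables
  and raw road / settlement distances, z-scored globally afterwards);
* the 1:1 matched conditional logistic estimator.  With exactly one
  observed and one random member per stratum the conditional
  log-likelihood for a single covariate reduces to logistic regression
  without intercept on the within-pair covariate differences,
  ``l(beta) = -sum_i log(1 + exp(-beta * d_i))``, which is maximized by
  Newton-Raphson with the observed-information standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from temposelect.synthetic_data import (
    MODELED_HABITATS,
    HABITAT_CLASSES,
    Landscape,
)


class DegenerateSampleError(ValueError):
    """Sample carries no information for the requested fit."""


@dataclass(frozen=True)
class GammaParams:
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class VonMisesParams:
    mu: float
    kappa: float


def fit_gamma(step_lengths, min_n: int = 10) -> tuple[GammaParams, int]:
    """Gamma MLE for step lengths; returns (params, n_zeros_dropped).

    Zeros are dropped (logged via the returned count) because the gamma
    density is supported on (0, inf).  Shape solves
    ``log(k) - digamma(k) = log(mean) - mean(log x)`` by Newton iteration;
    scale = mean / shape, so shape * scale equals the sample mean exactly
    (the first-order MLE condition).
    """
    x = np.asarray(step_lengths, dtype=float)
    n_zero = int((x <= 0).sum())
    x = x[x > 0]
    if len(x) < min_n:
        raise DegenerateSampleError(f"need >= {min_n} positive lengths")
    mean = x.mean()
    s = np.log(mean) - np.mean(np.log(x))
    if s <= 1e-12:
        raise DegenerateSampleError("degenerate sample: zero log-spread")
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return GammaParams(shape=float(k), scale=float(mean / k)), n_zero


def fit_vonmises(
    turning_angles, min_n: int = 10, kappa_max: float = 1e6
) -> VonMisesParams:
    """Von Mises MLE for turning angles (NaNs ignored).

    mu is the circular mean; kappa solves ``A1(kappa) = Rbar`` (mean
    resultant length) by bracketed root finding with ``A1 = I1/I0``
    computed from exponentially scaled Bessel functions.  ``Rbar`` below
    1e-8 gives kappa = 0 (uniform); ``Rbar`` beyond the solvable range
    returns the configured cap.
    """
    a = np.asarray(turning_angles, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < min_n:
        raise DegenerateSampleError(f"need >= {min_n} defined angles")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    mu = float(np.arctan2(s, c))
    rbar = float(np.hypot(c, s))
    if rbar < 1e-8:
        return VonMisesParams(mu=mu, kappa=0.0)

    def a1(k):
        return special.i1e(k) / special.i0e(k)

    if a1(kappa_max) <= rbar:
        return VonMisesParams(mu=mu, kappa=float(kappa_max))
    kappa = float(optimize.brentq(lambda k: a1(k) - rbar, 1e-12, kappa_max))
    return VonMisesParams(mu=mu, kappa=kappa)


def draw_random_steps(
    steps: pd.DataFrame,
    gamma: GammaParams,
    vm: VonMisesParams,
    rng: np.random.Generator,
    landscape: Landscape | None = None,
    max_redraw: int = 100,
) -> pd.DataFrame:
    """Draw one random endpoint per observed step with a defined turn.

    Only steps whose previous bearing exists (``turn`` defined) can receive
    a matched random step — mirroring the requirement that turning angles be
    computable.  Lengths come from the fitted gamma, turns from the fitted
    von Mises added to the previous bearing.  When a landscape is given,
    endpoints falling outside its extent are redrawn up to ``max_redraw``
    rounds and finally kept with ``oob_flag`` set.

    Returns a frame aligned with the usable steps: stratum_id, t_end,
    x_rand, y_rand, oob_flag.
    """
    usable = steps[steps["turn"].notna()].reset_index(drop=True)
    n = len(usable)
    x0 = usable["x_start"].to_numpy(dtype=float)
    y0 = usable["y_start"].to_numpy(dtype=float)
    base = usable["prev_bearing"].to_numpy(dtype=float)

    lengths = rng.gamma(gamma.shape, gamma.scale, size=n)
    turns = rng.vonmises(vm.mu, vm.kappa, size=n)  # kappa=0 gives uniform
    b = base + turns
    ex = x0 + lengths * np.cos(b)
    ey = y0 + lengths * np.sin(b)
    oob_flag = np.zeros(n, dtype=bool)
    if landscape is not None:
        oob = ~landscape.in_bounds(ex, ey)
        for _ in range(max_redraw):
            if not oob.any():
                break
            k = int(oob.sum())
            nl = rng.gamma(gamma.shape, gamma.scale, size=k)
            nt = rng.vonmises(vm.mu, vm.kappa, size=k)
            nb = base[oob] + nt
            ex[oob] = x0[oob] + nl * np.cos(nb)
            ey[oob] = y0[oob] + nl * np.sin(nb)
            oob = ~landscape.in_bounds(ex, ey)
        oob_flag = oob
    return pd.DataFrame(
        {
            "stratum_id": usable["stratum_id"].to_numpy(),
            "t_end": usable["t_end"].to_numpy(),
            "x_rand": ex,
            "y_rand": ey,
            "oob_flag": oob_flag,
        }
    )


def draw_random_step(
    x_start: float,
    y_start: float,
    prev_bearing: float,
    gamma: GammaParams,
    vm: VonMisesParams,
    rng: np.random.Generator,
    landscape: Landscape | None = None,
    max_redraw: int = 100,
) -> tuple[float, float, bool]:
    """Single-step convenience wrapper around :func:`draw_random_steps`."""
    step = pd.DataFrame(
        {
            "stratum_id": [0],
            "t_end": [pd.NaT],
            "x_start": [x_start],
            "y_start": [y_start],
            "prev_bearing": [prev_bearing],
            "turn": [0.0],
        }
    )
    out = draw_random_steps(step, gamma, vm, rng, landscape, max_redraw)
    return float(out["x_rand"].iloc[0]), float(out["y_rand"].iloc[0]), bool(
        out["oob_flag"].iloc[0]
    )


def extract_covariates(xs, ys, landscape: Landscape) -> pd.DataFrame:
    """Endpoint covariates by raster lookup of the containing cell.

    Habitat dummy variables for the five modeled classes and raw distances
    (z-scoring is applied later, globally over all endpoints).  Points
    outside the landscape extent raise ``ValueError``.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    if not np.all(landscape.in_bounds(xs, ys)):
        raise ValueError("point outside landscape extent")
    row, col = landscape.cell_index(xs, ys)
    codes = landscape.habitat_grid[row, col]
    out = pd.DataFrame(
        {
            name: (codes == HABITAT_CLASSES.index(name)).astype(int)
            for name in MODELED_HABITATS
        }
    )
    out["dist_road"] = landscape.dist_road_grid[row, col]
    out["dist_settlement"] = landscape.dist_settlement_grid[row, col]
    return out


def build_pairs(
    steps: pd.DataFrame,
    random_steps: pd.DataFrame,
    landscape: Landscape,
) -> pd.DataFrame:
    """Assemble the long pairs table (two rows per stratum, case 1/0)."""
    usable = steps[steps["stratum_id"].isin(random_steps["stratum_id"])]
    usable = usable.set_index("stratum_id").loc[random_steps["stratum_id"]]
    obs_cov = extract_covariates(
        usable["x_end"].to_numpy(), usable["y_end"].to_numpy(), landscape
    )
    rand_cov = extract_covariates(
        random_steps["x_rand"].to_numpy(), random_steps["y_rand"].to_numpy(), landscape
    )
    obs_cov.insert(0, "stratum_id", random_steps["stratum_id"].to_numpy())
    obs_cov.insert(1, "case", 1)
    obs_cov.insert(2, "t_end", usable["t_end"].to_numpy())
    rand_cov.insert(0, "stratum_id", random_steps["stratum_id"].to_numpy())
    rand_cov.insert(1, "case", 0)
    rand_cov.insert(2, "t_end", usable["t_end"].to_numpy())
    pairs = pd.concat([obs_cov, rand_cov], ignore_index=True)
    return pairs.sort_values(["stratum_id", "case"], ascending=[True, False]).reset_index(
        drop=True
    )


def standardize_distances(
    pairs: pd.DataFrame,
    columns: tuple[str, ...] = ("dist_road", "dist_settlement"),
) -> pd.DataFrame:
    """Z-score distance covariates over ALL endpoints pooled globally.

    Sample standard deviation (ddof=1).  Adds ``<col>_z`` columns; raises on
    zero variance.
    """
    out = pairs.copy()
    for col in columns:
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateSampleError(f"zero variance in {col}")
        out[f"{col}_z"] = (v - v.mean()) / sd
    return out


@dataclass
class SubsetFit:
    """One conditional-logit fit: a single covariate in one temporal cell."""

    model_id: str
    beta: float
    se: float
    n_pairs: int
    n_informative: int
    converged: bool
    separation: bool
    estimable: bool
    period: int | None = None
    hour: int | None = None

    @property
    def usable(self) -> bool:
        """Whether beta may enter the second-stage smoothing."""
        return self.estimable and self.converged and not self.separation


def pair_differences(pairs: pd.DataFrame, covariate: str) -> np.ndarray:
    """Within-stratum observed-minus-random covariate differences."""
    wide = pairs.pivot_table(
        index="stratum_id", columns="case", values=covariate, aggfunc="first"
    )
    if 1 not in wide.columns or 0 not in wide.columns:
        raise ValueError("each stratum needs one case and one control row")
    return (wide[1] - wide[0]).to_numpy(dtype=float)


def clogit_loglik(beta: float, d: np.ndarray) -> float:
    """Matched-pair conditional log-likelihood at ``beta``."""
    return float(-np.logaddexp(0.0, -beta * d).sum())


def clogit_fit(
    pairs: pd.DataFrame,
    covariate: str,
    beta_cap: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> SubsetFit:
    """1:1 matched conditional logistic regression for a single covariate.

    Newton-Raphson on the within-pair differences.  Pairs whose covariate
    does not differ between the observed and random member contribute
    nothing to the likelihood; with no informative pair the fit is flagged
    non-estimable.  Complete separation (all informative differences share
    one sign) makes the MLE infinite: beta is reported as ``sign * beta_cap``
    with the separation flag set, and such fits are excluded downstream.
    """
    d_all = pair_differences(pairs, covariate)
    return fit_from_differences(d_all, covariate, beta_cap, tol, max_iter)


def fit_from_differences(
    d_all: np.ndarray,
    covariate: str = "x",
    beta_cap: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> SubsetFit:
    """Conditional-logit fit given precomputed within-pair differences."""
    n_pairs = len(d_all)
    d = d_all[d_all != 0.0]
    n_inf = len(d)
    if n_inf == 0:
        return SubsetFit(covariate, np.nan, np.nan, n_pairs, 0, False, False, False)
    if np.all(d > 0) or np.all(d < 0):
        sign = 1.0 if d[0] > 0 else -1.0
        return SubsetFit(
            covariate, sign * beta_cap, np.nan, n_pairs, n_inf, False, True, True
        )
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        p = special.expit(beta * d)  # P(observed member wins) per pair
        score = float(np.sum(d * (1.0 - p)))
        if abs(score) < tol:
            converged = True
            break
        info = float(np.sum(d * d * p * (1.0 - p)))
        if info <= 0:
            break
        beta += float(np.clip(score / info, -5.0, 5.0))
    p = special.expit(beta * d)
    info = float(np.sum(d * d * p * (1.0 - p)))
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.nan
    return SubsetFit(
        covariate, float(beta), se, n_pairs, n_inf, converged, False, True
    )
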