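"""Cyclic penalized-spline smoothing of the per-cell selection coefficients.

The 624 per-cell conditional-logit coefficients for one habitat are treated
as a Gaussian response over two cyclic covariates — clock hour (period 24)
and the 14-day period index (period 26, i.e. a 364-day year cycle with days
365-366 absorbed into the last period) — and smoothed with an additive
model

    y = alpha + f_hour(h) + f_year(p) + f_int(h, p) + eps,

where the marginal terms are cyclic cubic B-spline smooths (basis
dimensions 5 for hour, 10 for year by default), the interaction is the
tensor product of the constrained marginal bases, and each term carries a
cyclic second-difference penalty.  Smoothing parameters are selected by
generalized cross-validation on a fixed log-spaced grid, which keeps the
whole fit deterministic.  Marginal smooths are constrained to average zero
over their cycle, so the intercept is identified as the surface mean.

Time coordinates use a left-edge convention throughout: the cell for period
p and hour h sits at (p - 1, h), and calendar day d maps to the year-cycle
coordinate (d - 1) / 14 (days 365-366 land inside the period-26 interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space

HOUR_PERIOD = 24.0
YEAR_PERIOD = 26.0  # 26 fourteen-day periods

DEFAULT_LAMBDA_GRID = np.logspace(-3.0, 5.0, 9)


def year_coord_from_period(period) -> np.ndarray:
    """Year-cycle coordinate of a period cell (left edge): p - 1."""
    return np.asarray(period, dtype=float) - 1.0


def year_coord_from_day(day) -> np.ndarray:
    """Map calendar day 1..366 to [0, 26); days beyond 364 stay in period 26."""
    return np.minimum((np.asarray(day, dtype=float) - 1.0) / 14.0, YEAR_PERIOD - 1e-9)


class CyclicBasis:
    """Cyclic cubic B-spline basis on k equally spaced knots.

    The k + 3 ordinary cubic B-splines on the uniformly extended knot vector
    are wrapped modulo k, which makes basis values and all derivatives match
    across the period seam.  The penalty is the cyclic second-order
    difference matrix on the coefficients (null space = constants).
    """

    def __init__(self, k: int, period: float):
        if k < 3:
            raise ValueError("cyclic basis needs k >= 3")
        self.k = int(k)
        self.period = float(period)
        self._knots = np.arange(-3, k + 4) * (period / k)

    def design(self, x) -> np.ndarray:
        x = np.mod(np.asarray(x, dtype=float), self.period)
        full = BSpline.design_matrix(x, self._knots, 3).toarray()
        out = np.zeros((len(x), self.k))
        for j in range(full.shape[1]):
            out[:, j % self.k] += full[:, j]
        return out

    def penalty(self) -> np.ndarray:
        k = self.k
        d = np.zeros((k, k))
        for i in range(k):
            d[i, i] += 1.0
            d[i, (i + 1) % k] += -2.0
            d[i, (i + 2) % k] += 1.0
        return d.T @ d

    def constraint(self, n_grid: int = 400) -> np.ndarray:
        """Cycle-average of each basis function (sum-to-zero constraint row)."""
        xg = np.linspace(0.0, self.period, n_grid, endpoint=False)
        return self.design(xg).mean(axis=0)


@dataclass
class SmoothModel:
    """A fitted cyclic additive smooth with its full fitting context."""

    basis_hour: CyclicBasis
    basis_year: CyclicBasis
    z_hour: np.ndarray  # constraint null-space bases
    z_year: np.ndarray
    coef: np.ndarray  # full coefficient vector [alpha, hour, year, int]
    lambdas: dict[str, float]
    edf: dict[str, float]
    scale: float  # residual variance estimate
    gcv: float
    gcv_grid: np.ndarray  # searched lambda values (shared per term)
    gcv_table: np.ndarray  # GCV over the (lh, ly, li) grid
    boundary_hit: bool
    x_hour: np.ndarray = field(repr=False)
    x_year: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    penalty_blocks: dict = field(repr=False, default=None)

    # -- design helpers -------------------------------------------------
    def _blocks(self, x_hour, x_year):
        bh = self.basis_hour.design(x_hour) @ self.z_hour
        by = self.basis_year.design(x_year) @ self.z_year
        bi = np.einsum("ij,ik->ijk", bh, by).reshape(len(bh), -1)
        return bh, by, bi

    def design(self, x_hour, x_year) -> np.ndarray:
        bh, by, bi = self._blocks(x_hour, x_year)
        return np.column_stack([np.ones(len(bh)), bh, by, bi])

    @property
    def slices(self) -> dict[str, slice]:
        ph = self.z_hour.shape[1]
        py = self.z_year.shape[1]
        return {
            "intercept": slice(0, 1),
            "hour": slice(1, 1 + ph),
            "year": slice(1 + ph, 1 + ph + py),
            "interaction": slice(1 + ph + py, 1 + ph + py + ph * py),
        }

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def predict(self, x_hour, x_year) -> np.ndarray:
        return self.design(x_hour, x_year) @ self.coef

    def term_contributions(self, x_hour, x_year) -> dict[str, np.ndarray]:
        x = self.design(x_hour, x_year)
        return {
            name: x[:, s] @ self.coef[s] for name, s in self.slices.items()
        }


def _penalty_blocks(basis_hour, basis_year, z_hour, z_year):
    sh = z_hour.T @ basis_hour.penalty() @ z_hour
    sy = z_year.T @ basis_year.penalty() @ z_year
    ih = np.eye(sh.shape[0])
    iy = np.eye(sy.shape[0])
    s_int = np.kron(sh, iy) + np.kron(ih, sy)
    return {"hour": sh, "year": sy, "interaction": s_int}


def fit_gam(
    x_hour,
    x_year,
    y,
    k_hour: int = 5,
    k_year: int = 10,
    lambda_grid=None,
    min_obs: int = 50,
) -> SmoothModel:
    """Fit the cyclic additive smooth by penalized least squares + GCV.

    ``x_hour`` on [0, 24), ``x_year`` on [0, 26), ``y`` the per-cell
    coefficients (non-estimable or separated fits must be excluded before
    calling).  The three smoothing parameters (hour, year, interaction) are
    chosen by exhaustive GCV minimization over ``lambda_grid``; a warning is
    emitted when the optimum sits on the grid boundary.
    """
    x_hour = np.asarray(x_hour, dtype=float)
    x_year = np.asarray(x_year, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_obs:
        raise ValueError(f"need >= {min_obs} estimable coefficients, got {n}")
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    bh_basis = CyclicBasis(k_hour, HOUR_PERIOD)
    by_basis = CyclicBasis(k_year, YEAR_PERIOD)
    zh = null_space(bh_basis.constraint()[None, :])
    zy = null_space(by_basis.constraint()[None, :])

    bh = bh_basis.design(x_hour) @ zh
    by = by_basis.design(x_year) @ zy
    bi = np.einsum("ij,ik->ijk", bh, by).reshape(n, -1)
    x = np.column_stack([np.ones(n), bh, by, bi])
    p = x.shape[1]
    ph, py = zh.shape[1], zy.shape[1]

    pen = _penalty_blocks(bh_basis, by_basis, zh, zy)
    xtx = x.T @ x
    xty = x.T @ y

    def penalty_matrix(lh, ly, li):
        s = np.zeros((p, p))
        s[1 : 1 + ph, 1 : 1 + ph] = lh * pen["hour"]
        s[1 + ph : 1 + ph + py, 1 + ph : 1 + ph + py] = ly * pen["year"]
        s[1 + ph + py :, 1 + ph + py :] = li * pen["interaction"]
        return s

    ng = len(lambda_grid)
    gcv_table = np.full((ng, ng, ng), np.inf)
    best = None
    # tiny ridge keeps the system well-posed when a lambda is ~0
    ridge = 1e-10 * np.eye(p)
    for a, lh in enumerate(lambda_grid):
        for b, ly in enumerate(lambda_grid):
            for c, li in enumerate(lambda_grid):
                amat = xtx + penalty_matrix(lh, ly, li) + ridge
                try:
                    cho = cho_factor(amat)
                except np.linalg.LinAlgError:
                    continue
                beta = cho_solve(cho, xty)
                edf_total = float(np.trace(cho_solve(cho, xtx)))
                rss = float(np.sum((y - x @ beta) ** 2))
                denom = n - edf_total
                if denom <= 1e-6:
                    continue
                gcv = n * rss / denom**2
                gcv_table[a, b, c] = gcv
                if best is None or gcv < best[0]:
                    best = (gcv, (a, b, c), beta, cho, edf_total, rss)
    if best is None:
        raise np.linalg.LinAlgError("singular penalized system for every lambda")

    gcv, (a, b, c), beta, cho, edf_total, rss = best
    boundary = any(i in (0, ng - 1) for i in (a, b, c))
    if boundary:
        warnings.warn("GCV optimum on the lambda grid boundary", stacklevel=2)

    lambdas = {
        "hour": float(lambda_grid[a]),
        "year": float(lambda_grid[b]),
        "interaction": float(lambda_grid[c]),
    }
    amap = cho_solve(cho, xtx)  # influence of each coefficient direction
    diag = np.diag(amap)
    edf = {
        "intercept": float(diag[0]),
        "hour": float(diag[1 : 1 + ph].sum()),
        "year": float(diag[1 + ph : 1 + ph + py].sum()),
        "interaction": float(diag[1 + ph + py :].sum()),
    }
    scale = rss / max(n - edf_total, 1.0)
    return SmoothModel(
        basis_hour=bh_basis,
        basis_year=by_basis,
        z_hour=zh,
        z_year=zy,
        coef=beta,
        lambdas=lambdas,
        edf=edf,
        scale=float(scale),
        gcv=float(gcv),
        gcv_grid=lambda_grid,
        gcv_table=gcv_table,
        boundary_hit=bool(boundary),
        x_hour=x_hour,
        x_year=x_year,
        y=y,
        penalty_blocks=pen,
    )


def fit_gam_cells(fits, model_id: str, **kwargs) -> SmoothModel:
    """Fit the smooth for one model from a usable-fits table.

    ``fits`` is the per-cell fits frame (period, hour, model_id, beta, ...)
    already filtered to usable rows.
    """
    sub = fits[fits["model_id"] == model_id]
    return fit_gam(
        sub["hour"].to_numpy(dtype=float),
        year_coord_from_period(sub["period"].to_numpy()),
        sub["beta"].to_numpy(dtype=float),
        **kwargs,
    )


def predict_surface(model: SmoothModel, days=None, hours=None) -> np.ndarray:
    """Predicted beta on the day x hour grid (365 x 24 by default)."""
    if days is None:
        days = np.arange(1, 366)
    if hours is None:
        hours = np.arange(24)
    days = np.asarray(days)
    hours = np.asarray(hours)
    dd, hh = np.meshgrid(year_coord_from_day(days), hours, indexing="ij")
    pred = model.predict(hh.ravel(), dd.ravel())
    return pred.reshape(len(days), len(hours))


def significance_by_permutation(
    model: SmoothModel,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation p-values for the three smooth terms.

    The response is permuted across cells and the model refitted with the
    smoothing parameters held at their selected values; each term's
    explained sum of squares is compared with its permutation null:
    p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a coarse p-value resolution", stacklevel=2)
    rng = np.random.default_rng(seed)
    x = model.design(model.x_hour, model.x_year)
    p = x.shape[1]
    sl = model.slices
    pen = model.penalty_blocks
    s = np.zeros((p, p))
    s[sl["hour"], sl["hour"]] = model.lambdas["hour"] * pen["hour"]
    s[sl["year"], sl["year"]] = model.lambdas["year"] * pen["year"]
    s[sl["interaction"], sl["interaction"]] = (
        model.lambdas["interaction"] * pen["interaction"]
    )
    cho = cho_factor(x.T @ x + s + 1e-10 * np.eye(p))
    solver = cho_solve(cho, x.T)  # maps y -> coefficients

    def term_ess(y):
        beta = solver @ y
        return {
            name: float(np.sum((x[:, sl[name]] @ beta[sl[name]]) ** 2))
            for name in ("hour", "year", "interaction")
        }

    obs = term_ess(model.y)
    counts = {name: 0 for name in obs}
    y_perm = model.y.copy()
    for _ in range(n_perm):
        rng.shuffle(y_perm)
        ess = term_ess(y_perm)
        for name in counts:
            if ess[name] >= obs[name]:
                counts[name] += 1
    return {name: (1 + counts[name]) / (n_perm + 1) for name in counts}
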