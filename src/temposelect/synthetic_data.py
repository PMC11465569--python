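"""Synthetic landscapes and forward-simulated movement tracks.

The generator exists so that the whole step-selection pipeline can be
validated by parameter recovery: a patchy categorical landscape with road
and settlement distance fields, plus an agent that moves with a
gamma step-length / von Mises turning-angle kernel and chooses among M
candidate endpoints with probability proportional to
``exp(sum_h beta_h(day, hour) * x_h)``, where each selection coefficient
``beta_h`` varies smoothly and cyclically in hour-of-day and day-of-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

#: The nine landscape classes; integer codes are positions in this tuple.
HABITAT_CLASSES: tuple[str, ...] = (
    "deciduous_forest",
    "coniferous_forest",
    "wetland",
    "grassland",
    "arable",
    "anthropogenic",
    "moorland",
    "bare",
    "water",
)

#: Habitat classes that receive their own dummy-covariate selection model.
MODELED_HABITATS: tuple[str, ...] = HABITAT_CLASSES[:5]

#: The seven single-covariate selection models, in fitting order.
MODEL_COVARIATES: tuple[str, ...] = MODELED_HABITATS + ("dist_road", "dist_settlement")


class InvalidConfigError(ValueError):
    """Raised when a generator configuration cannot produce a valid artifact."""


@dataclass
class Landscape:
    """Aligned categorical habitat grid plus two continuous distance grids.

    The georeference is a plain projected-meter frame: ``origin_x, origin_y``
    is the lower-left corner of cell ``(row=0, col=0)`` and rows grow with y.
    Cells are half-open intervals ``[edge, edge + cell_size)`` in both axes,
    so a point lying exactly on a shared edge belongs to the higher-index
    cell.  Distance grids are Euclidean distances in meters, zero exactly on
    road / settlement source cells.
    """

    habitat_grid: np.ndarray
    dist_road_grid: np.ndarray
    dist_settlement_grid: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.habitat_grid.shape != self.dist_road_grid.shape or (
            self.habitat_grid.shape != self.dist_settlement_grid.shape
        ):
            raise InvalidConfigError("landscape grids must share one shape")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.habitat_grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.habitat_grid.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_index(self, x, y):
        """Row/col of the containing cell under the half-open convention."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, x, y):
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def habitat_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.habitat_grid[row, col]

    def write_ascii(self, path) -> None:
        """Write all three grids to one plain-text file.

        Header line: ``n_rows n_cols origin_x origin_y cell_size``; then the
        habitat code rows, then the two distance grids, blocks separated by
        a blank line.
        """
        with open(path, "w") as fh:
            fh.write(
                f"{self.n_rows} {self.n_cols} {self.origin_x} "
                f"{self.origin_y} {self.cell_size}\n"
            )
            np.savetxt(fh, self.habitat_grid, fmt="%d")
            fh.write("\n")
            np.savetxt(fh, self.dist_road_grid, fmt="%.6f")
            fh.write("\n")
            np.savetxt(fh, self.dist_settlement_grid, fmt="%.6f")

    @classmethod
    def read_ascii(cls, path) -> "Landscape":
        with open(path) as fh:
            header = fh.read().split("\n", 1)
        n_rows, n_cols, ox, oy, cs = header[0].split()
        n_rows, n_cols = int(n_rows), int(n_cols)
        blocks = header[1].split("\n\n")
        if len(blocks) < 3:
            raise ValueError("expected three grid blocks")
        grids = [
            np.loadtxt(block.strip().splitlines()).reshape(n_rows, n_cols)
            for block in blocks[:3]
        ]
        return cls(
            habitat_grid=grids[0].astype(int),
            dist_road_grid=grids[1],
            dist_settlement_grid=grids[2],
            origin_x=float(ox),
            origin_y=float(oy),
            cell_size=float(cs),
        )


def make_landscape(
    seed: int,
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size: float = 10.0,
    n_seeds_per_class: int = 3,
    n_roads: int = 2,
    n_settlements: int = 3,
) -> Landscape:
    """Generate a patchy multi-class mosaic with road/settlement distances.

    The habitat mosaic is a nearest-seed (Voronoi) tessellation of random
    patch-seed points, ``n_seeds_per_class`` per class, which guarantees
    every class owns at least its own seed cells.  Roads are straight
    edge-to-edge polylines; settlements are small point clusters.  Distance
    grids come from a Euclidean distance transform (in meters).  Fully
    deterministic given ``seed``.
    """
    if n_rows < 50 or n_cols < 50:
        raise InvalidConfigError("landscape must be at least 50 x 50 cells")
    if n_seeds_per_class < 1:
        raise InvalidConfigError("every habitat class needs at least one seed")
    rng = np.random.default_rng(seed)
    n_classes = len(HABITAT_CLASSES)

    # continuous seed coordinates avoid equidistance ties in the tessellation
    seed_rows = rng.uniform(0, n_rows, size=n_classes * n_seeds_per_class)
    seed_cols = rng.uniform(0, n_cols, size=n_classes * n_seeds_per_class)
    seed_class = np.repeat(np.arange(n_classes), n_seeds_per_class)
    tree = cKDTree(np.column_stack([seed_rows, seed_cols]))
    rr, cc = np.meshgrid(
        np.arange(n_rows) + 0.5, np.arange(n_cols) + 0.5, indexing="ij"
    )
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    habitat = seed_class[nearest].reshape(n_rows, n_cols)

    road_mask = np.zeros((n_rows, n_cols), dtype=bool)
    for _ in range(max(1, n_roads)):
        # straight polyline from one grid edge to the opposite edge
        if rng.random() < 0.5:
            r0, r1 = rng.uniform(0, n_rows, size=2)
            c0, c1 = 0.0, float(n_cols)
        else:
            c0, c1 = rng.uniform(0, n_cols, size=2)
            r0, r1 = 0.0, float(n_rows)
        n_samp = int(4 * max(n_rows, n_cols))
        t = np.linspace(0.0, 1.0, n_samp)
        rows = np.clip((r0 + t * (r1 - r0)).astype(int), 0, n_rows - 1)
        cols = np.clip((c0 + t * (c1 - c0)).astype(int), 0, n_cols - 1)
        road_mask[rows, cols] = True

    settlement_mask = np.zeros((n_rows, n_cols), dtype=bool)
    for _ in range(max(1, n_settlements)):
        cr = rng.uniform(5, n_rows - 5)
        cc_ = rng.uniform(5, n_cols - 5)
        pts_r = np.clip(rng.normal(cr, 1.5, size=8).astype(int), 0, n_rows - 1)
        pts_c = np.clip(rng.normal(cc_, 1.5, size=8).astype(int), 0, n_cols - 1)
        settlement_mask[pts_r, pts_c] = True

    dist_road = ndimage.distance_transform_edt(~road_mask, sampling=cell_size)
    dist_settlement = ndimage.distance_transform_edt(
        ~settlement_mask, sampling=cell_size
    )
    return Landscape(
        habitat_grid=habitat,
        dist_road_grid=dist_road,
        dist_settlement_grid=dist_settlement,
        origin_x=0.0,
        origin_y=0.0,
        cell_size=cell_size,
    )


@dataclass(frozen=True)
class HarmonicBeta:
    """First-order harmonic selection surface for one covariate.

    beta(d, t) = a0 + a_hour * cos(2 pi t / 24 - phi_hour)
                    + a_year * cos(2 pi d / 365 - phi_year)
                    + a_int  * cos(2 pi t / 24) * cos(2 pi d / 365)

    with day-of-year d in [1, 365] and clock hour t in [0, 24).  The surface
    is exactly 24-periodic in t and 365-periodic in d, so it is recoverable
    by cyclic smoothers.
    """

    a0: float = 0.0
    a_hour: float = 0.0
    phi_hour: float = 0.0
    a_year: float = 0.0
    phi_year: float = 0.0
    a_int: float = 0.0

    def __call__(self, day, hour):
        day = np.asarray(day, dtype=float)
        hour = np.asarray(hour, dtype=float)
        th = 2.0 * np.pi * hour / 24.0
        td = 2.0 * np.pi * day / 365.0
        return (
            self.a0
            + self.a_hour * np.cos(th - self.phi_hour)
            + self.a_year * np.cos(td - self.phi_year)
            + self.a_int * np.cos(th) * np.cos(td)
        )


@dataclass
class TrueBetaSpec:
    """Known time-varying selection coefficients, one harmonic per covariate.

    Covariate names must come from :data:`MODEL_COVARIATES`.  Unlisted
    covariates have beta identically zero.
    """

    coefficients: Mapping[str, HarmonicBeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.coefficients:
            if name not in MODEL_COVARIATES:
                raise KeyError(f"unknown covariate {name!r}")

    def beta(self, covariate: str, day, hour):
        if covariate not in MODEL_COVARIATES:
            raise KeyError(f"unknown covariate {covariate!r}")
        h = self.coefficients.get(covariate)
        if h is None:
            return np.zeros(np.broadcast(np.asarray(day), np.asarray(hour)).shape)
        return h(day, hour)

    def surface(self, covariate: str) -> np.ndarray:
        """True beta on the 365-day x 24-hour grid (days as rows)."""
        days = np.arange(1, 366)[:, None]
        hours = np.arange(24)[None, :]
        return np.asarray(self.beta(covariate, days, hours), dtype=float) + np.zeros(
            (365, 24)
        )


def true_beta(spec: TrueBetaSpec, habitat: str, day, hour):
    """Evaluate the harmonic selection surface for one covariate.

    ``day`` in [1, 365], ``hour`` in [0, 24).  Raises ``KeyError`` for a
    covariate outside the model set.
    """
    day_arr = np.asarray(day, dtype=float)
    hour_arr = np.asarray(hour, dtype=float)
    if np.any((day_arr < 1) | (day_arr > 365)):
        raise ValueError("day must lie in [1, 365]")
    if np.any((hour_arr < 0) | (hour_arr >= 24)):
        raise ValueError("hour must lie in [0, 24)")
    return spec.beta(habitat, day, hour)


@dataclass
class SimConfig:
    """Configuration of the forward movement simulation."""

    n_individuals: int = 5
    start: str = "2016-01-01T00:00:00"
    end: str = "2016-12-30T23:00:00"
    fix_interval_min: int = 60
    gamma_shape: float = 2.0
    gamma_scale: float = 150.0
    vm_kappa: float = 1.0
    n_candidates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise InvalidConfigError("gamma parameters must be positive")
        if self.vm_kappa < 0:
            raise InvalidConfigError("vm_kappa must be non-negative")
        if self.n_candidates < 2:
            raise InvalidConfigError("need at least 2 candidate steps")
        if self.n_individuals < 1:
            raise InvalidConfigError("need at least one individual")


def _beta_tables(landscape: Landscape, spec: TrueBetaSpec):
    """Precompute per-(class, day, hour) log-weights plus distance terms.

    Returns ``(class_table, road_table, settle_table, z_road, z_settle)``
    where class_table has shape (n_classes, 365, 24); the distance tables are
    (365, 24) arrays of beta (or None when absent from the spec) and z_* are
    the landscape-wide standardized distance grids.
    """
    days = np.arange(1, 366)[:, None]
    hours = np.arange(24)[None, :]
    class_table = np.zeros((len(HABITAT_CLASSES), 365, 24))
    for code, name in enumerate(HABITAT_CLASSES):
        if name in MODELED_HABITATS and name in spec.coefficients:
            class_table[code] = spec.beta(name, days, hours)

    def z(grid):
        sd = grid.std()
        return (grid - grid.mean()) / (sd if sd > 0 else 1.0)

    road_table = settle_table = None
    z_road = z_settle = None
    if "dist_road" in spec.coefficients:
        road_table = np.asarray(spec.beta("dist_road", days, hours))
        z_road = z(landscape.dist_road_grid)
    if "dist_settlement" in spec.coefficients:
        settle_table = np.asarray(spec.beta("dist_settlement", days, hours))
        z_settle = z(landscape.dist_settlement_grid)
    return class_table, road_table, settle_table, z_road, z_settle


def simulate_tracks(
    landscape: Landscape,
    config: SimConfig,
    beta_spec: TrueBetaSpec,
    start_xy: Sequence[tuple[float, float]] | None = None,
    collect_stats: bool = False,
):
    """Forward-simulate hourly tracks under the step-selection choice kernel.

    At each fix, every individual draws ``n_candidates`` candidate endpoints
    (length ~ gamma, turn ~ von Mises relative to the previous bearing; the
    first move uses a uniform absolute bearing), and one candidate is chosen
    with probability proportional to ``exp(sum_h beta_h(day, hour) x_h)``.
    Candidates leaving the landscape are redrawn (up to 100 rounds), then
    reflected back into the extent.  Deterministic given ``config.seed``.

    Returns a tidy location table with columns id, timestamp (UTC), x, y.
    With ``collect_stats=True`` additionally returns per-habitat-class
    endpoint counts over all candidates and over the chosen endpoints
    (the oracle for checking the choice kernel against availability).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m = config.n_candidates
    xmin, ymin, xmax, ymax = landscape.extent
    margin = 0.1 * min(xmax - xmin, ymax - ymin)

    if start_xy is None:
        sx = rng.uniform(xmin + margin, xmax - margin, size=n)
        sy = rng.uniform(ymin + margin, ymax - margin, size=n)
    else:
        sx = np.array([p[0] for p in start_xy], dtype=float)
        sy = np.array([p[1] for p in start_xy], dtype=float)
        if not np.all(landscape.in_bounds(sx, sy)):
            raise InvalidConfigError("a start position lies outside the landscape")

    timestamps = pd.date_range(
        config.start, config.end, freq=f"{config.fix_interval_min}min", tz="UTC"
    )
    n_steps = len(timestamps) - 1
    if n_steps < 1:
        raise InvalidConfigError("simulation window shorter than one fix interval")

    class_table, road_table, settle_table, z_road, z_settle = _beta_tables(
        landscape, beta_spec
    )

    x = sx.copy()
    y = sy.copy()
    bearing = rng.uniform(-np.pi, np.pi, size=n)  # absolute bearing of first move
    xs = np.empty((len(timestamps), n))
    ys = np.empty((len(timestamps), n))
    xs[0], ys[0] = x, y

    day_idx = timestamps.dayofyear.to_numpy()
    day_idx = np.minimum(day_idx, 365) - 1
    hour_idx = timestamps.hour.to_numpy()
    cand_counts = np.zeros(len(HABITAT_CLASSES), dtype=np.int64)
    chosen_counts = np.zeros(len(HABITAT_CLASSES), dtype=np.int64)

    for i in range(1, len(timestamps)):
        d, h = day_idx[i], hour_idx[i]
        lengths = rng.gamma(config.gamma_shape, config.gamma_scale, size=(n, m))
        if i == 1:
            cand_bearing = rng.uniform(-np.pi, np.pi, size=(n, m))
        else:
            cand_bearing = bearing[:, None] + rng.vonmises(
                0.0, config.vm_kappa, size=(n, m)
            )
        ex = x[:, None] + lengths * np.cos(cand_bearing)
        ey = y[:, None] + lengths * np.sin(cand_bearing)

        # redraw out-of-bounds candidates, then reflect any stragglers
        oob = ~landscape.in_bounds(ex, ey)
        for _ in range(100):
            if not oob.any():
                break
            k = int(oob.sum())
            new_len = rng.gamma(config.gamma_shape, config.gamma_scale, size=k)
            new_turn = rng.vonmises(0.0, config.vm_kappa, size=k)
            base = np.broadcast_to(bearing[:, None], (n, m))[oob]
            nb = base + new_turn
            rows = np.nonzero(oob)[0]
            ex[oob] = x[rows] + new_len * np.cos(nb)
            ey[oob] = y[rows] + new_len * np.sin(nb)
            cand_bearing[oob] = nb
            oob = ~landscape.in_bounds(ex, ey)
        if oob.any():
            ex[oob] = _reflect(ex[oob], xmin, xmax)
            ey[oob] = _reflect(ey[oob], ymin, ymax)

        row, col = landscape.cell_index(ex, ey)
        logw = class_table[landscape.habitat_grid[row, col], d, h]
        if road_table is not None:
            logw = logw + road_table[d, h] * z_road[row, col]
        if settle_table is not None:
            logw = logw + settle_table[d, h] * z_settle[row, col]
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        choice = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
        choice = np.minimum(choice, m - 1)

        idx = np.arange(n)
        if collect_stats:
            codes = landscape.habitat_grid[row, col]
            cand_counts += np.bincount(codes.ravel(), minlength=len(HABITAT_CLASSES))
            chosen_counts += np.bincount(
                codes[idx, choice], minlength=len(HABITAT_CLASSES)
            )
        newx, newy = ex[idx, choice], ey[idx, choice]
        bearing = np.arctan2(newy - y, newx - x)
        x, y = newx, newy
        xs[i], ys[i] = x, y

    frames = []
    for j in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "id": f"sim{j:03d}",
                    "timestamp": timestamps,
                    "x": xs[:, j],
                    "y": ys[:, j],
                }
            )
        )
    tracks = pd.concat(frames, ignore_index=True)
    if collect_stats:
        return tracks, cand_counts, chosen_counts
    return tracks


def _reflect(v, lo, hi):
    """Mirror coordinates into [lo, hi) (nudged off the closed upper edge)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return np.clip(v + lo, lo, hi - 1e-9)


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    """Write a location table as GPS CSV (id, ISO-8601 UTC timestamp, x, y)."""
    out = tracks.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def make_synthetic_pairs(
    seed: int,
    beta_spec: TrueBetaSpec,
    n_pairs_per_cell: int = 900,
    availability: Mapping[str, float] | None = None,
    year: int = 2016,
) -> pd.DataFrame:
    """Directly generate matched step pairs covering every temporal cell.

    A lightweight alternative to the full movement simulation: for every
    14-day period x clock hour cell, candidate endpoints get a habitat class
    drawn from ``availability`` and raw distances from exponential fields,
    and within each pair the observed member is picked with probability
    proportional to ``exp(beta x)`` evaluated at the cell's timestamp — the
    exact data-generating process assumed by the matched conditional
    logistic likelihood.

    Returns the long pairs table (two rows per stratum, ``case`` 1/0) with
    habitat dummies, raw distances and ``t_end`` timestamps.
    """
    rng = np.random.default_rng(seed)
    if availability is None:
        availability = {name: 1.0 / len(HABITAT_CLASSES) for name in HABITAT_CLASSES}
    classes = list(availability)
    probs = np.array([availability[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    class_names = np.array(classes)
    frames = []
    stratum = 0
    k = n_pairs_per_cell
    for period in range(1, 27):
        mid_day = min((period - 1) * 14 + 7, 365)
        ts = pd.Timestamp(f"{year}-01-01", tz="UTC") + pd.Timedelta(days=mid_day - 1)
        for hour in range(24):
            t_end = ts + pd.Timedelta(hours=hour)
            cls = rng.choice(len(classes), size=(k, 2), p=probs)
            d_road = rng.exponential(500.0, size=(k, 2))
            d_settle = rng.exponential(800.0, size=(k, 2))
            # linear predictor at this cell's (day, hour) for both members
            lp = np.zeros((k, 2))
            for name in MODELED_HABITATS:
                if name in beta_spec.coefficients:
                    b = float(beta_spec.beta(name, mid_day, hour))
                    lp += b * (class_names[cls] == name)
            # distance betas are interpreted on the z scale of the raw draws
            for dname, draws, scale in (
                ("dist_road", d_road, 500.0),
                ("dist_settlement", d_settle, 800.0),
            ):
                if dname in beta_spec.coefficients:
                    b = float(beta_spec.beta(dname, mid_day, hour))
                    lp += b * (draws - scale) / scale
            p_first = 1.0 / (1.0 + np.exp(lp[:, 1] - lp[:, 0]))
            obs_is_first = rng.random(k) < p_first
            # column 0 = observed member index, column 1 = random member
            obs_idx = np.where(obs_is_first, 0, 1)
            j = np.arange(k)
            member = np.empty(2 * k, dtype=int)
            member[0::2] = obs_idx
            member[1::2] = 1 - obs_idx
            jj = np.repeat(j, 2)
            cell = pd.DataFrame(
                {
                    "stratum_id": stratum + jj,
                    "case": np.tile([1, 0], k),
                    "t_end": t_end,
                    "dist_road": d_road[jj, member],
                    "dist_settlement": d_settle[jj, member],
                }
            )
            chosen = class_names[cls[jj, member]]
            for name in MODELED_HABITATS:
                cell[name] = (chosen == name).astype(int)
            frames.append(cell)
            stratum += k
    return pd.concat(frames, ignore_index=True)
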