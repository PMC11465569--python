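"""GPS track cleaning, regularization to hourly bursts, and step geometry.

The raw material is a location table (columns ``id``, ``timestamp`` in UTC,
projected ``x``/``y`` in meters).  Processing follows the standard
step-selection workflow: remove positional outliers by a speed rule,
regularize each individual's track to fixes separated by the target
interval within a tolerance (yielding bursts), drop bursts too short to
carry a turning angle, and compute step lengths and signed turning angles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("id", "timestamp", "x", "y")


def _ts_ns(series: pd.Series) -> np.ndarray:
    """Timestamps as tz-naive datetime64[ns] (UTC wall time)."""
    s = pd.to_datetime(series, utc=True)
    return s.dt.tz_localize(None).to_numpy()


def _check_locations(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"location table missing columns: {missing}")
    for _, g in df.groupby("id", sort=False):
        t = _ts_ns(g["timestamp"])
        if len(t) > 1 and not (np.diff(t) > np.timedelta64(0)).all():
            raise ValueError("timestamps must be strictly increasing per individual")


def filter_outliers(
    locations: pd.DataFrame,
    max_step_km: float = 15.0,
    max_interval_h: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop positional outliers by an implied-speed rule.

    A fix is an outlier when the step from the previous retained fix exceeds
    ``max_step_km`` per ``max_interval_h`` — i.e. implied speed above
    ``max_step_km / max_interval_h`` km/h, scaled to the actual gap.  The
    later fix of the offending pair is removed and speeds are re-evaluated
    against the last retained fix, so a single spike costs one fix even when
    it would flag both its flanks.

    Returns ``(retained, removal_log)``; the log carries one row per removed
    fix with the implied speed that triggered removal.
    """
    _check_locations(locations)
    if len(locations) == 0:
        return locations.copy(), pd.DataFrame(columns=[*REQUIRED_COLUMNS, "speed_kmh"])
    speed_limit = max_step_km / max_interval_h

    keep_mask = np.ones(len(locations), dtype=bool)
    log_rows = []
    for _, g in locations.groupby("id", sort=False):
        idx = g.index.to_numpy()
        t = _ts_ns(g["timestamp"])
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        last = 0
        for i in range(1, len(idx)):
            dt_h = (t[i] - t[last]) / np.timedelta64(1, "h")
            dist_km = np.hypot(x[i] - x[last], y[i] - y[last]) / 1000.0
            if dt_h > 0 and dist_km / dt_h > speed_limit:
                keep_mask[locations.index.get_loc(idx[i])] = False
                log_rows.append(
                    {**g.loc[idx[i], list(REQUIRED_COLUMNS)].to_dict(),
                     "speed_kmh": dist_km / dt_h}
                )
            else:
                last = i
    retained = locations[keep_mask].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=[*REQUIRED_COLUMNS, "speed_kmh"])
    return retained, log


def regularize(
    locations: pd.DataFrame,
    target_min: float = 60.0,
    tol_min: float = 15.0,
) -> pd.DataFrame:
    """Split each track into bursts of fixes at the target interval.

    Greedy forward scan per individual: starting from an anchor fix, the
    next fix is kept when its gap from the last kept fix lies within
    ``[target_min - tol_min, target_min + tol_min]``; a gap outside the
    window closes the burst and the offending fix anchors a new one.
    Bursts with fewer than three locations (too short to define a turning
    angle) are discarded.

    Returns the kept fixes with an added globally unique ``burst_id``.
    """
    _check_locations(locations)
    out = []
    burst_counter = 0
    lo, hi = target_min - tol_min, target_min + tol_min
    for _, g in locations.groupby("id", sort=False):
        t = _ts_ns(g["timestamp"])
        kept: list[int] = []
        bursts: list[list[int]] = []
        current = [0]
        for i in range(1, len(g)):
            gap_min = (t[i] - t[current[-1]]) / np.timedelta64(1, "m")
            if lo <= gap_min <= hi:
                current.append(i)
            else:
                bursts.append(current)
                current = [i]
        bursts.append(current)
        for b in bursts:
            if len(b) >= 3:
                chunk = g.iloc[b].copy()
                chunk["burst_id"] = burst_counter
                out.append(chunk)
                burst_counter += 1
    if not out:
        return locations.iloc[0:0].assign(burst_id=pd.Series(dtype=int))
    return pd.concat(out, ignore_index=True)


def _wrap_angle(a):
    """Wrap radians into (-pi, pi]."""
    a = np.mod(np.asarray(a, dtype=float), 2.0 * np.pi)
    return np.where(a > np.pi, a - 2.0 * np.pi, a)


def compute_steps(bursts: pd.DataFrame) -> pd.DataFrame:
    """Turn regularized bursts into steps with lengths and turning angles.

    A burst of n locations yields n-1 steps.  The turning angle of step i is
    the signed difference between its bearing and the previous step's
    bearing, wrapped to (-pi, pi]; the first step of a burst has no previous
    bearing and carries ``turn = NaN`` (it anchors the bearing only).  A
    zero-length previous step leaves the bearing undefined: the turn is NaN
    and ``turn_undefined`` is flagged.

    Each step receives a globally unique ``stratum_id`` used downstream to
    match it with its random counterpart.
    """
    if "burst_id" not in bursts.columns:
        raise ValueError("input must carry burst_id (run regularize first)")
    frames = []
    for burst_id, g in bursts.groupby("burst_id", sort=True):
        if len(g) < 3:
            raise ValueError(f"burst {burst_id} has fewer than 3 locations")
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        dx, dy = np.diff(x), np.diff(y)
        length = np.hypot(dx, dy)
        bearing = np.arctan2(dy, dx)
        turn = np.full(len(dx), np.nan)
        undefined = np.zeros(len(dx), dtype=bool)
        prev_zero = length[:-1] == 0.0
        turn[1:] = _wrap_angle(bearing[1:] - bearing[:-1])
        turn[1:][prev_zero] = np.nan
        undefined[1:][prev_zero] = True
        frames.append(
            pd.DataFrame(
                {
                    "id": g["id"].iloc[0],
                    "burst_id": burst_id,
                    "t_start": g["timestamp"].to_numpy()[:-1],
                    "t_end": g["timestamp"].to_numpy()[1:],
                    "x_start": x[:-1],
                    "y_start": y[:-1],
                    "x_end": x[1:],
                    "y_end": y[1:],
                    "length": length,
                    "bearing": bearing,
                    "turn": turn,
                    "turn_undefined": undefined,
                    "prev_bearing": np.concatenate([[np.nan], bearing[:-1]]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "id", "burst_id", "t_start", "t_end", "x_start", "y_start",
                "x_end", "y_end", "length", "bearing", "turn",
                "turn_undefined", "prev_bearing", "stratum_id",
            ]
        )
    steps = pd.concat(frames, ignore_index=True)
    steps["stratum_id"] = np.arange(len(steps))
    return steps


def write_steps_csv(steps: pd.DataFrame, path) -> None:
    out = steps.copy()
    for col in ("t_start", "t_end"):
        out[col] = pd.to_datetime(out[col], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
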