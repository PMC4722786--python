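"""GPS fix preparation: resampling, capture-day trimming, error screening.

Screening follows the two-stage rule for telemetry error detection:
stage 1 removes gross outliers by distance from a windowed location median
(mu within the movement window, delta regardless of window); stage 2 removes
"spikes" — out-and-back displacements whose inbound and outbound speeds both
exceed alpha while the turn cosine falls below cos_theta. Flagged fixes are
retained with flags rather than deleted so the screening is auditable;
downstream stages drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class ScreeningParams:
    """Thresholds of the two-stage screening.

    alpha: speed threshold, km/h. cos_theta: turn-cosine threshold
    (dimensionless, in [-1, 1]). mu: distance from the windowed median, km.
    delta: distance from the whole-trajectory median, km. window: width of
    the moving window, hours.
    """

    alpha: float = 1.5
    cos_theta: float = -0.97
    mu: float = 50.0
    delta: float = 200.0
    window: float = 20.0

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not -1.0 <= self.cos_theta <= 1.0:
            raise ValueError("cos_theta must lie in [-1, 1]")
        if not self.delta > self.mu > 0:
            raise ValueError("delta > mu > 0 required")
        if self.window <= 0:
            raise ValueError("window must be positive")


def _times_seconds(traj: pd.DataFrame) -> np.ndarray:
    t = pd.to_datetime(traj["t"], utc=True)
    return t.astype("int64").to_numpy() / 1e9


def resample_fixes(traj: pd.DataFrame, interval: float = 14400.0) -> pd.DataFrame:
    """Resample a fix table to a common interval.

    For each grid time (multiples of ``interval`` from the first fix) the
    nearest fix within ``interval/2`` is retained; each fix is used at most
    once. Data already on the grid pass through unchanged.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if interval <= 0:
        raise ValueError("interval must be positive")
    t = _times_seconds(traj)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be sorted and unique")
    rel = t - t[0]
    grid = np.arange(0.0, rel[-1] + 1e-9, interval)
    keep: list[int] = []
    used = -1
    for g in grid:
        i = int(np.argmin(np.abs(rel - g)))
        if abs(rel[i] - g) <= interval / 2.0 and i > used:
            keep.append(i)
            used = i
    out = traj.iloc[keep].reset_index(drop=True)
    out.attrs = dict(traj.attrs)
    return out


def trim_capture_days(traj: pd.DataFrame, capture_events=()) -> pd.DataFrame:
    """Drop the first and last calendar days plus any capture-event days.

    Calendar days are evaluated in UTC. Raises if nothing remains (e.g. a
    single-day record).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t = pd.to_datetime(traj["t"], utc=True)
    days = t.dt.floor("D")
    drop = {days.iloc[0], days.iloc[-1]}
    for ev in capture_events:
        drop.add(pd.Timestamp(ev, tz="UTC").floor("D"))
    keep = ~days.isin(drop)
    if not keep.any():
        raise ValueError("trimming removed every fix (record too short?)")
    out = traj.loc[keep].reset_index(drop=True)
    out.attrs = dict(traj.attrs)
    return out


def screen_errors(traj: pd.DataFrame, params: ScreeningParams | None = None) -> pd.DataFrame:
    """Flag erroneous fixes; returns a table with flag_stage1/flag_stage2.

    Stage 1 flags a fix farther than ``mu`` km from the median location of
    the other fixes within the centred ``window`` (truncated at the record
    ends), or farther than ``delta`` km from the whole-trajectory median.
    Stage 2 flags interior fixes whose inbound and outbound speeds both
    exceed ``alpha`` km/h while the turn cosine is below ``cos_theta``.
    Order-preserving; the input is not modified.
    """
    params = params or ScreeningParams()
    params.validate()
    n = len(traj)
    if n == 0:
        raise ValueError("empty trajectory")
    t = _times_seconds(traj)
    xy = traj[["x", "y"]].to_numpy(dtype=float)

    mu_m = params.mu * 1000.0
    delta_m = params.delta * 1000.0
    half = params.window * 3600.0 / 2.0
    global_med = np.median(xy, axis=0)

    stage1 = np.zeros(n, dtype=bool)
    for i in range(n):
        sel = (np.abs(t - t[i]) <= half)
        sel[i] = False
        if sel.any():
            med = np.median(xy[sel], axis=0)
            if np.linalg.norm(xy[i] - med) > mu_m:
                stage1[i] = True
        if np.linalg.norm(xy[i] - global_med) > delta_m:
            stage1[i] = True

    stage2 = np.zeros(n, dtype=bool)
    warn = False
    if n < 3:
        warnings.warn("fewer than 3 fixes: spike screening skipped")
        warn = True
    else:
        alpha_ms = params.alpha * 1000.0 / 3600.0
        for i in range(1, n - 1):
            a = xy[i] - xy[i - 1]
            b = xy[i + 1] - xy[i]
            dt_in = t[i] - t[i - 1]
            dt_out = t[i + 1] - t[i]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if dt_in <= 0 or dt_out <= 0 or na == 0 or nb == 0:
                continue
            v_in = na / dt_in
            v_out = nb / dt_out
            cth = float(a @ b / (na * nb))
            if v_in > alpha_ms and v_out > alpha_ms and cth < params.cos_theta:
                stage2[i] = True

    return pd.DataFrame(
        {
            "flag_stage1": stage1,
            "flag_stage2": stage2,
            "screening_warning": np.full(n, warn),
        },
        index=traj.index,
    )


def location_error(fixes: pd.DataFrame) -> float:
    """Collar location error of a stationary test site, in metres.

    Computed as sqrt(sd(x)^2 + sd(y)^2) with sample (n-1) standard
    deviations over repeated fixes of a fixed collar.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes from a stationary collar")
    sx = float(np.std(fixes["x"].to_numpy(dtype=float), ddof=1))
    sy = float(np.std(fixes["y"].to_numpy(dtype=float), ddof=1))
    return float(np.hypot(sx, sy))


class GPSScreener(BaseEstimator, TransformerMixin):
    """Transformer bundling resampling, trimming and error screening.

    ``transform`` returns the prepared fix table with ``flag_stage1`` /
    ``flag_stage2`` columns appended; ``clean`` additionally drops flagged
    fixes.

    Parameters mirror :class:`ScreeningParams`, plus the resampling interval
    (seconds). Set ``interval=None`` to skip resampling, ``trim=False`` to
    keep first/last days.
    """

    def __init__(self, alpha=1.5, cos_theta=-0.97, mu=50.0, delta=200.0,
                 window=20.0, interval=14400.0, trim=False, capture_events=()):
        self.alpha = alpha
        self.cos_theta = cos_theta
        self.mu = mu
        self.delta = delta
        self.window = window
        self.interval = interval
        self.trim = trim
        self.capture_events = capture_events

    def _params(self) -> ScreeningParams:
        p = ScreeningParams(self.alpha, self.cos_theta, self.mu, self.delta, self.window)
        p.validate()
        return p

    def fit(self, X: pd.DataFrame, y=None):
        self._params()
        self.n_fixes_in_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        params = self._params()
        traj = X
        if self.interval is not None:
            traj = resample_fixes(traj, self.interval)
        if self.trim:
            traj = trim_capture_days(traj, self.capture_events)
        flags = screen_errors(traj, params)
        out = traj.copy()
        out.attrs = dict(traj.attrs)
        out["flag_stage1"] = flags["flag_stage1"].to_numpy()
        out["flag_stage2"] = flags["flag_stage2"].to_numpy()
        return out

    def clean(self, X: pd.DataFrame) -> pd.DataFrame:
        out = self.fit(X).transform(X)
        keep = ~(out["flag_stage1"] | out["flag_stage2"])
        res = out.loc[keep].drop(columns=["flag_stage1", "flag_stage2"]).reset_index(drop=True)
        res.attrs = dict(out.attrs)
        return res
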