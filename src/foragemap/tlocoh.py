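"""Time-local convex hulls: TSD, hulls, revisitation metrics, isopleths.

The engine models space use by building a local convex hull around every fix
from its nearest neighbours under the time-scaled distance

    TSD(i, j) = sqrt(dx^2 + dy^2 + (s * v_max * dt)^2)

which converts the time lag between two fixes into an equivalent distance
via the trajectory's maximum observed speed ``v_max`` and the weighting
parameter ``s``. Hulls are sorted by a time-use metric — here the number of
separate visits (NSV) under an inter-visit gap, normalised to NNSV — and
progressively merged into isopleths. The 30% isopleth of the
revisitation-sorted hulls delineates the core foraging area (CFA).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from sklearn.base import BaseEstimator

__all__ = [
    "TSDParams", "HullConfig", "Hull", "HullSet", "IsoplethLevel",
    "IsoplethSet", "tsd", "tsd_matrix", "max_observed_speed", "select_s",
    "select_neighbors", "build_hulls", "hull_metrics", "build_isopleths",
    "select_a", "export_cfa", "import_cfa", "TLoCoH",
]


@dataclass
class TSDParams:
    """Weighting of the time term in the time-scaled distance."""

    s: float
    v_max: float

    def validate(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.s > 0 and self.v_max <= 0:
            raise ValueError("v_max must be positive when s > 0")


@dataclass
class HullConfig:
    """Neighbour-selection rule and isopleth settings.

    Exactly one of ``a`` (cumulative TSD, metres), ``k`` (neighbour count,
    parent included) or ``r`` (TSD radius, metres) must be set, matching
    ``method``. ``ivg`` is the inter-visit gap in seconds (12 h default);
    ``levels`` the isopleth fractions, ascending.
    """

    method: str = "a"
    a: float | None = None
    k: int | None = None
    r: float | None = None
    ivg: float = 43200.0
    levels: tuple[float, ...] = (0.3,)
    sort_metric: str = "nnsv"

    def validate(self) -> None:
        if self.method not in ("a", "k", "r"):
            raise ValueError("method must be 'a', 'k' or 'r'")
        given = {m for m, v in (("a", self.a), ("k", self.k), ("r", self.r)) if v is not None}
        if given != {self.method}:
            raise ValueError(
                f"exactly the parameter of method {self.method!r} must be set, got {sorted(given)}"
            )
        if self.ivg <= 0:
            raise ValueError("ivg must be positive")
        lv = list(self.levels)
        if not lv or lv != sorted(lv) or not all(0 < l <= 1 for l in lv):
            raise ValueError("levels must be ascending fractions in (0, 1]")


# ---------------------------------------------------------------------------
# distances


def _fix_xyz(fix) -> tuple[float, float, float]:
    if isinstance(fix, (tuple, list, np.ndarray)):
        x, y, t = fix
        return float(x), float(y), float(t)
    t = fix["t"]
    if isinstance(t, pd.Timestamp):
        t = t.value / 1e9
    return float(fix["x"]), float(fix["y"]), float(t)


def tsd(fix_i, fix_j, params: TSDParams) -> float:
    """Time-scaled distance between two fixes (metres).

    Fixes are (x, y, t_seconds) triples or mappings with keys x/y/t.
    """
    params.validate()
    xi, yi, ti = _fix_xyz(fix_i)
    xj, yj, tj = _fix_xyz(fix_j)
    dt = ti - tj
    return float(np.sqrt((xi - xj) ** 2 + (yi - yj) ** 2 + (params.s * params.v_max * dt) ** 2))


def _traj_arrays(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    xy = traj[["x", "y"]].to_numpy(dtype=float)
    t = pd.to_datetime(traj["t"], utc=True).astype("int64").to_numpy() / 1e9
    return xy, t


def tsd_matrix(xy: np.ndarray, t: np.ndarray, s: float, v_max: float) -> np.ndarray:
    """Full pairwise TSD matrix; O(n^2) memory, fine for deployment-scale n."""
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    dt = t[:, None] - t[None, :]
    return np.sqrt(dx * dx + dy * dy + (s * v_max * dt) ** 2)


def max_observed_speed(traj: pd.DataFrame) -> float:
    """Maximum displacement/time over consecutive fixes, m/s."""
    xy, t = _traj_arrays(traj)
    if len(xy) < 2:
        raise ValueError("need at least 2 fixes")
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return float(np.max(d / dt))


# ---------------------------------------------------------------------------
# s selection (proportion of time-selected hulls)


def _knn_sets(dist: np.ndarray, k: int) -> list[tuple[int, ...]]:
    """Deterministic k-nearest-neighbour sets per row, self excluded.

    Ties are broken by point index so results are reproducible.
    """
    n = dist.shape[0]
    out = []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))
        order = order[order != i][:k]
        out.append(tuple(np.sort(order)))
    return out


def ptsh(traj_or_arrays, s: float, v_max: float | None = None, k_probe: int = 10) -> float:
    """Proportion of time-selected hulls at weighting ``s``.

    A point counts as time-selected when its ``k_probe`` nearest-neighbour
    set under TSD(s) differs from the set under s=0 (pure space).
    """
    if isinstance(traj_or_arrays, pd.DataFrame):
        xy, t = _traj_arrays(traj_or_arrays)
        v_max = max_observed_speed(traj_or_arrays) if v_max is None else v_max
    else:
        xy, t = traj_or_arrays
        if v_max is None:
            raise ValueError("v_max required with array input")
    base = _knn_sets(tsd_matrix(xy, t, 0.0, v_max), k_probe)
    cur = _knn_sets(tsd_matrix(xy, t, s, v_max), k_probe)
    return float(np.mean([b != c for b, c in zip(base, cur)]))


def select_s(
    traj: pd.DataFrame,
    target_ptsh: float = 0.60,
    k_probe: int = 10,
    s_grid: np.ndarray | None = None,
    refine_iter: int = 25,
) -> tuple[float, float]:
    """Choose s so the proportion of time-selected hulls is near the target.

    Evaluates ptsh over a log-spaced candidate grid and bisects between the
    bracketing candidates; returns ``(s, achieved_ptsh)``.
    """
    xy, t = _traj_arrays(traj)
    v_max = max_observed_speed(traj)
    if v_max <= 0:
        raise ValueError("trajectory has no movement; s cannot be selected")
    if s_grid is None:
        s_grid = np.logspace(-4, 1, 24)
    base = _knn_sets(tsd_matrix(xy, t, 0.0, v_max), k_probe)

    def _ptsh(s: float) -> float:
        cur = _knn_sets(tsd_matrix(xy, t, s, v_max), k_probe)
        return float(np.mean([b != c for b, c in zip(base, cur)]))

    vals = np.array([_ptsh(s) for s in s_grid])
    if np.all(vals == 0.0):
        raise ValueError("every candidate s yields ptsh 0 (are all fixes simultaneous?)")

    best_i = int(np.argmin(np.abs(vals - target_ptsh)))
    best_s, best_p = float(s_grid[best_i]), float(vals[best_i])

    # bisect between the last candidate below target and the first above
    lo = hi = None
    for i in range(len(s_grid) - 1):
        if vals[i] <= target_ptsh <= vals[i + 1]:
            lo, hi = i, i + 1
            break
    if lo is not None:
        a, b = np.log10(s_grid[lo]), np.log10(s_grid[hi])
        for _ in range(refine_iter):
            m = 0.5 * (a + b)
            pm = _ptsh(10 ** m)
            if abs(pm - target_ptsh) < abs(best_p - target_ptsh):
                best_s, best_p = float(10 ** m), float(pm)
            if pm < target_ptsh:
                a = m
            else:
                b = m
            if abs(pm - target_ptsh) <= 0.005:
                break
    return best_s, best_p


# ---------------------------------------------------------------------------
# neighbours and hulls


def select_neighbors(
    traj: pd.DataFrame, s: float, config: HullConfig, v_max: float | None = None
) -> list[np.ndarray]:
    """Per-point neighbour lists (parent included) under the configured rule.

    a-method: nearest TSD neighbours accumulate while the running TSD sum
    stays within ``a``. k-method: the ``k`` nearest points including the
    parent itself. r-method: all points with TSD <= ``r``. Ties broken by
    point index.
    """
    config.validate()
    xy, t = _traj_arrays(traj)
    n = len(xy)
    if v_max is None:
        v_max = max_observed_speed(traj) if s > 0 else 1.0
    dist = tsd_matrix(xy, t, s, v_max)
    idx = np.arange(n)
    lists: list[np.ndarray] = []
    for i in range(n):
        order = np.lexsort((idx, dist[i]))
        order = order[order != i]
        d = dist[i, order]
        if config.method == "a":
            csum = np.cumsum(d)
            take = order[csum <= config.a]
        elif config.method == "k":
            take = order[: max(config.k - 1, 0)]
        else:
            take = order[d <= config.r]
        nbrs = np.sort(np.concatenate(([i], take)))
        if len(nbrs) < 3:
            # degenerate hull (point or segment); recorded, not fatal
            pass
        lists.append(nbrs)
    return lists


@dataclass
class Hull:
    """A local convex hull around one parent fix."""

    parent: int
    neighbours: np.ndarray
    polygon: BaseGeometry
    area: float
    perimeter: float
    enclosed: np.ndarray
    nsv: int | None = None
    nnsv: float | None = None


@dataclass
class HullSet:
    """All hulls of one individual plus the trajectory they came from."""

    hulls: list[Hull]
    xy: np.ndarray
    t: np.ndarray

    def __len__(self) -> int:
        return len(self.hulls)


def _geom_perimeter(geom: BaseGeometry) -> float:
    if geom.geom_type == "Polygon" or geom.geom_type == "MultiPolygon":
        return float(geom.length)
    # degenerate segment: out-and-back boundary
    return float(2.0 * geom.length)


def build_hulls(traj: pd.DataFrame, neighbor_lists: list[np.ndarray]) -> HullSet:
    """Convex hull of each parent+neighbour point set, with enclosed fixes.

    Enclosed points are all trajectory fixes inside or on the hull
    (boundary counts as enclosed); degenerate hulls (fewer than 3 unique
    positions) are retained with zero area.
    """
    xy, t = _traj_arrays(traj)
    pts = shapely.points(xy)
    hulls: list[Hull] = []
    for i, nbrs in enumerate(neighbor_lists):
        geom = shapely.convex_hull(shapely.multipoints(xy[nbrs]))
        covered = shapely.covers(geom, pts)
        enclosed = np.nonzero(covered)[0]
        hulls.append(
            Hull(
                parent=i,
                neighbours=np.asarray(nbrs),
                polygon=geom,
                area=float(geom.area),
                perimeter=_geom_perimeter(geom),
                enclosed=enclosed,
            )
        )
    return HullSet(hulls=hulls, xy=xy, t=t)


def _count_visits(times: np.ndarray, ivg: float) -> int:
    if len(times) == 0:
        return 0
    gaps = np.diff(np.sort(times))
    return int(1 + np.sum(gaps > ivg))


def hull_metrics(hullset: HullSet, ivg: float = 43200.0) -> HullSet:
    """Attach NSV (separate visits under the inter-visit gap) and NNSV.

    NSV counts maximal runs of enclosed timestamps with consecutive gaps
    <= ivg; NNSV rescales NSV to [0, 1] by the maximum NSV in the set.
    """
    if len(hullset) == 0:
        raise ValueError("empty hull set")
    for h in hullset.hulls:
        h.nsv = _count_visits(hullset.t[h.enclosed], ivg)
    max_nsv = max(h.nsv for h in hullset.hulls)
    denom = max(max_nsv, 1)
    for h in hullset.hulls:
        h.nnsv = h.nsv / denom
    return hullset


@dataclass
class IsoplethLevel:
    level: float
    polygon: BaseGeometry
    enclosed_fraction: float
    area: float
    edge_area_ratio: float


@dataclass
class IsoplethSet:
    """Nested isopleth polygons built by progressive hull union."""

    levels: dict[float, IsoplethLevel] = field(default_factory=dict)

    def __getitem__(self, level: float) -> IsoplethLevel:
        if level not in self.levels:
            raise KeyError(f"isopleth level {level} not present")
        return self.levels[level]

    def __contains__(self, level: float) -> bool:
        return level in self.levels


def _sorted_hulls(hullset: HullSet, sort_metric: str) -> list[Hull]:
    def key(h: Hull):
        m = getattr(h, sort_metric)
        if m is None:
            raise ValueError(f"metric {sort_metric!r} not computed; run hull_metrics first")
        return (-m, h.area, h.parent)

    return sorted(hullset.hulls, key=key)


def build_isopleths(
    hullset: HullSet, levels=(0.3,), sort_metric: str = "nnsv"
) -> IsoplethSet:
    """Union hulls in descending metric order until each level is enclosed.

    Hulls are sorted by the metric (ties: smaller area, then lower parent
    index) and unioned progressively; the level-L polygon is the first
    union enclosing at least fraction L of all fixes.
    """
    levels = sorted(levels)
    if not levels:
        raise ValueError("no isopleth levels requested")
    ordered = _sorted_hulls(hullset, sort_metric)
    pts = shapely.points(hullset.xy)
    n = len(hullset.xy)
    out = IsoplethSet()
    running = None
    pending = list(levels)
    for h in ordered:
        running = h.polygon if running is None else running.union(h.polygon)
        frac = float(np.count_nonzero(shapely.covers(running, pts))) / n
        while pending and frac >= pending[0]:
            lv = pending.pop(0)
            area = float(running.area)
            ear = float(running.length / area) if area > 0 else float("inf")
            out.levels[lv] = IsoplethLevel(
                level=lv,
                polygon=shapely.from_wkb(shapely.to_wkb(running)),
                enclosed_fraction=frac,
                area=area,
                edge_area_ratio=ear,
            )
        if not pending:
            break
    if pending:
        raise ValueError(f"isopleth levels {pending} unreachable")
    return out


def select_a(
    traj: pd.DataFrame,
    s: float,
    candidates,
    level: float = 0.3,
    ivg: float = 43200.0,
    sort_metric: str = "nnsv",
    tol_ratio: float = 0.05,
    jump_tol: float = 0.50,
) -> tuple[float, pd.DataFrame]:
    """Pick the cumulative-TSD threshold that stabilises the isopleths.

    For each candidate ``a`` the core-level isopleth's area and edge:area
    ratio are computed; the selected ``a`` is the smallest whose relative
    edge:area change versus the previous candidate is below ``tol_ratio``
    while the relative area increase at the next candidate stays within
    ``jump_tol``. Returns ``(a, diagnostics)`` with the full curve.
    """
    candidates = list(candidates)
    if len(candidates) < 3:
        raise ValueError("need at least 3 ascending candidates for a")
    if candidates != sorted(candidates):
        raise ValueError("candidates must be ascending")
    v_max = max_observed_speed(traj) if s > 0 else 1.0
    rows = []
    for a in candidates:
        cfg = HullConfig(method="a", a=a, ivg=ivg, levels=(level,), sort_metric=sort_metric)
        hs = build_hulls(traj, select_neighbors(traj, s, cfg, v_max=v_max))
        hull_metrics(hs, ivg)
        iso = build_isopleths(hs, (level,), sort_metric)[level]
        rows.append({"a": a, "area": iso.area, "edge_area_ratio": iso.edge_area_ratio})
    diag = pd.DataFrame(rows)
    area = diag["area"].to_numpy()
    ear = diag["edge_area_ratio"].to_numpy()
    chosen = None
    for i in range(1, len(candidates)):
        if ear[i - 1] <= 0 or not np.isfinite(ear[i - 1]):
            continue
        rel = abs(ear[i] - ear[i - 1]) / ear[i - 1]
        nxt_jump = (area[i + 1] - area[i]) / area[i] if i + 1 < len(candidates) and area[i] > 0 else 0.0
        if rel < tol_ratio and nxt_jump <= jump_tol:
            chosen = candidates[i]
            break
    if chosen is None:
        # no candidate stabilised: stop just before the largest relative
        # area expansion (the "jump" that starts bridging separate cores)
        jumps = [
            (area[i + 1] - area[i]) / area[i] if area[i] > 0 else 0.0
            for i in range(len(candidates) - 1)
        ]
        chosen = candidates[int(np.argmax(jumps))]
        warnings.warn(
            "no candidate met the stabilisation rules; returning the last "
            "candidate before the largest area jump"
        )
    return float(chosen), diag


# ---------------------------------------------------------------------------
# export


def export_cfa(isopleths: IsoplethSet, path, level: float = 0.3, **metadata) -> None:
    """Write one isopleth polygon as a GeoJSON feature with metadata."""
    entry = isopleths[level]
    feature = {
        "type": "Feature",
        "geometry": mapping(entry.polygon),
        "properties": {
            "level": entry.level,
            "area_m2": entry.area,
            "enclosed_fraction": entry.enclosed_fraction,
            **metadata,
        },
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def import_cfa(path) -> tuple[BaseGeometry, dict]:
    """Read a CFA polygon written by :func:`export_cfa`."""
    with open(path) as fh:
        doc = json.load(fh)
    feat = doc["features"][0]
    return shape(feat["geometry"]), feat["properties"]


# ---------------------------------------------------------------------------
# estimator


class TLoCoH(BaseEstimator):
    """Time-local convex hull estimator for one individual's trajectory.

    ``fit`` consumes a fix table (columns id/t/x/y, optionally
    flag_stage1/flag_stage2 from screening — flagged fixes are dropped) and
    exposes the fitted hull set and isopleths:

    Attributes
    ----------
    v_max_ : maximum observed speed (m/s)
    s_, ptsh_ : selected time weighting and achieved proportion of
        time-selected hulls (when ``s='auto'``)
    a_ : the cumulative-TSD threshold used (after auto-selection when
        ``a='auto'``)
    hulls_ : :class:`HullSet` with NSV/NNSV metrics
    isopleths_ : :class:`IsoplethSet`
    cfa_ : shapely polygon of the core foraging area (lowest level)
    """

    def __init__(self, method="a", a=None, k=None, r=None, s="auto",
                 target_ptsh=0.60, k_probe=10, ivg=43200.0, levels=(0.3,),
                 sort_metric="nnsv", a_candidates=None, drop_flagged=True):
        self.method = method
        self.a = a
        self.k = k
        self.r = r
        self.s = s
        self.target_ptsh = target_ptsh
        self.k_probe = k_probe
        self.ivg = ivg
        self.levels = levels
        self.sort_metric = sort_metric
        self.a_candidates = a_candidates
        self.drop_flagged = drop_flagged

    def fit(self, X: pd.DataFrame, y=None):
        traj = X
        if self.drop_flagged:
            for col in ("flag_stage1", "flag_stage2"):
                if col in traj.columns:
                    traj = traj.loc[~traj[col]]
            traj = traj.reset_index(drop=True)
        if len(traj) < 5:
            raise ValueError("too few fixes after screening")
        self.v_max_ = max_observed_speed(traj)
        if self.s == "auto":
            self.s_, self.ptsh_ = select_s(traj, self.target_ptsh, self.k_probe)
        else:
            self.s_ = float(self.s)
            self.ptsh_ = None
        a = self.a
        if self.method == "a" and (a == "auto" or a is None):
            cands = self.a_candidates
            if cands is None:
                # default grid spans the scale of pairwise spatial distances
                xy = traj[["x", "y"]].to_numpy(dtype=float)
                span = float(np.linalg.norm(xy.max(axis=0) - xy.min(axis=0)))
                cands = list(np.linspace(0.05, 1.0, 12) * max(span, 1.0))
            self.a_, self.a_diagnostics_ = select_a(
                traj, self.s_, cands, level=min(self.levels), ivg=self.ivg,
                sort_metric=self.sort_metric,
            )
        else:
            self.a_ = a
        cfg = HullConfig(
            method=self.method,
            a=self.a_ if self.method == "a" else None,
            k=self.k if self.method == "k" else None,
            r=self.r if self.method == "r" else None,
            ivg=self.ivg, levels=tuple(sorted(self.levels)),
            sort_metric=self.sort_metric,
        )
        nbrs = select_neighbors(traj, self.s_, cfg, v_max=self.v_max_)
        self.hulls_ = hull_metrics(build_hulls(traj, nbrs), self.ivg)
        self.isopleths_ = build_isopleths(self.hulls_, cfg.levels, self.sort_metric)
        self.cfa_ = self.isopleths_[min(cfg.levels)].polygon
        self.n_fixes_ = len(traj)
        return self

    def cfa_polygon(self, level: float = 0.3) -> BaseGeometry:
        return self.isopleths_[level].polygon
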