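"""Synthetic trajectories, hyperspectral scenes and species usage with known truth.

Everything downstream (screening, hull analysis, spectral regression,
multinomial comparison) is validated against data generated here, because the
generators plant the exact structure each stage is meant to recover:

* trajectories follow a patch itinerary, so revisitation is ground truth,
  not emergent behaviour;
* grass-cell reflectance is constructed so a chosen band ratio encodes plant
  biomass (and another one plant nitrogen) through a known functional form;
* species' cell use follows a known logit preference on (BiomRS, N).

Coordinates are planar metres in an arbitrary local CRS; timestamps are UTC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint

SECONDS_PER_DAY = 86400.0

SPECIES = ("chamois", "ibex", "red_deer")

ENDMEMBER_LABELS = ("grass", "forest", "rock", "snow", "water")


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class Patch:
    """A circular foraging patch the simulated animal returns to."""

    x: float
    y: float
    radius: float
    weight: float = 1.0


@dataclass
class TrajectoryConfig:
    """Parameters of the patch-itinerary biased random walk.

    Defaults emulate a 43-day deployment at a 4 h fix interval (6 fixes per
    day) with repeated patch revisitation at a daily-scale return period.
    """

    n_days: int = 43
    fix_interval: float = 14400.0
    patches: list[Patch] = field(default_factory=lambda: [Patch(0.0, 0.0, 25.0)])
    step_scale: float = 60.0
    turn_concentration: float = 4.0
    revisit_period: float = SECONDS_PER_DAY
    dwell_time: float | None = None
    seed: int = 0
    individual: str = "animal01"
    start: str = "2013-06-01T00:00:00Z"

    def validate(self) -> None:
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if not self.patches:
            raise ValueError("at least one patch is required")
        for p in self.patches:
            if p.radius <= 0:
                raise ValueError("patch radius must be positive")
        if self.step_scale < 0:
            raise ValueError("step_scale must be >= 0")
        if self.turn_concentration < 0:
            raise ValueError("turn_concentration must be >= 0")
        if self.revisit_period <= 0:
            raise ValueError("revisit_period must be positive")


def _as_patches(patches) -> list[Patch]:
    out = []
    for p in patches:
        if isinstance(p, Patch):
            out.append(p)
        else:
            out.append(Patch(*p))
    return out


@dataclass
class FieldConfig:
    """First and second moments plus correlation length of a spatial field."""

    mean: float
    sd: float
    corr_length: float = 30.0
    floor: float = 0.0


@dataclass
class SceneConfig:
    """Parameters of a synthetic 2 m grassland reflectance scene.

    ``biomass_relation`` / ``n_relation`` give the planted functional form
    mapping the simple ratio index band_i/band_j to the response:
    ``("linear", (b0, b1))`` means response = b0 + b1 * SRI,
    ``("exponential", (b0, b1))`` means response = b0 * exp(b1 * SRI),
    ``("polynomial2", (b0, b1, b2))`` means response = b0 + b1*SRI + b2*SRI^2.
    Grass spectra are built so the relation holds exactly before endmember
    mixing and noise.
    """

    n_rows: int = 60
    n_cols: int = 60
    n_bands: int = 30
    cell_size: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)
    biomass_field: FieldConfig = field(
        default_factory=lambda: FieldConfig(mean=295.0, sd=110.0, corr_length=30.0, floor=25.0)
    )
    n_field: FieldConfig = field(
        default_factory=lambda: FieldConfig(mean=2.1, sd=0.5, corr_length=30.0, floor=0.1)
    )
    biomass_band_pair: tuple[int, int] = (6, 4)
    n_band_pair: tuple[int, int] = (10, 2)
    biomass_relation: tuple[str, tuple[float, ...]] = ("polynomial2", (20.0, 60.0, 8.0))
    n_relation: tuple[str, tuple[float, ...]] = ("polynomial2", (0.05, 0.1, 0.08))
    endmember_spectra: np.ndarray | None = None
    noise_sd: float = 0.0
    grass_variability: float = 0.05
    pure_grass: bool = False
    grass_dominance: float = 1.5
    mixing_sharpness: float = 4.0
    mixing_corr_length: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        for pair in (self.biomass_band_pair, self.n_band_pair):
            i, j = pair
            if not (0 <= i < self.n_bands and 0 <= j < self.n_bands):
                raise ValueError(f"band pair {pair} outside 0..{self.n_bands - 1}")
            if i == j:
                raise ValueError(f"band pair {pair} must use two distinct bands")
        ib, jb = self.biomass_band_pair
        in_, jn = self.n_band_pair
        if ib == in_ or ib == jn or in_ == jb:
            raise ValueError(
                "biomass and nitrogen numerator bands must not collide with "
                "each other or with the other response's denominator"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.endmember_spectra is not None and np.any(self.endmember_spectra < 0):
            raise ValueError("endmember spectra must be non-negative")


@dataclass(frozen=True)
class SpeciesPreference:
    """Cell-use preference of one species on the (BiomRS, N) plane.

    The probability that the species uses a grass cell is proportional to
    ``exp(intercept + b_biom_rs*BiomRS + b_n*N + b_interaction*BiomRS*N)``
    where BiomRS = biomass / 100.
    """

    species: str
    intercept: float = 0.0
    b_biom_rs: float = 0.0
    b_n: float = 0.0
    b_interaction: float = 0.0

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")


# ---------------------------------------------------------------------------
# trajectory simulation


def _build_itinerary(cfg: TrajectoryConfig, patches: list[Patch]):
    """Return per-fix target indices implementing the patch schedule.

    The schedule cycles the targets with dwell times long enough that
    successive visits to any one patch are separated by more than
    ``revisit_period``. For a single-patch config a virtual excursion target
    is added so the patch is genuinely left between visits.
    """
    targets = list(patches)
    if len(targets) == 1:
        p = targets[0]
        off = 6.0 * p.radius + 4.0 * max(cfg.step_scale, 1.0)
        targets.append(Patch(p.x + off, p.y, p.radius, p.weight))
    m = len(targets)
    # dwell long enough that the time away between successive visits to a
    # patch exceeds the revisit period; an explicit dwell_time lengthens
    # bouts (fewer commutes, so revisitation concentrates on the patches)
    base = 1.1 * cfg.revisit_period / (m - 1)
    if cfg.dwell_time is not None:
        base = max(base, cfg.dwell_time)
    wmax = max(t.weight for t in targets)
    dwell = np.array(
        [max(2.0 * cfg.fix_interval, base * t.weight / wmax) for t in targets]
    )
    # guarantee: for every target, time spent away between visits exceeds
    # the revisit period
    away = dwell.sum() - dwell
    factor = max(1.0, 1.05 * cfg.revisit_period / away.min())
    dwell *= factor

    total = cfg.n_days * SECONDS_PER_DAY
    cycle = dwell.sum()
    if total < 2.0 * cycle:
        raise ValueError(
            "record too short to schedule two visits per patch at this "
            "revisit period"
        )
    times = np.arange(0.0, total + 0.5 * cfg.fix_interval, cfg.fix_interval)
    phase = np.mod(times, cycle)
    edges = np.cumsum(dwell)
    target_idx = np.searchsorted(edges, phase, side="right").clip(max=m - 1)
    return times, np.asarray(target_idx), targets


def simulate_trajectory(config: TrajectoryConfig) -> pd.DataFrame:
    """Simulate a patch-revisiting biased correlated random walk.

    Returns a fix table with columns ``id``, ``t`` (UTC timestamps at exact
    multiples of the fix interval), ``x`` and ``y`` (metres). The walk
    alternates biased travel toward the currently scheduled patch with
    within-patch wandering; per-fix displacement never exceeds
    ``step_scale``. ``df.attrs['target_index']`` records the scheduled
    target of every fix and ``df.attrs['targets']`` the target list.
    """
    config.validate()
    patches = _as_patches(config.patches)
    rng = np.random.default_rng(config.seed)
    times, target_idx, targets = _build_itinerary(config, patches)

    n = len(times)
    xy = np.empty((n, 2))
    first = targets[target_idx[0]]
    xy[0] = (first.x, first.y)
    for k in range(1, n):
        tgt = targets[target_idx[k]]
        pos = xy[k - 1]
        d = np.array([tgt.x, tgt.y]) - pos
        dist = math.hypot(d[0], d[1])
        if dist > tgt.radius:
            # travel: biased step toward the patch centre
            ang = math.atan2(d[1], d[0]) + rng.vonmises(0.0, config.turn_concentration)
            step = min(config.step_scale, dist)
            new = pos + step * np.array([math.cos(ang), math.sin(ang)])
        else:
            # wander inside the patch
            raw = rng.normal(0.0, config.step_scale / 3.0, size=2)
            norm = math.hypot(raw[0], raw[1])
            if norm > config.step_scale:
                raw *= config.step_scale / norm
            new = pos + raw
            off = new - np.array([tgt.x, tgt.y])
            r = math.hypot(off[0], off[1])
            if r > tgt.radius:
                new = np.array([tgt.x, tgt.y]) + off * (tgt.radius / r)
        # hard speed bound: displacement per fix never exceeds step_scale
        disp = new - pos
        dn = math.hypot(disp[0], disp[1])
        if dn > config.step_scale and dn > 0:
            new = pos + disp * (config.step_scale / dn)
        xy[k] = new

    t0 = pd.Timestamp(config.start)
    ts = t0 + pd.to_timedelta(times, unit="s")
    df = pd.DataFrame(
        {"id": config.individual, "t": ts, "x": xy[:, 0], "y": xy[:, 1]}
    )
    df.attrs["target_index"] = target_idx
    df.attrs["targets"] = targets
    df.attrs["patches"] = patches
    return df


def inject_gps_errors(
    traj: pd.DataFrame,
    n_spikes: int = 0,
    n_outliers: int = 0,
    seed: int = 0,
    alpha: float = 1.5,
    cos_theta: float = -0.97,
    mu: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject out-and-back spikes and gross outliers into a clean trajectory.

    Spikes displace an interior fix far enough that both its implied
    inbound/outbound speeds exceed ``alpha`` (km/h) and the turn cosine
    falls below ``cos_theta``; outliers displace a fix more than ``mu`` km
    (default beyond 50 km) from the trajectory median. Returns the corrupted
    table and a truth table with boolean columns ``true_spike`` and
    ``true_outlier``.
    """
    n = len(traj)
    if n < 5:
        raise ValueError("trajectory must have at least 5 fixes")
    interior = np.arange(1, n - 1)
    # keep corrupted fixes non-adjacent so each error's neighbours stay clean
    needed = n_spikes + n_outliers
    if needed * 2 - 1 > len(interior):
        raise ValueError("requested errors exceed available interior fixes")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    candidates = list(interior)
    rng.shuffle(candidates)
    for idx in candidates:
        if len(chosen) == needed:
            break
        if all(abs(idx - c) >= 2 for c in chosen):
            chosen.append(idx)
    if len(chosen) < needed:
        raise ValueError("requested errors exceed available interior fixes")
    spike_idx = sorted(chosen[:n_spikes])
    outlier_idx = sorted(chosen[n_spikes:needed])

    out = traj.copy()
    out.attrs = dict(traj.attrs)
    xy = out[["x", "y"]].to_numpy(dtype=float)
    tsec = out["t"].astype("int64").to_numpy() / 1e9
    med = np.median(xy, axis=0)

    alpha_ms = alpha * 1000.0 / 3600.0

    for idx in outlier_idx:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        r = (mu + 10.0 + rng.uniform(0.0, 20.0)) * 1000.0
        xy[idx] = med + r * np.array([math.cos(ang), math.sin(ang)])

    for idx in spike_idx:
        prev, nxt = xy[idx - 1], xy[idx + 1]
        dt_in = tsec[idx] - tsec[idx - 1]
        dt_out = tsec[idx + 1] - tsec[idx]
        u = rng.uniform(0.0, 2.0 * math.pi)
        uvec = np.array([math.cos(u), math.sin(u)])
        D = max(3.0 * alpha_ms * max(dt_in, dt_out), 12000.0)
        for _ in range(30):
            cand = prev + D * uvec
            v_in = np.linalg.norm(cand - prev) / dt_in
            v_out = np.linalg.norm(nxt - cand) / dt_out
            a = cand - prev
            b = nxt - cand
            cth = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
            if v_in > alpha_ms and v_out > alpha_ms and cth < cos_theta:
                break
            D *= 1.5
        else:
            raise RuntimeError("could not construct a threshold-violating spike")
        xy[idx] = cand

    out["x"], out["y"] = xy[:, 0], xy[:, 1]
    flags = pd.DataFrame(
        {
            "true_spike": np.isin(np.arange(n), spike_idx),
            "true_outlier": np.isin(np.arange(n), outlier_idx),
        },
        index=out.index,
    )
    return out, flags


# ---------------------------------------------------------------------------
# scenes


def default_wavelengths(n_bands: int) -> np.ndarray:
    """Band-centre wavelengths (nm) evenly covering 400–2450 nm."""
    return np.linspace(400.0, 2450.0, n_bands)


def default_endmember_library(n_bands: int = 30) -> np.ndarray:
    """Smooth synthetic endmember spectra for grass/forest/rock/snow/water.

    Shapes are caricatures of the real materials (red edge and SWIR water
    absorption for vegetation, bright flat rock, very bright blue-peaked
    snow, dark water) — sufficient for unmixing, not radiative transfer.
    Rows follow :data:`ENDMEMBER_LABELS`.
    """
    wl = default_wavelengths(n_bands)

    def sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    swir = 1.0 - 0.55 * np.exp(-0.5 * ((wl - 1450.0) / 120.0) ** 2) \
        - 0.45 * np.exp(-0.5 * ((wl - 1940.0) / 120.0) ** 2)
    grass = (0.04 + 0.46 * sigmoid((wl - 715.0) / 25.0) * np.exp(-((wl - 900.0) / 1400.0) ** 2)) * swir
    forest = (0.025 + 0.28 * sigmoid((wl - 735.0) / 20.0) * np.exp(-((wl - 900.0) / 1200.0) ** 2)) * swir
    rock = 0.12 + 0.00012 * (wl - 400.0)
    snow = 0.95 * np.exp(-((wl - 450.0) / 1100.0) ** 2)
    water = 0.07 * np.exp(-(wl - 400.0) / 450.0)
    lib = np.vstack([grass, forest, rock, snow, water])
    return np.clip(lib, 0.0, None)


def _gaussian_field(rng, shape, cfg: FieldConfig, cell_size: float) -> np.ndarray:
    """Smoothed white noise affinely mapped to the configured mean/sd."""
    z = rng.standard_normal(shape)
    sigma = max(cfg.corr_length / cell_size, 1e-6)
    f = gaussian_filter(z, sigma=sigma, mode="reflect")
    f = (f - f.mean()) / max(f.std(), 1e-12)
    return np.maximum(f * cfg.sd + cfg.mean, cfg.floor)


def _invert_relation(form: str, coefs: tuple[float, ...], y: np.ndarray) -> np.ndarray:
    """Solve the planted relation y = f(SRI) for SRI."""
    if form == "linear":
        b0, b1 = coefs
        if b1 == 0:
            raise ValueError(f"linear relation with b1=0 not invertible: {coefs}")
        return (y - b0) / b1
    if form == "exponential":
        b0, b1 = coefs
        if b0 <= 0 or b1 == 0:
            raise ValueError(f"exponential relation not invertible: {coefs}")
        return np.log(y / b0) / b1
    if form == "polynomial2":
        b0, b1, b2 = coefs
        if b2 == 0:
            raise ValueError(f"polynomial2 relation with b2=0: {coefs}")
        disc = b1 * b1 - 4.0 * b2 * (b0 - y)
        if np.any(disc < 0):
            raise ValueError(f"polynomial2 relation has no real inverse for coefficients {coefs}")
        return (-b1 + np.sqrt(disc)) / (2.0 * b2)
    raise ValueError(f"unknown relation form {form!r}")


@dataclass
class Scene:
    """A synthetic reflectance scene with full ground truth.

    ``cube`` has shape (n_bands, n_rows, n_cols); ``fractions`` has shape
    (n_endmembers, n_rows, n_cols) and lies on the unit simplex per cell.
    """

    cube: np.ndarray
    wavelengths: np.ndarray
    fractions: np.ndarray
    endmember_labels: tuple[str, ...]
    endmember_spectra: np.ndarray
    biomass: np.ndarray
    nitrogen: np.ndarray
    config: SceneConfig

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    @property
    def origin(self) -> tuple[float, float]:
        return self.config.origin

    @property
    def grass_fraction(self) -> np.ndarray:
        return self.fractions[self.endmember_labels.index("grass")]

    @property
    def true_grass_mask(self) -> np.ndarray:
        return self.grass_fraction >= 0.5

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centres, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.config.n_cols) + 0.5) * self.cell_size
        rows = y0 + (np.arange(self.config.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cols, rows)
        return xx, yy


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a reflectance cube with planted band-ratio relations.

    Grass spectra are per-cell copies of the grass endmember whose numerator
    bands are overwritten so that band_i/band_j equals the inverse of the
    planted biomass (and nitrogen) relation; the cube is then a linear
    mixture with the other endmembers plus Gaussian noise, floored at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)

    biomass = _gaussian_field(rng, shape, config.biomass_field, config.cell_size)
    nitrogen = _gaussian_field(rng, shape, config.n_field, config.cell_size)

    library = (
        config.endmember_spectra
        if config.endmember_spectra is not None
        else default_endmember_library(config.n_bands)
    )
    library = np.asarray(library, dtype=float)
    if library.shape != (len(ENDMEMBER_LABELS), config.n_bands):
        raise ValueError(
            f"endmember spectra must have shape {(len(ENDMEMBER_LABELS), config.n_bands)}"
        )

    grass = library[0]
    ib, jb = config.biomass_band_pair
    in_, jn = config.n_band_pair
    sri_b = _invert_relation(*config.biomass_relation, y=biomass)
    sri_n = _invert_relation(*config.n_relation, y=nitrogen)
    for name, sri, rel in (("biomass", sri_b, config.biomass_relation),
                           ("nitrogen", sri_n, config.n_relation)):
        if np.any(sri <= 0):
            raise ValueError(
                f"{name} relation {rel[0]} with coefficients {rel[1]} produces "
                "non-positive reflectance in the numerator band"
            )

    # per-cell grass spectrum: smooth per-band variability (so no band pair
    # other than the planted ones is exactly collinear with a response),
    # then the planted ratios overwrite the numerator bands
    grass_cells = np.broadcast_to(
        grass[:, None, None], (config.n_bands,) + shape
    ).copy()
    if config.grass_variability > 0:
        sigma = max(config.mixing_corr_length / config.cell_size, 1e-6)
        for b in range(config.n_bands):
            eta = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
            eta = eta / max(eta.std(), 1e-12) * config.grass_variability
            grass_cells[b] *= np.clip(1.0 + eta, 0.05, None)
    grass_cells[ib] = sri_b * grass_cells[jb]
    grass_cells[in_] = sri_n * grass_cells[jn]

    # endmember fractions
    n_end = len(ENDMEMBER_LABELS)
    if config.pure_grass:
        fractions = np.zeros((n_end,) + shape)
        fractions[0] = 1.0
    else:
        sigma = max(config.mixing_corr_length / config.cell_size, 1e-6)
        pot = np.empty((n_end,) + shape)
        for e in range(n_end):
            f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
            pot[e] = f / max(f.std(), 1e-12)
        pot[0] += config.grass_dominance
        z = config.mixing_sharpness * pot
        z -= z.max(axis=0, keepdims=True)
        w = np.exp(z)
        fractions = w / w.sum(axis=0, keepdims=True)

    # mixture: grass uses the per-cell spectrum, others the library rows
    cube = fractions[0][None, :, :] * grass_cells
    for e in range(1, n_end):
        cube = cube + fractions[e][None, :, :] * library[e][:, None, None]

    if config.noise_sd > 0:
        cube = cube + rng.normal(0.0, config.noise_sd, size=cube.shape)
    cube = np.maximum(cube, 0.0)

    return Scene(
        cube=cube,
        wavelengths=default_wavelengths(config.n_bands),
        fractions=fractions,
        endmember_labels=ENDMEMBER_LABELS,
        endmember_spectra=library,
        biomass=biomass,
        nitrogen=nitrogen,
        config=config,
    )


def band_columns(n_bands: int) -> list[str]:
    return [f"band_{b:03d}" for b in range(n_bands)]


def sample_plots(scene: Scene, n_plots: int, seed: int = 0) -> pd.DataFrame:
    """Sample ground-truth plots with 3x3-cell aggregated spectra.

    Plot centres fall on grass-dominated cells with a full 3x3 neighbourhood
    inside the scene. Each record carries the plot centre coordinates, the
    per-band mean spectrum over the 3x3 window and the window-averaged true
    biomass (g m^-2) and nitrogen (%).
    """
    rng = np.random.default_rng(seed)
    mask = scene.true_grass_mask.copy()
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    rows, cols = np.nonzero(mask)
    if len(rows) < n_plots:
        raise ValueError(
            f"scene supports only {len(rows)} plot locations, {n_plots} requested"
        )
    pick = rng.choice(len(rows), size=n_plots, replace=False)
    pick.sort()
    xx, yy = scene.cell_centres()
    records = []
    nb = scene.config.n_bands
    for pid, p in enumerate(pick):
        r, c = int(rows[p]), int(cols[p])
        win = np.s_[r - 1:r + 2, c - 1:c + 2]
        spectrum = scene.cube[(np.s_[:],) + win].reshape(nb, -1).mean(axis=1)
        rec = {
            "plot_id": f"plot{pid:03d}",
            "row": r,
            "col": c,
            "x": xx[r, c],
            "y": yy[r, c],
            "biomass": float(scene.biomass[win].mean()),
            "nitrogen": float(scene.nitrogen[win].mean()),
        }
        rec.update(zip(band_columns(nb), spectrum))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def simulate_species_usage(
    scene: Scene,
    prefs: list[SpeciesPreference],
    n_cells_per_species: int,
    seed: int = 0,
):
    """Sample species' cell use following planted logit preferences.

    Grass cells are sampled (without replacement, per species) with
    probability proportional to exp(preference logit) evaluated at the cell's
    true (BiomRS, N). Returns the labelled observation table and a dict of
    convex-hull footprint polygons per species.
    """
    if len(prefs) != 3 or {p.species for p in prefs} != set(SPECIES):
        raise ValueError("exactly one preference per species is required")
    if n_cells_per_species <= 0:
        raise ValueError("a species would receive zero cells")
    rng = np.random.default_rng(seed)
    mask = scene.true_grass_mask
    rows, cols = np.nonzero(mask)
    if len(rows) < n_cells_per_species:
        raise ValueError("not enough grass cells for the requested usage sample")
    xx, yy = scene.cell_centres()
    biom = scene.biomass[rows, cols]
    nitro = scene.nitrogen[rows, cols]
    biom_rs = biom / 100.0

    frames = []
    polygons = {}
    for pref in sorted(prefs, key=lambda p: SPECIES.index(p.species)):
        logit = (
            pref.intercept
            + pref.b_biom_rs * biom_rs
            + pref.b_n * nitro
            + pref.b_interaction * biom_rs * nitro
        )
        logit = logit - logit.max()
        w = np.exp(np.maximum(logit, -700.0))
        p = w / w.sum()
        idx = rng.choice(len(rows), size=n_cells_per_species, replace=False, p=p)
        idx.sort()
        frames.append(
            pd.DataFrame(
                {
                    "species": pref.species,
                    "individual": f"{pref.species}_01",
                    "row": rows[idx],
                    "col": cols[idx],
                    "x": xx[rows[idx], cols[idx]],
                    "y": yy[rows[idx], cols[idx]],
                    "biomass": biom[idx],
                    "biom_rs": biom_rs[idx],
                    "nitrogen": nitro[idx],
                }
            )
        )
        pts = MultiPoint(list(zip(xx[rows[idx], cols[idx]], yy[rows[idx], cols[idx]])))
        polygons[pref.species] = pts.convex_hull
    table = pd.concat(frames, ignore_index=True)
    return table, polygons
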