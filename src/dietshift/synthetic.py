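"""Synthetic dietary-DNA and GPS data with controllable seasonal structure.

The generator emulates a five-species large-herbivore community sampled at
the herd level in two focal seasons. Each species-season has a mean diet
profile over a global plant-taxon pool; herd samples are compound
multinomial draws (Dirichlet herd profile around the mean, then a
multinomial of ``read_depth`` reads), so every generated sample sums to the
rarefaction depth exactly.

Three effect axes are configurable, all linear in log10 body mass (grams):

* **turnover** — the expected summer-winter Bray-Curtis dissimilarity of a
  species follows ``turnover_intercept + turnover_slope * (log10 m - ref)``.
  Cross-season overlap is calibrated at the *count* level: a normal
  approximation of E|x - y| for Dirichlet-multinomial counts is inverted so
  sampling noise does not bias the realized dissimilarity.
* **richness** — expected per-sample taxon richness follows
  ``richness_intercept + richness_slope * (log10 m - ref)`` plus/minus half
  of ``season_richness_delta`` in summer/winter; taxon counts are inflated
  for the expected probability of non-detection at the read depth.
* **uniqueness** — in winter the fraction of a species' seasonal diet drawn
  from a community-wide "commons" pool declines with mass
  (``winter_commons_base - winter_commons_slope * (log10 m - ref)``), so
  larger species hold more exclusive winter diets; in summer all species
  share the same commons fraction. This produces the size x season
  interaction in Bluethgen d'.

Setting every slope and delta to zero (``null_config``) removes all size
and season effects while keeping realistic noise, which is how downstream
type-I error rates are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import gammaln

from .diet_table import DietTable, FunctionalAnnotation, FUNCTIONAL_GROUPS
from .rasters import Raster

#: Adult female body masses (kg) of the five focal ungulates.
DEFAULT_MASSES_KG = {
    "pronghorn": 48.0,
    "bighorn_sheep": 75.0,
    "mule_deer": 85.0,
    "elk": 241.0,
    "bison": 625.0,
}

#: Herd samples per (species, season): seasonal totals of 93 (summer) and
#: 90 (winter) with a minimum cell of 4, mirroring a two-year field design.
DEFAULT_SAMPLES_PER_CELL = {
    ("pronghorn", "summer"): 15,
    ("bighorn_sheep", "summer"): 8,
    ("mule_deer", "summer"): 15,
    ("elk", "summer"): 25,
    ("bison", "summer"): 30,
    ("pronghorn", "winter"): 19,
    ("bighorn_sheep", "winter"): 4,
    ("mule_deer", "winter"): 12,
    ("elk", "winter"): 30,
    ("bison", "winter"): 25,
}


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the synthetic diet community."""

    species_masses: dict = field(default_factory=lambda: dict(DEFAULT_MASSES_KG))
    n_taxa: int = 450
    taxa_pool_by_season: dict | None = None
    turnover_slope: float = -0.07
    turnover_intercept: float = 0.90
    richness_slope: float = 15.0
    richness_intercept: float = 35.0
    season_richness_delta: float = 14.0
    winter_commons_base: float = 0.75
    winter_commons_slope: float = 0.45
    summer_commons_frac: float = 0.75
    reference_log10_mass_g: float = 5.0
    samples_per_cell: dict = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_CELL)
    )
    read_depth: int = 1453
    concentration: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if any(m <= 0 for m in self.species_masses.values()):
            raise ValueError("all body masses must be positive")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        seasons = self.seasons
        for sp in self.species_masses:
            for se in seasons:
                if (sp, se) not in self.samples_per_cell:
                    raise ValueError(
                        f"samples_per_cell missing cell ({sp!r}, {se!r})"
                    )

    @property
    def seasons(self) -> tuple:
        return tuple(sorted({se for _, se in self.samples_per_cell}))


def null_config(**overrides) -> CommunityConfig:
    """Configuration with no size or season effects (for type-I checks)."""
    base = dict(
        turnover_slope=0.0,
        richness_slope=0.0,
        season_richness_delta=0.0,
        winter_commons_slope=0.0,
    )
    base.update(overrides)
    return CommunityConfig(**base)


# -- detection / dissimilarity calibration ----------------------------------


def _p_zero(p: float, n: int, alpha0: float) -> float:
    """P(count = 0) for a Dirichlet-multinomial marginal with mean share p."""
    if p <= 0:
        return 1.0
    if p >= 1:
        return 0.0
    if not np.isfinite(alpha0):
        return float((1.0 - p) ** n)
    a = alpha0 * p
    return float(
        np.exp(
            gammaln(alpha0)
            + gammaln(alpha0 - a + n)
            - gammaln(alpha0 - a)
            - gammaln(alpha0 + n)
        )
    )


#: Rank-abundance decay within a profile segment: weight of the r-th taxon
#: is (r+1)^-RANK_DECAY, a gentle skew so rare taxa exist (incidence
#: heterogeneity, Q1 > 0) without starving detection at the read depth.
RANK_DECAY = 0.6


def _segment_weights(k: int, decay: float = RANK_DECAY) -> np.ndarray:
    w = (np.arange(1, k + 1)) ** (-decay)
    return w / w.sum()


def _detect_adjusted_k(
    k_target: int, mass: float, n: int, alpha0: float, decay: float = RANK_DECAY
) -> tuple[int, np.ndarray]:
    """Taxon count and within-segment weights whose expected number of
    *detected* taxa at depth ``n`` is ~``k_target``."""
    if k_target <= 0:
        return 0, np.array([])
    best = (k_target, _segment_weights(k_target, decay))
    best_err = np.inf
    for k in range(k_target, 3 * k_target + 1):
        w = _segment_weights(k, decay)
        expected = sum(1.0 - _p_zero(mass * wi, n, alpha0) for wi in w)
        err = abs(expected - k_target)
        if err < best_err:
            best, best_err = (k, w), err
    return best


def _expected_pair_bc(sigma: float, k_sh: int, n: int, alpha0: float) -> float:
    """Expected Bray-Curtis between one summer and one winter sample when a
    profile mass ``sigma`` is shared over ``k_sh`` cross-season taxa."""
    if k_sh == 0:
        return 1.0
    p = sigma / k_sh
    rho = 0.0 if not np.isfinite(alpha0) else 1.0 / (1.0 + alpha0)
    var = n * p * (1 - p) * (1 + (n - 1) * rho)
    e_abs = min(np.sqrt(2 * var) * np.sqrt(2 / np.pi), 2 * n * p)
    return (1.0 - sigma) + k_sh * e_abs / (2.0 * n)


def _solve_shared_mass(tau: float, k_sh: int, n: int, alpha0: float) -> float:
    """Shared profile mass giving expected count-level dissimilarity tau."""
    lo, hi = 1e-9, 1.0 - 1e-9
    f = lambda s: _expected_pair_bc(s, k_sh, n, alpha0) - tau
    if f(hi) >= 0:  # even full sharing stays noisier than tau
        return hi
    if f(lo) <= 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-10)


# -- diet-table generation ---------------------------------------------------

_SUMMER_COMMONS = 120
_WINTER_COMMONS = 40


def _zipf_weights(k: int) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1)
    return w / w.sum()


def _weighted_subset(rng, pool, k, weights):
    k = min(k, len(pool))
    if k <= 0:
        return np.array([], dtype=int)
    return rng.choice(pool, size=k, replace=False, p=weights)


def species_profiles(config: CommunityConfig) -> dict:
    """Mean diet profile per (species, season) as arrays over the taxon pool.

    Deterministic given ``config.seed``. Returned dict maps
    (species, season) -> length-``n_taxa`` probability vector.
    """
    rng = np.random.default_rng(config.seed)
    n, depth, a0 = config.n_taxa, config.read_depth, config.concentration
    idx = np.arange(n)
    summer_commons = idx[:_SUMMER_COMMONS]
    winter_commons = idx[_SUMMER_COMMONS:_SUMMER_COMMONS + _WINTER_COMMONS]
    private_pool = list(idx[_SUMMER_COMMONS + _WINTER_COMMONS:])

    pools = config.taxa_pool_by_season or {}
    w_su = pools.get("summer")
    w_su = (
        np.asarray(w_su, dtype=float)[summer_commons]
        if w_su is not None
        else _zipf_weights(_SUMMER_COMMONS)
    )
    w_su = w_su / w_su.sum()
    w_wi = pools.get("winter")
    w_wi = (
        np.asarray(w_wi, dtype=float)[winter_commons]
        if w_wi is not None
        else _zipf_weights(_WINTER_COMMONS)
    )
    w_wi = w_wi / w_wi.sum()

    profiles = {}
    for sp in sorted(config.species_masses):
        mass_kg = config.species_masses[sp]
        dL = np.log10(mass_kg * 1000.0) - config.reference_log10_mass_g
        tau = float(
            np.clip(config.turnover_intercept + config.turnover_slope * dL, 0.02, 0.98)
        )
        base_R = config.richness_intercept + config.richness_slope * dL
        R_su = max(4, round(base_R + config.season_richness_delta / 2.0))
        R_wi = max(4, round(base_R - config.season_richness_delta / 2.0))
        g_wi = float(
            np.clip(
                config.winter_commons_base - config.winter_commons_slope * dL,
                0.05,
                0.95,
            )
        )
        g_su = float(np.clip(config.summer_commons_frac, 0.05, 0.95))

        k_sh = max(2, round((1.0 - tau) * min(R_su, R_wi)))
        sigma = _solve_shared_mass(tau, k_sh, depth, a0)

        def take_private(k):
            k = min(k, len(private_pool))
            chosen = private_pool[:k]
            del private_pool[:k]
            return np.array(chosen, dtype=int)

        # shared (cross-season) segment stays even: the turnover calibration
        # models its per-taxon sampling noise under equal shares
        k_sh_adj, _ = _detect_adjusted_k(k_sh, sigma, depth, a0, decay=0.0)
        shared_taxa = take_private(k_sh_adj)
        seg = {}
        for se, R, g, commons, w in (
            ("summer", R_su, g_su, summer_commons, w_su),
            ("winter", R_wi, g_wi, winter_commons, w_wi),
        ):
            excl_R = max(2, R - k_sh)
            k_comm = round(excl_R * g)
            k_priv = excl_R - k_comm
            m_excl = 1.0 - sigma
            kc, wc = _detect_adjusted_k(k_comm, m_excl * g, depth, a0)
            comm_taxa = _weighted_subset(rng, commons, kc, w)
            kp, wp = _detect_adjusted_k(k_priv, m_excl * (1 - g), depth, a0)
            priv_taxa = take_private(kp)
            prof = np.zeros(n)
            if len(shared_taxa):
                prof[shared_taxa] = sigma / len(shared_taxa)
            m_comm = m_excl * g if len(comm_taxa) else 0.0
            m_priv = m_excl - m_comm
            if len(comm_taxa):
                prof[comm_taxa] += m_comm * wc[: len(comm_taxa)] / wc[: len(comm_taxa)].sum()
            if len(priv_taxa):
                prof[priv_taxa] += m_priv * wp[: len(priv_taxa)] / wp[: len(priv_taxa)].sum()
            prof = prof / prof.sum()
            seg[se] = prof
        profiles[(sp, "summer")] = seg["summer"]
        profiles[(sp, "winter")] = seg["winter"]
        for se in config.seasons:
            if se in ("spring", "autumn"):
                mix = 0.5 * seg["summer"] + 0.5 * seg["winter"]
                profiles[(sp, se)] = mix / mix.sum()
    return profiles


_SEASON_DATES = {
    "winter": "2017-01-15",
    "spring": "2017-04-15",
    "summer": "2017-07-15",
    "autumn": "2017-10-15",
}


def generate_diet_table(config: CommunityConfig) -> tuple[DietTable, FunctionalAnnotation]:
    """Generate a herd-level diet table and its functional annotation.

    Every sample's counts sum to ``config.read_depth`` exactly. Reruns with
    the same config (including seed) are identical.
    """
    profiles = species_profiles(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, depth, a0 = config.n_taxa, config.read_depth, config.concentration
    taxon_ids = [f"taxon_{i + 1:04d}" for i in range(n)]

    rows, meta_rows, ids = [], [], []
    for sp in sorted(config.species_masses):
        for se in config.seasons:
            k = config.samples_per_cell[(sp, se)]
            prof = profiles[(sp, se)]
            support = prof > 0
            for i in range(k):
                if np.isfinite(a0):
                    herd = np.zeros(n)
                    herd[support] = rng.dirichlet(a0 * prof[support])
                else:
                    herd = prof
                counts = rng.multinomial(depth, herd)
                sid = f"{sp}_{se}_{i + 1:03d}"
                ids.append(sid)
                rows.append(counts)
                meta_rows.append(
                    {
                        "species": sp,
                        "season": se,
                        "herd": f"{sp}_h{i + 1:03d}",
                        "date": pd.Timestamp(_SEASON_DATES[se])
                        + pd.Timedelta(days=int(rng.integers(-30, 31))),
                        "animal_id": sid,
                    }
                )
    counts = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="sample_id"),
                          columns=taxon_ids)
    # keep taxa that belong to some species-season pool
    used = np.zeros(n, dtype=bool)
    for prof in profiles.values():
        used |= prof > 0
    counts = counts.loc[:, np.asarray(used)]
    meta = pd.DataFrame(meta_rows, index=counts.index)
    annot = _annotate(config, counts.columns, rng)
    return DietTable(counts, meta), annot


_GROUP_PROBS = {
    "summer_commons": [0.02, 0.03, 0.55, 0.12, 0.05, 0.08, 0.02, 0.13],
    "winter_commons": [0.20, 0.08, 0.08, 0.28, 0.12, 0.14, 0.02, 0.08],
    "private": [0.06, 0.06, 0.30, 0.10, 0.07, 0.17, 0.04, 0.20],
}


def _annotate(config, taxon_ids, rng) -> FunctionalAnnotation:
    mapping = {}
    for t in taxon_ids:
        i = int(t.split("_")[1]) - 1
        if i < _SUMMER_COMMONS:
            probs = _GROUP_PROBS["summer_commons"]
        elif i < _SUMMER_COMMONS + _WINTER_COMMONS:
            probs = _GROUP_PROBS["winter_commons"]
        else:
            probs = _GROUP_PROBS["private"]
        mapping[t] = str(rng.choice(FUNCTIONAL_GROUPS, p=probs))
    return FunctionalAnnotation(mapping)


# -- movement ---------------------------------------------------------------


@dataclass(frozen=True)
class MovementConfig:
    """Parameters of the synthetic GPS tracks and rasters."""

    fix_interval_h: float = 2.0
    window_h: float = 72.0
    step_scale_by_species_season: dict | None = None
    raster_extent: int = 400
    cell_size: float = 30.0
    n_cover_classes: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        ratio = self.window_h / self.fix_interval_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fix_interval_h must divide window_h")

    @property
    def n_fixes(self) -> int:
        return int(round(self.window_h / self.fix_interval_h)) + 1


@dataclass
class MovementData:
    fixes: pd.DataFrame            # animal_id, timestamp, x, y
    elevation: Raster
    cover: Raster
    sample_times: pd.Series        # animal_id -> sampling timestamp


def _default_step_scale(species: str, season: str) -> float:
    mass = DEFAULT_MASSES_KG.get(species, 100.0)
    base = 60.0 * (mass / 100.0) ** 0.25
    return base * (1.3 if season == "summer" else 1.0)


def generate_rasters(config: MovementConfig, rng) -> tuple[Raster, Raster]:
    """Smoothed random elevation field and quantile-binned cover classes."""
    n = config.raster_extent
    field1 = gaussian_filter(rng.normal(size=(n, n)), sigma=8, mode="wrap")
    field2 = gaussian_filter(rng.normal(size=(n, n)), sigma=18, mode="wrap")
    f1 = (field1 - field1.mean()) / field1.std()
    elevation = 1900.0 + 350.0 * f1 + 0.8 * np.linspace(0, n, n)[None, :] * config.cell_size / 30.0
    edges = np.quantile(field2, np.linspace(0, 1, config.n_cover_classes + 1)[1:-1])
    cover = np.digitize(field2, edges) + 1
    ext = config.cell_size
    return (
        Raster(elevation, 0.0, 0.0, ext),
        Raster(cover.astype(float), 0.0, 0.0, ext),
    )


def generate_movement(config: MovementConfig, animals) -> MovementData:
    """Correlated-random-walk GPS tracks for the given animals.

    ``animals`` is a DataFrame (or list of dicts) with columns
    ``animal_id``, ``species``, ``season`` and optionally ``sample_time``.
    Each animal receives fixes spanning exactly ``window_h`` hours at
    ``fix_interval_h`` spacing (inclusive endpoints), ending at its
    sampling time. Raises if a track would leave the raster extent.
    """
    animals = pd.DataFrame(animals)
    rng = np.random.default_rng(config.seed)
    elevation, cover = generate_rasters(config, rng)
    xmin, ymin, xmax, ymax = elevation.bounds
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0

    steps = config.step_scale_by_species_season or {}
    rows = []
    sample_times = {}
    for _, a in animals.iterrows():
        sid = a["animal_id"]
        scale = steps.get(
            (a["species"], a["season"]), _default_step_scale(a["species"], a["season"])
        )
        t_end = pd.to_datetime(
            a.get("sample_time", _SEASON_DATES.get(a["season"], "2017-07-15"))
        )
        times = pd.date_range(
            t_end - pd.Timedelta(hours=config.window_h),
            t_end,
            periods=config.n_fixes,
        )
        x = cx + rng.uniform(-500, 500)
        y = cy + rng.uniform(-500, 500)
        heading = rng.uniform(0, 2 * np.pi)
        xs, ys = [x], [y]
        for _ in range(config.n_fixes - 1):
            heading += rng.normal(0, 0.7)
            step = scale * rng.gamma(2.0, 0.5) if scale > 0 else 0.0
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            xs.append(x)
            ys.append(y)
        xs, ys = np.array(xs), np.array(ys)
        margin = 450.0
        if (
            xs.min() < xmin + margin
            or xs.max() > xmax - margin
            or ys.min() < ymin + margin
            or ys.max() > ymax - margin
        ):
            raise ValueError(
                f"track {sid} leaves the raster extent; enlarge raster_extent"
            )
        sample_times[sid] = t_end
        for t, xi, yi in zip(times, xs, ys):
            rows.append({"animal_id": sid, "timestamp": t, "x": xi, "y": yi})
    fixes = pd.DataFrame(rows)
    return MovementData(
        fixes=fixes,
        elevation=elevation,
        cover=cover,
        sample_times=pd.Series(sample_times, name="sample_time"),
    )


def scaled_config(**overrides) -> CommunityConfig:
    """A smaller community (fewer samples/taxa) for quick experiments."""
    small_cells = {
        (sp, se): max(4, k // 3) for (sp, se), k in DEFAULT_SAMPLES_PER_CELL.items()
    }
    base = dict(samples_per_cell=small_cells, n_taxa=300)
    base.update(overrides)
    return CommunityConfig(**base)
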