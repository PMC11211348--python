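"""Forward simulation of fossil records with known truth.

Lineages evolve under a birth-death process with constant, piecewise-constant
or covariate-driven rates (and optional trait-specific extinction
multipliers); each lineage leaves fossil occurrences under a (time-varying)
Poisson preservation process; occurrences are binned into geological stages,
attached to shared localities and scattered around regional centres on the
sphere.  Every generated table passes occurrence validation, and the full
generating truth (rates, effects, true origination/extinction times) is
serialised alongside so downstream inference can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occurrences import OCCURRENCE_COLUMNS, validate_occurrences

#: GTS2020 stage boundaries (Ma) of the Albian-Maastrichtian study window.
DEFAULT_STAGE_BOUNDS = [113.2, 100.5, 93.9, 89.8, 86.3, 83.6, 72.1, 66.0]
DEFAULT_STAGE_NAMES = [
    "Albian", "Cenomanian", "Turonian", "Coniacian",
    "Santonian", "Campanian", "Maastrichtian",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot satisfy its acceptance conditions."""


def _as_segments(rate, window):
    """Normalise a rate spec to piecewise-constant segments over the window.

    ``rate`` may be a positive scalar, a ``(boundaries desc, values)`` pair of
    piecewise-constant frames, or an ``(ages, values)`` grid (ages descending;
    treated as constant per grid cell).  Returns (edges descending, values).
    """
    start, end = window
    if np.isscalar(rate):
        return np.array([start, end], float), np.array([float(rate)])
    bounds, values = rate
    bounds = np.asarray(bounds, float)
    values = np.asarray(values, float)
    if len(bounds) == len(values):  # grid form: cell edges from consecutive ages
        edges = np.concatenate([[start], 0.5 * (bounds[1:] + bounds[:-1]), [end]])
        return edges, values
    if len(bounds) != len(values) + 1:
        raise ValueError("rate boundaries must bracket the rate values")
    return bounds, values


def _rate_at(edges_desc, values, age):
    idx = np.clip(np.searchsorted(-edges_desc, -age, side="right") - 1, 0, len(values) - 1)
    return values[idx]


@dataclass
class SimulationTruth:
    """Everything needed to reproduce and score a simulated record."""

    seed: int
    window: tuple
    lam: object
    mu: object
    q: object
    times: pd.DataFrame  # lineage, ts, te, survived
    dropped_lineages: list = field(default_factory=list)
    driver_effects: dict = field(default_factory=dict)
    trait_multipliers: dict = field(default_factory=dict)
    drivers: dict = field(default_factory=dict)  # name -> {"ages": [...], "values": [...]}
    occurrence_true_ages: dict = field(default_factory=dict)
    region_centres: list = field(default_factory=list)
    dispersion_km: float = 0.0

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return {"__frame__": o.to_dict(orient="list")}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(self.__dict__, default=default, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        raw = json.loads(text)
        raw["times"] = pd.DataFrame(raw["times"]["__frame__"])
        raw["window"] = tuple(raw["window"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# birth-death lineages
# ---------------------------------------------------------------------------

def simulate_lineages(
    lam,
    mu,
    window,
    n_initial: int = 1,
    seed: int = 0,
    accept_range=None,
    max_attempts: int = 1000,
    max_lineages: int = 100_000,
) -> pd.DataFrame:
    """Forward birth-death simulation over an age window (old -> young).

    Starts ``n_initial`` lineages at the window start and runs an exact
    event-driven simulation with piecewise-constant rates.  Lineages alive at
    the window end get ``te`` equal to the end age and ``survived=True``.
    When ``accept_range=(lo, hi)`` is given, whole simulations are rejected
    until the total lineage count falls in the range.

    Returns a frame with columns ``lineage``, ``ts``, ``te``, ``survived``.
    """
    start, end = float(window[0]), float(window[1])
    if start <= end:
        raise ValueError("window must run from older to younger age")
    lam_e, lam_v = _as_segments(lam, window)
    mu_e, mu_v = _as_segments(mu, window)
    if np.any(lam_v < 0) or np.any(mu_v < 0):
        raise ValueError("rates must be non-negative")
    # merged piecewise-constant segments
    edges = np.unique(np.concatenate([lam_e, mu_e, [start, end]]))[::-1]
    edges = edges[(edges <= start) & (edges >= end)]

    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        ts = list(np.full(n_initial, start))
        te = [None] * n_initial
        alive = list(range(n_initial))
        overflow = False
        for seg_hi, seg_lo in zip(edges[:-1], edges[1:]):
            lam_s = float(_rate_at(lam_e, lam_v, 0.5 * (seg_hi + seg_lo)))
            mu_s = float(_rate_at(mu_e, mu_v, 0.5 * (seg_hi + seg_lo)))
            age = seg_hi
            total = lam_s + mu_s
            while alive and total > 0:
                wait = rng.exponential(1.0 / (len(alive) * total))
                if age - wait <= seg_lo:
                    break
                age -= wait
                if rng.random() < lam_s / total:
                    ts.append(age)
                    te.append(None)
                    alive.append(len(ts) - 1)
                    if len(ts) > max_lineages:
                        overflow = True
                        break
                else:
                    k = alive.pop(rng.integers(len(alive)))
                    te[k] = age
            if overflow or not alive:
                break
        if overflow:
            continue
        survived = np.zeros(len(ts), bool)
        for k in alive:
            te[k] = end
            survived[k] = True
        out = pd.DataFrame(
            {
                "lineage": [f"g{i:05d}" for i in range(len(ts))],
                "ts": np.asarray(ts, float),
                "te": np.asarray(te, float),
                "survived": survived,
            }
        )
        if accept_range is None or accept_range[0] <= len(out) <= accept_range[1]:
            return out
    raise SimulationError(
        f"no simulation satisfied accept_range={accept_range} in {max_attempts} "
        f"attempts (last count {len(out)})"
    )


# ---------------------------------------------------------------------------
# preservation and spatial structure
# ---------------------------------------------------------------------------

def simulate_preservation(
    times: pd.DataFrame,
    q,
    stage_bounds=DEFAULT_STAGE_BOUNDS,
    stage_names=None,
    localities_per_stage: int = 12,
    substages_per_stage: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, list]:
    """Sample fossil occurrences along each lineage under a Poisson process.

    Each lineage leaves occurrences at ages drawn from a (piecewise-constant)
    Poisson process with rate ``q`` on ``[te, ts]``; unsampled lineages are
    dropped and reported.  Each occurrence is dated to its enclosing substage
    (stages split evenly into ``substages_per_stage`` dating intervals,
    emulating the mostly substage-level resolution of well-studied records;
    ``max_ma``/``min_ma`` are the substage bounds) and attached to a locality
    drawn from the substage's locality pool, so localities share a dating
    interval.

    Returns ``(occurrence table, occurrence_id -> true age, dropped lineages)``.
    """
    stage_bounds = np.asarray(stage_bounds, float)
    if len(stage_bounds) < 2:
        raise ValueError("need at least two stage boundaries")
    if substages_per_stage < 1:
        raise ValueError("substages_per_stage must be >= 1")
    if stage_names is None:
        stage_names = (
            DEFAULT_STAGE_NAMES
            if len(stage_bounds) == len(DEFAULT_STAGE_BOUNDS)
            else [f"S{i}" for i in range(len(stage_bounds) - 1)]
        )
    # substage dating grid nested within the stages
    sub_bounds, sub_stage = [], []
    for s in range(len(stage_bounds) - 1):
        cuts = np.linspace(stage_bounds[s], stage_bounds[s + 1],
                           substages_per_stage + 1)
        for j in range(substages_per_stage):
            sub_bounds.append((float(cuts[j]), float(cuts[j + 1])))
            sub_stage.append(s)
    sub_tops = np.array([b[0] for b in sub_bounds])

    window = (float(stage_bounds[0]), float(stage_bounds[-1]))
    q_e, q_v = _as_segments(q, (max(window[0], times["ts"].max()), 0.0))
    if np.any(q_v <= 0):
        raise ValueError("preservation rate must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    true_ages = {}
    dropped = []
    occ_counter = 0
    for lineage, ts, te in times[["lineage", "ts", "te"]].itertuples(index=False):
        ages = []
        for seg_hi, seg_lo in zip(q_e[:-1], q_e[1:]):
            a, b = min(ts, seg_hi), max(te, seg_lo)
            if a <= b:
                continue
            rate = float(_rate_at(q_e, q_v, 0.5 * (a + b)))
            n = rng.poisson(rate * (a - b))
            if n:
                ages.extend(rng.uniform(b, a, n))
        if not ages:
            dropped.append(lineage)
            continue
        for age in sorted(ages, reverse=True):
            k = int(np.clip(np.searchsorted(-sub_tops, -age, side="right") - 1,
                            0, len(sub_bounds) - 1))
            hi, lo = sub_bounds[k]
            stage = stage_names[sub_stage[k]]
            occ_id = f"occ{occ_counter:06d}"
            occ_counter += 1
            loc = f"L_{k:02d}_{rng.integers(localities_per_stage):03d}"
            rows.append(
                (occ_id, loc, "", "", lineage, "", hi, lo, 0.0, 0.0, stage)
            )
            true_ages[occ_id] = float(age)
    table = pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
    return table, true_ages, dropped


def _destination(lon, lat, bearing_deg, dist_km, radius_km=6371.0088):
    """Great-circle destination point (degrees)."""
    d = dist_km / radius_km
    th = math.radians(bearing_deg)
    la1 = math.radians(lat)
    lo1 = math.radians(lon)
    la2 = math.asin(
        math.sin(la1) * math.cos(d) + math.cos(la1) * math.sin(d) * math.cos(th)
    )
    lo2 = lo1 + math.atan2(
        math.sin(th) * math.sin(d) * math.cos(la1),
        math.cos(d) - math.sin(la1) * math.sin(la2),
    )
    return (math.degrees(lo2) + 180.0) % 360.0 - 180.0, math.degrees(la2)


def simulate_space(
    table: pd.DataFrame, region_centres, dispersion_km: float, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Scatter localities around regional centres; all rows of a locality share
    coordinates.  Distances are half-normal with scale ``dispersion_km``."""
    if dispersion_km < 0:
        raise ValueError("dispersion_km must be >= 0")
    if len(region_centres) == 0:
        raise ValueError("need at least one region centre")
    rng = np.random.default_rng(seed)
    table = table.copy()
    localities = sorted(table["locality_id"].unique())
    assignment = {}
    for loc in localities:
        r = int(rng.integers(len(region_centres)))
        clon, clat = region_centres[r]
        dist = abs(rng.normal(0.0, dispersion_km)) if dispersion_km > 0 else 0.0
        bearing = rng.uniform(0.0, 360.0)
        lon, lat = _destination(clon, clat, bearing, dist)
        assignment[loc] = (r, lon, lat)
    table["plon"] = table["locality_id"].map(lambda l: assignment[l][1])
    table["plat"] = table["locality_id"].map(lambda l: assignment[l][2])
    regions = {loc: a[0] for loc, a in assignment.items()}
    return table, regions


# ---------------------------------------------------------------------------
# drivers and the full generator
# ---------------------------------------------------------------------------

def simulate_driver_grid(window, step: float, seed: int, smooth: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """A rescaled, smoothed Gaussian random walk on a regular age grid
    (descending ages), emulating a geological proxy time series in [0, 1]."""
    start, end = window
    n = int(round((start - end) / step)) + 1
    ages = np.linspace(start, end, n)
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(size=n + 2 * smooth))
    kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
    walk = np.convolve(walk, kernel, mode="valid")
    if np.ptp(walk) < 1e-12:
        values = np.full(n, 0.5)
    else:
        values = (walk - walk.min()) / np.ptp(walk)
    return ages, values


@dataclass
class SimulationConfig:
    """Defaults emulate a single well-sampled Late Cretaceous regional record."""

    seed: int = 0
    window: tuple = (113.2, 66.0)
    n_initial: int = 2
    lam: float = 0.12
    mu: float = 0.1
    accept_range: tuple = (80, 400)
    stage_bounds: tuple = tuple(DEFAULT_STAGE_BOUNDS)
    q: float = 1.5
    localities_per_stage: int = 12
    n_decoy_drivers: int = 2
    driver_effects: dict = field(default_factory=dict)  # name -> ("origination"|"extinction", G)
    n_suborders: int = 5
    n_superfamilies: int = 12
    trait_multipliers: dict = field(default_factory=dict)  # suborder name -> multiplier
    region_centres: tuple = ((10.0, 35.0), (-95.0, 40.0), (140.0, 35.0))
    dispersion_km: float = 400.0
    driver_step: float = 0.1


def simulate_full(config: SimulationConfig):
    """Compose the generators into a full synthetic dataset.

    Returns ``(occurrence table, drivers dict, trait table, SimulationTruth)``.
    Covariate effects use the exponential link ``rate = base * exp(G x(t))``;
    trait multipliers scale extinction per suborder.
    """
    cfg = config
    if cfg.trait_multipliers and cfg.n_suborders < 1:
        raise ValueError("trait effects declared without traits")
    valid_subs = {f"Sub{chr(65 + i)}" for i in range(cfg.n_suborders)}
    unknown_sub = set(cfg.trait_multipliers) - valid_subs
    if unknown_sub:
        raise ValueError(f"trait multipliers for unknown suborders: {sorted(unknown_sub)}")
    bad_rate = {r for r, _ in cfg.driver_effects.values()} - {"origination", "extinction"}
    if bad_rate:
        raise ValueError(f"driver effects must target origination/extinction, got {sorted(bad_rate)}")
    rng = np.random.default_rng(cfg.seed)

    # drivers on the age grid
    drivers = {}
    names = [f"driver_{i + 1}" for i in range(cfg.n_decoy_drivers)]
    names += [n for n in cfg.driver_effects if n not in names]
    for i, name in enumerate(sorted(set(names))):
        ages, values = simulate_driver_grid(
            cfg.window, cfg.driver_step, seed=cfg.seed * 1000 + i + 1
        )
        drivers[name] = (ages, values)
    unknown = set(cfg.driver_effects) - set(drivers)
    if unknown:
        raise ValueError(f"driver effects refer to unknown drivers: {sorted(unknown)}")

    def rate_spec(base, which):
        effects = [
            (drivers[n], g) for n, (r, g) in cfg.driver_effects.items() if r == which
        ]
        if not effects:
            return base
        ages = effects[0][0][0]
        logr = np.zeros(len(ages))
        for (a, v), g in effects:
            logr += g * v
        return (ages, base * np.exp(logr))

    lam_spec = rate_spec(cfg.lam, "origination")

    # taxonomy: suborders -> superfamilies -> genera (lineages)
    suborders = [f"Sub{chr(65 + i)}" for i in range(cfg.n_suborders)]
    superfamily_of = {}
    per = max(1, cfg.n_superfamilies // cfg.n_suborders)
    sf_names = [f"SF{j + 1:02d}" for j in range(cfg.n_superfamilies)]
    for j, sf in enumerate(sf_names):
        superfamily_of[sf] = suborders[min(j // per, cfg.n_suborders - 1)]

    # simulate lineages per suborder so trait multipliers act on extinction
    frames = []
    for i, sub in enumerate(suborders):
        mult = float(cfg.trait_multipliers.get(sub, 1.0))
        mu_spec = rate_spec(cfg.mu * mult, "extinction")
        n_init = max(1, cfg.n_initial // cfg.n_suborders + (i < cfg.n_initial % cfg.n_suborders))
        lo, hi = cfg.accept_range
        sub_times = simulate_lineages(
            lam_spec, mu_spec, cfg.window, n_initial=n_init,
            seed=cfg.seed * 100 + i,
            accept_range=(max(1, lo // cfg.n_suborders), hi),
        )
        sub_times = sub_times.assign(suborder=sub)
        frames.append(sub_times)
    times = pd.concat(frames, ignore_index=True)
    times["lineage"] = [f"g{i:05d}" for i in range(len(times))]
    sfs = sorted(sf_names, key=lambda s: superfamily_of[s])
    times["superfamily"] = [
        rng.choice([s for s in sf_names if superfamily_of[s] == sub])
        for sub in times["suborder"]
    ]

    table, true_ages, dropped = simulate_preservation(
        times, cfg.q, list(cfg.stage_bounds),
        localities_per_stage=cfg.localities_per_stage, seed=cfg.seed + 7,
    )
    tax = times.set_index("lineage")
    table["suborder"] = table["genus"].map(tax["suborder"])
    table["superfamily"] = table["genus"].map(tax["superfamily"])
    n_species = {g: int(rng.integers(1, 4)) for g in tax.index}
    table["species"] = [
        f"{g} sp{rng.integers(n_species[g]) + 1}" for g in table["genus"]
    ]
    table, _regions = simulate_space(
        table, list(cfg.region_centres), cfg.dispersion_km, seed=cfg.seed + 11
    )
    table = validate_occurrences(table, strict=True)

    trait_table = (
        times[["lineage", "suborder", "superfamily"]]
        .loc[~times["lineage"].isin(dropped)]
        .reset_index(drop=True)
    )
    truth = SimulationTruth(
        seed=cfg.seed,
        window=cfg.window,
        lam=cfg.lam,
        mu=cfg.mu,
        q=cfg.q,
        times=times[["lineage", "ts", "te", "survived"]],
        dropped_lineages=dropped,
        driver_effects=dict(cfg.driver_effects),
        trait_multipliers=dict(cfg.trait_multipliers),
        drivers={n: {"ages": a.tolist(), "values": v.tolist()} for n, (a, v) in drivers.items()},
        occurrence_true_ages=true_ages,
        region_centres=[list(c) for c in cfg.region_centres],
        dispersion_km=cfg.dispersion_km,
    )
    return table, drivers, trait_table, truth
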