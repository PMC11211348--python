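"""Bayesian birth-death-sampling inference from fossil occurrence data.

Jointly infers, by MCMC, the preservation rate underlying an incompletely
sampled set of fossil lineages, the sampling-corrected origination (``ts``)
and extinction (``te``) age of each lineage, and piecewise-constant
origination/extinction rates whose number and position of shifts are sampled
by reversible jump.  The preservation process is a Poisson process on each
lineage's true duration, homogeneous (HPP) or piecewise-constant per
geological stage (TPP), conditioned on at least one occurrence per lineage.

Rates are events per lineage per Myr; ages are Ma before present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Ceiling age for the open-ended oldest rate frame (Ma); far above any data.
AGE_CEILING = 400.0


class UnsupportedModelError(ValueError):
    """Raised when an unsupported preservation model is requested."""


# ---------------------------------------------------------------------------
# piecewise rates and likelihoods
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseRates:
    """Piecewise-constant rate: descending frame ``boundaries`` (first = window
    start, last = window end) and one positive rate per frame."""

    boundaries: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, float)
        self.rates = np.asarray(self.rates, float)
        if len(self.boundaries) != len(self.rates) + 1:
            raise ValueError("need one rate per frame (len(boundaries) == len(rates)+1)")
        if np.any(np.diff(self.boundaries) >= 0):
            raise ValueError("boundaries must be strictly decreasing ages")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    def _asc(self):
        return self.boundaries[::-1], self.rates[::-1]

    def rate_at(self, ages):
        edges, vals = self._asc()
        idx = np.clip(np.searchsorted(edges, ages, side="left") - 1, 0, len(vals) - 1)
        return vals[idx]

    def cumulative(self):
        """(ascending edges, cumulative integral from the youngest boundary)."""
        edges, vals = self._asc()
        cum = np.concatenate([[0.0], np.cumsum(vals * np.diff(edges))])
        return edges, cum

    def integral(self, a, b):
        """Exact integral of the rate over age interval [a, b] (a <= b)."""
        edges, cum = self.cumulative()
        return np.interp(b, edges, cum) - np.interp(a, edges, cum)


def bd_loglik(times: pd.DataFrame, lam: PiecewiseRates, mu: PiecewiseRates) -> float:
    """Birth-death log-likelihood of lineage origination/extinction times.

    ``sum ln lam(ts_i) + sum_extinct ln mu(te_i) - sum int_[te,ts] (lam+mu)``,
    the piecewise integrals computed exactly.  A lineage is an extinction
    event unless flagged extant (column ``extant`` True, or ``te`` equal to
    the rate window end).
    """
    ts = times["ts"].to_numpy(float)
    te = times["te"].to_numpy(float)
    top = max(lam.boundaries[0], mu.boundaries[0])
    bottom = min(lam.boundaries[-1], mu.boundaries[-1])
    if np.any(ts > top) or np.any(te < bottom):
        raise ValueError("lineage times outside the rate window")
    if np.any(ts <= te):
        raise ValueError("require ts > te for every lineage")
    if "extant" in times.columns:
        extinct = ~times["extant"].to_numpy(bool)
    else:
        extinct = te > bottom + 1e-12 if bottom > 0 else np.ones(len(te), bool)
    ll = float(np.sum(np.log(lam.rate_at(ts))))
    ll += float(np.sum(np.log(mu.rate_at(te[extinct]))))
    ll -= float(np.sum(lam.integral(te, ts) + mu.integral(te, ts)))
    return ll


@dataclass
class PreservationModel:
    """Poisson preservation model: HPP (one rate) or TPP (one rate per stage
    bin, bins bounded by descending stage boundaries)."""

    kind: str
    boundaries: np.ndarray  # descending bin boundaries (TPP); [top, bottom] for HPP
    q: np.ndarray
    gamma_shape: float = 1.5
    hyper_rate: float = 1.0

    def __post_init__(self):
        if self.kind == "NHPP":
            raise UnsupportedModelError(
                "the non-homogeneous (distance-from-endpoints) preservation "
                "model is not supported; use HPP or TPP"
            )
        if self.kind not in ("HPP", "TPP"):
            raise UnsupportedModelError(f"unknown preservation model {self.kind!r}")
        self.boundaries = np.asarray(self.boundaries, float)
        self.q = np.atleast_1d(np.asarray(self.q, float))
        if np.any(self.q <= 0):
            raise ValueError("preservation rates must be positive")
        if len(self.boundaries) != len(self.q) + 1:
            raise ValueError("need one q per bin")

    def _extended(self):
        """Ascending bin edges extended to [0, AGE_CEILING]; the end bins'
        rates apply beyond the youngest/oldest boundaries."""
        edges = self.boundaries[::-1].copy()
        edges[0] = 0.0
        edges = np.concatenate([edges, [AGE_CEILING]])
        vals = self.q[::-1]
        return edges, np.concatenate([vals, vals[-1:]])

    def rate_at(self, ages):
        edges, vals = self._extended()
        idx = np.clip(np.searchsorted(edges, ages, side="left") - 1, 0, len(vals) - 1)
        return vals[idx]

    def integral(self, a, b):
        edges, vals = self._extended()
        cum = np.concatenate([[0.0], np.cumsum(vals * np.diff(edges))])
        return np.interp(b, edges, cum) - np.interp(a, edges, cum)


def preservation_loglik(occurrence_ages: dict, times: pd.DataFrame, model: PreservationModel) -> float:
    """Log-likelihood of occurrence ages given lineage durations.

    Per lineage: ``sum_j ln q(a_j) - int_[te,ts] q - ln(1 - exp(-int q))``,
    the last term conditioning on the lineage being sampled at least once.
    """
    tl = times.set_index("lineage") if "lineage" in times.columns else times
    ll = 0.0
    for lineage, ages in occurrence_ages.items():
        ages = np.asarray(ages, float)
        ts = float(tl.loc[lineage, "ts"])
        te = float(tl.loc[lineage, "te"])
        if ages.size == 0:
            raise ValueError(f"lineage {lineage!r} has no occurrences")
        if np.any(ages > ts) or np.any(ages < te):
            raise ValueError(f"occurrence outside [te, ts] for lineage {lineage!r}")
        big_q = float(model.integral(te, ts))
        ll += float(np.sum(np.log(model.rate_at(ages))))
        ll += -big_q - math.log(-math.expm1(-big_q))
    return ll


# ---------------------------------------------------------------------------
# maximum-likelihood preservation model comparison
# ---------------------------------------------------------------------------

def _bin_index(ages, edges_asc):
    return np.clip(np.searchsorted(edges_asc, ages, side="left") - 1, 0, len(edges_asc) - 2)


def fit_preservation_ml(lineages, point_ages, stage_bounds) -> pd.DataFrame:
    """Compare HPP vs TPP preservation models by maximum likelihood and AIC.

    Lineage durations are fixed at the observed first/last point ages;
    zero-duration (single-age) lineages carry no rate information under the
    conditioned likelihood and are excluded.  TPP bins are the stage bins;
    bins with no lineage time keep a floor rate and contribute no free
    parameter.  Returns one row per model (lnL, k, AIC, winner flag).
    """
    lineages = np.asarray(lineages)
    ages = np.asarray(point_ages, float)
    df = pd.DataFrame({"lineage": lineages, "age": ages})
    grp = df.groupby("lineage")["age"]
    o = grp.max()
    y = grp.min()
    keep = (o - y) > 0
    if (~keep).any():
        logger.warning("excluding %d zero-duration lineage(s) from the ML fit",
                       int((~keep).sum()))
    kept = set(o.index[keep])
    df = df[df["lineage"].isin(kept)]
    if df.empty:
        raise ValueError("no lineages with positive observed duration")
    o = o[keep].to_numpy()
    y = y[keep].to_numpy()
    d = o - y
    n_occ = grp.count()[sorted(kept)].to_numpy()
    n_total = int(df.shape[0])

    # HPP
    def neg_hpp(logq):
        q = math.exp(logq)
        qd = q * d
        return -(n_total * logq - np.sum(qd) - np.sum(np.log(-np.expm1(-qd))))

    res = minimize_scalar(neg_hpp, bounds=(-10, 5), method="bounded")
    ll_hpp, k_hpp = -res.fun, 1

    # TPP on stage bins
    edges = np.sort(np.asarray(stage_bounds, float))
    order = sorted(kept)
    dfo = df.set_index("lineage")
    t_ib = np.zeros((len(order), len(edges) - 1))
    n_ib = np.zeros_like(t_ib)
    for i, lineage in enumerate(order):
        a = dfo.loc[[lineage], "age"].to_numpy()
        lo, hi = a.min(), a.max()
        t_ib[i] = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0, None)
        np.add.at(n_ib[i], _bin_index(a, edges), 1)
    live = t_ib.sum(axis=0) > 0
    nb = n_ib.sum(axis=0)

    def neg_tpp(logq):
        q = np.full(len(live), 1e-8)
        q[live] = np.exp(logq)
        big_q = t_ib @ q
        return -(float(nb[live] @ logq) - big_q.sum()
                 - np.sum(np.log(-np.expm1(-np.maximum(big_q, 1e-300)))))

    x0 = np.full(int(live.sum()), math.log(max(n_total / d.sum(), 1e-3)))
    res_t = minimize(neg_tpp, x0, method="L-BFGS-B")
    ll_tpp, k_tpp = -res_t.fun, int(live.sum())
    if not live.all():
        logger.warning("%d stage bin(s) with zero lineage time: q floored",
                       int((~live).sum()))

    out = pd.DataFrame(
        {
            "model": ["HPP", "TPP"],
            "lnL": [ll_hpp, ll_tpp],
            "k": [k_hpp, k_tpp],
        }
    )
    out["AIC"] = 2 * out["k"] - 2 * out["lnL"]
    out["winner"] = out["AIC"] == out["AIC"].min()
    return out


# ---------------------------------------------------------------------------
# the reversible-jump sampler
# ---------------------------------------------------------------------------

@dataclass
class BDSConfig:
    """Sampler settings; the defaults are a desk-scale run."""

    iterations: int = 200_000
    sampling_interval: int = 100
    edge_window: tuple = (113.2, 66.0)  # rate shifts restricted to this window
    seed: int = 0
    stage_bounds: tuple = (113.2, 100.5, 93.9, 89.8, 86.3, 83.6, 72.1, 66.0)
    shift_prior_mean: float = 1.0      # Poisson prior mean on shifts per rate
    rate_prior_shape: float = 2.0      # gamma prior on frame rates
    rate_prior_rate: float = 1.0
    q_prior_shape: float = 1.5         # gamma prior on bin preservation rates
    hyper_prior_rate: float = 1.0      # exponential hyper-prior on the gamma rate
    time_window: float = 1.5           # sliding-window width for ts/te (Myr)
    rate_step: float = 0.8             # log-multiplier width for rate proposals
    q_step: float = 0.7
    shift_move_window: float = 3.0
    prior_only: bool = False
    max_init_attempts: int = 20


@dataclass
class BDSData:
    """Point-aged lineage data ready for the sampler."""

    lineage: np.ndarray
    oldest: np.ndarray
    youngest: np.ndarray
    n_ib: np.ndarray       # lineage x preservation-bin occurrence counts
    q_edges_asc: np.ndarray
    extant: np.ndarray

    @classmethod
    def from_replicate(cls, table: pd.DataFrame, point_age, stage_bounds,
                       level: str = "genus", extant_taxa=()) -> "BDSData":
        """Group one age-randomised replicate into lineages at a taxonomic level."""
        names = table[level].to_numpy()
        if level == "species":
            full = names != ""
            names = np.where(full, table["genus"].to_numpy() + " " + names, "")
            keep = names != ""
        else:
            keep = names != ""
        ages = np.asarray(point_age, float)[keep]
        names = names[keep]
        order = np.unique(names)
        edges = np.sort(np.asarray(stage_bounds, float))
        q_edges = np.concatenate([[0.0], edges[1:-1], [AGE_CEILING]])
        n_ib = np.zeros((len(order), len(q_edges) - 1))
        idx = {n: i for i, n in enumerate(order)}
        rows = np.array([idx[n] for n in names])
        cols = _bin_index(ages, q_edges)
        np.add.at(n_ib, (rows, cols), 1)
        oldest = np.full(len(order), -np.inf)
        youngest = np.full(len(order), np.inf)
        np.maximum.at(oldest, rows, ages)
        np.minimum.at(youngest, rows, ages)
        extant = np.isin(order, list(extant_taxa))
        return cls(order, oldest, youngest, n_ib, q_edges, extant)

    @property
    def n_lineages(self) -> int:
        return len(self.lineage)


def _reflect(x, lo, hi):
    """Fold proposals back into [lo, hi] (symmetric reflection)."""
    span = hi - lo
    y = np.abs(np.mod(x - lo, 2 * span))
    return lo + np.minimum(y, 2 * span - y)


class _RJState:
    """Mutable sampler state for one rate (shifts + frame rates)."""

    __slots__ = ("shifts", "rates")

    def __init__(self, rate0):
        self.shifts = np.empty(0)  # ascending ages
        self.rates = np.array([rate0], float)  # per frame, youngest first

    def edges(self):
        return np.concatenate([[0.0], self.shifts, [AGE_CEILING]])

    def cum(self):
        e = self.edges()
        return e, np.concatenate([[0.0], np.cumsum(self.rates * np.diff(e))])

    def rate_at(self, ages):
        idx = np.clip(np.searchsorted(self.edges(), ages, side="left") - 1,
                      0, len(self.rates) - 1)
        return self.rates[idx]


def run_rjmcmc(data: BDSData, config: BDSConfig) -> pd.DataFrame:
    """Sample lineage times, piecewise birth/death rates and bin preservation
    rates; returns the chain log (one row per sampled iteration)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = data.n_lineages
    o, y = data.oldest, data.youngest
    extant = data.extant
    extinct = ~extant
    w_lo, w_hi = cfg.edge_window[1], cfg.edge_window[0]
    width = w_hi - w_lo
    nu = cfg.shift_prior_mean
    a_r, b_r = cfg.rate_prior_shape, cfg.rate_prior_rate
    a_q = cfg.q_prior_shape
    n_bins = data.n_ib.shape[1]
    nb = data.n_ib.sum(axis=0)

    # --- initial state
    ts = o + 0.5
    te = np.maximum(y - 0.5, 0.0)
    te[extant] = 0.0
    total_span = float(np.sum(ts - te))
    rate0 = max(n / max(total_span, 1.0), 1e-3)
    lam = _RJState(rate0)
    mu = _RJState(rate0)
    q = np.full(n_bins, max(data.n_ib.sum() / max(total_span, 1.0), 1e-3))
    beta = 1.0

    def vec_ll(ts_v, te_v, lam_s, mu_s, q_v):
        """Per-lineage log-likelihood (bd + preservation time terms)."""
        if cfg.prior_only:
            return np.zeros(len(ts_v))
        le, lc = lam_s.cum()
        me, mc = mu_s.cum()
        qe = data.q_edges_asc
        qc = np.concatenate([[0.0], np.cumsum(q_v * np.diff(qe))])
        big_q = np.maximum(np.interp(ts_v, qe, qc) - np.interp(te_v, qe, qc), 1e-12)
        v = (
            np.log(lam_s.rate_at(ts_v))
            - (np.interp(ts_v, le, lc) - np.interp(te_v, le, lc))
            - (np.interp(ts_v, me, mc) - np.interp(te_v, me, mc))
            - big_q
            - np.log(-np.expm1(-big_q))
        )
        v[extinct] += np.log(mu_s.rate_at(te_v[extinct]))
        return v

    def pres_const(q_v):
        return 0.0 if cfg.prior_only else float(nb @ np.log(q_v))

    def log_prior(lam_s, mu_s, q_v, beta_v):
        lp = 0.0
        for st in (lam_s, mu_s):
            k = len(st.shifts)
            lp += -nu + k * math.log(nu) - k * math.log(width)
            lp += float(np.sum((a_r - 1) * np.log(st.rates) - b_r * st.rates)) \
                + len(st.rates) * (a_r * math.log(b_r) - gammaln(a_r))
        lp += float(np.sum((a_q - 1) * np.log(q_v) - beta_v * q_v)) \
            + n_bins * (a_q * math.log(beta_v) - gammaln(a_q))
        lp += -cfg.hyper_prior_rate * beta_v + math.log(cfg.hyper_prior_rate)
        return lp

    ll_vec = vec_ll(ts, te, lam, mu, q)
    if not np.all(np.isfinite(ll_vec)):
        for attempt in range(cfg.max_init_attempts):
            ts = o + rng.uniform(0.1, 2.0, n)
            te = np.maximum(y - rng.uniform(0.1, 2.0, n), 0.0)
            te[extant] = 0.0
            ll_vec = vec_ll(ts, te, lam, mu, q)
            if np.all(np.isfinite(ll_vec)):
                break
        else:
            raise RuntimeError(
                "non-finite posterior at initialisation after "
                f"{cfg.max_init_attempts} attempts; check input ages"
            )
    ll_const = pres_const(q)

    records = []
    move_p = np.array([0.30, 0.12, 0.12, 0.08, 0.08, 0.20, 0.10])
    move_cum = np.cumsum(move_p)

    def rj_move(state: _RJState):
        nonlocal ll_vec
        k = len(state.shifts)
        choice = rng.integers(3)
        if choice == 0:  # add a shift
            s = rng.uniform(w_lo, w_hi)
            new_rate = rng.gamma(a_r, 1.0 / b_r)
            if new_rate <= 0:
                return
            pos = int(np.searchsorted(state.shifts, s))
            side = rng.integers(2)  # 0: new rate below the shift, 1: above
            cand = _RJState(1.0)
            cand.shifts = np.insert(state.shifts, pos, s)
            cand.rates = np.insert(state.rates, pos + side, new_rate)
            cand_vec = vec_ll(ts, te, cand if state is lam else lam,
                              cand if state is mu else mu, q)
            d_ll = float(cand_vec.sum() - ll_vec.sum())
            # the new rate is drawn from its prior, so its prior density
            # cancels against the proposal; position prior and order factor
            # reduce to nu / (k + 1)
            log_a = d_ll + math.log(nu) - math.log(k + 1)
            if math.log(rng.random()) < log_a:
                state.shifts, state.rates = cand.shifts, cand.rates
                ll_vec = cand_vec
        elif choice == 1 and k > 0:  # delete a shift
            j = int(rng.integers(k))
            side = rng.integers(2)
            cand = _RJState(1.0)
            cand.shifts = np.delete(state.shifts, j)
            cand.rates = np.delete(state.rates, j + side)
            cand_vec = vec_ll(ts, te, cand if state is lam else lam,
                              cand if state is mu else mu, q)
            d_ll = float(cand_vec.sum() - ll_vec.sum())
            log_a = d_ll + math.log(k) - math.log(nu)
            if math.log(rng.random()) < log_a:
                state.shifts, state.rates = cand.shifts, cand.rates
                ll_vec = cand_vec
        elif choice == 2 and k > 0:  # move a shift within its neighbours
            j = int(rng.integers(k))
            s = _reflect(state.shifts[j] + rng.uniform(-cfg.shift_move_window,
                                                       cfg.shift_move_window),
                         w_lo, w_hi)
            lo = state.shifts[j - 1] if j > 0 else w_lo
            hi = state.shifts[j + 1] if j < k - 1 else w_hi
            if not (lo < s < hi):
                return  # crossing a neighbour would reshuffle frames; reject
            cand = _RJState(1.0)
            cand.shifts = state.shifts.copy()
            cand.shifts[j] = s
            cand.rates = state.rates.copy()
            cand_vec = vec_ll(ts, te, cand if state is lam else lam,
                              cand if state is mu else mu, q)
            if math.log(rng.random()) < float(cand_vec.sum() - ll_vec.sum()):
                state.shifts, state.rates = cand.shifts, cand.rates
                ll_vec = cand_vec

    for it in range(cfg.iterations + 1):
        u = rng.random()
        if u < move_cum[0]:
            # joint sliding-window update of every lineage's ts and te
            ts_c = _reflect(ts + rng.uniform(-cfg.time_window, cfg.time_window, n),
                            o, AGE_CEILING)
            te_c = _reflect(te + rng.uniform(-cfg.time_window, cfg.time_window, n),
                            0.0, np.maximum(y, 1e-9))
            te_c[extant] = 0.0
            cand_vec = vec_ll(ts_c, te_c, lam, mu, q)
            acc = np.log(rng.random(n)) < cand_vec - ll_vec
            ts = np.where(acc, ts_c, ts)
            te = np.where(acc, te_c, te)
            ll_vec = np.where(acc, cand_vec, ll_vec)
        elif u < move_cum[1] or (move_cum[1] <= u < move_cum[2]):
            state = lam if u < move_cum[1] else mu
            j = int(rng.integers(len(state.rates)))
            m = math.exp(cfg.rate_step * (rng.random() - 0.5))
            old = state.rates[j]
            state.rates[j] = old * m
            cand_vec = vec_ll(ts, te, lam, mu, q)
            d_pr = (a_r - 1) * math.log(m) - b_r * (old * m - old)
            log_a = float(cand_vec.sum() - ll_vec.sum()) + d_pr + math.log(m)
            if math.log(rng.random()) < log_a:
                ll_vec = cand_vec
            else:
                state.rates[j] = old
        elif u < move_cum[3]:
            rj_move(lam)
        elif u < move_cum[4]:
            rj_move(mu)
        elif u < move_cum[5]:
            j = int(rng.integers(n_bins))
            m = math.exp(cfg.q_step * (rng.random() - 0.5))
            old = q[j]
            q[j] = old * m
            cand_vec = vec_ll(ts, te, lam, mu, q)
            cand_const = pres_const(q)
            d_pr = (a_q - 1) * math.log(m) - beta * (old * m - old)
            log_a = (float(cand_vec.sum() - ll_vec.sum())
                     + (cand_const - ll_const) + d_pr + math.log(m))
            if math.log(rng.random()) < log_a:
                ll_vec = cand_vec
                ll_const = cand_const
            else:
                q[j] = old
        else:
            # conjugate update: beta | q ~ Gamma(1 + a_q * B, hyper_rate + sum q)
            beta = rng.gamma(1.0 + a_q * n_bins,
                             1.0 / (cfg.hyper_prior_rate + float(q.sum())))

        if it % cfg.sampling_interval == 0:
            ll = float(ll_vec.sum()) + ll_const
            lp = log_prior(lam, mu, q, beta)
            row = {
                "iteration": it,
                "posterior": ll + lp,
                "likelihood": ll,
                "prior": lp,
                "beta": beta,
                "root_age": float(ts.max()),
                "k_lam": len(lam.shifts),
                "k_mu": len(mu.shifts),
                "lam_bounds": ";".join(repr(float(v)) for v in
                                       [w_hi, *lam.shifts[::-1], w_lo]),
                "lam_rates": ";".join(repr(float(v)) for v in lam.rates[::-1]),
                "mu_bounds": ";".join(repr(float(v)) for v in
                                      [w_hi, *mu.shifts[::-1], w_lo]),
                "mu_rates": ";".join(repr(float(v)) for v in mu.rates[::-1]),
            }
            for b in range(n_bins):
                row[f"q_{b}"] = q[b]
            for i, name in enumerate(data.lineage):
                row[f"ts_{name}"] = ts[i]
                row[f"te_{name}"] = te[i]
            records.append(row)

    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# chain post-processing
# ---------------------------------------------------------------------------

def combine_logs(logs, burnin_fraction: float = 0.10) -> pd.DataFrame:
    """Drop per-log burn-in and concatenate with a provenance column."""
    if not logs:
        raise ValueError("need at least one log")
    cols = list(logs[0].columns)
    out = []
    for r, log in enumerate(logs):
        if list(log.columns) != cols:
            raise ValueError("chain logs have mismatched schemas")
        cut = int(math.floor(burnin_fraction * len(log)))
        kept = log.iloc[cut:].copy()
        kept.insert(0, "replicate", r)
        out.append(kept)
    return pd.concat(out, ignore_index=True)


def hpd_interval(samples, prob: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob * n)`` samples."""
    if not (0 < prob < 1):
        raise ValueError("prob must be in (0, 1)")
    s = np.sort(np.asarray(samples, float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least two samples")
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def chain_ess(chain: pd.DataFrame, column: str = "likelihood", warn_below: float = 200.0) -> float:
    """Effective sample size of a chain column (warns when low)."""
    import arviz

    ess = float(arviz.ess(np.asarray(chain[column], float)))
    if ess < warn_below:
        logger.warning("ESS of %s is %.0f (< %.0f); consider longer chains",
                       column, ess, warn_below)
    return ess


def _parse_rates(row, prefix):
    bounds = np.array([float(v) for v in row[f"{prefix}_bounds"].split(";")])
    rates = np.array([float(v) for v in row[f"{prefix}_rates"].split(";")])
    return bounds, rates


@dataclass
class RTTResult:
    """Rates-through-time summary with shift support per candidate bin."""

    ages: np.ndarray
    summary: pd.DataFrame       # age, mean/lo/hi for lam, mu, net
    shift_support: pd.DataFrame  # rate, bin_old, bin_young, p, p0, logbf


def rates_through_time(
    chain: pd.DataFrame,
    age_grid,
    edge_window=(113.2, 66.0),
    shift_prior_mean: float = 1.0,
    boundary_bins=None,
    hpd_prob: float = 0.95,
) -> RTTResult:
    """Posterior mean and HPD of lam, mu and net diversification on an age
    grid, plus log Bayes-factor support (2 ln BF) for a shift in each
    candidate boundary bin."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    ages = np.asarray(age_grid, float)
    w_hi, w_lo = edge_window
    width = w_hi - w_lo
    n_samp = len(chain)
    rates = {"lam": np.empty((n_samp, len(ages))), "mu": np.empty((n_samp, len(ages)))}
    shifts = {"lam": [], "mu": []}
    for i, (_, row) in enumerate(chain.iterrows()):
        for name in ("lam", "mu"):
            bounds, vals = _parse_rates(row, name)
            asc = bounds[::-1]
            idx = np.clip(np.searchsorted(asc, ages, side="left") - 1, 0, len(vals) - 1)
            rates[name][i] = vals[::-1][idx]
            shifts[name].append(bounds[1:-1])
    rows = []
    for j, age in enumerate(ages):
        entry = {"age": age}
        for name in ("lam", "mu"):
            col = rates[name][:, j]
            lo, hi = hpd_interval(col, hpd_prob)
            entry[f"{name}_mean"] = col.mean()
            entry[f"{name}_lo"] = lo
            entry[f"{name}_hi"] = hi
        net = rates["lam"][:, j] - rates["mu"][:, j]
        lo, hi = hpd_interval(net, hpd_prob)
        entry.update(net_mean=net.mean(), net_lo=lo, net_hi=hi)
        rows.append(entry)
    summary = pd.DataFrame(rows)

    if boundary_bins is None:
        boundary_bins = [(w_hi, w_lo)]
    support = []
    for name in ("lam", "mu"):
        for b_old, b_young in boundary_bins:
            hi = min(b_old, w_hi)
            lo = max(b_young, w_lo)
            if hi <= lo:
                continue
            got = np.array([
                np.any((s > lo) & (s <= hi)) for s in shifts[name]
            ])
            p = got.mean()
            p0 = 1.0 - math.exp(-shift_prior_mean * (hi - lo) / width)
            pc = min(max(p, 1e-12), 1 - 1e-12)
            logbf = 2.0 * (math.log(pc / (1 - pc)) - math.log(p0 / (1 - p0)))
            support.append((name, b_old, b_young, p, p0, logbf))
    shift_support = pd.DataFrame(
        support, columns=["rate", "bin_old", "bin_young", "p", "p0", "logbf"]
    )
    return RTTResult(ages, summary, shift_support)


@dataclass
class DiversityCurve:
    """Range-through richness on a regular age grid with central intervals."""

    ages: np.ndarray
    summary: pd.DataFrame
    level: str = "genus"


def diversity_curve(chain: pd.DataFrame, step: float = 0.5,
                    levels=(0.75, 0.95), level_label: str = "genus") -> DiversityCurve:
    """Range-through diversity from sampled lineage durations.

    Richness at age t in one posterior sample is the number of lineages with
    ``ts >= t > te``; the mean and central intervals are taken across samples.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if len(chain) == 0:
        raise ValueError("empty chain")
    ts_cols = [c for c in chain.columns if c.startswith("ts_")]
    te_cols = ["te_" + c[3:] for c in ts_cols]
    ts = chain[ts_cols].to_numpy(float)
    te = chain[te_cols].to_numpy(float)
    top = float(np.ceil(ts.max() / step) * step)
    ages = np.arange(0.0, top + step / 2, step)[::-1]
    rich = np.empty((ts.shape[0], len(ages)), int)
    for i in range(ts.shape[0]):
        s_ts = np.sort(ts[i])
        s_te = np.sort(te[i])
        # lineages with ts >= t minus lineages with te >= t
        rich[i] = (len(s_ts) - np.searchsorted(s_ts, ages, side="left")) - (
            len(s_te) - np.searchsorted(s_te, ages, side="left")
        )
    rows = {"age": ages, "mean_richness": rich.mean(axis=0)}
    for lev in levels:
        a = (1 - lev) / 2
        rows[f"lo_{int(lev * 100)}"] = np.quantile(rich, a, axis=0)
        rows[f"hi_{int(lev * 100)}"] = np.quantile(rich, 1 - a, axis=0)
    return DiversityCurve(ages, pd.DataFrame(rows), level_label)
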