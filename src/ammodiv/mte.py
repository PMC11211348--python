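"""Trait-dependent extinction risk with Bayesian variable selection.

Each lineage's extinction rate is a mean rate times the multipliers of its
discrete trait categories (here taxonomic proxies for ecological guilds:
suborder and superfamily membership):

    mu_i = mu_mean * prod_{t included} delta_{t, cat_t(i)}

Category multipliers are log-normal around 1 with a per-trait spread under a
half-Cauchy shrinkage hyper-prior, centred so each trait's multipliers have
geometric mean 1 (identifiable against the mean rate).  A per-trait inclusion
indicator with prior inclusion probability 0.05 (95% prior mass on "no
effect") switches the trait's multipliers on or off; traits whose posterior
inclusion frequency exceeds the threshold equivalent to logBF > 6 (51.4% at
the 0.05 prior) are flagged significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bds import combine_logs

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (100.5, 68.0)


def significance_threshold(prior_p: float, logbf: float) -> float:
    """Posterior inclusion frequency equivalent to a log Bayes factor.

    ``logbf`` is on the 2 ln scale; posterior odds = exp(logbf / 2) * prior
    odds; returns the corresponding posterior probability.
    """
    if not (0 < prior_p < 1):
        raise ValueError("prior_p must be in (0, 1)")
    odds = math.exp(logbf / 2.0) * prior_p / (1.0 - prior_p)
    return odds / (1.0 + odds)


@dataclass
class MTEState:
    """Mean extinction rate, per-trait inclusion indicators and multipliers."""

    mu_mean: float
    included: dict            # trait -> bool
    log_mult: dict            # trait -> array of raw log-multipliers per category
    spread: dict              # trait -> per-trait log-scale
    categories: dict          # trait -> list of category labels

    def multipliers(self, trait: str) -> np.ndarray:
        """Effective multipliers (geometric mean 1) or ones when excluded."""
        z = self.log_mult[trait]
        if not self.included[trait]:
            return np.ones(len(z))
        return np.exp(z - z.mean())


def _window_durations(times: pd.DataFrame, window):
    start, end = window
    ts = times["ts"].to_numpy(float)
    te = times["te"].to_numpy(float)
    a = np.minimum(ts, start)
    b = np.maximum(te, end)
    keep = a > b
    d = (a - b)[keep]
    extinct = (te > end)[keep]   # extinction event inside the window
    return keep, d, extinct


def mte_loglik(times: pd.DataFrame, state: MTEState, traits: pd.DataFrame,
               window=DEFAULT_WINDOW) -> float:
    """Exponential-duration log-likelihood with trait-specific rates.

    ``sum_i [extinct_i * ln mu_i - mu_i * d_i]`` over within-window lineage
    segments; lineages surviving past the window end are right-censored and
    contribute only the exposure term.
    """
    keep, d, extinct = _window_durations(times, window)
    if keep.sum() == 0:
        raise ValueError("no lineage time inside the analysis window")
    tl = traits.set_index("lineage") if "lineage" in traits.columns else traits
    names = times["lineage"].to_numpy()[keep]
    log_mu = np.full(len(d), math.log(state.mu_mean))
    for trait, cats in state.categories.items():
        mult = state.multipliers(trait)
        if not np.all(mult > 0):
            raise ValueError("trait multipliers must be positive and finite")
        cat_index = {c: i for i, c in enumerate(cats)}
        idx = np.array([cat_index[c] for c in tl.loc[names, trait]])
        log_mu += np.log(mult)[idx]
    mu = np.exp(log_mu)
    return float(np.sum(extinct * log_mu) - np.sum(mu * d))


# ---------------------------------------------------------------------------
# MCMC with spike-and-slab inclusion
# ---------------------------------------------------------------------------

@dataclass
class MTEConfig:
    iterations: int = 12000      # full parameter sweeps
    sampling_interval: int = 5
    burnin_fraction: float = 0.10
    seed: int = 0
    prior_inclusion: float = 0.05
    z_step: float = 0.3
    spread_step: float = 0.5
    spread_scale: float = 0.2    # half-Cauchy scale of the per-trait spread
    spread_max: float = 1.5      # truncation of the spread prior (log scale)
    mu_prior_shape: float = 1.5
    mu_prior_rate: float = 0.5
    window: tuple = DEFAULT_WINDOW
    significance_logbf: float = 6.0


@dataclass
class MTESummary:
    trait_table: pd.DataFrame     # trait, inclusion_frequency, significant
    category_table: pd.DataFrame  # trait, category, posterior_mean_multiplier
    threshold: float


def _trait_design(times, traits, window, trait_columns):
    """Category index arrays for the within-window lineages."""
    keep, d, extinct = _window_durations(times, window)
    names = times["lineage"].to_numpy()[keep]
    tl = traits.set_index("lineage") if "lineage" in traits.columns else traits
    design = {}
    categories = {}
    for trait in trait_columns:
        cats = sorted(pd.unique(tl.loc[names, trait]))
        if len(cats) < 2:
            logger.warning("trait %r has a single category; excluded (no contrast)", trait)
            continue
        cat_index = {c: i for i, c in enumerate(cats)}
        design[trait] = np.array([cat_index[c] for c in tl.loc[names, trait]])
        categories[trait] = cats
    return d, extinct.astype(float), design, categories


def run_mte_mcmc(times_replicates, traits: pd.DataFrame, config: MTEConfig,
                 trait_columns=("suborder", "superfamily")):
    """Sample the multi-trait extinction model; returns (chain, MTESummary)."""
    if isinstance(times_replicates, pd.DataFrame):
        times_replicates = [times_replicates]
    cfg = config
    threshold = significance_threshold(cfg.prior_inclusion, cfg.significance_logbf)
    prior_odds = math.log(cfg.prior_inclusion / (1 - cfg.prior_inclusion))

    logs = []
    for r, times in enumerate(times_replicates):
        d, extinct, design, categories = _trait_design(
            times, traits, cfg.window, trait_columns
        )
        if not design:
            raise ValueError("no usable traits (each needs >= 2 categories)")
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, r]))
        n_events = float(extinct.sum())

        mu_mean = max(n_events / d.sum(), 1e-4)
        included = {t: False for t in design}
        z = {t: np.zeros(len(categories[t])) for t in design}
        spread = {t: 0.3 for t in design}

        def log_mult_per_lineage():
            lm = np.zeros(len(d))
            for t, idx in design.items():
                if included[t]:
                    zz = z[t] - z[t].mean()
                    lm += zz[idx]
            return lm

        def loglik(lm, mu_v):
            mu_i = mu_v * np.exp(lm)
            return float(extinct @ (np.log(mu_v) + lm) - mu_i @ d)

        lm = log_mult_per_lineage()
        ll = loglik(lm, mu_mean)

        rows = []
        for it in range(cfg.iterations + 1):
            # mean rate: conjugate given the multipliers
            eff = np.exp(lm) @ d
            mu_mean = rng.gamma(cfg.mu_prior_shape + n_events,
                                1.0 / (cfg.mu_prior_rate + eff))
            ll = loglik(lm, mu_mean)
            for t, idx in design.items():
                # inclusion flip (multiplier values kept as latent state)
                cand_inc = dict(included)
                cand_inc[t] = not included[t]
                lm_c = np.zeros(len(d))
                for t2, idx2 in design.items():
                    if cand_inc[t2]:
                        zz = z[t2] - z[t2].mean()
                        lm_c += zz[idx2]
                cand_ll = loglik(lm_c, mu_mean)
                log_a = cand_ll - ll + (prior_odds if cand_inc[t] else -prior_odds)
                if math.log(rng.random()) < log_a:
                    included = cand_inc
                    lm, ll = lm_c, cand_ll
                if included[t]:
                    # per-category multiplier updates under N(0, spread^2)
                    for c in range(len(z[t])):
                        old = z[t][c]
                        z[t][c] = old + rng.normal(0.0, cfg.z_step)
                        lm_c = log_mult_per_lineage()
                        cand_ll = loglik(lm_c, mu_mean)
                        log_a = cand_ll - ll + \
                            (old * old - z[t][c] ** 2) / (2 * spread[t] ** 2)
                        if math.log(rng.random()) < log_a:
                            lm, ll = lm_c, cand_ll
                        else:
                            z[t][c] = old
                    # trait spread: truncated half-Cauchy prior, log-scale walk
                    old_s = spread[t]
                    m = math.exp(cfg.spread_step * (rng.random() - 0.5))
                    new_s = old_s * m
                    if new_s <= cfg.spread_max:
                        zz = z[t]
                        log_a = (
                            -len(zz) * math.log(new_s / old_s)
                            - float(zz @ zz) / 2 * (1 / new_s**2 - 1 / old_s**2)
                            + math.log((1 + (old_s / cfg.spread_scale) ** 2)
                                       / (1 + (new_s / cfg.spread_scale) ** 2))
                            + math.log(m)
                        )
                        if math.log(rng.random()) < log_a:
                            spread[t] = new_s
                else:
                    # refresh latent multipliers from the same truncated prior
                    while True:
                        s = abs(cfg.spread_scale * rng.standard_cauchy())
                        if 0 < s <= cfg.spread_max:
                            break
                    spread[t] = s
                    z[t] = rng.normal(0.0, s, len(z[t]))
            if it % cfg.sampling_interval == 0:
                row = {"iteration": it, "likelihood": ll, "mu_mean": mu_mean}
                for t in design:
                    row[f"I_{t}"] = int(included[t])
                    mult = np.exp(z[t] - z[t].mean()) if included[t] \
                        else np.ones(len(z[t]))
                    for c, cat in enumerate(categories[t]):
                        row[f"delta_{t}_{cat}"] = mult[c]
                rows.append(row)
        logs.append(pd.DataFrame(rows))

    chain = combine_logs(logs, cfg.burnin_fraction)
    trait_rows = []
    cat_rows = []
    for t in categories:
        freq = float(chain[f"I_{t}"].mean())
        trait_rows.append((t, freq, freq > threshold))
        for cat in categories[t]:
            cat_rows.append((t, cat, float(chain[f"delta_{t}_{cat}"].mean())))
    summary = MTESummary(
        pd.DataFrame(trait_rows, columns=["trait", "inclusion_frequency", "significant"]),
        pd.DataFrame(cat_rows, columns=["trait", "category", "posterior_mean_multiplier"]),
        threshold,
    )
    return chain, summary
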