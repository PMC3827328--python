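"""Synthetic applicant pools and selected-entrant cohorts.

Emulates the statistical structure of medical-school selection data: latent
true predictor and outcome constructs are bivariate normal with correlation
``rho_true``; observed scores add measurement error set by the reliabilities;
entrants are the top fraction of applicants on a selection composite that
mixes the observed predictor with other information (indirect selection);
the observed predictor is right-censored at a grade-ceiling quantile; and
the outcome can be binned to an ordinal or binary scale.  Because nothing is
downloaded, every stage of the estimation pipeline can be tested against
known generative truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .censored import CensoredSample, SevenParameterModel

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "bin_outcome"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic selection cohort.

    Defaults mirror a UK-style cohort: true construct correlation .65,
    predictor reliability .815 and outcome reliability .834 (the observed
    averages across the measures this generator emulates), a quarter of
    applicants admitted, an indirect selection composite with weight .8 on
    the observed predictor, and a grade ceiling at the 90th percentile of
    the applicant pool.
    """

    n_applicants: int = 20000
    rho_true: float = 0.65
    r_XXa: float = 0.815
    r_YYa: float = 0.834
    selection_fraction: float = 0.25
    w: float = 0.8
    ceiling_quantile: float = 0.9
    selection_basis: str = "construct"     # construct | observed
    outcome_mode: str = "continuous"       # continuous | ordinal | binary
    ordinal_cuts: tuple = (0.03, 0.15, 0.9)
    binary_cut: float = 0.5
    predictor_mean: float = 0.0
    predictor_sd: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("r_XXa", "r_YYa", "selection_fraction", "ceiling_quantile"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not abs(self.rho_true) < 1:
            raise ValueError("rho_true must be in (-1, 1)")
        if not 0 <= self.w <= 1:
            raise ValueError("w must be in [0, 1]")
        if self.outcome_mode not in ("continuous", "ordinal", "binary"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.selection_basis not in ("construct", "observed"):
            raise ValueError(f"unknown selection_basis {self.selection_basis!r}")


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated applicant pool with its selected entrants and the truth.

    ``truth`` records the implied seven-parameter quantities plus the
    generative rho_true, the realised selection ratio u (decensored entrant
    SD over applicant SD) and the realised restricted reliabilities, so
    recovery tests can assert against known values.
    """

    applicants: CensoredSample
    entrants_x: np.ndarray
    entrants_y: np.ndarray
    entrants_x_latent: np.ndarray
    ceiling: float
    config: SimulationConfig
    truth: dict = field(default_factory=dict)


def _observed(latent: np.ndarray, reliability: float, rng) -> np.ndarray:
    return (math.sqrt(reliability) * latent
            + math.sqrt(1.0 - reliability) * rng.standard_normal(latent.size))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one applicant pool and its selected, censored entrant cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_applicants

    # latent constructs and observed (error-laden) scores, all unit scale
    t = rng.standard_normal(n)
    p = config.rho_true * t + math.sqrt(1 - config.rho_true ** 2) * rng.standard_normal(n)
    x = _observed(t, config.r_XXa, rng)
    y = _observed(p, config.r_YYa, rng)

    # Indirect selection through a suitability composite.  The default basis
    # weights the construct the predictor indicates (the structure indirect
    # range-restriction corrections assume: selection is independent of the
    # predictor's measurement error); the "observed" basis selects on the
    # error-laden score itself, whose w = 1 limit is classical direct
    # selection (and under which indirect corrections overcorrect).
    basis = t if config.selection_basis == "construct" else x
    s = config.w * basis + math.sqrt(1 - config.w ** 2) * rng.standard_normal(n)
    n_entrants = int(round(config.selection_fraction * n))
    if n_entrants < 50:
        raise ValueError(
            f"selection fraction {config.selection_fraction} admits only "
            f"{n_entrants} entrants; need at least 50"
        )
    order = np.argsort(s)[::-1]
    admitted = np.zeros(n, dtype=bool)
    admitted[order[:n_entrants]] = True

    # rescale to the reporting scale, then censor at the applicant quantile
    x_points = config.predictor_mean + config.predictor_sd * x
    if config.ceiling_quantile < 1:
        ceiling = float(np.quantile(x_points, config.ceiling_quantile))
    else:
        ceiling = math.inf
    applicants = CensoredSample.from_values(x_points, ceiling)

    y_ent = y[admitted]
    if config.outcome_mode == "ordinal":
        y_out = bin_outcome(y_ent, config.ordinal_cuts)
    elif config.outcome_mode == "binary":
        y_out = bin_outcome(y_ent, (config.binary_cut,))
    else:
        y_out = y_ent

    sd_a = float(x_points.std(ddof=1))
    sd_i = float(x_points[admitted].std(ddof=1))
    u = sd_i / sd_a
    var_p_i = float(p[admitted].var(ddof=1))
    r_yyi = config.r_YYa * var_p_i / (config.r_YYa * var_p_i + (1 - config.r_YYa))
    var_t_i = float(t[admitted].var(ddof=1))
    r_xxi = config.r_XXa * var_t_i / (config.r_XXa * var_t_i + (1 - config.r_XXa))

    truth = {
        "rho_true": config.rho_true,
        "model": SevenParameterModel(
            mu_a=float(x_points.mean()), sigma_a=sd_a,
            mu_i=float(x_points[admitted].mean()), sigma_i=sd_i,
            mu_y=float(y_ent.mean()), sigma_y=float(y_ent.std(ddof=1)),
            r_i=float(np.corrcoef(x_points[admitted], y_ent)[0, 1]),
        ),
        "u": u,
        "r_XXa": config.r_XXa,
        "r_YYa": config.r_YYa,
        "r_YYi": r_yyi,
        "r_XXi": r_xxi,
        "ceiling": ceiling,
        "n_entrants": n_entrants,
    }
    return SyntheticCohort(
        applicants=applicants,
        entrants_x=np.minimum(x_points[admitted], ceiling),
        entrants_y=y_out,
        entrants_x_latent=x_points[admitted],
        ceiling=ceiling,
        config=config,
        truth=truth,
    )


def bin_outcome(y, cuts) -> np.ndarray:
    """Bin continuous outcomes into ordinal categories at quantile cuts."""
    y = np.asarray(y, dtype=float)
    cuts = np.asarray(cuts, dtype=float)
    if cuts.size == 0 or np.any((cuts <= 0) | (cuts >= 1)):
        raise ValueError("cuts must lie strictly inside (0, 1)")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("cuts must be strictly increasing")
    edges = np.quantile(y, cuts)
    labels = np.searchsorted(edges, y, side="right")
    counts = np.bincount(labels, minlength=cuts.size + 1)
    if np.any(counts == 0):
        raise ValueError(f"empty outcome bin; occupancy {counts.tolist()}")
    return labels
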