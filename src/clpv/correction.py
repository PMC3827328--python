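"""Hunter-Schmidt-Le correction for indirect range restriction and unreliability.

Turns an entrant-pool predictor-outcome correlation into a construct-level
predictive validity (CLPV): the correlation between the latent constructs in
the whole applicant pool.  The correction chain is the Case IV procedure for
indirect selection: restrict the predictor reliability to the entrant pool,
infer the true-score selection ratio, disattenuate the entrant correlation
for unreliability of both measures, then undo range restriction on the
true-score metric.  Applied per MCMC draw, it yields a CLPV with a standard
error and percentile interval, from which an "equivalent N" can be
back-calculated for meta-analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .mcmc import Chain

__all__ = [
    "ReliabilitySpec",
    "SelectionRatio",
    "CLPVEstimate",
    "DEFAULT_PREDICTOR_RELIABILITY",
    "DEFAULT_OUTCOME_RELIABILITY",
    "DEFAULT_SELECTION_RATIOS",
    "selection_ratio",
    "restrict_reliability",
    "hsl_case_iv",
    "clpv_with_uncertainty",
    "equivalent_n",
]

# Observed averages across the selection measures this package targets; used
# (and logged) when a study supplies no reliability of its own.
DEFAULT_PREDICTOR_RELIABILITY = 0.815
DEFAULT_OUTCOME_RELIABILITY = 0.834

# Median selection ratios by predictor class, for cohorts with no applicant
# data of their own.
DEFAULT_SELECTION_RATIOS = {
    "A-levels": 0.664,
    "GCSEs/O-levels": 0.690,
    "aptitude": 0.750,
}


@dataclass(frozen=True)
class ReliabilitySpec:
    """r_XXa: predictor reliability in applicants (unrestricted);
    r_YYi: outcome reliability in entrants (restricted)."""

    r_XXa: float = DEFAULT_PREDICTOR_RELIABILITY
    r_YYi: float = DEFAULT_OUTCOME_RELIABILITY

    def __post_init__(self) -> None:
        for name in ("r_XXa", "r_YYi"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class SelectionRatio:
    """u = sigma_entrants / sigma_applicants; < 1 under selection."""

    u: float

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError(f"selection ratio must be positive, got {self.u}")
        if self.u > 1:
            warnings.warn(
                f"selection ratio u = {self.u:.3f} exceeds 1; entrants are "
                "more variable than applicants", stacklevel=3)


@dataclass(frozen=True)
class CLPVEstimate:
    rho: float
    se: float
    ci: tuple
    equivalent_n: float | None = None
    n_draws: int = 0
    n_rejected: int = 0
    reliable: bool = True

    def as_dict(self) -> dict:
        return {
            "rho": self.rho, "se": self.se, "ci": list(self.ci),
            "equivalent_n": self.equivalent_n, "n_draws": self.n_draws,
            "n_rejected": self.n_rejected, "reliable": self.reliable,
        }


def selection_ratio(sd_entrants: float, sd_applicants: float) -> SelectionRatio:
    """u from decensored (latent) predictor SDs in entrants and applicants."""
    if sd_entrants <= 0 or sd_applicants <= 0:
        raise ValueError(
            f"SDs must be positive (entrants {sd_entrants}, applicants {sd_applicants})")
    return SelectionRatio(sd_entrants / sd_applicants)


def restrict_reliability(r_XXa: float, u) -> float:
    """Predictor reliability in the restricted (entrant) pool.

    Selection shrinks true-score variance but leaves error variance alone,
    so r_XXi = 1 - (1 - r_XXa)/u^2.  Requires u^2 > 1 - r_XXa, else the
    implied entrant true-score variance is non-positive.
    """
    u = u.u if isinstance(u, SelectionRatio) else float(u)
    if not 0 < r_XXa <= 1:
        raise ValueError(f"reliability must be in (0, 1], got {r_XXa}")
    u2 = u * u
    if u2 <= 1 - r_XXa:
        raise ValueError(
            f"u^2 = {u2:.4f} <= 1 - r_XXa = {1 - r_XXa:.4f}: selection this "
            "strong is inconsistent with the stated applicant reliability")
    r_xxi = 1 - (1 - r_XXa) / u2
    if r_xxi < 0.1:
        warnings.warn(
            f"restricted reliability r_XXi = {r_xxi:.3f} is near-degenerate",
            stacklevel=2)
    return r_xxi


def hsl_case_iv(r_i: float, r_XXa: float, r_YYi: float, u) -> float:
    """Construct-level predictive validity from the entrant correlation.

    Steps: r_XXi = 1 - (1-r_XXa)/u^2; true-score selection ratio
    u_T = sqrt((u^2 - (1-r_XXa))/r_XXa); disattenuation
    r_TPi = r_i / sqrt(r_XXi * r_YYi); then the range-restriction reversal
    rho = (r_TPi/u_T) / sqrt(1 + r_TPi^2 (1/u_T^2 - 1)).  With reliabilities
    of one and u of one the chain collapses to rho = r_i.  Output clipped to
    (-1, 1) with a warning if an extreme draw lands outside.
    """
    u = u.u if isinstance(u, SelectionRatio) else float(u)
    if not abs(r_i) < 1:
        raise ValueError(f"|r_i| must be < 1, got {r_i}")
    if not 0 < r_YYi <= 1:
        raise ValueError(f"r_YYi must be in (0, 1], got {r_YYi}")
    r_xxi = restrict_reliability(r_XXa, u)
    u_t = math.sqrt((u * u - (1 - r_XXa)) / r_XXa)
    r_tpi = r_i / math.sqrt(r_xxi * r_YYi)
    if abs(r_tpi) >= 1:
        raise ValueError(
            f"disattenuated entrant correlation r_TPi = {r_tpi:.4f} is out of "
            "range; the inputs are mutually inconsistent")
    rho = (r_tpi / u_t) / math.sqrt(1 + r_tpi * r_tpi * (1 / (u_t * u_t) - 1))
    if abs(rho) >= 1:
        warnings.warn(f"CLPV {rho:.4f} clipped to the open unit interval",
                      stacklevel=2)
        rho = math.copysign(1 - 1e-12, rho)
    return float(rho)


def clpv_with_uncertainty(chain: Chain, rel: ReliabilitySpec,
                          sigma_a_index: int = 1, sigma_i_index: int = 3,
                          r_index: int = -1) -> CLPVEstimate:
    """Propagate the correction through every retained MCMC draw.

    For each retained draw, u is that draw's sigma_i/sigma_a and r_i that
    draw's correlation; the per-draw CLPVs give the estimate (mean), its
    standard error (SD) and the 2.5th/97.5th percentile interval, plus the
    equivalent N implied by the SE.  If more than 5% of draws violate the
    correction's preconditions the estimate is flagged unreliable.
    """
    seg = chain.retained
    rhos = []
    rejected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in seg:
            try:
                u = float(row[sigma_i_index] / row[sigma_a_index])
                rhos.append(hsl_case_iv(float(row[r_index]), rel.r_XXa,
                                        rel.r_YYi, u))
            except (ValueError, ZeroDivisionError):
                rejected += 1
    if not rhos:
        raise ValueError("every chain draw violated the correction preconditions")
    rhos = np.asarray(rhos)
    rho = float(rhos.mean())
    se = float(rhos.std(ddof=1)) if rhos.size > 1 else 0.0
    lo, hi = (np.percentile(rhos, [2.5, 97.5]) if rhos.size > 1
              else (rho, rho))
    eq_n = equivalent_n(rho, se) if se > 0 else None
    return CLPVEstimate(rho=rho, se=se, ci=(float(lo), float(hi)),
                        equivalent_n=eq_n, n_draws=seg.shape[0],
                        n_rejected=rejected,
                        reliable=rejected <= 0.05 * seg.shape[0])


def equivalent_n(rho: float, se: float) -> float:
    """Sample size whose plain-correlation SE matches the chain-derived SE.

    Inverts SE(r) = (1 - r^2)/sqrt(n - 1):  n = ((1 - rho^2)/se)^2 + 1.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    n = ((1 - rho * rho) / se) ** 2 + 1
    if n < 4:
        warnings.warn(
            f"equivalent N = {n:.1f} is below 4; the SE is too large for a "
            "correlation-type effect", stacklevel=2)
    return float(n)
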