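"""End-to-end estimation: censored fit -> MCMC -> correction -> equivalent N.

Glues the pieces into the estimation route a study runs per
predictor/outcome pair: fit the seven-parameter censored model by maximum
likelihood, sample its posterior with DRAM, push every retained draw through
the Hunter-Schmidt-Le correction, and report the CLPV with its chain-derived
standard error, percentile interval and equivalent N.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .censored import (CensoredSample, OutcomeSpec, SevenParameterLogPost,
                       fit_seven_parameter_mle)
from .correction import (CLPVEstimate, ReliabilitySpec, clpv_with_uncertainty,
                         DEFAULT_SELECTION_RATIOS, hsl_case_iv, equivalent_n)
from .mcmc import Chain, ChainConfig, run_dram, summarize_chain

__all__ = ["EstimateResult", "estimate_clpv", "estimate_clpv_from_summary"]


@dataclass
class EstimateResult:
    clpv: CLPVEstimate
    chain: Chain
    summary: object
    mle: object
    rel: ReliabilitySpec
    warnings: list = field(default_factory=list)

    def record(self) -> dict:
        """One machine-readable row suitable for the meta-regression stage."""
        out = {
            "rho": self.clpv.rho,
            "se": self.clpv.se,
            "ci_low": self.clpv.ci[0],
            "ci_high": self.clpv.ci[1],
            "equivalent_n": self.clpv.equivalent_n,
            "r_XXa": self.rel.r_XXa,
            "r_YYi": self.rel.r_YYi,
            "acceptance_rate": self.chain.acceptance_rate,
            "warnings": list(self.warnings),
        }
        out["parameters"] = self.summary.as_dict()
        return out


def _numerical_hessian(f, x0, rel_step: float = 1e-4):
    """Central-difference Hessian of a scalar function (for proposal scaling)."""
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    h = np.maximum(np.abs(x0), 1.0) * rel_step
    H = np.empty((d, d))
    f0 = f(x0)
    for i in range(d):
        for j in range(i, d):
            xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _proposal_cov(logpost, theta):
    """Inverse observed-information proposal covariance, with fallbacks."""
    try:
        H = _numerical_hessian(logpost, theta)
        cov = np.linalg.inv(-H)
        # must be symmetric positive definite to be usable
        np.linalg.cholesky((cov + cov.T) / 2 + 1e-12 * np.eye(theta.size))
        return (cov + cov.T) / 2
    except np.linalg.LinAlgError:
        scale = np.maximum(np.abs(theta), 0.1) * 0.02
        return np.diag(scale ** 2)


def estimate_clpv(applicants: CensoredSample, entrants_x, entrants_y,
                  rel: ReliabilitySpec,
                  spec: OutcomeSpec | None = None,
                  ceiling: float = math.inf,
                  chain_config: ChainConfig | None = None) -> EstimateResult:
    """Full estimation for one cohort's predictor/outcome pair."""
    chain_config = chain_config or ChainConfig()
    spec = spec or OutcomeSpec()
    logpost = SevenParameterLogPost(applicants, entrants_x, entrants_y,
                                    spec=spec, ceiling=ceiling)
    mle = fit_seven_parameter_mle(applicants, entrants_x, entrants_y,
                                  spec=spec, ceiling=ceiling)
    theta0 = logpost.free_from_model(mle.params)
    cov0 = _proposal_cov(logpost, theta0)
    chain = run_dram(logpost, theta0, chain_config, init_cov=cov0,
                     param_names=logpost.free_names)
    summary = summarize_chain(chain)
    names = logpost.free_names
    clpv = clpv_with_uncertainty(
        chain, rel,
        sigma_a_index=names.index("sigma_a"),
        sigma_i_index=names.index("sigma_i"),
        r_index=names.index("r_i"))
    warns = []
    if not summary.equilibrium_ok:
        warns.append("chain trend test flags possible non-equilibrium")
    if not clpv.reliable:
        warns.append(f"{clpv.n_rejected} draws violated correction preconditions")
    if not (0.1 < chain.acceptance_rate < 0.6):
        warns.append(f"acceptance rate {chain.acceptance_rate:.2f} outside (.1, .6)")
    return EstimateResult(clpv=clpv, chain=chain, summary=summary, mle=mle,
                          rel=rel, warnings=warns)


def estimate_clpv_from_summary(r_i: float, rel: ReliabilitySpec,
                               u: float | None = None,
                               predictor_class: str | None = None) -> dict:
    """Point correction when only summary statistics are available.

    When a cohort has no applicant data, ``u`` may be omitted and a default
    selection ratio looked up by predictor class; the default used is
    reported alongside the estimate.
    """
    used_default = False
    if u is None:
        if predictor_class not in DEFAULT_SELECTION_RATIOS:
            raise ValueError(
                f"no selection ratio and no default for {predictor_class!r}; "
                f"known classes: {sorted(DEFAULT_SELECTION_RATIOS)}")
        u = DEFAULT_SELECTION_RATIOS[predictor_class]
        used_default = True
    rho = hsl_case_iv(r_i, rel.r_XXa, rel.r_YYi, u)
    return {"rho": rho, "u": u, "u_defaulted": used_default,
            "r_XXa": rel.r_XXa, "r_YYi": rel.r_YYi}
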