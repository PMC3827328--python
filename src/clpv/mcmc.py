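"""Delayed-rejection adaptive Metropolis (DRAM) sampling and chain summaries.

A single-chain random-walk Metropolis sampler whose proposal covariance is
re-estimated from the chain history at a fixed interval (adaptive
Metropolis), with a delayed-rejection fallback: when a proposal is rejected,
a second proposal with a shrunken covariance is tried, accepted with the
two-stage probability that preserves the stationary distribution.  Chain
summaries follow the convention of estimating parameters from the final
segment of the chain only, with posterior means as estimates, posterior SDs
as standard errors, and 2.5th/97.5th percentiles as the 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ChainConfig", "Chain", "ChainSummary", "run_dram", "summarize_chain"]


@dataclass(frozen=True)
class ChainConfig:
    """Sampler settings.

    ``length`` total iterations and ``use_last`` retained for summaries
    (everything earlier is burn-in); ``adapt_interval`` iterations between
    covariance re-estimations; ``dr_stages`` delayed-rejection retries (0
    disables); ``dr_shrink`` scale factor on the proposal SD at the retry;
    ``scale`` multiplies the 2.38/sqrt(d) random-walk scaling.
    """

    length: int = 5000
    use_last: int = 2000
    seed: int = 0
    adapt_interval: int = 100
    adapt_start: int = 200
    dr_stages: int = 1
    dr_shrink: float = 0.5
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("chain length must be at least 1000")
        if not 0 < self.use_last < self.length:
            raise ValueError("use_last must be positive and below length")
        if self.adapt_interval < 1 or not 0 < self.dr_shrink < 1:
            raise ValueError("bad adaptation settings")


@dataclass
class Chain:
    draws: np.ndarray                 # (length, d)
    logpost: np.ndarray               # (length,)
    acceptance_rate: float
    config: ChainConfig
    param_names: tuple = ()

    @property
    def retained(self) -> np.ndarray:
        return self.draws[-self.config.use_last:]


@dataclass
class ChainSummary:
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_used: int
    param_names: tuple = ()
    equilibrium_ok: bool = True
    trend_pvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        names = self.param_names or tuple(f"p{i}" for i in range(self.mean.size))
        return {
            name: {
                "estimate": float(self.mean[i]),
                "se": float(self.sd[i]),
                "ci": [float(self.ci_low[i]), float(self.ci_high[i])],
            }
            for i, name in enumerate(names)
        }


def _tri_solve(chol, vec):
    from scipy.linalg import solve_triangular
    return solve_triangular(chol, vec, lower=True, check_finite=False)


def run_dram(logpost, init, config: ChainConfig,
             init_cov: np.ndarray | None = None,
             param_names: tuple = (),
             validate=None) -> Chain:
    """Sample ``logpost`` with DRAM starting from ``init``.

    ``init_cov`` seeds the proposal covariance (defaults to a diagonal built
    from the initial state's magnitudes); ``validate`` is an optional
    predicate that marks states out of support (their log-posterior is
    treated as -inf without being evaluated).  Identical seed, config and
    target give an identical chain.
    """
    init = np.asarray(init, dtype=float)
    d = init.size
    lp0 = float(logpost(init))
    if not math.isfinite(lp0):
        raise ValueError(
            "log-posterior is not finite at the initial state; "
            "initialise from a maximum-likelihood fit"
        )
    rng = np.random.default_rng(config.seed)
    sd_scale = config.scale * 2.38 / math.sqrt(d)
    if init_cov is None:
        diag = np.maximum(np.abs(init), 0.1) * 0.05
        init_cov = np.diag(diag ** 2)
    cov = sd_scale ** 2 * np.asarray(init_cov, dtype=float)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))

    draws = np.empty((config.length, d))
    lps = np.empty(config.length)
    current, lp_cur = init.copy(), lp0
    accepted = 0

    def eval_lp(x):
        if validate is not None and not validate(x):
            return -math.inf
        return float(logpost(x))

    for i in range(config.length):
        xi = rng.standard_normal(d)
        y1 = current + chol @ xi
        lp1 = eval_lp(y1)
        log_a1 = lp1 - lp_cur
        if math.log(rng.random()) < log_a1:
            current, lp_cur = y1, lp1
            accepted += 1
        elif config.dr_stages > 0:
            # delayed rejection: shrunken second-stage proposal; the
            # acceptance probability keeps the first-stage proposal-density
            # ratio q1(y1|y2)/q1(y1|x) so detailed balance holds
            y2 = current + config.dr_shrink * (chol @ rng.standard_normal(d))
            lp2 = eval_lp(y2)
            if math.isfinite(lp2):
                log_a1_rev = min(0.0, lp1 - lp2)
                log_a1_fwd = min(0.0, log_a1)
                num = 1.0 - math.exp(log_a1_rev)
                den = 1.0 - math.exp(log_a1_fwd)
                if den > 0 and num > 0:
                    u1 = _tri_solve(chol, y1 - y2)
                    logq = -0.5 * (float(u1 @ u1) - float(xi @ xi))
                    log_a2 = (lp2 - lp_cur + logq
                              + math.log(num) - math.log(den))
                    if math.log(rng.random()) < log_a2:
                        current, lp_cur = y2, lp2
                        accepted += 1
        draws[i] = current
        lps[i] = lp_cur

        if (i + 1) >= config.adapt_start and (i + 1) % config.adapt_interval == 0:
            hist = draws[: i + 1]
            emp = np.cov(hist, rowvar=False)
            emp = np.atleast_2d(emp)
            cov = sd_scale ** 2 * (emp + 1e-10 * np.eye(d))
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass  # keep the previous factor

    return Chain(draws, lps, accepted / config.length, config, param_names)


def summarize_chain(chain: Chain, config: ChainConfig | None = None) -> ChainSummary:
    """Summaries over exactly the final ``use_last`` draws.

    Besides moments and percentile intervals, regresses each retained
    parameter trace on iteration number; a slope significant at p < .01 for
    any parameter flags the chain as not yet at equilibrium.
    """
    config = config or chain.config
    if config.use_last > chain.draws.shape[0]:
        raise ValueError("use_last exceeds the chain length")
    seg = chain.draws[-config.use_last:]
    mean = seg.mean(axis=0)
    sd = seg.std(axis=0, ddof=1)
    lo, hi = np.percentile(seg, [2.5, 97.5], axis=0)

    # Trend test on a thinned trace: widely spaced draws are nearly
    # independent, so the regression p-value is not wrecked by the
    # autocorrelation of consecutive MCMC states.
    step = max(1, seg.shape[0] // 100)
    thin = seg[::step]
    t = np.arange(thin.shape[0], dtype=float)
    pvals = np.ones(seg.shape[1])
    for j in range(seg.shape[1]):
        col = thin[:, j]
        if np.ptp(col) == 0:
            continue
        res = stats.linregress(t, col)
        pvals[j] = res.pvalue
    return ChainSummary(mean, sd, lo, hi, seg.shape[0],
                        param_names=chain.param_names,
                        equilibrium_ok=bool(np.all(pvals >= 0.01)),
                        trend_pvalues=pvals)
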