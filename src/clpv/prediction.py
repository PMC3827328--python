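"""Closed-form downstream predictions from a construct-level validity.

Once a CLPV is in hand, simple normal-theory algebra predicts what entrants
from outside the usual grade range would do: attenuate the CLPV back to the
observed scale, place a grade profile as a z-score in the decensored
applicant pool, regress the standardized outcome on that z, and convert
base-rate cutoffs (failure or retake rates among conventional students) into
predicted rates for lower-grade entrants.  Also provides the A*-type
grade-increment projection and the Fisher-z power/sample-size formula for
detecting predictor-outcome correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AttenuationInput", "PredictionScenario", "attenuate", "predictor_z",
    "expected_outcome_z", "tail_rate", "grade_increment_effect",
    "sample_size_for_power", "scenario_table",
]


@dataclass(frozen=True)
class AttenuationInput:
    rho: float
    r_XX: float
    r_YY: float

    def __post_init__(self) -> None:
        for name in ("rho", "r_XX", "r_YY"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def attenuate(rho: float, r_XX: float, r_YY: float) -> float:
    """Observed-scale correlation implied by a CLPV and two reliabilities:
    r_att = rho * sqrt(r_XX * r_YY)."""
    AttenuationInput(rho, r_XX, r_YY)
    return rho * math.sqrt(r_XX * r_YY)


def predictor_z(points: float, pool_mean: float, pool_sd: float) -> float:
    """Standing of a tariff-point total in the decensored applicant pool."""
    if pool_sd <= 0:
        raise ValueError("pool_sd must be positive")
    return (points - pool_mean) / pool_sd


def expected_outcome_z(z: float, r_att: float) -> float:
    """Regression prediction of the standardized outcome: r_att * z."""
    if not abs(r_att) < 1:
        raise ValueError(f"|r_att| must be < 1, got {r_att}")
    return r_att * z


def tail_rate(base_rate: float, z: float, r_att: float,
              conditional_sd: bool = False) -> float:
    """Predicted failure/retake rate for a student at predictor z.

    The cutoff is the standard-normal quantile of ``base_rate`` (the rate
    among conventional, mean-level students); the student's outcome is
    modelled as normal with mean r_att * z and unit SD, giving
    Phi(z_cut - r_att * z).  ``conditional_sd=True`` swaps in the
    residual SD sqrt(1 - r_att^2) for the strict conditional-normal variant.
    """
    if not 0 < base_rate < 1:
        raise ValueError(f"base_rate must be in (0, 1), got {base_rate}")
    if not abs(r_att) < 1:
        raise ValueError(f"|r_att| must be < 1, got {r_att}")
    z_cut = stats.norm.ppf(base_rate)
    sd = math.sqrt(1 - r_att * r_att) if conditional_sd else 1.0
    return float(stats.norm.cdf((z_cut - r_att * z) / sd))


def grade_increment_effect(delta_points: float, pool_sd: float,
                           r_att: float) -> float:
    """Expected outcome gain (in SDs) from extra tariff points:
    r_att * delta_points / pool_sd."""
    if pool_sd <= 0:
        raise ValueError("pool_sd must be positive")
    return r_att * delta_points / pool_sd


def sample_size_for_power(r: float, alpha: float = 0.05, power: float = 0.9,
                          tails: int = 1) -> int:
    """Sample size to detect a correlation r at the given alpha and power.

    Fisher-z approximation: n = ((z_{1-alpha/tails} + z_{power})/atanh(r))^2 + 3,
    reported to the nearest integer.
    """
    if not 0 < r < 1:
        raise ValueError(f"r must be in (0, 1), got {r}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    z_a = stats.norm.ppf(1 - alpha / tails)
    z_b = stats.norm.ppf(power)
    n = ((z_a + z_b) / math.atanh(r)) ** 2 + 3
    return int(round(n))


@dataclass(frozen=True)
class PredictionScenario:
    """Inputs for an out-of-range prediction table.

    ``pool_mean``/``pool_sd`` are decensored applicant tariff moments;
    ``rho`` the CLPV with its two reliabilities; ``base_rates`` maps rate
    names (e.g. "failure", "retake") to the rates observed in conventional
    students; ``profiles`` maps grade-profile labels to tariff points.
    """

    pool_mean: float
    pool_sd: float
    rho: float
    r_XX: float
    r_YY: float
    base_rates: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)

    @property
    def r_att(self) -> float:
        return attenuate(self.rho, self.r_XX, self.r_YY)


def scenario_table(scenario: PredictionScenario):
    """Grade profile -> predictor z, expected outcome z, and each tail rate.

    Returns a pandas DataFrame (one row per profile); empty profiles give an
    empty table.
    """
    import pandas as pd

    r_att = scenario.r_att
    rows = []
    for label, points in scenario.profiles.items():
        z = predictor_z(points, scenario.pool_mean, scenario.pool_sd)
        row = {
            "profile": label,
            "points": points,
            "predictor_z": z,
            "expected_outcome_z": expected_outcome_z(z, r_att),
        }
        for name, base in scenario.base_rates.items():
            row[f"{name}_pct"] = 100.0 * tail_rate(base, z, r_att)
        rows.append(row)
    cols = ["profile", "points", "predictor_z", "expected_outcome_z"] + [
        f"{name}_pct" for name in scenario.base_rates]
    return pd.DataFrame(rows, columns=cols)
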