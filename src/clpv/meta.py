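"""Random-effects pooling and meta-regression of correlation-type effects.

Study validities (plain predictor-outcome correlations or CLPVs with their
equivalent N) are transformed to Fisher z with within-study variance
1/(n - 3); between-study variance tau^2 is estimated by the DerSimonian-Laird
method of moments (its meta-regression generalisation when moderators are
present); pooling and coefficients come from weighted least squares with
random-effects weights 1/(v_i + tau^2).  Q_B is the moderator chi-square
(Wald test that all non-intercept coefficients vanish) and Q_E the residual
heterogeneity statistic.  Pooled means are back-transformed to the r scale.
A raw-r pooling mode (Hunter-Schmidt style, no z transform, weights n_i) is
available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StudyEffect", "MetaModel", "pool_random_effects", "meta_regress",
           "variance_from_ci"]

# Stage-of-training coding used when the outcome stage enters as a
# continuous "years of training" moderator.
YEAR_OF_TRAINING = {
    "BMS1": 1, "BMSoverall": 2, "Finals": 5,
    "MRCP1": 8, "MRCP2": 9, "MRCPclinical": 10, "SpecialistRegister": 12,
}


@dataclass(frozen=True)
class StudyEffect:
    """One validity coefficient with its moderators.

    ``n`` is the actual N for plain correlations or the equivalent N for
    CLPVs; alternatively ``var_z`` supplies the Fisher-z variance directly
    (e.g. derived from a published confidence interval).
    """

    r: float
    n: float | None = None
    var_z: float | None = None
    predictor_class: str = ""
    outcome_stage: str = ""
    cohort: str = ""
    year_of_entry: float | None = None
    year_of_training: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError(f"|r| must be < 1, got {self.r} ({self.label})")
        if self.n is None and self.var_z is None:
            raise ValueError(f"study {self.label!r} needs n or var_z")
        if self.n is not None and self.n <= 3:
            raise ValueError(
                f"study {self.label!r} has n = {self.n} <= 3; its Fisher-z "
                "variance is undefined")

    @property
    def z(self) -> float:
        return math.atanh(self.r)

    @property
    def variance(self) -> float:
        if self.var_z is not None:
            return self.var_z
        return 1.0 / (self.n - 3.0)


def variance_from_ci(lo: float, hi: float, level: float = 0.95) -> float:
    """Fisher-z variance implied by a published CI on the r scale."""
    if not (-1 < lo < hi < 1):
        raise ValueError("CI bounds must satisfy -1 < lo < hi < 1")
    zcrit = stats.norm.ppf(0.5 + level / 2)
    se = (math.atanh(hi) - math.atanh(lo)) / (2 * zcrit)
    return se * se


@dataclass
class MetaModel:
    coefficients: np.ndarray
    coef_se: np.ndarray
    coef_names: tuple
    tau2: float
    q_between: float
    df_between: int
    p_between: float
    q_residual: float
    df_residual: int
    pooled_r: float | None = None
    pooled_ci: tuple | None = None
    k: int = 0
    scale: str = "fisher-z"
    fitted_z: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        out = {
            "k": self.k,
            "scale": self.scale,
            "tau2": self.tau2,
            "Q_B": self.q_between, "df_B": self.df_between, "p_B": self.p_between,
            "Q_E": self.q_residual, "df_E": self.df_residual,
            "coefficients": {
                name: {"estimate": float(b), "se": float(s)}
                for name, b, s in zip(self.coef_names, self.coefficients,
                                      self.coef_se)
            },
        }
        if self.pooled_r is not None:
            out["pooled_r"] = self.pooled_r
            out["pooled_ci"] = list(self.pooled_ci)
        return out


def _effects_arrays(effects):
    effects = list(effects)
    if not effects:
        raise ValueError("no effects supplied")
    z = np.array([e.z for e in effects])
    v = np.array([e.variance for e in effects])
    return effects, z, v


def _dl_tau2(z, v, X):
    """DerSimonian-Laird moment estimator, meta-regression form."""
    w = 1.0 / v
    W = np.diag(w)
    XtW = X.T * w
    M = XtW @ X
    Minv = np.linalg.inv(M)
    H = X @ Minv @ XtW          # FE hat matrix
    resid = z - H @ z
    q = float(resid @ (w * resid))
    p = X.shape[1]
    # E[Q] = (k - p) + tau2 * (tr(W) - tr((X'WX)^-1 X'W^2X))
    trace_term = float(np.trace(W) - np.trace(Minv @ (X.T * (w * w)) @ X))
    tau2 = max(0.0, (q - (len(z) - p)) / trace_term) if trace_term > 0 else 0.0
    return tau2, q


def _wls(z, v, X, tau2):
    w = 1.0 / (v + tau2)
    M = (X.T * w) @ X
    Minv = np.linalg.inv(M)
    beta = Minv @ (X.T @ (w * z))
    return beta, Minv, w


def pool_random_effects(effects, raw_r: bool = False) -> MetaModel:
    """Random-effects pooled mean of correlation-type effects.

    Default route: Fisher z, DL tau^2, inverse-variance weights, CI
    back-transformed to r.  ``raw_r=True`` pools untransformed correlations
    with sample-size weights and a matching moments tau^2 (a
    Hunter-Schmidt-style sensitivity check).
    """
    effects, z, v = _effects_arrays(effects)
    k = len(effects)
    if raw_r:
        r = np.array([e.r for e in effects])
        n = np.array([e.n if e.n is not None else 1.0 / e.variance + 3 for e in effects])
        rbar = float(np.sum(n * r) / n.sum())
        var_obs = float(np.sum(n * (r - rbar) ** 2) / n.sum())
        var_err = float(np.mean((1 - rbar ** 2) ** 2 / (n - 1)))
        tau2 = max(0.0, var_obs - var_err)
        se = math.sqrt((var_obs if k > 1 else var_err) / k)
        ci = (rbar - 1.959964 * se, rbar + 1.959964 * se)
        return MetaModel(
            coefficients=np.array([rbar]), coef_se=np.array([se]),
            coef_names=("mean_r",), tau2=tau2, q_between=0.0, df_between=0,
            p_between=1.0, q_residual=float("nan"), df_residual=k - 1,
            pooled_r=rbar, pooled_ci=ci, k=k, scale="raw-r")
    X = np.ones((k, 1))
    if k == 1:
        zb = z[0]
        se = math.sqrt(v[0])
        return MetaModel(
            coefficients=np.array([zb]), coef_se=np.array([se]),
            coef_names=("intercept",), tau2=0.0, q_between=0.0, df_between=0,
            p_between=1.0, q_residual=0.0, df_residual=0,
            pooled_r=float(np.tanh(zb)),
            pooled_ci=(float(np.tanh(zb - 1.959964 * se)),
                       float(np.tanh(zb + 1.959964 * se))),
            k=1)
    tau2, q = _dl_tau2(z, v, X)
    beta, Minv, w = _wls(z, v, X, tau2)
    se = math.sqrt(Minv[0, 0])
    zb = float(beta[0])
    return MetaModel(
        coefficients=beta, coef_se=np.array([se]), coef_names=("intercept",),
        tau2=tau2, q_between=0.0, df_between=0, p_between=1.0,
        q_residual=q, df_residual=k - 1,
        pooled_r=float(np.tanh(zb)),
        pooled_ci=(float(np.tanh(zb - 1.959964 * se)),
                   float(np.tanh(zb + 1.959964 * se))),
        k=k, fitted_z=np.full(k, zb))


def _design_matrix(effects, moderators):
    """Build intercept + dummy/linear columns from StudyEffect moderators."""
    cols = {"intercept": np.ones(len(effects))}
    frame = pd.DataFrame({
        "predictor_class": [e.predictor_class for e in effects],
        "outcome_stage": [e.outcome_stage for e in effects],
        "cohort": [e.cohort for e in effects],
        "year_of_entry": [e.year_of_entry for e in effects],
        "year_of_training": [e.year_of_training for e in effects],
    })
    for term in moderators:
        parts = term.split(":")
        built = np.ones(len(effects))
        name_bits = []
        for part in parts:
            if part in ("year_of_entry", "year_of_training"):
                vals = frame[part].astype(float).to_numpy()
                if np.any(~np.isfinite(vals)):
                    raise ValueError(f"moderator {part!r} has missing values")
                built = built * vals
                name_bits.append(part)
            elif part in ("predictor_class", "outcome_stage", "cohort"):
                dummies = pd.get_dummies(frame[part], prefix=part,
                                         drop_first=True, dtype=float)
                sub = {}
                for col in dummies.columns:
                    sub[col] = built * dummies[col].to_numpy()
                built = sub  # dict of columns
                name_bits.append(part)
            else:
                raise ValueError(f"unknown moderator {part!r}")
            if isinstance(built, dict):
                break
        if isinstance(built, dict):
            if len(parts) > len(name_bits):
                raise ValueError(
                    "categorical terms must come last in an interaction")
            cols.update(built)
        else:
            cols[":".join(name_bits)] = built
    names = tuple(cols)
    X = np.column_stack([cols[n] for n in names])
    return X, names


def meta_regress(effects, moderators) -> MetaModel:
    """Random-effects meta-regression of Fisher-z effects on moderators.

    ``moderators`` is a list of terms: categorical fields
    (``predictor_class``, ``outcome_stage``, ``cohort``) expand to dummy
    columns; ``year_of_entry`` / ``year_of_training`` enter linearly;
    ``a:b`` denotes an interaction.  Q_B tests all non-intercept
    coefficients jointly (chi-square, df = their number).
    """
    effects, z, v = _effects_arrays(effects)
    if len(effects) < 2:
        raise ValueError("meta-regression needs at least 2 effects")
    X, names = _design_matrix(effects, moderators)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank-revealing QR on the scaled matrix
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [names[j] for j in range(X.shape[1])
                   if diag[j] < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; aliased: {aliased}")
    tau2, _ = _dl_tau2(z, v, X)
    beta, Minv, w = _wls(z, v, X, tau2)
    se = np.sqrt(np.diag(Minv))
    fitted = X @ beta
    q_e = float(np.sum(w * (z - fitted) ** 2))
    df_e = len(effects) - X.shape[1]
    # Wald chi-square for the non-intercept block
    idx = [j for j, nm in enumerate(names) if nm != "intercept"]
    if idx:
        b = beta[idx]
        Vb = Minv[np.ix_(idx, idx)]
        q_b = float(b @ np.linalg.solve(Vb, b))
        df_b = len(idx)
        p_b = float(stats.chi2.sf(q_b, df_b))
    else:
        q_b, df_b, p_b = 0.0, 0, 1.0
    pooled_r = pooled_ci = None
    if not idx:
        zb, sez = float(beta[0]), float(se[0])
        pooled_r = float(np.tanh(zb))
        pooled_ci = (float(np.tanh(zb - 1.959964 * sez)),
                     float(np.tanh(zb + 1.959964 * sez)))
    return MetaModel(coefficients=beta, coef_se=se, coef_names=names,
                     tau2=tau2, q_between=q_b, df_between=df_b, p_between=p_b,
                     q_residual=q_e, df_residual=df_e,
                     pooled_r=pooled_r, pooled_ci=pooled_ci,
                     k=len(effects), fitted_z=fitted)
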