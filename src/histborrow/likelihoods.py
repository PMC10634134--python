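"""Logistic likelihoods for the two-arm mortality models, plus scalar utilities.

Two model specifications are supported:

* unadjusted:  logit Pr(death) = alpha + beta * I(PMX)
* adjusted:    logit Pr(death) = alpha + beta * I(PMX) + gamma * (apache - c)

exp(beta) is the (covariate-conditional, for the adjusted model) odds ratio
for 28-day mortality, PMX versus control.  The covariate is centered at a
constant c (by default the pooled sample mean of the dataset analyzed) so the
intercept and slope are close to orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import ARM_PMX, ContingencySummary, TrialDataset


@dataclass(frozen=True)
class ModelSpec:
    """Which likelihood to use and where the covariate is centered."""

    adjusted: bool = False
    centering: float = 0.0

    @property
    def n_parameters(self) -> int:
        return 3 if self.adjusted else 2


@dataclass(frozen=True)
class Parameters:
    """(alpha, beta[, gamma]) on the log-odds scale."""

    alpha: float
    beta: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        vals = [self.alpha, self.beta] + ([] if self.gamma is None else [self.gamma])
        if not np.all(np.isfinite(vals)):
            raise ValueError("parameters must be finite")


@dataclass(frozen=True)
class Terms:
    """Grouped sufficient representation of one or more datasets.

    Patients sharing (arm, centered covariate) collapse to a single group with
    trial count ``n`` and death count ``d``; ``w`` is the likelihood weight of
    the group (1 for current data, the power-prior exponent a0 for historical
    data).  The log-likelihood is sum_g w_g * [d_g*eta_g - n_g*softplus(eta_g)]
    with eta_g = alpha + beta*z_g + gamma*t_g.
    """

    w: np.ndarray
    z: np.ndarray
    t: np.ndarray
    n: np.ndarray
    d: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.w.size


def grouped_terms(data: TrialDataset | ContingencySummary, spec: ModelSpec,
                  weight: float = 1.0) -> Terms:
    """Collapse a dataset to weighted likelihood groups under ``spec``."""
    if isinstance(data, ContingencySummary):
        if spec.adjusted:
            raise TypeError("a contingency summary cannot feed an adjusted model")
        z = np.array([1.0, 0.0])
        t = np.zeros(2)
        n = np.array([data.n_pmx, data.n_ctrl], dtype=float)
        d = np.array([data.deaths_pmx, data.deaths_ctrl], dtype=float)
    elif isinstance(data, TrialDataset):
        df = data.df
        if spec.adjusted:
            g = df.groupby([df["arm"] == ARM_PMX, "apache"])["death28"].agg(["count", "sum"])
            z = g.index.get_level_values(0).to_numpy(dtype=float)
            t = g.index.get_level_values(1).to_numpy(dtype=float) - spec.centering
        else:
            g = df.groupby(df["arm"] == ARM_PMX)["death28"].agg(["count", "sum"])
            z = g.index.to_numpy(dtype=float)
            t = np.zeros(z.size)
        n = g["count"].to_numpy(dtype=float)
        d = g["sum"].to_numpy(dtype=float)
    else:
        raise TypeError(f"unsupported data type {type(data).__name__}")
    return Terms(w=np.full(z.size, float(weight)), z=z, t=t, n=n, d=d)


def concat_terms(parts: list[Terms]) -> Terms:
    return Terms(*(np.concatenate([getattr(p, f) for p in parts])
                   for f in ("w", "z", "t", "n", "d")))


def pooled_centering(*datasets: TrialDataset) -> float:
    """Pooled mean APACHE II across the given datasets (centering constant)."""
    return float(pd.concat([ds.df["apache"] for ds in datasets]).mean())


def log_likelihood(data: TrialDataset | ContingencySummary, params: Parameters,
                   spec: ModelSpec) -> float:
    """Bernoulli-logistic log-likelihood of ``params`` for ``data``."""
    if spec.adjusted and params.gamma is None:
        raise ValueError("adjusted model requires gamma")
    terms = grouped_terms(data, spec)
    gamma = params.gamma if spec.adjusted else 0.0
    eta = params.alpha + params.beta * terms.z + gamma * terms.t
    return float(np.sum(terms.d * eta - terms.n * np.logaddexp(0.0, eta)))


def log_likelihood_terms(terms: Terms, alpha, beta, gamma=None):
    """Weighted log-likelihood over groups, broadcasting over parameter arrays.

    ``alpha``, ``beta``, ``gamma`` may be scalars or mutually broadcastable
    arrays; the group axis is reduced.  This is the single evaluation kernel
    behind quadrature grids, MAP optimization, and MCMC.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = 0.0
    for i in range(terms.n_groups):
        eta = alpha + beta * terms.z[i]
        if gamma is not None and terms.t[i] != 0.0:
            eta = eta + np.asarray(gamma, dtype=float) * terms.t[i]
        sp = np.logaddexp(0.0, eta)
        out = out + terms.w[i] * (terms.d[i] * eta - terms.n[i] * sp)
    return out


def odds_ratio_from_counts(summary: ContingencySummary) -> float:
    """Sample odds ratio (d1/(n1-d1)) / (d0/(n0-d0)); raises on any zero cell."""
    a, b = summary.deaths_pmx, summary.n_pmx - summary.deaths_pmx
    c, d = summary.deaths_ctrl, summary.n_ctrl - summary.deaths_ctrl
    if min(a, b, c, d) == 0:
        raise ZeroDivisionError("odds ratio undefined: zero cell in the 2x2 table")
    return (a / b) / (c / d)


def probability_to_odds(p: float) -> float:
    """Probability -> odds (x : 1); e.g. 0.97 -> 32.3 to 1."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must lie strictly between 0 and 1")
    return p / (1.0 - p)


def odds_to_probability(odds: float) -> float:
    if odds <= 0.0:
        raise ValueError("odds must be positive")
    return odds / (1.0 + odds)
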