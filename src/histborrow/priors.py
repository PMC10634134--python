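"""Four uses of historical data as a prior for the new trial's treatment effect.

* ``none`` — wide independent Normal(0, sd) base priors only; the historical
  cohort is ignored.
* ``fixed_weight`` — power prior: the historical log-likelihood enters the
  joint posterior multiplied by a fixed exponent a0 in [0, 1], equivalent to
  shrinking the historical sample to a0 of its size.  a0 = 1 is full pooling,
  a0 = 0 recovers ``none``.
* ``normalized_power`` — power prior with a random weight: a0 gets a Beta
  hyperprior and the a0-dependent normalizing constant C(a0) =
  integral of exp(a0 * L_hist) * base_prior is divided out, so the data can
  inform how much is borrowed.
* ``commensurate`` — hierarchical prior linking only the treatment effect:
  beta_new ~ Normal(beta_hist, tau^2) with separate intercepts per study, the
  base prior as hyperprior on the historical parameters, and a half-Normal
  hyperprior on the between-study SD tau.  Small tau means heavy borrowing.

All parameters share the log-odds scale.  The historical cohort enters
unadjusted analyses through its 2x2 table and adjusted analyses through its
patient-level records (with synthetic APACHE II values).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from . import _numerics
from .cohorts import ContingencySummary, TrialDataset
from .likelihoods import (ModelSpec, Parameters, Terms, grouped_terms,
                          log_likelihood_terms)

PRIOR_KINDS = ("none", "fixed_weight", "normalized_power", "commensurate")

DEFAULT_BASE_SD = 10.0
#: Half-normal scale of the commensurate between-study SD (log-OR units) and
#: Beta hyperprior on the normalized-power-prior weight a0.  Jointly calibrated
#: (see docs/methods.md) so that (i) on the ARR-11% worked example the
#: commensurate analysis borrows about as much as a 50%-weight power prior and
#: (ii) the two adaptive priors give practically identical probabilities of
#: benefit across the worked examples.
DEFAULT_TAU_SCALE = 0.25
DEFAULT_A0_HYPERPRIOR = (2.0, 1.0)


@dataclass(frozen=True)
class PriorSpec:
    """Which use of historical data, plus its hyperparameters."""

    kind: str = "none"
    historical: TrialDataset | ContingencySummary | None = None
    a0: float | None = None
    a0_hyperprior: tuple[float, float] = DEFAULT_A0_HYPERPRIOR  # Beta(a, b) on a0
    tau_scale: float = DEFAULT_TAU_SCALE
    tau_fixed: float | None = None
    base_sd: float = DEFAULT_BASE_SD

    def __post_init__(self) -> None:
        if self.kind not in PRIOR_KINDS:
            raise ValueError(f"unknown prior kind {self.kind!r}; expected one of {PRIOR_KINDS}")
        if self.kind != "none" and self.historical is None:
            raise ValueError(f"prior kind {self.kind!r} requires historical data")
        if self.kind == "fixed_weight":
            if self.a0 is None or not 0.0 <= self.a0 <= 1.0:
                raise ValueError("fixed_weight prior requires a0 in [0, 1]")
        if self.base_sd <= 0 or self.tau_scale <= 0:
            raise ValueError("base_sd and tau_scale must be positive")

    def to_dict(self) -> dict:
        out = {"kind": self.kind, "base_sd": self.base_sd}
        if self.kind == "fixed_weight":
            out["a0"] = self.a0
        if self.kind == "normalized_power":
            out["a0_hyperprior"] = list(self.a0_hyperprior)
        if self.kind == "commensurate":
            out["tau_scale"] = self.tau_scale
            if self.tau_fixed is not None:
                out["tau_fixed"] = self.tau_fixed
        return out

    @classmethod
    def from_dict(cls, d: dict, historical=None) -> "PriorSpec":
        d = dict(d)
        if "a0_hyperprior" in d:
            d["a0_hyperprior"] = tuple(d["a0_hyperprior"])
        return cls(historical=historical if d.get("kind", "none") != "none" else None, **d)


def base_log_prior(sd: float, *params) -> np.ndarray | float:
    """Independent Normal(0, sd) log-density summed over the given parameters."""
    out = 0.0
    for p in params:
        p = np.asarray(p, dtype=float)
        out = out + (-0.5 * (p / sd) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(sd))
    return out


def _dataset_key(data) -> tuple:
    if isinstance(data, ContingencySummary):
        return ("summary", data.deaths_pmx, data.n_pmx, data.deaths_ctrl, data.n_ctrl)
    buf = data.df[["arm", "death28", "apache"]].to_csv(index=False).encode()
    return ("dataset", hashlib.sha1(buf).hexdigest())


_NORMALIZER_CACHE: dict[tuple, float] = {}
_HIST_MARGINAL_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
_COMM_PRIOR_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _power_grid_posterior(terms: Terms, spec: ModelSpec, base_sd: float,
                          npts: int | None = None,
                          half_width: float = 10.0) -> _numerics.GridPosterior:
    """Laplace-centered quadrature of base_prior * prod likelihood^w."""
    k = spec.n_parameters

    def neg_log_kernel(x):
        gamma = x[2] if k == 3 else None
        val = log_likelihood_terms(terms, x[0], x[1], gamma)
        return -(val + base_log_prior(base_sd, *x))

    center, cov = _numerics.find_map(neg_log_kernel, np.zeros(k))
    npts = npts or (401 if k == 2 else 101)
    for attempt in range(3):
        axes = _numerics.laplace_axes(center, cov, npts, half_width * 1.5**attempt)
        mesh = _numerics.meshed(axes)
        gamma = mesh[2] if k == 3 else None
        logd = log_likelihood_terms(terms, mesh[0], mesh[1], gamma) + base_log_prior(base_sd, *mesh)
        post = _numerics.GridPosterior(axes=axes, log_density=logd)
        if post.tail_mass < _numerics.TAIL_TOL:
            return post
    raise _numerics.QuadratureError(
        f"tail mass {post.tail_mass:.3g} above tolerance after widening")


def log_power_prior_normalizer(a0: float, historical, model_spec: ModelSpec,
                               base_sd: float = DEFAULT_BASE_SD) -> float:
    """log C(a0) = log integral of exp(a0 * L_hist) * base_prior d(params).

    Computed by deterministic Laplace-centered quadrature; C(0) = 1 because
    the base prior is normalized.
    """
    if not 0.0 <= a0 <= 1.0:
        raise ValueError("a0 must lie in [0, 1]")
    key = (_dataset_key(historical), model_spec, base_sd, round(float(a0), 12))
    if key not in _NORMALIZER_CACHE:
        terms = grouped_terms(historical, model_spec, weight=a0)
        _NORMALIZER_CACHE[key] = _power_grid_posterior(terms, model_spec, base_sd).log_normalizer
    return _NORMALIZER_CACHE[key]


def historical_beta_marginal(historical, model_spec: ModelSpec,
                             base_sd: float = DEFAULT_BASE_SD
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Marginal posterior density of the historical treatment log-OR.

    This is the posterior of beta from the historical cohort alone under the
    base prior — the building block of the commensurate prior (the base prior
    acts as the hyperprior on the historical parameters).
    """
    key = (_dataset_key(historical), model_spec, base_sd)
    if key not in _HIST_MARGINAL_CACHE:
        terms = grouped_terms(historical, model_spec, weight=1.0)
        post = _power_grid_posterior(terms, model_spec, base_sd)
        _HIST_MARGINAL_CACHE[key] = post.marginal(axis=1)
    return _HIST_MARGINAL_CACHE[key]


def commensurate_beta_log_prior(historical, model_spec: ModelSpec,
                                base_sd: float = DEFAULT_BASE_SD,
                                tau_scale: float = DEFAULT_TAU_SCALE,
                                tau_fixed: float | None = None,
                                n_tau: int = 121,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Marginal commensurate prior density of the new trial's treatment log-OR.

    Exact marginalization of the hierarchy: p(beta) = integral over tau and
    beta_hist of halfNormal(tau; tau_scale) * Normal(beta; beta_hist, tau^2)
    * p(beta_hist | historical).  The historical marginal is carried on a grid,
    so tau is smoothed as sqrt(tau^2 + h^2) with h the grid spacing (exact in
    the limit h -> 0; at tau = 0 this reproduces the historical marginal at
    its grid resolution).

    Returns (beta grid, log prior density) for interpolation.
    """
    key = (_dataset_key(historical), model_spec, base_sd, tau_scale, tau_fixed, n_tau)
    if key in _COMM_PRIOR_CACHE:
        return _COMM_PRIOR_CACHE[key]
    gb, fb = historical_beta_marginal(historical, model_spec, base_sd)
    h = gb[1] - gb[0]
    # point-mass weights of the historical marginal (trapezoid rule)
    wt = np.full(gb.size, h)
    wt[0] = wt[-1] = h / 2
    log_w = np.log(np.maximum(fb * wt, 1e-300))
    log_w -= logsumexp(log_w)

    if tau_fixed is not None:
        taus = np.array([float(tau_fixed)])
        log_wtau = np.array([0.0])
    else:
        taus = np.linspace(0.0, 6.0 * tau_scale, n_tau)
        wtau = np.exp(-0.5 * (taus / tau_scale) ** 2)
        wtau[0] *= 0.5
        wtau[-1] *= 0.5
        log_wtau = np.log(wtau / wtau.sum())

    beta_out = np.linspace(-12.0, 12.0, 2401)
    tau_eff = np.sqrt(taus**2 + h**2)
    parts = np.empty((taus.size, beta_out.size))
    for j, te in enumerate(tau_eff):
        logpdf = (-0.5 * ((beta_out[None, :] - gb[:, None]) / te) ** 2
                  - np.log(te) - 0.5 * np.log(2 * np.pi))
        parts[j] = logsumexp(log_w[:, None] + logpdf, axis=0) + log_wtau[j]
    log_prior = logsumexp(parts, axis=0)
    _COMM_PRIOR_CACHE[key] = (beta_out, log_prior)
    return _COMM_PRIOR_CACHE[key]


def joint_log_posterior_kernel(params: Parameters, prior_spec: PriorSpec,
                               new_data, model_spec: ModelSpec, *,
                               a0: float | None = None,
                               hist_params: Parameters | None = None,
                               tau: float | None = None) -> float:
    """Unnormalized joint log posterior at one parameter point.

    For kinds ``none`` and ``fixed_weight`` only ``params`` is needed.  The
    ``normalized_power`` kernel is joint in (params, a0); ``commensurate`` is
    joint in (params, hist_params, tau), with separate intercepts per study
    and the treatment effects linked by Normal(beta_hist, tau^2).
    """
    sd = prior_spec.base_sd
    new_terms = grouped_terms(new_data, model_spec)
    free = [params.alpha, params.beta] + ([params.gamma] if model_spec.adjusted else [])
    ll_new = log_likelihood_terms(new_terms, params.alpha, params.beta, params.gamma)

    if prior_spec.kind in ("none", "fixed_weight"):
        out = base_log_prior(sd, *free) + ll_new
        if prior_spec.kind == "fixed_weight" and prior_spec.a0 > 0:
            hist_terms = grouped_terms(prior_spec.historical, model_spec,
                                       weight=prior_spec.a0)
            out += log_likelihood_terms(hist_terms, params.alpha, params.beta, params.gamma)
        return float(out)

    if prior_spec.kind == "normalized_power":
        if a0 is None:
            raise ValueError("normalized_power kernel is joint in (params, a0)")
        hist_terms = grouped_terms(prior_spec.historical, model_spec, weight=a0)
        log_c = log_power_prior_normalizer(a0, prior_spec.historical, model_spec, sd)
        a, b = prior_spec.a0_hyperprior
        return float(base_log_prior(sd, *free) + ll_new
                     + log_likelihood_terms(hist_terms, params.alpha, params.beta, params.gamma)
                     - log_c + beta_dist.logpdf(a0, a, b))

    # commensurate: hierarchical joint kernel
    if hist_params is None or tau is None:
        raise ValueError("commensurate kernel is joint in (params, hist_params, tau)")
    if tau < 0:
        return -np.inf
    hist_terms = grouped_terms(prior_spec.historical, model_spec, weight=1.0)
    hist_free = [hist_params.alpha, hist_params.beta] + \
        ([hist_params.gamma] if model_spec.adjusted else [])
    ll_hist = log_likelihood_terms(hist_terms, hist_params.alpha, hist_params.beta,
                                   hist_params.gamma)
    others = [params.alpha] + ([params.gamma] if model_spec.adjusted else [])
    s = prior_spec.tau_scale
    log_tau_prior = 0.5 * np.log(2 / np.pi) - np.log(s) - 0.5 * (tau / s) ** 2
    link = (-0.5 * ((params.beta - hist_params.beta) / tau) ** 2
            - np.log(tau) - 0.5 * np.log(2 * np.pi))
    return float(base_log_prior(sd, *others) + base_log_prior(sd, *hist_free)
                 + ll_hist + ll_new + link + log_tau_prior)


@dataclass
class EffectiveWeightResult:
    a0_star: float
    at_boundary: bool
    pr_target: float
    pr_achieved: float


def effective_prior_weight(new_data, adaptive_pr_benefit: float,
                           model_spec: ModelSpec, historical,
                           base_sd: float = DEFAULT_BASE_SD,
                           tol: float = 1e-3, **fit_kwargs) -> EffectiveWeightResult:
    """Fixed weight a0* whose Pr(OR < 1) matches an adaptive analysis.

    Monotone bisection of the fixed-weight power-prior analysis over
    a0 in [0, 1].  If the adaptive probability falls outside the envelope
    spanned by a0 = 0 and a0 = 1, the nearer boundary is returned with
    ``at_boundary = True``.
    """
    from .posterior import fit_posterior  # local import to avoid a cycle

    target = float(adaptive_pr_benefit)

    def pr_at(a0: float) -> float:
        spec = PriorSpec(kind="fixed_weight", a0=a0, historical=historical,
                         base_sd=base_sd)
        return fit_posterior(new_data, spec, model_spec, **fit_kwargs).pr_benefit

    pr0, pr1 = pr_at(0.0), pr_at(1.0)
    lo_pr, hi_pr = min(pr0, pr1), max(pr0, pr1)
    if not lo_pr <= target <= hi_pr:
        a0_star = 0.0 if abs(target - pr0) <= abs(target - pr1) else 1.0
        return EffectiveWeightResult(a0_star, True, target,
                                     pr0 if a0_star == 0.0 else pr1)
    sign = 1.0 if pr1 >= pr0 else -1.0
    lo, hi = 0.0, 1.0
    pr_mid = pr0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        pr_mid = pr_at(mid)
        if abs(pr_mid - target) < tol:
            return EffectiveWeightResult(mid, False, target, pr_mid)
        if sign * (pr_mid - target) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    mid = 0.5 * (lo + hi)
    return EffectiveWeightResult(mid, False, target, pr_mid)
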