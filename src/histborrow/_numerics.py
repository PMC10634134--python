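"""Low-level numerical machinery: Laplace-centered product grids, trapezoid
normalization, marginal quantiles, and a seeded independence-Metropolis
sampler.  Shared by the prior constructions and the posterior engine."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize

TAIL_TOL = 1e-8


class QuadratureError(RuntimeError):
    """Raised when the integration grid cannot contain the posterior mass."""


def find_map(neg_log_kernel, x0: np.ndarray):
    """Posterior mode and Laplace covariance of a smooth log-kernel.

    BFGS from ``x0`` with a Nelder-Mead fallback; covariance from a central
    finite-difference Hessian at the mode (more reliable than BFGS's inverse
    Hessian estimate).
    """
    res = minimize(neg_log_kernel, x0, method="BFGS")
    if not res.success:
        res = minimize(neg_log_kernel, res.x, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    x = np.asarray(res.x, dtype=float)
    hess = _numeric_hessian(neg_log_kernel, x)
    try:
        cov = np.linalg.inv(hess)
        if not np.all(np.linalg.eigvalsh(cov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.asarray(res.hess_inv if hasattr(res, "hess_inv") else np.eye(x.size))
    return x, np.atleast_2d(cov)


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                hess[i, j] = hess[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return hess


def laplace_axes(center: np.ndarray, cov: np.ndarray, npts: int,
                 half_width: float = 10.0) -> list[np.ndarray]:
    """Per-dimension grids: mode +/- half_width marginal SDs, npts points."""
    scales = np.sqrt(np.diag(np.atleast_2d(cov)))
    scales = np.where(scales > 0, scales, 1e-3)
    u = np.linspace(-half_width, half_width, npts)
    return [c + s * u for c, s in zip(np.atleast_1d(center), scales)]


def meshed(axes: list[np.ndarray]) -> list[np.ndarray]:
    """Broadcastable (not materialized) meshgrid views of the axes."""
    k = len(axes)
    out = []
    for i, ax in enumerate(axes):
        shape = [1] * k
        shape[i] = ax.size
        out.append(ax.reshape(shape))
    return out


@dataclass
class GridPosterior:
    """Normalized posterior density on a product grid.

    Provides marginals by iterated trapezoid integration, quantiles by
    monotone interpolation of the marginal CDF, and a tail-mass diagnostic
    (fraction of mass in the outermost grid shell) that certifies the grid
    contained the posterior.
    """

    axes: list[np.ndarray]
    log_density: np.ndarray  # unnormalized on entry; normalized lazily

    def __post_init__(self) -> None:
        self._shift = float(np.max(self.log_density))
        dens = np.exp(self.log_density - self._shift)
        total = dens
        for i in range(len(self.axes) - 1, -1, -1):
            total = np.trapezoid(total, self.axes[i], axis=i)
        self._norm = float(total)
        self.density = dens / self._norm

    @property
    def log_normalizer(self) -> float:
        """log of the integral of exp(log_density) over the grid."""
        return self._shift + float(np.log(self._norm))

    def marginal(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        dens = self.density
        for i in range(len(self.axes) - 1, -1, -1):
            if i != axis:
                dens = np.trapezoid(dens, self.axes[i], axis=i)
        return self.axes[axis], dens

    def _cdf(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        g, f = self.marginal(axis)
        cdf = np.concatenate([[0.0], cumulative_trapezoid(f, g)])
        return g, cdf / cdf[-1]

    def prob_below(self, x: float, axis: int = 1) -> float:
        g, cdf = self._cdf(axis)
        return float(np.interp(x, g, cdf))

    def quantiles(self, qs, axis: int = 1) -> np.ndarray:
        g, cdf = self._cdf(axis)
        return np.interp(qs, cdf, g)

    @property
    def tail_mass(self) -> float:
        """Largest boundary-face mass fraction across dimensions."""
        worst = 0.0
        for i, ax in enumerate(self.axes):
            g, f = self.marginal(i)
            dx = g[1] - g[0]
            worst = max(worst, float(f[0] * dx), float(f[-1] * dx))
        return worst


def quadrature_posterior(log_kernel, bounds: list[tuple[float, float]],
                         npts: int = 401, tail_tol: float = TAIL_TOL) -> GridPosterior:
    """Normalize a log-kernel over an explicit product grid.

    ``log_kernel`` receives one broadcastable array per dimension and must
    return the elementwise log-density.  Raises :class:`QuadratureError` if
    boundary mass exceeds ``tail_tol``.
    """
    axes = [np.linspace(lo, hi, npts) for lo, hi in bounds]
    post = GridPosterior(axes=axes, log_density=np.asarray(log_kernel(*meshed(axes)), dtype=float))
    if post.tail_mass > tail_tol:
        raise QuadratureError(
            f"tail mass {post.tail_mass:.3g} exceeds {tail_tol:.1g}; widen the bounds")
    return post


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an (n_chains, n_draws) array of a scalar quantity."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    between = n * means.var(ddof=1)
    within = segs.var(axis=1, ddof=1).mean()
    if within == 0:
        return 1.0
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def independence_metropolis(log_target, center: np.ndarray, cov: np.ndarray,
                            seed, n_chains: int = 4, n_draws: int = 2000,
                            n_warmup: int = 1000, proposal_scale: float = 1.3,
                            proposal_df: float = 7.0):
    """Seeded independence Metropolis with a multivariate-t proposal.

    The proposal is centered at the Laplace mode with covariance
    ``proposal_scale**2 * cov`` and ``proposal_df`` degrees of freedom — heavy
    enough in the tails for logistic posteriors, so acceptance is high and
    mixing near-iid.  ``log_target`` must accept an (n, k) array and return
    (n,) log-densities.  Returns (draws[n_chains, n_draws, k], diagnostics).
    """
    rng = np.random.default_rng(seed)
    k = center.size
    total = n_chains * (n_warmup + n_draws)
    chol = np.linalg.cholesky(np.atleast_2d(cov) * proposal_scale**2)
    zs = rng.standard_normal((total, k))
    chi = rng.chisquare(proposal_df, total) / proposal_df
    props = center + (zs / np.sqrt(chi)[:, None]) @ chol.T
    # multivariate-t log pdf up to a constant
    sol = np.linalg.solve(chol, (props - center).T)
    quad = np.sum(sol**2, axis=0)
    log_q = -0.5 * (proposal_df + k) * np.log1p(quad / proposal_df)
    log_p = np.asarray(log_target(props), dtype=float)
    log_ratio_term = log_p - log_q  # accept if ratio of these terms beats a uniform
    log_u = np.log(rng.random(total))

    draws = np.empty((n_chains, n_draws, k))
    accepts = 0
    idx = 0
    for c in range(n_chains):
        cur = None
        for step in range(n_warmup + n_draws):
            if cur is None or log_u[idx] < log_ratio_term[idx] - cur:
                cur = log_ratio_term[idx]
                cur_x = props[idx]
                accepts += 1
            if step >= n_warmup:
                draws[c, step - n_warmup] = cur_x
            idx += 1
    diag = {
        "accept_rate": accepts / total,
        "rhat": {f"param_{j}": split_rhat(draws[:, :, j]) for j in range(k)},
    }
    return draws, diag
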