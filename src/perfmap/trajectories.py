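"""Sex-stratified normative trajectories: generalized gamma + fractional polynomials.

Perfusion in a parcel (or whole-brain) is modelled as a random variable
Y ~ GG(mu, sigma, nu) in the Stacy parameterisation used by location-scale-
shape (GAMLSS-style) software: with theta = 1/(sigma^2 nu^2) and
z = (y/mu)^nu,

    log f(y) = log|nu| + theta log theta + theta nu (log y - log mu)
               - theta z - log Gamma(theta) - log y ,

so nu = 1 recovers a gamma law with shape theta and mean mu. The location
mu(x) and scale sigma(x) are log-linked fractional-polynomial functions of
age x, the shape nu is a constant, and the best two-term fractional
polynomial over the power set {-2, -1, -0.5, 0, 0.5, 1, 2, 3} is selected
by exhaustive candidate search under a generalized AIC.

Ages are rescaled to decades (and shifted positive if needed) before the
power basis is built, purely for numerical conditioning; the constants are
recorded in the fit so curves evaluate on the original age axis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special

__all__ = [
    "GGParams",
    "TrajectoryFit",
    "FP_POWERS",
    "gg_logpdf",
    "gg_cdf",
    "gg_quantile",
    "gg_rvs",
    "fp_design",
    "fp_candidates",
    "fit_gg_fp",
    "centile_curves",
]

#: the fractional-polynomial power set
FP_POWERS: Tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class GGParams:
    """Generalized-gamma parameters: location mu > 0, scale sigma > 0, shape nu != 0."""

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.sigma > 0):
            raise ValueError("mu and sigma must be positive")
        if self.nu == 0:
            raise ValueError("nu must be nonzero (the lognormal limit is not parameterized)")

    @property
    def theta(self) -> float:
        return 1.0 / (self.sigma ** 2 * self.nu ** 2)


def _unpack(params) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(params, GGParams):
        return np.asarray(params.mu), np.asarray(params.sigma), np.asarray(params.nu)
    mu, sigma, nu = params
    return np.asarray(mu, float), np.asarray(sigma, float), np.asarray(nu, float)


def gg_logpdf(y, params) -> np.ndarray:
    """Log density of GG(mu, sigma, nu) at y > 0 (Stacy form)."""
    mu, sigma, nu = _unpack(params)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    if np.any(nu == 0):
        raise ValueError("nu must be nonzero")
    theta = 1.0 / (sigma ** 2 * nu ** 2)
    logy_mu = np.log(y) - np.log(mu)
    z = np.exp(nu * logy_mu)
    return (np.log(np.abs(nu)) + theta * np.log(theta) + theta * nu * logy_mu
            - theta * z - special.gammaln(theta) - np.log(y))


def gg_cdf(y, params) -> np.ndarray:
    """CDF of GG(mu, sigma, nu); nu < 0 handled by reflection of theta*z."""
    mu, sigma, nu = _unpack(params)
    y = np.asarray(y, dtype=float)
    theta = 1.0 / (sigma ** 2 * nu ** 2)
    z = (y / mu) ** nu
    g = special.gammainc(theta, theta * z)
    return np.where(nu > 0, g, 1.0 - g)


def gg_quantile(p, params) -> np.ndarray:
    """Quantile function; inverts the gamma CDF of theta*z (reflected for nu < 0)."""
    mu, sigma, nu = _unpack(params)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    theta = 1.0 / (sigma ** 2 * nu ** 2)
    pp = np.where(nu > 0, p, 1.0 - p)
    g = special.gammaincinv(theta, pp)
    return mu * (g / theta) ** (1.0 / nu)


def gg_rvs(mu, sigma, nu, rng: np.random.Generator, size=None) -> np.ndarray:
    """Sample GG(mu, sigma, nu): draw G ~ Gamma(theta, 1) and set Y = mu (G/theta)^(1/nu)."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    nu = np.asarray(nu, float)
    theta = 1.0 / (sigma ** 2 * nu ** 2)
    if size is None:
        size = np.broadcast_shapes(mu.shape, sigma.shape, nu.shape)
    g = rng.standard_gamma(np.broadcast_to(theta, size))
    return mu * (g / theta) ** (1.0 / nu)


# ---------------------------------------------------------------------------
# fractional-polynomial basis


def fp_design(x, powers: Sequence[float]) -> np.ndarray:
    """Fractional-polynomial design matrix with a leading intercept column.

    Power 0 maps to log x; a repeated power p contributes (x^p, x^p log x)
    — for p = 0 that is (log x, (log x)^2). x must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional-polynomial basis requires x > 0")
    powers = tuple(float(p) for p in powers)
    if len(powers) > 2:
        raise ValueError("at most two fractional-polynomial terms")
    cols = [np.ones_like(x)]
    logx = np.log(x)
    seen: dict[float, int] = {}
    for p in powers:
        base = logx if p == 0.0 else x ** p
        if p in seen:
            cols.append(base * logx)  # repeated-power rule
        else:
            cols.append(base)
        seen[p] = seen.get(p, 0) + 1
    return np.column_stack(cols)


def fp_candidates() -> list:
    """All FP1 and FP2 power multisets (8 singles + 36 pairs with repetition)."""
    singles = [(p,) for p in FP_POWERS]
    pairs = [tuple(c) for c in itertools.combinations_with_replacement(FP_POWERS, 2)]
    return singles + pairs


# ---------------------------------------------------------------------------
# fitting


@dataclass
class TrajectoryFit:
    """A fitted GG fractional-polynomial trajectory.

    Coefficients are on the log-link scale for mu and sigma; ``x_shift`` and
    ``x_scale`` record the age transform xs = (x + shift) / scale applied
    before the power basis.
    """

    mu_powers: Tuple[float, ...]
    sigma_powers: Tuple[float, ...]
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    nu: float
    loglik: float
    gaic: float
    n_params: int
    k: float
    x_shift: float
    x_scale: float
    n_obs: int
    converged: bool = True

    def _xs(self, x) -> np.ndarray:
        return (np.asarray(x, float) + self.x_shift) / self.x_scale

    def mu(self, x) -> np.ndarray:
        return np.exp(fp_design(self._xs(x), self.mu_powers) @ self.beta_mu)

    def sigma(self, x) -> np.ndarray:
        return np.exp(fp_design(self._xs(x), self.sigma_powers) @ self.beta_sigma)

    def to_dict(self) -> dict:
        return {
            "mu_powers": list(self.mu_powers), "sigma_powers": list(self.sigma_powers),
            "beta_mu": self.beta_mu.tolist(), "beta_sigma": self.beta_sigma.tolist(),
            "nu": self.nu, "loglik": self.loglik, "gaic": self.gaic,
            "n_params": self.n_params, "k": self.k,
            "x_shift": self.x_shift, "x_scale": self.x_scale, "n_obs": self.n_obs,
        }


def _negll(theta_vec, dmu, dsig, y, logy):
    pmu = dmu.shape[1]
    psig = dsig.shape[1]
    eta_mu = np.clip(dmu @ theta_vec[:pmu], -30.0, 30.0)
    eta_sig = np.clip(dsig @ theta_vec[pmu:pmu + psig], -8.0, 4.0)
    lognu = np.clip(theta_vec[-1], math.log(0.05), math.log(8.0))
    nu = math.exp(lognu)
    sigma = np.exp(eta_sig)
    theta = 1.0 / (sigma ** 2 * nu ** 2)
    logy_mu = logy - eta_mu
    znu = np.clip(nu * logy_mu, -60.0, 60.0)
    ll = (lognu + theta * np.log(theta) + theta * nu * logy_mu
          - theta * np.exp(znu) - special.gammaln(theta) - logy)
    val = -np.sum(ll)
    return val if np.isfinite(val) else 1e12


def _fit_one(xs, y, mu_powers, sigma_powers, n_restarts, rng) -> Optional[dict]:
    dmu = fp_design(xs, mu_powers)
    dsig = fp_design(xs, sigma_powers)
    logy = np.log(y)
    # initialise mu coefficients from OLS of log y on the mu design
    b0, *_ = np.linalg.lstsq(dmu, logy, rcond=None)
    resid_sd = max(np.std(logy - dmu @ b0, ddof=1), 1e-3)
    s0 = np.zeros(dsig.shape[1])
    s0[0] = math.log(resid_sd)
    start = np.concatenate([b0, s0, [0.0]])
    best = None
    for r in range(n_restarts):
        x0 = start if r == 0 else start + rng.normal(scale=0.3, size=start.shape)
        res = optimize.minimize(_negll, x0, args=(dmu, dsig, y, logy),
                                method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        return None
    pmu, psig = dmu.shape[1], dsig.shape[1]
    return {
        "beta_mu": best.x[:pmu], "beta_sigma": best.x[pmu:pmu + psig],
        "nu": math.exp(np.clip(best.x[-1], math.log(0.05), math.log(8.0))),
        "loglik": -best.fun, "n_params": pmu + psig + 1,
        "converged": bool(best.success),
    }


def fit_gg_fp(x, y, k: float = 2.0, n_restarts: int = 3, seed: int = 0,
              mu_powers: Optional[Sequence[float]] = None,
              sigma_powers: Optional[Sequence[float]] = None,
              joint: bool = False) -> TrajectoryFit:
    """Fit the GG trajectory, selecting fractional-polynomial powers by GAIC.

    Default search is two-stage: choose the mu powers with an intercept-only
    sigma, then the sigma powers (including intercept-only) given the best
    mu. ``joint=True`` searches all mu x sigma combinations instead (slow;
    intended for small data). ``mu_powers`` / ``sigma_powers`` pin either
    side and skip its search. GAIC = -2 loglik + k * n_params (k = 2 is AIC).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(y) < 30:
        raise ValueError("need at least 30 observations")
    if np.any(y <= 0):
        raise ValueError("responses must be strictly positive")
    shift = 0.0 if x.min() > 0 else (1e-3 - x.min())
    scale = 10.0  # ages in decades for conditioning
    xs = (x + shift) / scale
    rng = np.random.default_rng(seed)

    def evaluate(mp, sp):
        fit = _fit_one(xs, y, mp, sp, n_restarts, rng)
        if fit is None:
            return None
        fit["gaic"] = -2.0 * fit["loglik"] + k * fit["n_params"]
        fit["mu_powers"] = tuple(mp)
        fit["sigma_powers"] = tuple(sp)
        return fit

    mu_cands = [tuple(mu_powers)] if mu_powers is not None else fp_candidates()
    sig_cands = [tuple(sigma_powers)] if sigma_powers is not None else [()] + fp_candidates()

    results = []
    if joint and mu_powers is None and sigma_powers is None:
        for mp in mu_cands:
            for sp in sig_cands:
                f = evaluate(mp, sp)
                if f is not None:
                    results.append(f)
    else:
        stage1 = []
        sp0 = sig_cands[0] if sigma_powers is not None else ()
        for mp in mu_cands:
            f = evaluate(mp, sp0)
            if f is not None:
                stage1.append(f)
        if not stage1:
            raise RuntimeError("optimizer failed to converge for every mu candidate")
        best_mu = min(stage1, key=lambda f: f["gaic"])["mu_powers"]
        for sp in sig_cands:
            f = evaluate(best_mu, sp)
            if f is not None:
                results.append(f)
    if not results:
        raise RuntimeError("optimizer failed to converge for every candidate model")
    best = min(results, key=lambda f: f["gaic"])
    return TrajectoryFit(
        mu_powers=best["mu_powers"], sigma_powers=best["sigma_powers"],
        beta_mu=np.asarray(best["beta_mu"]), beta_sigma=np.asarray(best["beta_sigma"]),
        nu=best["nu"], loglik=best["loglik"], gaic=best["gaic"],
        n_params=best["n_params"], k=k, x_shift=shift, x_scale=scale,
        n_obs=len(y), converged=best["converged"],
    )


def centile_curves(fit: TrajectoryFit, x_grid, centiles=(5.0, 50.0, 95.0)) -> "np.ndarray":
    """Centile curves on an age grid: gg_quantile at each centile with mu(x), sigma(x), nu.

    Returns an array of shape (len(centiles), len(x_grid)).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    mu = fit.mu(x_grid)
    sigma = fit.sigma(x_grid)
    out = np.empty((len(centiles), len(x_grid)))
    for i, c in enumerate(centiles):
        out[i] = gg_quantile(c / 100.0, (mu, sigma, fit.nu))
    return out
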