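"""Per-sample age likelihood over the candidate grid, and its argmax.

For a sample with beta values x_j at the reference sites, the
log-likelihood of candidate age a is the sum over available sites of the
log-density of x_j under the reference moments (mu_j(a), sigma_j(a)).
Two density families are supported:

* ``normal`` (default): N(mu, sigma) on the beta scale;
* ``beta``: a Beta distribution with shape parameters obtained from
  (mu, sigma^2) by the method of moments,

      alpha = mu (-mu^2 + mu - sigma^2) / sigma^2
      beta  = (mu - 1)(mu^2 - mu + sigma^2) / sigma^2.

Sites missing in the sample are silently excluded (intersection
semantics); the predicted age is the grid argmax, ties broken toward the
youngest age.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import ClockConfig
from .errors import InfeasibleMomentsError, NoOverlapError, ValidationError
from .trend import ReferenceMatrix

_LOG_2PI = math.log(2.0 * math.pi)


class BetaShape(NamedTuple):
    alpha: float
    beta_param: float


def beta_shape_params(mu: float, var: float) -> BetaShape:
    """Beta shape parameters matching a given mean and variance.

    Requires ``0 < mu < 1`` and ``0 < var < mu * (1 - mu)`` (the Bernoulli
    bound); outside that region no Beta distribution has these moments and
    an :class:`InfeasibleMomentsError` is raised — callers clip the
    variance first.
    """
    if not (np.isfinite(mu) and 0.0 < mu < 1.0):
        raise ValidationError(f"mu must lie in (0, 1), got {mu}")
    if not np.isfinite(var) or var <= 0.0:
        raise ValidationError(f"var must be > 0, got {var}")
    if var >= mu * (1.0 - mu):
        raise InfeasibleMomentsError(
            f"var {var} >= mu(1-mu) = {mu * (1.0 - mu)}; no Beta law has these moments"
        )
    alpha = mu * (-(mu**2) + mu - var) / var
    beta = (mu - 1.0) * (mu**2 - mu + var) / var
    return BetaShape(float(alpha), float(beta))


def log_prob_beta(x, shape: BetaShape, x_eps: float = 1e-6):
    """Log Beta density at ``x`` (clipped into [x_eps, 1 - x_eps]).

    Evaluated through log-gamma, never through the raw gamma function, so
    large shape parameters cannot overflow.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("x must be finite")
    xc = np.clip(x, x_eps, 1.0 - x_eps)
    a, b = shape.alpha, shape.beta_param
    out = (
        gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(xc)
        + (b - 1.0) * np.log1p(-xc)
    )
    return out if out.ndim else float(out)


def log_prob_normal(x, mu, sigma):
    """Gaussian log-density of ``x`` under N(mu, sigma)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0.0):
        raise ValidationError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    z = (x - np.asarray(mu, dtype=float)) / sigma
    out = -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z**2
    return out if out.ndim else float(out)


@dataclass
class AgeLikelihoodProfile:
    """Log-likelihood L(a) over the candidate-age grid for one sample.

    ``support`` is the reference's observed training-age range; grid ages
    outside it carry constant-extrapolated moments, so their likelihood
    values are exact copies of the boundary value.
    """

    age_grid: np.ndarray
    log_likelihood: np.ndarray
    n_sites_used: int
    support: Optional[tuple] = None

    def posterior(self) -> np.ndarray:
        """Grid probabilities under a flat prior: exp(L - logsumexp(L))."""
        return np.exp(self.log_likelihood - logsumexp(self.log_likelihood))


def argmax_age(L: np.ndarray, age_grid: np.ndarray, support: Optional[tuple] = None) -> float:
    """Grid age maximizing L, ties toward the youngest *supported* age.

    Exact ties arise when the reference is constant-extrapolated outside
    its training range: every outside age duplicates the boundary
    likelihood.  Among tied maxima the youngest age inside ``support``
    (the training range) wins; without a support, or when no tied age
    falls inside it, the youngest overall wins.
    """
    m = np.max(L)
    tied = np.flatnonzero(L == m)
    if support is not None:
        inside = tied[
            (age_grid[tied] >= support[0]) & (age_grid[tied] <= support[1])
        ]
        if inside.size:
            return float(age_grid[inside[0]])
    return float(age_grid[tied[0]])


def _beta_grid_shapes(mu: np.ndarray, sigma: np.ndarray, config: ClockConfig):
    """Vectorized moment-matched shapes for a (sites x ages) moment grid.

    mu is clipped away from {0, 1} and the variance is clipped to
    ``feasibility_fraction * mu * (1 - mu)`` so every grid cell admits a
    Beta distribution (a floored variance near the boundaries otherwise
    violates the Bernoulli bound).
    """
    eps = config.x_eps
    mu_c = np.clip(mu, eps, 1.0 - eps)
    bound = mu_c * (1.0 - mu_c)
    var_c = np.minimum(sigma**2, config.feasibility_fraction * bound)
    alpha = mu_c * (bound - var_c) / var_c
    beta = (1.0 - mu_c) * (bound - var_c) / var_c
    return alpha, beta


def profile_matrix(
    betas: pd.DataFrame,
    reference: ReferenceMatrix,
    config: ClockConfig = ClockConfig(),
    family: Optional[str] = None,
):
    """Age log-likelihood profiles for many samples at once.

    Parameters
    ----------
    betas:
        samples x sites DataFrame; columns are intersected with the
        reference sites, missing entries (or absent columns) drop out of
        the per-sample sum.

    Returns
    -------
    (L, n_used):
        ``L`` is (n_samples, n_grid_ages); rows of samples with zero
        usable sites are ``NaN``.  ``n_used`` counts usable sites per
        sample.
    """
    family = family or config.family
    cols = [s for s in reference.site_ids if s in betas.columns]
    if not cols:
        raise NoOverlapError("no reference site present in the input matrix")
    site_idx = [reference.site_ids.index(s) for s in cols]
    x = betas.loc[:, cols].to_numpy(dtype=float)  # n x s
    mu = reference.mu[site_idx]  # s x g
    sigma = reference.sigma[site_idx]
    present = ~np.isnan(x)
    n_used = present.sum(axis=1)
    xf = np.where(present, x, 0.5)  # placeholder; masked out below

    n, g = x.shape[0], reference.age_grid.size
    L = np.zeros((n, g))
    if family == "normal":
        for k in range(g):
            ll = log_prob_normal(xf, mu[:, k], sigma[:, k])
            L[:, k] = np.where(present, ll, 0.0).sum(axis=1)
    elif family == "beta":
        alpha, beta = _beta_grid_shapes(mu, sigma, config)
        xc = np.clip(xf, config.x_eps, 1.0 - config.x_eps)
        log_x, log_1mx = np.log(xc), np.log1p(-xc)
        norm = gammaln(alpha + beta) - gammaln(alpha) - gammaln(beta)  # s x g
        for k in range(g):
            ll = (alpha[:, k] - 1.0) * log_x + (beta[:, k] - 1.0) * log_1mx + norm[:, k]
            L[:, k] = np.where(present, ll, 0.0).sum(axis=1)
    else:
        raise ValidationError(f"unknown likelihood family {family!r}")
    L[n_used < max(config.min_sites, 1)] = np.nan
    return L, n_used


def age_log_likelihood(
    sample_betas,
    reference: ReferenceMatrix,
    config: ClockConfig = ClockConfig(),
    family: Optional[str] = None,
    sample_id: str = "<sample>",
) -> AgeLikelihoodProfile:
    """Likelihood profile of one sample (a Series or mapping site -> beta)."""
    s = pd.Series(sample_betas, dtype=float)
    try:
        L, n_used = profile_matrix(s.to_frame().T, reference, config, family)
    except NoOverlapError:
        raise NoOverlapError(
            f"sample {sample_id}: no usable site overlaps the reference"
        ) from None
    if n_used[0] < max(config.min_sites, 1):
        raise NoOverlapError(
            f"sample {sample_id}: no usable site overlaps the reference"
        )
    return AgeLikelihoodProfile(
        age_grid=reference.age_grid.copy(),
        log_likelihood=L[0],
        n_sites_used=int(n_used[0]),
        support=(reference.support_min, reference.support_max),
    )


def predict_age(profile: AgeLikelihoodProfile) -> float:
    """Grid age maximizing L(a); exact ties resolve to the youngest age
    (preferring ages inside the reference's training range when known)."""
    return argmax_age(profile.log_likelihood, profile.age_grid, profile.support)
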