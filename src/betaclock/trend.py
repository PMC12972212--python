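"""LOWESS trend fits, replicate-based variance curves and reference matrices.

Training boils down to two smoothing problems per selected CpG site:

* the *trend*: expected methylation versus age, fit by LOWESS (tricube
  weights, local linear) and read out on the integer age grid 0-100;
* the *variance*: same-age samples are treated as technical replicates,
  each integer-age bin contributes its (mean methylation, variance) pair,
  and a second LOWESS of variance against mean methylation gives a
  methylation-level-dependent noise model.

The :class:`ReferenceMatrix` stores the result: mu and sigma per site per
grid age.  Everything downstream (likelihood, prediction, serialization)
depends only on these grids, not on the smoothing implementation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .config import AGE_GRID_MAX, AGE_GRID_MIN, ClockConfig
from .dataset import MethylationDataset
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidConfigError,
    ValidationError,
)


@dataclass(frozen=True)
class LowessConfig:
    """Smoothing fraction and robustness iterations for one LOWESS fit."""

    tau: float = 0.7
    n_robust_iters: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise InvalidConfigError(f"tau must lie in (0, 1], got {self.tau}")
        if self.n_robust_iters < 0:
            raise InvalidConfigError("n_robust_iters must be >= 0")


class LowessSmoother:
    """A fitted LOWESS curve, evaluable at arbitrary x.

    Stores fitted values at the unique observed x positions; evaluation
    elsewhere interpolates linearly between them and clamps (constant
    extrapolation) outside the observed range.
    """

    def __init__(self, x: np.ndarray, fitted: np.ndarray):
        self.x_ = np.asarray(x, dtype=float)
        self.fitted_ = np.asarray(fitted, dtype=float)

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.x_, self.fitted_)


def fit_lowess(xs, ys, config: LowessConfig = LowessConfig()) -> LowessSmoother:
    """Tricube-weighted local-linear smoother of ``ys`` against ``xs``.

    The local window at each point contains the nearest ``tau`` fraction
    of the data.  Requires at least 3 points and at least two distinct x
    values.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValidationError("xs and ys must be 1-D arrays of equal length")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValidationError("xs and ys must be finite")
    if xs.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {xs.size}")
    if np.unique(xs).size < 2:
        raise DegenerateDataError("all x values identical; no trend to fit")
    out = _sm_lowess(
        ys, xs, frac=config.tau, it=config.n_robust_iters, return_sorted=True
    )
    # replicated x positions share one local fit; keep one value per unique x
    ux, idx = np.unique(out[:, 0], return_index=True)
    return LowessSmoother(ux, out[idx, 1])


@dataclass
class VarianceCurve:
    """Smoothed mapping from methylation level to beta-value variance.

    ``support`` has one row per contributing integer-age bin: the bin's
    mean methylation, unbiased variance and size.  Lookup interpolates in
    methylation space over the support (sorted by bin mean), clamps
    outside it, and floors the result at ``sigma_floor**2``.
    """

    site_id: str
    support: pd.DataFrame
    _lookup_x: np.ndarray
    _lookup_y: np.ndarray
    sigma_floor: float

    def __call__(self, mu) -> np.ndarray:
        v = np.interp(np.asarray(mu, dtype=float), self._lookup_x, self._lookup_y)
        return np.maximum(v, self.sigma_floor**2)


def estimate_variance_curve(
    dataset: MethylationDataset,
    site: str,
    config: ClockConfig = ClockConfig(),
) -> VarianceCurve:
    """Variance model for one site from same-age technical replicates.

    Samples are grouped by integer age; bins with at least
    ``config.min_bin_size`` non-missing values contribute (mean, unbiased
    variance, n).  A LOWESS fit (same tau as the trend fit) of variance
    against bin mean methylation gives the smoothed lookup.  With fewer
    than two usable bins the curve degrades to a single pooled variance
    (flat), with a warning; with exactly two it interpolates linearly.
    """
    if dataset.ages is None:
        raise ValidationError("dataset has no ages")
    if site not in dataset.beta.columns:
        raise ValidationError(f"unknown site {site!r}")
    x = dataset.beta[site]
    ok = x.notna()
    ages_int = dataset.ages[ok].round().astype(int)
    grouped = x[ok].groupby(ages_int)
    rows = []
    for age, vals in grouped:
        if len(vals) >= config.min_bin_size:
            rows.append((age, vals.mean(), vals.var(ddof=1), len(vals)))
    support = pd.DataFrame(
        rows, columns=["age", "mean", "variance", "n"]
    ).sort_values("mean", ignore_index=True)

    if len(support) < 2:
        pooled = float(x[ok].var(ddof=1)) if ok.sum() >= 2 else 0.0
        warnings.warn(
            f"site {site}: fewer than 2 usable age bins; "
            "falling back to a flat pooled variance",
            stacklevel=2,
        )
        return VarianceCurve(
            site_id=site,
            support=support,
            _lookup_x=np.array([0.0, 1.0]),
            _lookup_y=np.array([pooled, pooled]),
            sigma_floor=config.sigma_floor,
        )

    means = support["mean"].to_numpy()
    variances = support["variance"].to_numpy()
    if len(support) == 2 or np.unique(means).size < 2:
        lx, ly = np.unique(means), [
            variances[means == m].mean() for m in np.unique(means)
        ]
        if len(lx) == 1:
            lx = np.array([lx[0] - 1e-9, lx[0] + 1e-9])
            ly = [ly[0], ly[0]]
        return VarianceCurve(site, support, np.asarray(lx), np.asarray(ly, dtype=float),
                             config.sigma_floor)
    smoother = fit_lowess(
        means, variances, LowessConfig(tau=config.tau, n_robust_iters=config.n_robust_iters)
    )
    return VarianceCurve(
        site_id=site,
        support=support,
        _lookup_x=smoother.x_,
        _lookup_y=smoother.fitted_,
        sigma_floor=config.sigma_floor,
    )


@dataclass
class ReferenceMatrix:
    """Expected methylation and its spread per site per integer age.

    ``mu`` and ``sigma`` are (n_sites, n_grid_ages) arrays over
    ``age_grid`` (0..100 by default).  This is the entire trained state a
    prediction needs.  ``support_min``/``support_max`` record the training
    age range: outside it the curves are constant extrapolations, every
    age is exactly tied in likelihood, and tie-breaking prefers ages the
    training data actually covered.
    """

    site_ids: list
    age_grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    support_min: float = float(AGE_GRID_MIN)
    support_max: float = float(AGE_GRID_MAX)

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n_sites, n_ages = len(self.site_ids), self.age_grid.size
        if self.mu.shape != (n_sites, n_ages) or self.sigma.shape != (n_sites, n_ages):
            raise ValidationError("mu/sigma shape does not match site_ids x age_grid")

    def to_dict(self) -> dict:
        return {
            "site_ids": list(self.site_ids),
            "age_grid": self.age_grid.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "support_min": self.support_min,
            "support_max": self.support_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceMatrix":
        return cls(
            site_ids=list(d["site_ids"]),
            age_grid=np.asarray(d["age_grid"], dtype=float),
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            support_min=float(d["support_min"]),
            support_max=float(d["support_max"]),
        )


def default_age_grid() -> np.ndarray:
    return np.arange(AGE_GRID_MIN, AGE_GRID_MAX + 1, dtype=float)


def build_reference_matrix(
    dataset: MethylationDataset,
    sites: Sequence[str],
    config: ClockConfig = ClockConfig(),
    age_grid: Optional[np.ndarray] = None,
) -> ReferenceMatrix:
    """Train mu(age) and sigma(age) grids for the given sites.

    Per site: LOWESS of methylation against age, evaluated at every grid
    age (linear interpolation between fitted values at observed ages,
    constant beyond the observed range) and clipped to ``[0, 1]``; then
    ``sigma(a) = sqrt(max(variance_curve(mu(a)), sigma_floor**2))``.
    Sites with no usable data are excluded with a warning.
    """
    if not len(sites):
        raise ValidationError("no sites given")
    if dataset.ages is None:
        raise ValidationError("dataset has no ages")
    grid = default_age_grid() if age_grid is None else np.asarray(age_grid, dtype=float)
    ages = dataset.ages.to_numpy()
    kept, mus, sigmas = [], [], []
    lcfg = LowessConfig(tau=config.tau, n_robust_iters=config.n_robust_iters)
    for site in sites:
        if site not in dataset.beta.columns:
            raise ValidationError(f"unknown site {site!r}")
        x = dataset.beta[site].to_numpy()
        ok = ~np.isnan(x)
        if ok.sum() < 3:
            warnings.warn(f"site {site}: fewer than 3 usable values; excluded",
                          stacklevel=2)
            continue
        smoother = fit_lowess(ages[ok], x[ok], lcfg)
        mu = np.clip(smoother(grid), 0.0, 1.0)
        var_curve = estimate_variance_curve(dataset, site, config)
        sigma = np.sqrt(np.maximum(var_curve(mu), config.sigma_floor**2))
        kept.append(site)
        mus.append(mu)
        sigmas.append(sigma)
    if not kept:
        raise DegenerateDataError("no site had enough data for a reference matrix")
    return ReferenceMatrix(
        site_ids=kept,
        age_grid=grid,
        mu=np.vstack(mus),
        sigma=np.vstack(sigmas),
        support_min=float(np.floor(ages.min())),
        support_max=float(np.ceil(ages.max())),
    )
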