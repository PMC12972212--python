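"""Clock-wide configuration.

A single :class:`ClockConfig` travels through training, serialization and
prediction so that a saved model carries every numerical choice that went
into it.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, fields

from .errors import InvalidConfigError

#: Likelihood families supported for the per-site density of a beta value.
FAMILIES = ("normal", "beta")


@dataclass(frozen=True)
class ClockConfig:
    """Hyper-parameters of the clock.

    Parameters
    ----------
    tau:
        LOWESS smoothing fraction (fraction of points in each local
        window), used both for the methylation-versus-age trend fit and
        for the variance-versus-methylation fit.
    n_robust_iters:
        Number of robustifying reweighting iterations in LOWESS.
    n_sites:
        Number of top age-correlated CpG sites kept per reference matrix.
    min_abs_rho:
        Spearman screening threshold: sites with ``|rho|`` below this are
        dropped before selection.
    family:
        Per-site likelihood family, ``"normal"`` or ``"beta"``.
    sigma_floor:
        Lower bound on the per-site, per-age standard deviation of beta
        values; prevents degenerate spike likelihoods.
    min_bin_size:
        Minimum number of same-age samples for an age bin to contribute a
        variance estimate.
    min_cohort_size:
        Minimum number of training samples per age cohort in stage 2.
    min_sites:
        Minimum number of overlapping sites required to predict a sample.
    x_eps:
        Beta values are clipped into ``[x_eps, 1 - x_eps]`` before
        evaluating the Beta log-density.
    feasibility_fraction:
        Variances are clipped to this fraction of the Bernoulli bound
        ``mu * (1 - mu)`` before Beta shape parameters are computed.
    """

    tau: float = 0.7
    n_robust_iters: int = 0
    n_sites: int = 16
    min_abs_rho: float = 0.60
    family: str = "normal"
    sigma_floor: float = 0.01
    min_bin_size: int = 3
    min_cohort_size: int = 30
    min_sites: int = 1
    x_eps: float = 1e-6
    feasibility_fraction: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise InvalidConfigError(f"tau must lie in (0, 1], got {self.tau}")
        if self.n_sites < 1:
            raise InvalidConfigError("n_sites must be >= 1")
        if not 0.0 <= self.min_abs_rho <= 1.0:
            raise InvalidConfigError("min_abs_rho must lie in [0, 1]")
        if self.family not in FAMILIES:
            raise InvalidConfigError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if self.sigma_floor <= 0:
            raise InvalidConfigError("sigma_floor must be > 0")
        if self.min_bin_size < 2:
            raise InvalidConfigError("min_bin_size must be >= 2")
        if not 0.0 < self.feasibility_fraction < 1.0:
            raise InvalidConfigError("feasibility_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClockConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


#: The candidate-age grid shared by every reference matrix (integer years).
AGE_GRID_MIN = 0
AGE_GRID_MAX = 100
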