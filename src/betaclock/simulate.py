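"""Synthetic methylation cohorts with the statistical structure the clock assumes.

The generator emulates the kind of blood-methylome compilation an epigenetic
clock is trained on: a minority of CpG sites whose beta value follows a
smooth monotone trend with age — saturating ("more logarithmic than linear")
by default — plus a background of age-independent sites, with
methylation-level-dependent noise variance, optional sex offsets and
optional missingness.  Every simulated dataset ships with a
:class:`GroundTruth` that can evaluate the noise-free curve exactly, so
recovery tests never need real data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dataset import MethylationDataset
from .errors import InvalidConfigError, ValidationError

CURVE_FAMILIES = ("logarithmic", "linear", "piecewise")
NOISE_FAMILIES = ("gaussian", "beta")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults describe the study conditions used throughout the test
    harness: a cohort spanning ages 0-100 with 16 informative CpG sites
    among 100, saturating logarithmic trends, and heteroscedastic noise
    with base standard deviation 0.03 on the beta scale (variance
    ``noise_scale**2 * (1 + 4 mu (1 - mu))``, largest at intermediate
    methylation).
    """

    n_samples: int = 500
    n_sites: int = 100
    n_informative: int = 16
    age_min: int = 0
    age_max: int = 100
    noise_scale: float = 0.03
    heteroscedastic: bool = True
    curve_family: Union[str, Sequence[str]] = "logarithmic"
    changepoint_age: float = 25.0
    junior_fraction: float = 0.6
    sex_effect_size: float = 0.0
    missing_rate: float = 0.0
    noise_family: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_sites:
            raise InvalidConfigError(
                f"n_informative ({self.n_informative}) exceeds n_sites ({self.n_sites})"
            )
        if self.age_min > self.age_max:
            raise InvalidConfigError(
                f"age_min ({self.age_min}) exceeds age_max ({self.age_max})"
            )
        if self.n_samples < 1 or self.n_sites < 1:
            raise InvalidConfigError("n_samples and n_sites must be >= 1")
        if self.noise_scale < 0:
            raise InvalidConfigError("noise_scale must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        fams = (
            [self.curve_family] * self.n_informative
            if isinstance(self.curve_family, str)
            else list(self.curve_family)
        )
        if len(fams) != self.n_informative and not isinstance(self.curve_family, str):
            raise InvalidConfigError(
                "curve_family list must have one entry per informative site"
            )
        for f in fams:
            if f not in CURVE_FAMILIES:
                raise InvalidConfigError(f"unknown curve family {f!r}")
        if self.noise_family not in NOISE_FAMILIES:
            raise InvalidConfigError(f"unknown noise family {self.noise_family!r}")
        if not self.age_min <= self.changepoint_age <= self.age_max:
            raise InvalidConfigError("changepoint_age must lie in [age_min, age_max]")
        if not 0.0 < self.junior_fraction < 1.0:
            raise InvalidConfigError("junior_fraction must lie in (0, 1)")

    @property
    def families(self) -> list:
        if isinstance(self.curve_family, str):
            return [self.curve_family] * self.n_informative
        return list(self.curve_family)


def _site_ids(n: int) -> list:
    # 450K-style probe IDs; zero-padded so lexicographic order is stable.
    return [f"cg{i:08d}" for i in range(n)]


@dataclass
class GroundTruth:
    """Noise-free description of a simulated cohort.

    ``curves`` holds one row per site: ``baseline`` (beta value at
    ``age_min``), signed ``amplitude`` (total change from ``age_min`` to
    ``age_max``; 0 for uninformative sites), ``family`` and
    ``informative``.  ``true_mean`` reproduces the exact noise-free curve
    used by the generator.
    """

    curves: pd.DataFrame
    ages: pd.Series
    sex: pd.Series
    config: SimConfig
    sex_shift_sites: list = field(default_factory=list)

    @property
    def informative_sites(self) -> list:
        return list(self.curves.index[self.curves["informative"]])

    def true_mean(self, site: str, age: float) -> float:
        """Noise-free methylation level of ``site`` at ``age`` (sex effects excluded)."""
        if site not in self.curves.index:
            raise KeyError(f"unknown site {site!r}")
        row = self.curves.loc[site]
        return float(
            _curve_value(
                np.asarray([float(age)]),
                row["baseline"],
                row["amplitude"],
                row["family"],
                self.config,
            )[0]
        )

    def true_mean_grid(self, ages: np.ndarray) -> pd.DataFrame:
        """Noise-free curves for all sites over ``ages`` (sites x ages)."""
        ages = np.asarray(ages, dtype=float)
        out = np.vstack(
            [
                _curve_value(ages, r.baseline, r.amplitude, r.family, self.config)
                for r in self.curves.itertuples()
            ]
        )
        return pd.DataFrame(out, index=self.curves.index, columns=ages)

    def to_dict(self) -> dict:
        return {
            "curves": self.curves.reset_index().to_dict(orient="list"),
            "ages": {"index": list(self.ages.index), "values": self.ages.tolist()},
            "sex": {"index": list(self.sex.index), "values": self.sex.tolist()},
            "config": asdict(self.config),
            "sex_shift_sites": list(self.sex_shift_sites),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        curves = pd.DataFrame(d["curves"]).set_index("site_id")
        cfg = dict(d["config"])
        if isinstance(cfg.get("curve_family"), list):
            cfg["curve_family"] = tuple(cfg["curve_family"])
        return cls(
            curves=curves,
            ages=pd.Series(d["ages"]["values"], index=d["ages"]["index"], dtype=float),
            sex=pd.Series(d["sex"]["values"], index=d["sex"]["index"]),
            config=SimConfig(**cfg),
            sex_shift_sites=list(d["sex_shift_sites"]),
        )


def _curve_value(
    ages: np.ndarray, baseline: float, amplitude: float, family: str, cfg: SimConfig
) -> np.ndarray:
    """Noise-free beta value of one site at the given ages, clipped to [0, 1].

    Families (t in [0, 1] is the normalized progress from age_min to age_max):

    * ``logarithmic`` — ``b + s * log(1 + a - age_min) / log(1 + age_max - age_min)``:
      saturating, fast change at young ages.
    * ``linear`` — ``b + s * t``: constant rate over life.
    * ``piecewise`` — two linear segments joined at ``changepoint_age``;
      a fraction ``junior_fraction`` of the amplitude is spent below the
      changepoint, so the junior slope is steeper than the senior slope.
    """
    a = np.asarray(ages, dtype=float) - cfg.age_min
    span = float(cfg.age_max - cfg.age_min)
    if family == "logarithmic":
        t = np.log1p(a) / np.log1p(span) if span > 0 else np.zeros_like(a)
    elif family == "linear":
        t = a / span if span > 0 else np.zeros_like(a)
    elif family == "piecewise":
        c = float(cfg.changepoint_age - cfg.age_min)
        r = cfg.junior_fraction
        junior = np.clip(a / c, 0.0, 1.0) if c > 0 else (a >= 0).astype(float)
        senior = np.clip((a - c) / (span - c), 0.0, 1.0) if span > c else np.zeros_like(a)
        t = r * junior + (1.0 - r) * senior
    else:  # pragma: no cover - guarded by SimConfig validation
        raise InvalidConfigError(f"unknown curve family {family!r}")
    return np.clip(baseline + amplitude * t, 0.0, 1.0)


def _noise_variance(mu: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.heteroscedastic:
        return cfg.noise_scale**2 * (1.0 + 4.0 * mu * (1.0 - mu))
    return np.full_like(mu, cfg.noise_scale**2)


def _draw_samples(
    curves: pd.DataFrame,
    sex_shift_sites: Sequence[str],
    cfg: SimConfig,
    n_samples: int,
    rng: np.random.Generator,
    id_prefix: str = "s",
):
    """Sample ages, sexes and noisy beta values under fixed site curves."""
    sites = list(curves.index)
    sample_ids = [f"{id_prefix}{i:05d}" for i in range(n_samples)]
    ages = rng.integers(cfg.age_min, cfg.age_max + 1, n_samples).astype(float)
    sex = np.where(rng.random(n_samples) < 0.5, "male", "female")

    mu = np.vstack(
        [
            _curve_value(ages, r.baseline, r.amplitude, r.family, cfg)
            for r in curves.itertuples()
        ]
    ).T  # samples x sites
    if cfg.sex_effect_size != 0.0 and len(sex_shift_sites):
        male = sex == "male"
        cols = [sites.index(s) for s in sex_shift_sites]
        mu[np.ix_(male, cols)] = np.clip(
            mu[np.ix_(male, cols)] + cfg.sex_effect_size, 0.0, 1.0
        )

    var = _noise_variance(mu, cfg)
    if cfg.noise_scale == 0.0:
        x = mu.copy()
    elif cfg.noise_family == "gaussian":
        x = np.clip(mu + rng.normal(0.0, np.sqrt(var)), 0.0, 1.0)
    else:  # moment-matched Beta noise
        eps = 1e-6
        mu_c = np.clip(mu, eps, 1.0 - eps)
        var_c = np.minimum(var, 0.99 * mu_c * (1.0 - mu_c))
        nu = mu_c * (1.0 - mu_c) / var_c - 1.0
        x = rng.beta(mu_c * nu, (1.0 - mu_c) * nu)

    if cfg.missing_rate > 0.0:
        mask = rng.random(x.shape) < cfg.missing_rate
        x = np.where(mask, np.nan, x)
        all_gone = np.isnan(x).all(axis=0)
        if all_gone.any():
            warnings.warn(
                f"{int(all_gone.sum())} sites lost every value to masking",
                stacklevel=3,
            )

    beta = pd.DataFrame(x, index=sample_ids, columns=sites)
    return MethylationDataset(
        beta=beta,
        ages=pd.Series(ages, index=sample_ids),
        sex=pd.Series(sex, index=sample_ids),
    )


def simulate_dataset(config: SimConfig):
    """Draw one synthetic cohort.

    Ages are integer years uniform on ``[age_min, age_max]``; sexes are
    balanced Bernoulli draws.  Informative sites follow their configured
    curve family with a baseline and signed amplitude drawn so the curve
    stays inside ``[0.02, 0.98]``; uninformative sites are age-independent
    noise around their baseline.  When ``sex_effect_size > 0``, a random
    25% of informative sites (at least one) get an additive offset for
    male samples.  Noise is truncated-Gaussian on the beta scale by
    default, or moment-matched Beta draws with ``noise_family="beta"``.

    Returns
    -------
    (MethylationDataset, GroundTruth)
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sites = _site_ids(cfg.n_sites)

    families = cfg.families
    n_inf = cfg.n_informative
    mag = rng.uniform(0.3, 0.6, n_inf)
    sign = rng.choice([-1.0, 1.0], n_inf)
    baseline = np.where(
        sign > 0,
        rng.uniform(0.02, np.maximum(0.98 - mag, 0.021)),
        rng.uniform(np.minimum(0.02 + mag, 0.979), 0.98),
    )
    amplitude = sign * mag

    curves = pd.DataFrame(
        {
            "baseline": np.concatenate(
                [baseline, rng.uniform(0.05, 0.95, cfg.n_sites - n_inf)]
            ),
            "amplitude": np.concatenate([amplitude, np.zeros(cfg.n_sites - n_inf)]),
            "family": families + ["linear"] * (cfg.n_sites - n_inf),
            "informative": [True] * n_inf + [False] * (cfg.n_sites - n_inf),
        },
        index=pd.Index(sites, name="site_id"),
    )

    sex_shift_sites: list = []
    if cfg.sex_effect_size != 0.0 and n_inf > 0:
        n_shift = max(1, int(round(0.25 * n_inf)))
        shift_idx = sorted(rng.choice(n_inf, size=n_shift, replace=False))
        sex_shift_sites = [sites[i] for i in shift_idx]

    dataset = _draw_samples(curves, sex_shift_sites, cfg, cfg.n_samples, rng)
    truth = GroundTruth(
        curves=curves,
        ages=dataset.ages.copy(),
        sex=dataset.sex.copy(),
        config=cfg,
        sex_shift_sites=sex_shift_sites,
    )
    return dataset, truth


def simulate_like(
    truth: GroundTruth, n_samples: int, seed: int, id_prefix: str = "t"
):
    """Draw a fresh cohort under an existing ground truth's curves.

    Ages, sexes, noise and missingness are re-sampled with the given seed
    while every site keeps its curve — the natural way to build a test
    set for a clock trained on :func:`simulate_dataset` output.
    """
    rng = np.random.default_rng(seed)
    return _draw_samples(
        truth.curves, truth.sex_shift_sites, truth.config, n_samples, rng, id_prefix
    )


def true_mean(truth: GroundTruth, site: str, age: float) -> float:
    """Noise-free methylation of ``site`` at ``age`` — oracle for recovery tests."""
    return truth.true_mean(site, age)
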