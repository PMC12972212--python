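"""Error metrics, cross-validation and penalized-regression baselines.

Conventions: errors are ``predicted - real`` throughout, so a positive
mean bias error (MBE) means over-prediction.  R^2 is
``1 - SS_res / SS_tot`` with real ages as targets, and is reported as NaN
when the real ages have zero variance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .config import ClockConfig
from .dataset import MethylationDataset
from .errors import (
    BetaClockError,
    DegenerateDataError,
    InvalidConfigError,
    ValidationError,
)
from .trend import LowessConfig, fit_lowess
from .two_stage import (
    DEFAULT_CUTOFF_CANDIDATES,
    predict_two_stage,
    train_two_stage,
)


class Metrics(NamedTuple):
    mae: float
    rmse: float
    mbe: float
    r2: float


def compute_metrics(predicted, real) -> Metrics:
    """MAE, RMSE, MBE and R^2 of predicted versus real ages."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(real, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValidationError("predicted and real must be 1-D and equally long")
    if p.size == 0:
        raise ValidationError("empty input")
    err = p - r
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    mbe = float(err.mean())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - float((err**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return Metrics(mae=mae, rmse=rmse, mbe=mbe, r2=r2)


@dataclass(frozen=True)
class FoldAssignment:
    """A k-fold partition: ``fold[i]`` is the fold index of sample i."""

    k: int
    seed: int
    fold: np.ndarray

    def test_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def train_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold != f)


def make_folds(n_samples: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded uniform partition into k mutually exclusive near-equal folds.

    The first ``n_samples % k`` folds get one extra sample.
    """
    if k < 2:
        raise InvalidConfigError(f"k must be >= 2, got {k}")
    if k > n_samples:
        raise InvalidConfigError(f"k ({k}) exceeds n_samples ({n_samples})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    sizes = np.full(k, n_samples // k)
    sizes[: n_samples % k] += 1
    fold = np.empty(n_samples, dtype=int)
    start = 0
    for f, size in enumerate(sizes):
        fold[perm[start : start + size]] = f
        start += size
    return FoldAssignment(k=k, seed=seed, fold=fold)


@dataclass
class EvaluationReport:
    """Out-of-fold predictions with overall and per-cohort error metrics.

    Cohort membership for *evaluation* is by real age at each sample's
    model cutoff (prediction routing, in contrast, uses the stage-1
    estimate).  ``failures`` maps fold index to the error that prevented
    training or prediction for that fold.
    """

    predictions: pd.DataFrame  # sample_id, real_age, stage1_age, final_age,
    #                            cohort, fold, cutoff_age
    overall: Metrics
    junior: Optional[Metrics]
    senior: Optional[Metrics]
    failures: dict = field(default_factory=dict)

    @property
    def residuals(self) -> pd.DataFrame:
        ok = self.predictions["final_age"].notna()
        out = self.predictions.loc[ok, ["real_age"]].copy()
        out["residual"] = (
            self.predictions.loc[ok, "final_age"] - out["real_age"]
        )
        return out


def _score(pred: pd.DataFrame) -> "EvaluationReport":
    ok = pred["final_age"].notna()
    scored = pred.loc[ok]
    if scored.empty:
        raise BetaClockError("no successful predictions to score")
    overall = compute_metrics(scored["final_age"], scored["real_age"])
    jr_mask = scored["real_age"] <= scored["cutoff_age"]
    junior = (
        compute_metrics(scored.loc[jr_mask, "final_age"], scored.loc[jr_mask, "real_age"])
        if jr_mask.any()
        else None
    )
    senior = (
        compute_metrics(scored.loc[~jr_mask, "final_age"], scored.loc[~jr_mask, "real_age"])
        if (~jr_mask).any()
        else None
    )
    return EvaluationReport(
        predictions=pred, overall=overall, junior=junior, senior=senior
    )


def run_cross_validation(
    dataset: MethylationDataset,
    config: ClockConfig = ClockConfig(),
    k: int = 10,
    seed: int = 0,
    cutoff: Optional[int] = 25,
    scan_validation_fraction: float = 0.2,
    candidates: Iterable[int] = DEFAULT_CUTOFF_CANDIDATES,
) -> EvaluationReport:
    """k-fold cross-validation of the full two-stage pipeline.

    Each fold's model trains on the remaining k-1 folds and predicts the
    held-out fold, so every sample receives exactly one out-of-fold
    prediction.  With ``cutoff=None`` the cutoff scan runs inside each
    fold on a seeded validation split (``scan_validation_fraction`` of
    that fold's training samples), never on the held-out fold.  Folds
    whose training fails (e.g. an under-sized cohort) are recorded in
    ``failures`` and the run continues.
    """
    if dataset.ages is None:
        raise ValidationError("dataset has no ages")
    folds = make_folds(dataset.n_samples, k=k, seed=seed)
    # folds attach to the sorted sample IDs, so the report is invariant to
    # the row order of the input matrix
    ids = np.array(sorted(dataset.sample_ids), dtype=object)
    parts = []
    failures: dict = {}
    for f in range(k):
        train = dataset.subset_samples(ids[folds.train_indices(f)])
        test = dataset.subset_samples(ids[folds.test_indices(f)])
        try:
            if cutoff is None:
                inner_rng = np.random.default_rng((seed, f))
                n_tr = train.n_samples
                n_val = max(1, int(round(scan_validation_fraction * n_tr)))
                val_idx = inner_rng.choice(n_tr, size=n_val, replace=False)
                val_mask = np.zeros(n_tr, dtype=bool)
                val_mask[val_idx] = True
                tr_ids = np.asarray(train.sample_ids, dtype=object)
                model, _ = train_two_stage(
                    train.subset_samples(tr_ids[~val_mask]),
                    config,
                    cutoff=None,
                    validation=train.subset_samples(tr_ids[val_mask]),
                    candidates=candidates,
                )
            else:
                model, _ = train_two_stage(train, config, cutoff=cutoff)
            pred = predict_two_stage(model, test)
        except BetaClockError as exc:
            failures[f] = str(exc)
            continue
        part = pred.reset_index()
        part["real_age"] = test.ages.to_numpy()
        part["fold"] = f
        part["cutoff_age"] = model.cutoff_age
        parts.append(part)
    if not parts:
        raise BetaClockError(f"every fold failed: {failures}")
    pred = pd.concat(parts, ignore_index=True)
    report = _score(pred)
    report.failures = failures
    return report


class PenalizedBaseline:
    """Elastic-net linear baseline: age regressed on site beta values.

    Minimizes ``(1 / 2n) ||y - X b||^2 + lam * (l1_ratio ||b||_1 +
    (1 - l1_ratio) / 2 ||b||_2^2)``; ``l1_ratio = 1`` is the LASSO.
    Missing beta values are imputed with the per-site training mean
    (the baseline only — the clock itself never imputes).
    """

    def __init__(self, lam: float = 0.01, l1_ratio: float = 1.0):
        if lam <= 0:
            raise InvalidConfigError("lambda must be > 0")
        if not 0.0 <= l1_ratio <= 1.0:
            raise InvalidConfigError("l1_ratio must lie in [0, 1]")
        self.lam = lam
        self.l1_ratio = l1_ratio
        self.site_ids_: Optional[list] = None
        self.site_means_: Optional[pd.Series] = None
        self.model_: Optional[ElasticNet] = None

    def fit(self, train: MethylationDataset) -> "PenalizedBaseline":
        if train.ages is None:
            raise ValidationError("training data has no ages")
        beta = train.beta
        means = beta.mean(axis=0, skipna=True)
        usable = means.notna()
        x = beta.loc[:, usable].fillna(means[usable])
        if x.shape[1] == 0 or (x.nunique(axis=0) <= 1).all():
            raise DegenerateDataError("design matrix has no non-constant columns")
        self.site_ids_ = list(x.columns)
        self.site_means_ = means[usable]
        self.model_ = ElasticNet(
            alpha=self.lam, l1_ratio=self.l1_ratio, max_iter=50000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny lambda
            self.model_.fit(x.to_numpy(), train.ages.to_numpy())
        return self

    def predict(self, dataset: MethylationDataset) -> pd.Series:
        if self.model_ is None:
            raise BetaClockError("baseline is not fitted")
        x = dataset.beta.reindex(columns=self.site_ids_)
        x = x.fillna(self.site_means_)
        return pd.Series(
            self.model_.predict(x.to_numpy()), index=dataset.beta.index
        )


def fit_penalized_baseline(
    train: MethylationDataset, lam: float = 0.01, l1_ratio: float = 1.0
) -> PenalizedBaseline:
    """Fit the elastic-net / LASSO age baseline on a training dataset."""
    return PenalizedBaseline(lam=lam, l1_ratio=l1_ratio).fit(train)


@dataclass
class ResidualTrend:
    """Linear and LOWESS summaries of residuals against real age."""

    slope: float
    intercept: float
    correlation: float
    mean_residual: float
    lowess_age: np.ndarray
    lowess_residual: np.ndarray


def residual_diagnostics(
    report_or_predictions, real=None, tau: float = 0.7
) -> ResidualTrend:
    """Trend of residuals (predicted - real) against real age.

    Accepts an :class:`EvaluationReport` or a ``(predicted, real)`` pair.
    A residual-versus-age correlation near zero is the signature of an
    unbiased clock.
    """
    if isinstance(report_or_predictions, EvaluationReport):
        res = report_or_predictions.residuals
        ages = res["real_age"].to_numpy()
        residuals = res["residual"].to_numpy()
    else:
        p = np.asarray(report_or_predictions, dtype=float)
        r = np.asarray(real, dtype=float)
        ages, residuals = r, p - r
    if ages.size < 10:
        raise ValidationError("need at least 10 samples for residual diagnostics")
    slope, intercept = np.polyfit(ages, residuals, 1)
    sd = residuals.std()
    # guard against float crumbs on effectively constant residuals
    degenerate = sd <= 1e-9 * max(1.0, float(np.abs(residuals).max()))
    corr = 0.0 if degenerate else float(np.corrcoef(ages, residuals)[0, 1])
    smoother = fit_lowess(ages, residuals, LowessConfig(tau=tau))
    return ResidualTrend(
        slope=float(slope),
        intercept=float(intercept),
        correlation=corr,
        mean_residual=float(residuals.mean()),
        lowess_age=smoother.x_,
        lowess_residual=smoother.fitted_,
    )
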