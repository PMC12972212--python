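"""Two-stage training and prediction, with optional sex-specific models.

Stage 1 trains a single clock on the whole training population: screen
sites by |Spearman rho|, keep the top ``n_sites``, build the reference
matrix.  Stage 2 splits the training samples at a cutoff age (real age <=
cutoff -> junior), re-ranks sites *within the screened set* per cohort,
and builds a junior and a senior reference matrix.  Prediction first runs
the stage-1 clock, routes each sample by its initial estimate (stage-1 age
<= routing threshold -> junior), and re-predicts with the routed cohort's
reference.  The cutoff is either fixed (the canonical choice is 25, the
junior/senior boundary of the original study) or chosen by scanning
candidates 10..30 and keeping the one with the smallest |mean bias error|
on a held-out validation set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ClockConfig
from .dataset import MethylationDataset
from .errors import (
    CohortSizeError,
    DegenerateDataError,
    ValidationError,
)
from .likelihood import argmax_age, profile_matrix
from .selection import screen_sites, select_top_sites, spearman_correlations
from .trend import ReferenceMatrix, build_reference_matrix

DEFAULT_CUTOFF_CANDIDATES = tuple(range(10, 31))

PREDICTION_COLUMNS = [
    "sample_id",
    "stage1_age",
    "final_age",
    "cohort",
    "n_sites_used",
    "max_log_likelihood",
]


@dataclass
class TwoStageModel:
    """The trained clock: three reference matrices plus routing rule."""

    stage1: ReferenceMatrix
    junior: ReferenceMatrix
    senior: ReferenceMatrix
    cutoff_age: int
    routing_threshold: int
    config: ClockConfig = field(default_factory=ClockConfig)
    sex_label: str = "mixed"


@dataclass
class CutoffScanResult:
    """Validation metrics per candidate cutoff and the selected cutoff."""

    table: pd.DataFrame  # columns: cutoff, mae, rmse, mbe (NaN rows = skipped)
    selected_cutoff: int


def _select_sites(dataset: MethylationDataset, config: ClockConfig,
                  universe: Optional[Sequence] = None) -> list:
    """Screen-then-rank site selection on (a restriction of) the dataset."""
    ds = dataset if universe is None else dataset.subset_sites(list(universe))
    corr = spearman_correlations(ds)
    kept = screen_sites(corr, config.min_abs_rho)
    sites = select_top_sites(corr.loc[kept], config.n_sites)
    if not sites:
        raise DegenerateDataError("no usable site after screening and selection")
    return sites


def train_stage1(
    train: MethylationDataset,
    config: ClockConfig = ClockConfig(),
    universe: Optional[Sequence] = None,
) -> ReferenceMatrix:
    """Whole-population clock: screen, select top sites, build the reference."""
    sites = _select_sites(train, config, universe)
    return build_reference_matrix(train, sites, config)


def screened_universe(train: MethylationDataset, config: ClockConfig) -> list:
    """Sites passing the |rho| screen on the full training population."""
    corr = spearman_correlations(train)
    return screen_sites(corr, config.min_abs_rho)


def train_cohort_models(
    train: MethylationDataset,
    cutoff_age: int,
    config: ClockConfig = ClockConfig(),
    universe: Optional[Sequence] = None,
) -> Tuple[ReferenceMatrix, ReferenceMatrix]:
    """Junior and senior reference matrices for a given training cutoff.

    The training set splits at real age <= ``cutoff_age``; each cohort
    re-runs screening and top-k selection on its own data, restricted to
    ``universe`` (normally the whole-population screened set) when given.
    """
    if train.ages is None:
        raise ValidationError("training data has no ages")
    junior_mask = train.ages <= cutoff_age
    refs = []
    for name, mask in (("junior", junior_mask), ("senior", ~junior_mask)):
        n = int(mask.sum())
        if n == 0:
            raise CohortSizeError(f"{name} cohort is empty at cutoff {cutoff_age}")
        if n < config.min_cohort_size:
            raise CohortSizeError(
                f"{name} cohort has {n} samples at cutoff {cutoff_age} "
                f"(minimum {config.min_cohort_size})"
            )
        cohort = train.subset_samples(mask)
        sites = _select_sites(cohort, config, universe)
        refs.append(build_reference_matrix(cohort, sites, config))
    return refs[0], refs[1]


def _predict_with_reference(
    samples: MethylationDataset, reference: ReferenceMatrix, config: ClockConfig
) -> pd.DataFrame:
    """Grid-MLE ages for all samples under one reference (NaN if no overlap)."""
    L, n_used = profile_matrix(samples.beta, reference, config)
    ok = ~np.isnan(L).all(axis=1)
    age = np.full(samples.n_samples, np.nan)
    max_ll = np.full(samples.n_samples, np.nan)
    support = (reference.support_min, reference.support_max)
    for i in np.flatnonzero(ok):
        age[i] = argmax_age(L[i], reference.age_grid, support)
        max_ll[i] = np.max(L[i])
    return pd.DataFrame(
        {"age": age, "n_sites_used": n_used, "max_log_likelihood": max_ll},
        index=samples.beta.index,
    )


def predict_single_stage(
    reference: ReferenceMatrix,
    samples: MethylationDataset,
    config: ClockConfig = ClockConfig(),
) -> pd.DataFrame:
    """Grid-MLE ages under a single reference matrix (no routing).

    Returns columns ``age``, ``n_sites_used`` and ``max_log_likelihood``;
    ``age`` is NaN for samples with no usable site.
    """
    return _predict_with_reference(samples, reference, config)


def predict_two_stage(
    model: TwoStageModel, samples: MethylationDataset
) -> pd.DataFrame:
    """Route by the stage-1 estimate and re-predict with the cohort model.

    Returns one row per input sample with columns ``stage1_age``,
    ``final_age``, ``cohort`` (``junior``/``senior``, or ``failed`` when a
    sample shares no site with the required reference), ``n_sites_used``
    and ``max_log_likelihood`` of the final prediction.
    """
    stage1 = _predict_with_reference(samples, model.stage1, model.config)
    out = pd.DataFrame(index=samples.beta.index)
    out["stage1_age"] = stage1["age"]
    out["final_age"] = np.nan
    out["cohort"] = "failed"
    out["n_sites_used"] = 0
    out["max_log_likelihood"] = np.nan

    junior_mask = stage1["age"] <= model.routing_threshold  # NaN -> False
    senior_mask = stage1["age"].notna() & ~junior_mask
    for name, mask, ref in (
        ("junior", junior_mask, model.junior),
        ("senior", senior_mask, model.senior),
    ):
        if not mask.any():
            continue
        sub = samples.subset_samples(mask)
        pred = _predict_with_reference(sub, ref, model.config)
        ok = pred["age"].notna()
        out.loc[pred.index[ok], "final_age"] = pred.loc[ok, "age"]
        out.loc[pred.index[ok], "cohort"] = name
        out.loc[pred.index[ok], "n_sites_used"] = pred.loc[ok, "n_sites_used"]
        out.loc[pred.index[ok], "max_log_likelihood"] = pred.loc[ok, "max_log_likelihood"]
    n_failed = int((out["cohort"] == "failed").sum())
    if n_failed:
        warnings.warn(f"{n_failed} samples could not be predicted (no site overlap)",
                      stacklevel=2)
    out.index.name = "sample_id"
    return out


def optimize_cutoff(
    train: MethylationDataset,
    validation: MethylationDataset,
    candidates: Iterable[int] = DEFAULT_CUTOFF_CANDIDATES,
    config: ClockConfig = ClockConfig(),
) -> CutoffScanResult:
    """Scan junior/senior cutoffs and keep the one with the lowest |MBE|.

    For each candidate cutoff the cohort models are retrained on
    ``train``, a full two-stage prediction (routing threshold = the
    candidate) is produced for ``validation``, and MAE / RMSE / MBE are
    recorded.  Candidates that leave a cohort under-sized are skipped with
    a warning.  Ties in |MBE| resolve to the smallest cutoff.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValidationError("no cutoff candidates given")
    if validation.ages is None:
        raise ValidationError("validation data has no ages")
    universe = screened_universe(train, config)
    stage1 = train_stage1(train, config, universe=universe)
    rows = []
    for cutoff in candidates:
        try:
            junior, senior = train_cohort_models(train, cutoff, config, universe)
        except CohortSizeError as exc:
            warnings.warn(f"cutoff {cutoff} skipped: {exc}", stacklevel=2)
            rows.append((cutoff, np.nan, np.nan, np.nan))
            continue
        model = TwoStageModel(
            stage1=stage1, junior=junior, senior=senior,
            cutoff_age=cutoff, routing_threshold=cutoff, config=config,
        )
        pred = predict_two_stage(model, validation)
        ok = pred["final_age"].notna()
        err = pred.loc[ok, "final_age"] - validation.ages[ok]
        rows.append(
            (
                cutoff,
                float(err.abs().mean()),
                float(np.sqrt((err**2).mean())),
                float(err.mean()),
            )
        )
    table = pd.DataFrame(rows, columns=["cutoff", "mae", "rmse", "mbe"])
    usable = table.dropna(subset=["mbe"])
    if usable.empty:
        raise CohortSizeError("every cutoff candidate was skipped")
    best = usable.loc[usable["mbe"].abs().idxmin()]  # idxmin: first (smallest cutoff)
    return CutoffScanResult(table=table, selected_cutoff=int(best["cutoff"]))


def train_two_stage(
    train: MethylationDataset,
    config: ClockConfig = ClockConfig(),
    cutoff: Optional[int] = 25,
    validation: Optional[MethylationDataset] = None,
    candidates: Iterable[int] = DEFAULT_CUTOFF_CANDIDATES,
    sex_label: str = "mixed",
) -> Tuple[TwoStageModel, Optional[CutoffScanResult]]:
    """Full training pipeline.

    With ``cutoff=None`` the cutoff is chosen by :func:`optimize_cutoff`
    on ``validation`` (required in that case); otherwise the given cutoff
    is used directly and no scan is run.
    """
    universe = screened_universe(train, config)
    scan = None
    if cutoff is None:
        if validation is None:
            raise ValidationError("cutoff scan requires a validation dataset")
        scan = optimize_cutoff(train, validation, candidates, config)
        cutoff = scan.selected_cutoff
    stage1 = train_stage1(train, config, universe=universe)
    junior, senior = train_cohort_models(train, int(cutoff), config, universe)
    model = TwoStageModel(
        stage1=stage1,
        junior=junior,
        senior=senior,
        cutoff_age=int(cutoff),
        routing_threshold=int(cutoff),
        config=config,
        sex_label=sex_label,
    )
    return model, scan


def train_sex_specific(
    train: MethylationDataset,
    config: ClockConfig = ClockConfig(),
    cutoff: Optional[int] = 25,
    validation: Optional[MethylationDataset] = None,
    candidates: Iterable[int] = DEFAULT_CUTOFF_CANDIDATES,
) -> Dict[str, TwoStageModel]:
    """Independent two-stage clocks per sex.

    Samples with unknown sex are excluded with a warning; an absent or
    under-sized sex group is an error.  When a validation set is given it
    is split by sex the same way.
    """
    models: Dict[str, TwoStageModel] = {}
    n_unknown = int((train.sex == "unknown").sum())
    if n_unknown:
        warnings.warn(f"{n_unknown} training samples with unknown sex excluded",
                      stacklevel=2)
    for sex in ("male", "female"):
        mask = train.sex == sex
        n = int(mask.sum())
        if n < config.min_cohort_size:
            raise CohortSizeError(
                f"{sex} group has {n} samples (minimum {config.min_cohort_size})"
            )
        sub = train.subset_samples(mask)
        val = None
        if validation is not None:
            vmask = validation.sex == sex
            val = validation.subset_samples(vmask) if vmask.any() else None
        models[sex], _ = train_two_stage(
            sub, config, cutoff=cutoff, validation=val,
            candidates=candidates, sex_label=sex,
        )
    return models
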