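"""In-memory containers for methylation data.

The central object is :class:`MethylationDataset`: a samples x CpG-sites
matrix of beta values in ``[0, 1]`` (``NaN`` marks a missing measurement)
together with optional per-sample chronological ages and sex labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

SEXES = ("male", "female", "unknown")


def normalize_sex(value: object) -> str:
    """Map free-form sex labels onto ``male`` / ``female`` / ``unknown``."""
    s = str(value).strip().lower()
    if s in {"m", "male"}:
        return "male"
    if s in {"f", "female"}:
        return "female"
    return "unknown"


@dataclass
class MethylationDataset:
    """Beta-value matrix with per-sample metadata.

    Parameters
    ----------
    beta:
        DataFrame of beta values, index = sample IDs, columns = CpG probe
        IDs (e.g. ``cg00000029``). ``NaN`` encodes a missing entry.
    ages:
        Chronological age in years per sample, aligned to ``beta.index``;
        ``None`` for prediction-only data.
    sex:
        Sex label per sample (``male``/``female``/``unknown``); defaults
        to ``unknown`` everywhere.
    """

    beta: pd.DataFrame
    ages: Optional[pd.Series] = None
    sex: Optional[pd.Series] = field(default=None)

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        if self.beta.columns.has_duplicates:
            dups = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site IDs: {dups[:5]}")
        values = self.beta.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "beta value out of [0, 1] at sample "
                f"{self.beta.index[i]!r}, site {self.beta.columns[j]!r}: "
                f"{values[i, j]}"
            )
        self.beta = pd.DataFrame(values, index=self.beta.index, columns=self.beta.columns)
        if self.ages is not None:
            ages = pd.Series(self.ages, dtype=float).reindex(self.beta.index)
            if ages.isna().any():
                missing = ages.index[ages.isna()].tolist()
                raise ValidationError(f"samples without an age: {missing[:5]}")
            if (ages < 0).any():
                raise ValidationError("negative ages are not allowed")
            self.ages = ages
        if self.sex is None:
            self.sex = pd.Series("unknown", index=self.beta.index)
        else:
            sex = pd.Series(self.sex).reindex(self.beta.index)
            self.sex = sex.map(normalize_sex)

    # -- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_sites(self) -> int:
        return self.beta.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(self.beta.index)

    @property
    def site_ids(self) -> list:
        return list(self.beta.columns)

    # -- subsetting -----------------------------------------------------
    def subset_samples(self, which: Iterable) -> "MethylationDataset":
        """Restrict to the given sample IDs (or boolean mask)."""
        which = list(which) if not isinstance(which, (pd.Series, np.ndarray)) else which
        beta = self.beta.loc[which]
        ages = self.ages.loc[beta.index] if self.ages is not None else None
        sex = self.sex.loc[beta.index]
        return MethylationDataset(beta=beta, ages=ages, sex=sex)

    def subset_sites(self, site_ids: Sequence) -> "MethylationDataset":
        """Restrict to the given CpG sites (order preserved)."""
        missing = [s for s in site_ids if s not in self.beta.columns]
        if missing:
            raise ValidationError(f"unknown site IDs: {missing[:5]}")
        return MethylationDataset(
            beta=self.beta.loc[:, list(site_ids)], ages=self.ages, sex=self.sex
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationDataset):
            return NotImplemented
        same_beta = self.beta.equals(other.beta)
        same_ages = (
            (self.ages is None and other.ages is None)
            or (self.ages is not None and other.ages is not None and self.ages.equals(other.ages))
        )
        return same_beta and same_ages and self.sex.equals(other.sex)
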