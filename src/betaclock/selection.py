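"""Age-correlation screening and selection of CpG sites.

Sites are ranked by the Spearman rank correlation between methylation and
chronological age, computed on pairwise-complete observations with average
(midrank) handling of ties.  Spearman is used because the trends of
interest are monotone but not linear.  A coarse screen (``|rho| >=
min_abs_rho``, default 0.60) first narrows the site universe; the top-k
selection (default 16) then operates within the screened set.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MethylationDataset
from .errors import InvalidConfigError, ValidationError

#: fewer usable (age, beta) pairs than this leaves rho undefined
MIN_PAIRS = 3


def spearman_correlations(dataset: MethylationDataset) -> pd.DataFrame:
    """Per-site Spearman correlation of methylation with age.

    Returns a DataFrame indexed by site ID with columns ``rho`` and
    ``n_used`` (number of non-missing pairs).  Sites with fewer than
    three usable pairs, or with constant methylation, get ``rho = NaN``
    and are excluded from any downstream screening or selection.
    """
    if dataset.ages is None:
        raise ValidationError("dataset has no ages; cannot correlate with age")
    ages = dataset.ages.to_numpy()
    values = dataset.beta.to_numpy()
    rhos = np.full(dataset.n_sites, np.nan)
    n_used = np.zeros(dataset.n_sites, dtype=int)
    for j in range(dataset.n_sites):
        x = values[:, j]
        ok = ~np.isnan(x)
        n = int(ok.sum())
        n_used[j] = n
        if n < MIN_PAIRS:
            continue
        with warnings.catch_warnings():
            # constant input raises a ConstantInputWarning and returns NaN,
            # which is exactly the "undefined rho" we want
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(ages[ok], x[ok]).statistic
        rhos[j] = rho
    return pd.DataFrame(
        {"rho": rhos, "n_used": n_used},
        index=pd.Index(dataset.site_ids, name="site_id"),
    )


def screen_sites(correlations: pd.DataFrame, min_abs_rho: float = 0.60) -> list:
    """Retain the sites with ``|rho| >= min_abs_rho`` (undefined rho drops out)."""
    if not 0.0 <= min_abs_rho <= 1.0:
        raise InvalidConfigError("min_abs_rho must lie in [0, 1]")
    rho = correlations["rho"]
    kept = list(correlations.index[rho.abs() >= min_abs_rho])
    if not kept:
        warnings.warn(
            f"no site passed the |rho| >= {min_abs_rho} screen", stacklevel=2
        )
    return kept


def select_top_sites(correlations: pd.DataFrame, k: int = 16) -> list:
    """The ``k`` sites most strongly correlated with age, strongest first.

    Ordering is by ``|rho|`` descending with ties broken by site ID
    ascending, which makes the selection invariant to input order.  If
    fewer than ``k`` sites have a defined rho, all of them are returned
    with a warning.
    """
    if k < 1:
        raise InvalidConfigError(f"k must be >= 1, got {k}")
    defined = correlations.dropna(subset=["rho"])
    order = sorted(
        defined.index, key=lambda s: (-abs(defined.at[s, "rho"]), str(s))
    )
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} sites available for top-{k} selection",
            stacklevel=2,
        )
    return order[:k]
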