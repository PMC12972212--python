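"""Reading and writing matrices, metadata, predictions and trained models.

File conventions
----------------
* Beta matrix: TSV/CSV with a header of probe IDs and a first column of
  sample IDs (``orientation="sites_by_samples"`` transposes on read).
  Empty cells or ``NA`` mark missing values.
* Metadata: TSV/CSV with columns ``sample_id``, ``age``, ``sex``.
* Predictions: TSV with one row per sample.
* Model: versioned JSON holding the three reference-matrix grids, the
  cutoff and routing threshold, and the full configuration, so a loaded
  model reproduces predictions bit-exactly regardless of the smoothing
  implementation that produced it.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ClockConfig
from .dataset import MethylationDataset, normalize_sex
from .errors import ModelSchemaError, ValidationError
from .trend import ReferenceMatrix
from .two_stage import TwoStageModel

MODEL_FORMAT = "betaclock-model"
MODEL_SCHEMA_VERSION = 1

_NA_TOKENS = {"", "na", "nan", "null", "none"}


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_beta_matrix(
    path, orientation: str = "samples_by_sites", sep: Optional[str] = None
) -> pd.DataFrame:
    """Parse a beta-value matrix into a samples x sites DataFrame.

    Values must be numeric in [0, 1] or missing (empty/``NA``); anything
    else raises a :class:`ValidationError` naming the offending cell.
    """
    if orientation not in ("samples_by_sites", "sites_by_samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0, dtype=str)
    if orientation == "sites_by_samples":
        raw = raw.T
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise ValidationError("duplicate sample or site IDs in matrix file")

    raw = raw.astype("string")
    stripped = raw.apply(lambda c: c.str.strip())
    na_mask = raw.isna() | stripped.apply(lambda c: c.str.lower().isin(_NA_TOKENS))
    # parse via float() (not pandas' fast-but-lossy parser) so values
    # round-trip bit-exactly
    filled = stripped.where(~na_mask.to_numpy(), other="nan")
    values = np.empty(raw.shape)
    for j in range(raw.shape[1]):
        col = filled.iloc[:, j].to_numpy(dtype=object)
        try:
            values[:, j] = col.astype(float)
        except ValueError:
            for i, token in enumerate(col):
                try:
                    float(token)
                except ValueError:
                    raise ValidationError(
                        f"non-numeric value {raw.iat[i, j]!r} at sample "
                        f"{raw.index[i]!r}, site {raw.columns[j]!r}"
                    ) from None
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {values[i, j]} out of [0, 1] at sample "
            f"{raw.index[i]!r}, site {raw.columns[j]!r}"
        )
    out = pd.DataFrame(
        values, index=raw.index.astype(str), columns=raw.columns.astype(str)
    )
    out.index.name = None
    out.columns.name = None
    return out


def write_beta_matrix(beta: pd.DataFrame, path, sep: Optional[str] = None) -> None:
    # %.17g keeps the text round-trip bit-exact
    beta.to_csv(path, sep=sep or _sep_for(path), index_label="sample_id",
                na_rep="NA", float_format="%.17g")


def read_metadata(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Parse sample metadata (sample_id, age, sex) with normalization.

    Ages must be non-negative numbers (may be absent for prediction-only
    data); sex is normalized case-insensitively from {M, F, male, female},
    anything else becomes ``unknown``.
    """
    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValidationError("metadata needs a sample_id column")
    out = pd.DataFrame()
    out["sample_id"] = df[cols["sample_id"]].astype(str)
    if out["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample IDs in metadata")
    if "age" in cols:
        ages = pd.to_numeric(df[cols["age"]], errors="coerce")
        bad = ages.isna() & df[cols["age"]].notna() & (
            ~df[cols["age"]].str.strip().str.lower().isin(_NA_TOKENS)
        )
        if bad.any():
            raise ValidationError(
                f"non-numeric age for sample {out['sample_id'][bad].iloc[0]!r}"
            )
        if (ages < 0).any():
            raise ValidationError(
                f"negative age for sample {out['sample_id'][ages < 0].iloc[0]!r}"
            )
        out["age"] = ages
    else:
        out["age"] = np.nan
    if "sex" in cols:
        out["sex"] = df[cols["sex"]].map(normalize_sex)
    else:
        out["sex"] = "unknown"
    return out.set_index("sample_id")


def write_metadata(dataset: MethylationDataset, path, sep: Optional[str] = None) -> None:
    df = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "age": dataset.ages if dataset.ages is not None else np.nan,
            "sex": dataset.sex.to_numpy(),
        }
    )
    df.to_csv(path, sep=sep or _sep_for(path), index=False)


def load_dataset(
    beta_path,
    metadata_path=None,
    orientation: str = "samples_by_sites",
    strict: bool = True,
) -> MethylationDataset:
    """Read a matrix (and optional metadata) into a MethylationDataset.

    In strict mode, matrix samples absent from the metadata are an error;
    in lenient mode they are dropped with a warning.
    """
    beta = read_beta_matrix(beta_path, orientation=orientation)
    if metadata_path is None:
        return MethylationDataset(beta=beta)
    meta = read_metadata(metadata_path)
    missing = [s for s in beta.index if s not in meta.index]
    if missing:
        if strict:
            raise ValidationError(
                f"samples missing from metadata: {missing[:10]}"
                + (" ..." if len(missing) > 10 else "")
            )
        warnings.warn(
            f"dropping {len(missing)} samples missing from metadata", stacklevel=2
        )
        beta = beta.drop(index=missing)
    meta = meta.reindex(beta.index)
    ages = meta["age"] if meta["age"].notna().all() else None
    return MethylationDataset(beta=beta, ages=ages, sex=meta["sex"])


def write_predictions(predictions: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a prediction table (as produced by ``predict_two_stage``)."""
    df = predictions.reset_index() if predictions.index.name == "sample_id" else predictions
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_predictions(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValidationError("predictions file needs a sample_id column")
    return df.set_index("sample_id")


def save_model(model: TwoStageModel, path) -> None:
    """Serialize a trained model to versioned JSON."""
    payload = {
        "format": MODEL_FORMAT,
        "schema_version": MODEL_SCHEMA_VERSION,
        "sex_label": model.sex_label,
        "cutoff_age": int(model.cutoff_age),
        "routing_threshold": int(model.routing_threshold),
        "config": model.config.to_dict(),
        "stage1": model.stage1.to_dict(),
        "junior": model.junior.to_dict(),
        "senior": model.senior.to_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TwoStageModel:
    """Load a model saved by :func:`save_model`.

    Unknown formats or schema versions raise :class:`ModelSchemaError`
    rather than being silently coerced.
    """
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelSchemaError(f"{path} is not a {MODEL_FORMAT} file")
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelSchemaError(
            f"model schema version {version!r} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return TwoStageModel(
        stage1=ReferenceMatrix.from_dict(payload["stage1"]),
        junior=ReferenceMatrix.from_dict(payload["junior"]),
        senior=ReferenceMatrix.from_dict(payload["senior"]),
        cutoff_age=int(payload["cutoff_age"]),
        routing_threshold=int(payload["routing_threshold"]),
        config=ClockConfig.from_dict(payload["config"]),
        sex_label=payload["sex_label"],
    )
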