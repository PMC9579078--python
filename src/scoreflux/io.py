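"""CSV readers/writers, flat config files and the Dataset container.

Responses are a CSV with a header row of item names and one integer row per
person. Covariates are a CSV with a person-id column plus named covariate
columns; each covariate's kind (continuous / ordered / unordered) is declared
in the schema, never inferred, and ordered covariates may declare their level
order there as well. An optional dichotomization rule recodes 0 as 0 and
every positive category as 1 (the usual "no" vs "any other response" coding).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .response import ResponseMatrix


@dataclass(frozen=True)
class Dataset:
    responses: ResponseMatrix
    covariates: pd.DataFrame | None
    kinds: dict = field(default_factory=dict)        # covariate name -> kind
    levels: dict = field(default_factory=dict)       # covariate name -> level order
    provenance: dict = field(default_factory=dict)   # paths + sha256 checksums


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _validated_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        col = df.columns[int(np.argmax(df.isna().iloc[row].to_numpy()))]
        raise DataError(f"{path}: missing cell at row {row}, column {col!r}")
    return df


def read_responses(path, dichotomize: bool = False, n_categories=None) -> ResponseMatrix:
    df = _validated_frame(path)
    values = df.to_numpy()
    try:
        values = values.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-integer response values ({exc})") from None
    if dichotomize:
        values = (values > 0).astype(np.int64)
        n_categories = np.full(values.shape[1], 2)
    return ResponseMatrix.from_array(
        values, n_categories=n_categories, item_names=tuple(df.columns)
    )


def read_dataset(
    responses_path, covariates_path=None, schema: dict | None = None
) -> Dataset:
    """Load and cross-validate a response matrix and its covariate table.

    ``schema`` keys: ``dichotomize`` (bool), ``person_id`` (covariate column
    holding person labels), ``covariates`` (mapping name -> {"kind": ...,
    "levels": [...]}).
    """
    schema = schema or {}
    resp = read_responses(responses_path, dichotomize=bool(schema.get("dichotomize")))
    provenance = {"responses": str(responses_path), "responses_sha256": _sha256(responses_path)}
    covariates = None
    kinds, levels = {}, {}
    if covariates_path is not None:
        covariates = _validated_frame(covariates_path)
        id_col = schema.get("person_id")
        if id_col is not None and id_col in covariates.columns:
            covariates = covariates.set_index(id_col)
        if len(covariates) != resp.n_persons:
            raise DataError(
                f"row-count mismatch: {resp.n_persons} response rows vs "
                f"{len(covariates)} covariate rows"
            )
        for name, decl in (schema.get("covariates") or {}).items():
            if name not in covariates.columns:
                raise DataError(f"declared covariate {name!r} not in {covariates_path}")
            kinds[name] = decl.get("kind", "continuous")
            if "levels" in decl:
                observed = set(covariates[name].astype(str).unique())
                declared = [str(v) for v in decl["levels"]]
                if not observed.issubset(declared):
                    raise DataError(
                        f"covariate {name!r}: observed values {sorted(observed - set(declared))} "
                        "missing from declared levels"
                    )
                levels[name] = list(decl["levels"])
        provenance["covariates"] = str(covariates_path)
        provenance["covariates_sha256"] = _sha256(covariates_path)
    return Dataset(resp, covariates, kinds, levels, provenance)


def write_responses(resp: ResponseMatrix, path) -> None:
    pd.DataFrame(resp.values, columns=list(resp.item_names)).to_csv(path, index=False)


def read_config(path) -> dict:
    """Flat ``key: value`` configuration dialect.

    Values parse as int, float, bool or comma-separated lists thereof;
    anything else stays a string. ``#`` starts a comment.
    """
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = _parse_scalar(value.strip())
    return out


def _parse_scalar(text: str):
    if "," in text:
        return [_parse_scalar(part.strip()) for part in text.split(",")]
    low = text.lower()
    if low in ("true", "yes"):
        return True
    if low in ("false", "no"):
        return False
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text
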