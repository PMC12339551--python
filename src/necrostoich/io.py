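"""Tidy-CSV and YAML-config I/O with schema validation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .necromass import BIOMARKER_COLUMNS, NecromassError

VALID_TREATMENTS = {"CK", "NPS0", "NPS1", "NPS2", "NPS3"}
VALID_DEPTHS = {"topsoil", "subsoil"}


class SchemaError(NecromassError):
    """The input table does not match the declared biomarker schema."""


def read_biomarker_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy biomarker table, validating columns, keys and signs.

    Expected columns (declared units): treatment, depth, day, replicate,
    glcn [mg g⁻¹], mura [mg g⁻¹], phenol_v/s/c [μg g⁻¹], soc [mg g⁻¹],
    plus optional covariates.
    """
    df = pd.read_csv(path)
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_trt = set(df["treatment"].unique()) - VALID_TREATMENTS
    if bad_trt:
        raise SchemaError(f"{path}: unknown treatment label(s) {sorted(bad_trt)}")
    bad_depth = set(df["depth"].unique()) - VALID_DEPTHS
    if bad_depth:
        raise SchemaError(f"{path}: unknown depth label(s) {sorted(bad_depth)}")
    value_cols = ["glcn", "mura", "phenol_v", "phenol_s", "phenol_c", "soc"]
    neg = df.index[(df[value_cols] < 0).any(axis=1)]
    if len(neg):
        raise SchemaError(
            f"{path}: negative biomarker value(s) in row(s) {list(neg[:5])}"
        )
    keys = ["treatment", "depth", "day", "replicate"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate (treatment, depth, day, replicate) key(s) "
            f"in row(s) {list(df.index[dup][:5])}"
        )
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data
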