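"""Biomarker-to-necromass conversions and SOC-partition accounting.

Bacterial necromass C (BNC) is estimated from muramic acid, which occurs only
in bacterial cell walls; fungal necromass C (FNC) from glucosamine after
removing the bacterial share (2 mol GlcN per mol MurA); microbial necromass C
(MNC) is their sum. Plant necromass C (PNC) is estimated from CuO-oxidation
lignin phenols (vanillyl, syringyl, cinnamyl), each scaled by its oxidative
release fraction and the summed lignin divided by the minimum lignin content
of major crop residues. All conversions are linear in the biomarkers.

Units: GlcN/MurA mg g⁻¹ soil, phenols μg C g⁻¹ soil, necromass pools and SOC
mg C g⁻¹ soil.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .constants import CONVERSION as CC


class NecromassError(ValueError):
    """Invalid input to a necromass conversion."""


class DataQualityWarning(UserWarning):
    """A record required clamping or looked physically implausible."""


#: mg GlcN accounted for by 1 mg MurA at the 2:1 molar bacterial correction.
GLCN_PER_MURA = 2.0 * CC.mw_glcn / CC.mw_mura


def _check_nonneg(**named):
    for name, value in named.items():
        if np.any(np.asarray(value) < 0):
            raise NecromassError(f"{name} must be >= 0")


def bacterial_necromass(mura):
    """BNC (mg C g⁻¹) from muramic acid (mg g⁻¹): 45 × MurA."""
    _check_nonneg(mura=mura)
    return CC.mura_to_bnc * np.asarray(mura, dtype=float)[()]


def fungal_necromass(glcn, mura, *, clamp: bool = True):
    """FNC (mg C g⁻¹) from glucosamine and muramic acid (mg g⁻¹).

    9 × (GlcN − 2 × MurA × 179.17/251.23): glucosamine left after crediting
    two moles to bacterial murein per mole of muramic acid, converted with the
    fungal coefficient 9. Negative values (MurA-rich, GlcN-poor samples) are
    clamped to 0 with a :class:`DataQualityWarning` unless ``clamp=False``.
    """
    _check_nonneg(glcn=glcn, mura=mura)
    raw = CC.glcn_to_fnc * (
        np.asarray(glcn, dtype=float) - GLCN_PER_MURA * np.asarray(mura, dtype=float)
    )
    if clamp:
        # warn only beyond roundoff: exact-boundary inputs can land a few
        # ulp below zero without signalling a data problem
        if np.any(raw < -1e-9):
            warnings.warn(
                "negative fungal necromass clamped to 0 (muramic acid large "
                "relative to glucosamine)",
                DataQualityWarning,
                stacklevel=2,
            )
        raw = np.maximum(raw, 0.0)
    return raw[()]


def microbial_necromass(bnc, fnc):
    """MNC = BNC + FNC (mg C g⁻¹)."""
    _check_nonneg(bnc=bnc, fnc=fnc)
    return (np.asarray(bnc, dtype=float) + np.asarray(fnc, dtype=float))[()]


def plant_necromass(phenol_v, phenol_s, phenol_c):
    """PNC (mg C g⁻¹) from V/S/C lignin phenols (μg g⁻¹).

    (V/0.33 + S/0.90 + C/1.00) / (0.08 × 1,000): phenols scaled up by their
    CuO release fractions, lignin scaled to residue mass by the 8% minimum
    lignin content, μg converted to mg.
    """
    _check_nonneg(phenol_v=phenol_v, phenol_s=phenol_s, phenol_c=phenol_c)
    lignin = (
        np.asarray(phenol_v, dtype=float) / CC.release_v
        + np.asarray(phenol_s, dtype=float) / CC.release_s
        + np.asarray(phenol_c, dtype=float) / CC.release_c
    )
    return (lignin / (CC.lignin_min * CC.ug_to_mg))[()]


def phenol_ratios(phenol_v, phenol_s, phenol_c):
    """(C/V, S/V) lignin transformation diagnostics; lower = more transformed."""
    _check_nonneg(phenol_v=phenol_v, phenol_s=phenol_s, phenol_c=phenol_c)
    v = np.asarray(phenol_v, dtype=float)
    if np.any(v == 0):
        raise NecromassError("phenol ratios undefined for phenol_v = 0")
    return (
        (np.asarray(phenol_c, dtype=float) / v)[()],
        (np.asarray(phenol_s, dtype=float) / v)[()],
    )


def soc_contribution(nc, soc):
    """Percent of SOC made up by a necromass pool: 100 × NC/SOC."""
    _check_nonneg(nc=nc)
    soc = np.asarray(soc, dtype=float)
    if np.any(soc <= 0):
        raise NecromassError("soc must be > 0")
    return (100.0 * np.asarray(nc, dtype=float) / soc)[()]


def percent_change(value, reference):
    """Signed percent difference of ``value`` from ``reference``."""
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise NecromassError("reference must be > 0")
    return (100.0 * (np.asarray(value, dtype=float) - reference) / reference)[()]


# ---------------------------------------------------------------------------
# Table-level processing
# ---------------------------------------------------------------------------

BIOMARKER_COLUMNS = (
    "treatment", "depth", "day", "replicate",
    "glcn", "mura", "phenol_v", "phenol_s", "phenol_c", "soc",
)


def process_table(records: pd.DataFrame) -> pd.DataFrame:
    """Derive per-sample necromass estimates from a tidy biomarker table.

    Adds BNC/FNC/MNC/PNC, the C/V and S/V diagnostics, SOC contributions, and
    an ``fnc_clamped`` flag marking records whose raw FNC was negative.
    """
    missing = [c for c in BIOMARKER_COLUMNS if c not in records.columns]
    if missing:
        raise NecromassError(f"biomarker table missing columns: {missing}")
    out = records.copy()
    glcn = out["glcn"].to_numpy(float)
    mura = out["mura"].to_numpy(float)
    out["bnc"] = bacterial_necromass(mura)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        raw_fnc = fungal_necromass(glcn, mura, clamp=False)
    out["fnc_clamped"] = raw_fnc < -1e-9  # beyond-roundoff negatives only
    out["fnc"] = np.maximum(raw_fnc, 0.0)
    if out["fnc_clamped"].any():
        warnings.warn(
            f"{int(out['fnc_clamped'].sum())} record(s) had negative raw "
            "fungal necromass clamped to 0",
            DataQualityWarning,
            stacklevel=2,
        )
    out["mnc"] = out["bnc"] + out["fnc"]
    out["pnc"] = plant_necromass(
        out["phenol_v"].to_numpy(float),
        out["phenol_s"].to_numpy(float),
        out["phenol_c"].to_numpy(float),
    )
    cv, sv = phenol_ratios(
        out["phenol_v"].to_numpy(float),
        out["phenol_s"].to_numpy(float),
        out["phenol_c"].to_numpy(float),
    )
    out["cv_ratio"] = cv
    out["sv_ratio"] = sv
    out["mnc_soc_pct"] = soc_contribution(out["mnc"].to_numpy(float),
                                          out["soc"].to_numpy(float))
    out["pnc_soc_pct"] = soc_contribution(out["pnc"].to_numpy(float),
                                          out["soc"].to_numpy(float))
    return out


RESPONSES = ("bnc", "fnc", "mnc", "pnc", "cv_ratio", "sv_ratio",
             "mnc_soc_pct", "pnc_soc_pct", "soc")


def summarize(
    estimates: pd.DataFrame,
    by: list[str] | tuple[str, ...] = ("treatment", "depth", "day"),
    responses: tuple[str, ...] = RESPONSES,
) -> pd.DataFrame:
    """Group means and SDs of replicate-level estimates (long format).

    Summaries average replicate-level necromass values; because every
    conversion is linear this equals converting the mean biomarkers.
    """
    present = [r for r in responses if r in estimates.columns]
    long = estimates.melt(
        id_vars=list(by), value_vars=present,
        var_name="response", value_name="value",
    )
    g = long.groupby(["response", *by], sort=False, observed=True)["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out
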