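"""Synthetic biomarker datasets with the field experiment's factorial layout.

The generator emulates a 5-treatment (CK, NPS0–NPS3) × 2-depth (topsoil
0–20 cm, subsoil 20–40 cm) × 3-day (30, 90, 150) × n-replicate straw-
amendment trial. Treatment, depth and day effects are injected
*multiplicatively at the biomarker level* — amino sugars for the microbial
necromass channel, lignin phenols for the plant channel — so the conversion
equations downstream are genuinely exercised; because those conversions are
linear, a biomarker-level multiplier maps to exactly the same necromass-level
multiplier. Noise is multiplicative lognormal with unit mean and a
configurable coefficient of variation, which keeps concentrations positive
and effect recovery unbiased.

Default effect sizes encode the study conditions this package models: the
NPS3:NPS1 microbial-necromass ratio is 1.053 in topsoil and 1.139 in subsoil,
and the plant-necromass ratio 0.930 and 0.837.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import DAYS, DEPTHS, TREATMENTS


class GeneratorConfigError(ValueError):
    pass


# Per-depth biomarker baselines (NPS1 reference levels). Chosen so the
# implied pools sit at realistic cropland magnitudes: topsoil SOC 16 mg g⁻¹
# with MNC/SOC ≈ 55% and PNC/SOC ≈ 27%; subsoil SOC 10 mg g⁻¹ with
# MNC/SOC ≈ 48%. GlcN/MurA in mg g⁻¹, phenols in μg g⁻¹, SOC in mg g⁻¹.
DEFAULT_BASELINES = {
    "topsoil": {
        "glcn": 0.771, "mura": 0.0578,
        "phenol_v": 78.0, "phenol_s": 78.0, "phenol_c": 23.4,
        "soc": 16.0,
        "an": 100.0, "sap": 20.0, "sm": 20.0,
        "bg": 120.0, "cbh": 45.0, "nag": 50.0, "lap": 30.0, "ap": 200.0,
    },
    "subsoil": {
        "glcn": 0.421, "mura": 0.0316,
        "phenol_v": 46.8, "phenol_s": 46.8, "phenol_c": 14.05,
        "soc": 10.0,
        "an": 60.0, "sap": 10.0, "sm": 24.0,
        "bg": 72.0, "cbh": 27.0, "nag": 30.0, "lap": 18.0, "ap": 120.0,
    },
}

# Treatment multipliers per response channel and depth. "mnc" scales GlcN and
# MurA together, "pnc" scales the three phenols, "soc" scales SOC. NPS3 is
# expressed as NPS1 × the configured NPS3:NPS1 ratio so that ratio is exact.
_MNC31_TOP, _MNC31_SUB = 1.053, 1.139
_PNC31_TOP, _PNC31_SUB = 0.930, 0.837

DEFAULT_TREATMENT_EFFECTS = {
    "mnc": {
        "topsoil": {"CK": 1.00, "NPS0": 1.02, "NPS1": 1.04,
                    "NPS2": 1.07, "NPS3": 1.04 * _MNC31_TOP},
        "subsoil": {"CK": 1.00, "NPS0": 1.02, "NPS1": 1.04,
                    "NPS2": 1.10, "NPS3": 1.04 * _MNC31_SUB},
    },
    "pnc": {
        "topsoil": {"CK": 1.00, "NPS0": 1.15, "NPS1": 1.12,
                    "NPS2": 1.07, "NPS3": 1.12 * _PNC31_TOP},
        "subsoil": {"CK": 1.00, "NPS0": 1.15, "NPS1": 1.12,
                    "NPS2": 1.02, "NPS3": 1.12 * _PNC31_SUB},
    },
    "soc": {
        "topsoil": {t: 1.0 for t in TREATMENTS},
        "subsoil": {t: 1.0 for t in TREATMENTS},
    },
}

# Microbial necromass builds up over the season while plant-derived lignin is
# progressively transformed.
DEFAULT_DAY_EFFECTS = {
    "mnc": {30: 0.92, 90: 1.00, 150: 1.08},
    "pnc": {30: 1.10, 90: 1.00, 150: 0.85},
    "soc": {30: 1.00, 90: 1.00, 150: 1.00},
}

# Covariate treatment multipliers (monotone available-nutrient response to
# the amendment gradient; enzymes mildly stimulated). Interface realism only.
DEFAULT_COVARIATE_EFFECTS = {
    "an": {"CK": 0.90, "NPS0": 1.00, "NPS1": 1.15, "NPS2": 1.30, "NPS3": 1.45},
    "sap": {"CK": 0.90, "NPS0": 1.00, "NPS1": 1.20, "NPS2": 1.40, "NPS3": 1.60},
    "sm": {t: 1.0 for t in TREATMENTS},
    "bg": {"CK": 0.95, "NPS0": 1.00, "NPS1": 1.05, "NPS2": 1.10, "NPS3": 1.15},
    "cbh": {"CK": 0.95, "NPS0": 1.00, "NPS1": 1.05, "NPS2": 1.08, "NPS3": 1.10},
    "nag": {t: 1.0 for t in TREATMENTS},
    "lap": {t: 1.0 for t in TREATMENTS},
    "ap": {"CK": 0.95, "NPS0": 1.00, "NPS1": 1.10, "NPS2": 1.05, "NPS3": 1.00},
}

_MNC_MARKERS = ("glcn", "mura")
_PNC_MARKERS = ("phenol_v", "phenol_s", "phenol_c")
COVARIATES = ("an", "sap", "sm", "bg", "cbh", "nag", "lap", "ap")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic factorial experiment.

    ``noise_cv`` is the relative standard deviation of the multiplicative
    lognormal noise applied independently to every biomarker value; the true
    replicate-level dispersion of such trials is not pinned down by published
    summaries, so the 0.1 default is a plausible placeholder, not a measured
    value.
    """

    baselines: dict = field(default_factory=lambda: DEFAULT_BASELINES)
    treatment_effects: dict = field(default_factory=lambda: DEFAULT_TREATMENT_EFFECTS)
    day_effects: dict = field(default_factory=lambda: DEFAULT_DAY_EFFECTS)
    covariate_effects: dict = field(default_factory=lambda: DEFAULT_COVARIATE_EFFECTS)
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise GeneratorConfigError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise GeneratorConfigError("n_replicates must be >= 1")
        for channel, per_depth in self.treatment_effects.items():
            for depth, mults in per_depth.items():
                for trt, m in mults.items():
                    if m <= 0:
                        raise GeneratorConfigError(
                            f"multiplier {channel}/{depth}/{trt} must be > 0"
                        )
        for channel, per_day in self.day_effects.items():
            for day, m in per_day.items():
                if m <= 0:
                    raise GeneratorConfigError(
                        f"day multiplier {channel}/{day} must be > 0"
                    )

    def with_effects(self, **channels) -> "GeneratorConfig":
        """Copy with replaced treatment-effect channels (e.g. ``mnc={...}``)."""
        effects = {**self.treatment_effects, **channels}
        return replace(self, treatment_effects=effects)


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal multipliers with E = 1 and SD/mean = cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic experiment as a tidy biomarker table.

    Rows are keyed by (treatment, depth, day, replicate); columns are the
    biomarkers and covariates the downstream readers expect. Fixed seed ⇒
    identical output.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for treatment in TREATMENTS:
        for depth in DEPTHS:
            base = config.baselines[depth]
            for day in DAYS:
                for rep in range(1, config.n_replicates + 1):
                    row = {"treatment": treatment, "depth": depth,
                           "day": day, "replicate": rep}
                    for marker in _MNC_MARKERS + _PNC_MARKERS + ("soc",):
                        channel = ("mnc" if marker in _MNC_MARKERS
                                   else "pnc" if marker in _PNC_MARKERS
                                   else "soc")
                        mult = (
                            config.treatment_effects[channel][depth][treatment]
                            * config.day_effects[channel][day]
                        )
                        row[marker] = base[marker] * mult
                    for cov in COVARIATES:
                        row[cov] = base[cov] * config.covariate_effects[cov][treatment]
                    rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = list(_MNC_MARKERS + _PNC_MARKERS) + ["soc"] + list(COVARIATES)
    noise = _unit_mean_lognormal(rng, config.noise_cv,
                                 (len(df), len(value_cols)))
    df[value_cols] = df[value_cols].to_numpy(float) * noise
    return df
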