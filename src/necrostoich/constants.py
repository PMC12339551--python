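"""Fixed constants: biomarker conversion coefficients, molar masses, and the
published straw-amendment experiment (compositions, recipes, targets).

Everything here is a literature or design constant, not a fitted quantity.
All per-soil masses are mg per 100 g dry soil; residue concentrations are
g kg⁻¹; solution concentrations are g L⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

CONSTANTS_VERSION = "1.0"


@dataclass(frozen=True)
class ConversionConstants:
    """Biomarker-to-necromass conversion coefficients.

    ``mura_to_bnc`` converts muramic acid (mg g⁻¹) to bacterial necromass C;
    ``glcn_to_fnc`` converts bacterially corrected glucosamine to fungal
    necromass C.  ``release_v/s/c`` are the CuO-oxidation release fractions of
    vanillyl, syringyl and cinnamyl phenols; ``lignin_min`` is the minimum
    lignin mass fraction of major crop residues used to scale summed phenols
    up to plant necromass C; ``ug_to_mg`` converts μg to mg.
    """

    mura_to_bnc: float = 45.0
    glcn_to_fnc: float = 9.0
    mw_glcn: float = 179.17
    mw_mura: float = 251.23
    release_v: float = 0.33
    release_s: float = 0.90
    release_c: float = 1.00
    lignin_min: float = 0.08
    ug_to_mg: float = 1_000.0


CONVERSION = ConversionConstants()

# Anhydrous molar masses (g mol⁻¹) for the salt formulation.
MW_NH4NO3 = 80.04
MW_KH2PO4 = 136.09
MW_NH4SO4 = 132.14  # (NH4)2SO4
MW_N = 14.007
MW_P = 30.974
MW_S = 32.06

# N atoms per formula unit.
N_PER_NH4NO3 = 2
N_PER_NH4SO4 = 2

# ---------------------------------------------------------------------------
# The published field experiment: maize straw cut to 2–5 mm, mixed at
# 2 g per 100 g dry soil, with an assumed 30% humification efficiency.
# ---------------------------------------------------------------------------

STRAW_C = 417.6   # g C kg⁻¹ residue
STRAW_N = 9.74
STRAW_P = 1.20
STRAW_S = 1.19

STRAW_RATE = 2.0          # g residue per 100 g dry soil
HUMIFICATION_EFF = 0.30   # fraction of residue C assumed stabilized
SOLUTION_DOSE = 1.0       # mL nutrient solution per 100 g dry soil

# Microbial C:N:P:S demand presets, parts per 10,000 parts C.
FUNGAL_PARTS = (1034.0, 110.0, 94.0)
BACTERIAL_PARTS = (2004.0, 494.0, 264.0)

# Design targets actually used for each amended treatment (parts per 10,000 C).
# NPS1 tracks the fungal N demand but over-supplies P and S relative to the
# fungal preset; NPS2 is a custom intermediate; NPS3 is the bacterial preset.
TREATMENT_TARGETS = {
    "NPS1": (1034.0, 167.0, 133.0),
    "NPS2": (1556.0, 238.0, 171.0),
    "NPS3": (2004.0, 494.0, 264.0),
}

# Published recipe table: humified C and residue-borne nutrient base
# (mg per 100 g soil) as printed, then supplemental additions per treatment.
# The NPS2 P addition is stored as 3.57, the value consistent with both the
# table's own ratio cell (238) and the inverse design arithmetic that
# regenerates every other printed addition.
PUBLISHED_HUMIFIED_C = 250.54
PUBLISHED_BASE = {"n": 19.49, "p": 2.39, "s": 2.38}
PUBLISHED_ADDITIONS = {
    "NPS0": (0.0, 0.0, 0.0),
    "NPS1": (6.42, 1.79, 0.95),
    "NPS2": (19.50, 3.57, 1.90),
    "NPS3": (30.72, 9.98, 4.23),
}

# Integer stoichiometric-ratio cells of the published table (N, P, S parts).
PUBLISHED_RATIOS = {
    "NPS0": (778, 95, 95),
    "NPS1": (1034, 167, 133),
    "NPS2": (1556, 238, 171),
    "NPS3": (2004, 494, 264),
}

TREATMENTS = ("CK", "NPS0", "NPS1", "NPS2", "NPS3")
DEPTHS = ("topsoil", "subsoil")
DAYS = (30, 90, 150)
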