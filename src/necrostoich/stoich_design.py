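"""Stoichiometric design of substrate amendments.

Forward arithmetic: residue mass × elemental composition × humification
efficiency gives the stabilized-C base and the residue-borne N/P/S supply.
Inverse arithmetic: given a target microbial C:N:P:S demand (normalized to
C = 10,000), solve for the supplemental N/P/S additions, the nutrient-solution
concentrations that deliver them at a given dose, and the anhydrous salt
masses (NH₄NO₃, KH₂PO₄, (NH₄)₂SO₄) that realize them.

Units: residue concentrations g kg⁻¹, per-soil masses mg per 100 g dry soil,
solution concentrations g L⁻¹ (so mg per 100 g ≡ g L⁻¹ at a 1 mL dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import constants as K


class DesignError(ValueError):
    """Invalid input to the stoichiometric design arithmetic."""


class InfeasibleFormulationError(DesignError):
    """The requested additions cannot be realized with the salt set."""

    def __init__(self, n_surplus: float):
        self.n_surplus = n_surplus
        super().__init__(
            "ammonium sulfate alone supplies "
            f"{n_surplus:.4g} mg more N than requested; the NH4NO3/KH2PO4/"
            "(NH4)2SO4 salt set cannot realize this addition"
        )


@dataclass(frozen=True)
class ResidueComposition:
    """Elemental composition of the added plant residue, g kg⁻¹ dry residue."""

    c_conc: float
    n_conc: float
    p_conc: float
    s_conc: float

    def __post_init__(self):
        for name in ("c_conc", "n_conc", "p_conc", "s_conc"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.c_conc <= 0:
            raise DesignError("c_conc must be > 0")


#: Maize straw used in the published experiment.
MAIZE_STRAW = ResidueComposition(K.STRAW_C, K.STRAW_N, K.STRAW_P, K.STRAW_S)


@dataclass(frozen=True)
class StoichTarget:
    """Microbial C:N:P:S demand as mass parts per 10,000 parts C."""

    n_per_1e4c: float
    p_per_1e4c: float
    s_per_1e4c: float

    def __post_init__(self):
        for name in ("n_per_1e4c", "p_per_1e4c", "s_per_1e4c"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.n_per_1e4c, self.p_per_1e4c, self.s_per_1e4c)

    def rounded(self) -> tuple[int, int, int]:
        """Parts rounded to the nearest integer (table display convention)."""
        return tuple(round(x) for x in self.as_tuple())


FUNGAL = StoichTarget(*K.FUNGAL_PARTS)
BACTERIAL = StoichTarget(*K.BACTERIAL_PARTS)


@dataclass(frozen=True)
class AmendmentRecipe:
    """One treatment's amendment: stabilized C base, residue-borne nutrients,
    and supplemental additions, all mg per 100 g dry soil.

    ``floored`` lists elements whose solved addition was clamped at zero
    because the residue alone already exceeded the target.
    """

    humified_c: float
    base_n: float
    base_p: float
    base_s: float
    add_n: float = 0.0
    add_p: float = 0.0
    add_s: float = 0.0
    floored: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.humified_c <= 0:
            raise DesignError("humified_c must be > 0")
        for name in ("base_n", "base_p", "base_s", "add_n", "add_p", "add_s"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")

    @property
    def total_n(self) -> float:
        return self.base_n + self.add_n

    @property
    def total_p(self) -> float:
        return self.base_p + self.add_p

    @property
    def total_s(self) -> float:
        return self.base_s + self.add_s


@dataclass(frozen=True)
class SolutionSpec:
    """Nutrient-solution concentrations (g L⁻¹) at a given dose (mL per 100 g)."""

    n_conc: float
    p_conc: float
    s_conc: float
    dose: float

    def __post_init__(self):
        if self.dose <= 0:
            raise DesignError("dose must be > 0")
        for name in ("n_conc", "p_conc", "s_conc"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SaltFormulation:
    """Anhydrous salt masses (mg per 100 g soil) realizing an N/P/S addition."""

    mass_nh4no3: float
    mass_kh2po4: float
    mass_nh4so4: float

    def __post_init__(self):
        for name in ("mass_nh4no3", "mass_kh2po4", "mass_nh4so4"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")

    def elemental_masses(self) -> tuple[float, float, float]:
        """Decompose the salts back into (N, P, S) masses, mg per 100 g."""
        n = (
            self.mass_nh4no3 * K.N_PER_NH4NO3 * K.MW_N / K.MW_NH4NO3
            + self.mass_nh4so4 * K.N_PER_NH4SO4 * K.MW_N / K.MW_NH4SO4
        )
        p = self.mass_kh2po4 * K.MW_P / K.MW_KH2PO4
        s = self.mass_nh4so4 * K.MW_S / K.MW_NH4SO4
        return n, p, s


# ---------------------------------------------------------------------------
# Forward arithmetic
# ---------------------------------------------------------------------------

def humified_c_input(
    residue_mass: float,
    residue: ResidueComposition,
    humification_eff: float = K.HUMIFICATION_EFF,
) -> float:
    """Stabilized (humified) C input, mg C per 100 g soil.

    ``residue_mass`` is g residue per 100 g soil; g × g kg⁻¹ = mg, so the
    product needs no further unit factor.
    """
    if residue_mass < 0:
        raise DesignError("residue_mass must be >= 0")
    if not 0 < humification_eff <= 1:
        raise DesignError("humification_eff must be in (0, 1]")
    return residue_mass * residue.c_conc * humification_eff


def residue_nutrient_supply(
    residue_mass: float, residue: ResidueComposition
) -> tuple[float, float, float]:
    """Residue-borne (N, P, S) supply, mg per 100 g soil."""
    if residue_mass < 0:
        raise DesignError("residue_mass must be >= 0")
    return (
        residue_mass * residue.n_conc,
        residue_mass * residue.p_conc,
        residue_mass * residue.s_conc,
    )


def realized_ratio(recipe: AmendmentRecipe) -> StoichTarget:
    """Realized substrate stoichiometry, parts per 10,000 parts humified C.

    Full precision is retained; use :meth:`StoichTarget.rounded` for the
    integer display convention.
    """
    if recipe.humified_c <= 0:
        raise DesignError("realized ratio undefined for humified_c <= 0")
    scale = 10_000.0 / recipe.humified_c
    return StoichTarget(
        recipe.total_n * scale,
        recipe.total_p * scale,
        recipe.total_s * scale,
    )


# ---------------------------------------------------------------------------
# Inverse arithmetic
# ---------------------------------------------------------------------------

def solve_additions(
    target: StoichTarget,
    residue_mass: float,
    residue: ResidueComposition,
    humification_eff: float = K.HUMIFICATION_EFF,
    *,
    base: tuple[float, float, float] | None = None,
    humified_c: float | None = None,
) -> AmendmentRecipe:
    """Solve for supplemental N/P/S additions meeting ``target``.

    The addition for each element is ``target_part/10,000 × humified_c −
    residue-borne base``, floored at zero: nutrients cannot be removed, so an
    element whose residue supply already exceeds the target is flagged in
    ``recipe.floored`` instead of going negative.

    ``base`` and ``humified_c`` may be given explicitly to solve against a
    published recipe row instead of the forward arithmetic.
    """
    hc = humified_c if humified_c is not None else humified_c_input(
        residue_mass, residue, humification_eff
    )
    if hc <= 0:
        raise DesignError("humified C must be > 0 to solve additions")
    b = base if base is not None else residue_nutrient_supply(residue_mass, residue)
    parts = target.as_tuple()
    adds, floored = [], []
    for elem, part, supplied in zip("nps", parts, b):
        want = part / 10_000.0 * hc
        add = want - supplied
        if add < 0:
            adds.append(0.0)
            floored.append(elem)
        else:
            adds.append(add)
    return AmendmentRecipe(
        humified_c=hc,
        base_n=b[0], base_p=b[1], base_s=b[2],
        add_n=adds[0], add_p=adds[1], add_s=adds[2],
        floored=tuple(floored),
    )


def solution_concentrations(
    recipe: AmendmentRecipe, dose: float = K.SOLUTION_DOSE
) -> SolutionSpec:
    """Nutrient-solution concentrations delivering the recipe's additions.

    mg per 100 g soil divided by mL per 100 g soil is mg mL⁻¹ = g L⁻¹, so at
    the experiment's 1 mL dose the numbers coincide with the additions.
    """
    if dose <= 0:
        raise DesignError("dose must be > 0")
    return SolutionSpec(
        recipe.add_n / dose, recipe.add_p / dose, recipe.add_s / dose, dose
    )


def salt_formulation(add_n: float, add_p: float, add_s: float) -> SaltFormulation:
    """Anhydrous salt masses supplying the requested N/P/S addition.

    S comes entirely from (NH₄)₂SO₄ and P from KH₂PO₄; the N the sulfate
    brings along is credited against ``add_n`` and the remainder supplied as
    NH₄NO₃. If the sulfate's N alone exceeds ``add_n`` the formulation is
    infeasible with this salt set.
    """
    if min(add_n, add_p, add_s) < 0:
        raise DesignError("additions must be >= 0")
    mass_nh4so4 = add_s * K.MW_NH4SO4 / K.MW_S
    n_from_sulfate = mass_nh4so4 * K.N_PER_NH4SO4 * K.MW_N / K.MW_NH4SO4
    residual_n = add_n - n_from_sulfate
    if residual_n < -1e-9:
        raise InfeasibleFormulationError(-residual_n)
    mass_nh4no3 = max(residual_n, 0.0) * K.MW_NH4NO3 / (K.N_PER_NH4NO3 * K.MW_N)
    mass_kh2po4 = add_p * K.MW_KH2PO4 / K.MW_P
    return SaltFormulation(mass_nh4no3, mass_kh2po4, mass_nh4so4)


# ---------------------------------------------------------------------------
# Published experiment
# ---------------------------------------------------------------------------

def published_recipes() -> dict[str, AmendmentRecipe]:
    """The published amendment table, one recipe per straw-amended treatment.

    Uses the table's printed masses (humified C 250.54 mg; base 19.49/2.39/2.38
    mg per 100 g) so realized ratios reproduce the printed integer cells.
    """
    out = {}
    b = K.PUBLISHED_BASE
    for trt, (an, ap, as_) in K.PUBLISHED_ADDITIONS.items():
        out[trt] = AmendmentRecipe(
            humified_c=K.PUBLISHED_HUMIFIED_C,
            base_n=b["n"], base_p=b["p"], base_s=b["s"],
            add_n=an, add_p=ap, add_s=as_,
        )
    return out


def design_table(
    residue: ResidueComposition = MAIZE_STRAW,
    residue_mass: float = K.STRAW_RATE,
    humification_eff: float = K.HUMIFICATION_EFF,
    targets: dict[str, StoichTarget] | None = None,
    dose: float = K.SOLUTION_DOSE,
) -> pd.DataFrame:
    """Tidy recipe table for a set of named targets (default: the published
    NPS1–NPS3 design targets plus the no-addition NPS0)."""
    if targets is None:
        targets = {t: StoichTarget(*p) for t, p in K.TREATMENT_TARGETS.items()}
    hc = humified_c_input(residue_mass, residue, humification_eff)
    base = residue_nutrient_supply(residue_mass, residue)
    rows = []
    nps0 = AmendmentRecipe(hc, *base)
    for name, recipe in [("NPS0", nps0)] + [
        (name, solve_additions(tgt, residue_mass, residue, humification_eff))
        for name, tgt in targets.items()
    ]:
        ratio = realized_ratio(recipe)
        sol = solution_concentrations(recipe, dose)
        salts = salt_formulation(recipe.add_n, recipe.add_p, recipe.add_s)
        rows.append(
            {
                "treatment": name,
                "humified_c_mg": recipe.humified_c,
                "base_n_mg": recipe.base_n,
                "base_p_mg": recipe.base_p,
                "base_s_mg": recipe.base_s,
                "add_n_mg": recipe.add_n,
                "add_p_mg": recipe.add_p,
                "add_s_mg": recipe.add_s,
                "floored": ",".join(recipe.floored),
                "ratio_n": ratio.n_per_1e4c,
                "ratio_p": ratio.p_per_1e4c,
                "ratio_s": ratio.s_per_1e4c,
                "ratio_n_int": ratio.rounded()[0],
                "ratio_p_int": ratio.rounded()[1],
                "ratio_s_int": ratio.rounded()[2],
                "sol_n_g_per_l": sol.n_conc,
                "sol_p_g_per_l": sol.p_conc,
                "sol_s_g_per_l": sol.s_conc,
                "salt_nh4no3_mg": salts.mass_nh4no3,
                "salt_kh2po4_mg": salts.mass_kh2po4,
                "salt_nh4so4_mg": salts.mass_nh4so4,
            }
        )
    return pd.DataFrame(rows)
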