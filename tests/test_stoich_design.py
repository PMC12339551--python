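"""Stoichiometric amendment-design arithmetic: forward, inverse, salts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from necrostoich import constants as K
from necrostoich import stoich_design as sd


class TestForward:
    def test_humified_c_from_straw(self):
        # 2 g straw at 417.6 g C kg⁻¹, 30% stabilized -> 250.56 mg C
        assert sd.humified_c_input(2.0, sd.MAIZE_STRAW, 0.30) == pytest.approx(
            250.56, abs=1e-9
        )

    @pytest.mark.parametrize(
        "mass,c_conc,eff,expected",
        [(0.0, 417.6, 0.3, 0.0), (1.0, 1000.0, 1.0, 1000.0)],
    )
    def test_humified_c_scaling(self, mass, c_conc, eff, expected):
        residue = sd.ResidueComposition(c_conc, 1.0, 1.0, 1.0)
        assert sd.humified_c_input(mass, residue, eff) == expected

    def test_humified_c_domain_errors(self):
        with pytest.raises(sd.DesignError):
            sd.humified_c_input(-1.0, sd.MAIZE_STRAW, 0.3)
        for eff in (0.0, -0.1, 1.5):
            with pytest.raises(sd.DesignError):
                sd.humified_c_input(1.0, sd.MAIZE_STRAW, eff)

    def test_residue_nutrient_supply(self):
        n, p, s = sd.residue_nutrient_supply(2.0, sd.MAIZE_STRAW)
        assert n == pytest.approx(19.48)
        assert p == pytest.approx(2.40)
        assert s == pytest.approx(2.38)
        assert sd.residue_nutrient_supply(0.0, sd.MAIZE_STRAW) == (0, 0, 0)

    def test_residue_invariants(self):
        with pytest.raises(sd.DesignError):
            sd.ResidueComposition(0.0, 1.0, 1.0, 1.0)  # C must be positive
        with pytest.raises(sd.DesignError):
            sd.ResidueComposition(400.0, -1.0, 1.0, 1.0)


class TestRealizedRatio:
    def test_published_no_addition_row(self):
        recipe = sd.AmendmentRecipe(250.54, 19.49, 2.39, 2.38)
        ratio = sd.realized_ratio(recipe)
        assert ratio.n_per_1e4c == pytest.approx(777.9, abs=0.05)
        assert ratio.rounded() == (778, 95, 95)

    def test_published_bacterial_row(self):
        recipe = sd.AmendmentRecipe(250.54, 19.49, 2.39, 2.38, add_n=30.72)
        ratio = sd.realized_ratio(recipe)
        assert ratio.n_per_1e4c == pytest.approx(2004.1, abs=0.05)
        assert ratio.rounded()[0] == 2004

    def test_zero_element_ratio(self):
        recipe = sd.AmendmentRecipe(100.0, 1.0, 0.0, 1.0)
        assert sd.realized_ratio(recipe).p_per_1e4c == 0.0

    def test_published_table_cells(self):
        """Every integer ratio cell of the published amendment table."""
        for trt, recipe in sd.published_recipes().items():
            assert sd.realized_ratio(recipe).rounded() == K.PUBLISHED_RATIOS[trt]


class TestSolveAdditions:
    def test_fungal_n_from_published_base(self):
        recipe = sd.solve_additions(
            sd.FUNGAL, 2.0, sd.MAIZE_STRAW,
            base=(19.49, 2.39, 2.38), humified_c=250.54,
        )
        assert recipe.add_n == pytest.approx(6.416, abs=5e-3)
        assert round(recipe.add_n, 2) == 6.42

    def test_bacterial_n_from_published_base(self):
        recipe = sd.solve_additions(
            sd.BACTERIAL, 2.0, sd.MAIZE_STRAW,
            base=(19.49, 2.39, 2.38), humified_c=250.54,
        )
        assert round(recipe.add_n, 2) == 30.72

    def test_flooring_flags_oversupplied_element(self):
        # Residue alone already exceeds a tiny N target -> clamp and flag.
        target = sd.StoichTarget(10.0, 110.0, 94.0)
        recipe = sd.solve_additions(target, 2.0, sd.MAIZE_STRAW)
        assert recipe.add_n == 0.0
        assert "n" in recipe.floored

    def test_negative_target_rejected(self):
        with pytest.raises(sd.DesignError):
            sd.StoichTarget(-1.0, 0.0, 0.0)

    @given(
        n=st.floats(800, 4000),
        p=st.floats(100, 1000),
        s=st.floats(100, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_feasible_targets(self, n, p, s):
        """realized_ratio(solve_additions(t)) == t when nothing is floored."""
        target = sd.StoichTarget(n, p, s)
        recipe = sd.solve_additions(target, 2.0, sd.MAIZE_STRAW)
        realized = sd.realized_ratio(recipe)
        if not recipe.floored:
            for got, want in zip(realized.as_tuple(), target.as_tuple()):
                assert got == pytest.approx(want, abs=0.5)
        else:
            # Floored elements overshoot the target, never undershoot.
            for got, want in zip(realized.as_tuple(), target.as_tuple()):
                assert got >= want - 1e-9

    @given(k=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_ratio_homogeneity(self, k):
        """Scaling residue mass and additions by k leaves the ratio fixed."""
        base = sd.solve_additions(sd.BACTERIAL, 2.0, sd.MAIZE_STRAW)
        scaled = sd.AmendmentRecipe(
            base.humified_c * k,
            base.base_n * k, base.base_p * k, base.base_s * k,
            base.add_n * k, base.add_p * k, base.add_s * k,
        )
        for got, want in zip(
            sd.realized_ratio(scaled).as_tuple(),
            sd.realized_ratio(base).as_tuple(),
        ):
            assert got == pytest.approx(want, rel=1e-9)


class TestSolutions:
    @pytest.mark.parametrize(
        "add_n,dose,expected", [(6.42, 1.0, 6.42), (6.42, 2.0, 3.21), (0.0, 1.0, 0.0)]
    )
    def test_concentration_from_dose(self, add_n, dose, expected):
        recipe = sd.AmendmentRecipe(250.54, 19.49, 2.39, 2.38, add_n=add_n)
        assert sd.solution_concentrations(recipe, dose).n_conc == pytest.approx(
            expected
        )

    def test_bad_dose(self):
        recipe = sd.AmendmentRecipe(250.54, 19.49, 2.39, 2.38)
        with pytest.raises(sd.DesignError):
            sd.solution_concentrations(recipe, 0.0)


class TestSalts:
    def test_sulfate_mass_and_nitrogen_credit(self):
        salts = sd.salt_formulation(30.72, 9.98, 4.23)
        # Hand oracle: (NH4)2SO4 carries all S, crediting N against NH4NO3.
        mass_as = 4.23 * 132.14 / 32.06
        assert salts.mass_nh4so4 == pytest.approx(mass_as, rel=1e-12)
        assert salts.mass_nh4so4 == pytest.approx(17.43, abs=0.01)
        n_from_as = mass_as * 2 * 14.007 / 132.14
        assert salts.mass_nh4no3 == pytest.approx(
            (30.72 - n_from_as) * 80.04 / (2 * 14.007), rel=1e-12
        )
        assert salts.mass_nh4no3 == pytest.approx(77.2, abs=0.1)
        assert salts.mass_kh2po4 == pytest.approx(9.98 * 136.09 / 30.974, rel=1e-12)
        assert salts.mass_kh2po4 == pytest.approx(43.85, abs=0.01)

    def test_zero_addition(self):
        salts = sd.salt_formulation(0.0, 0.0, 0.0)
        assert (salts.mass_nh4no3, salts.mass_kh2po4, salts.mass_nh4so4) == (0, 0, 0)

    def test_infeasible_when_sulfate_nitrogen_exceeds_request(self):
        with pytest.raises(sd.InfeasibleFormulationError) as exc:
            sd.salt_formulation(0.1, 0.0, 4.23)
        assert exc.value.n_surplus > 0

    @given(
        add_n=st.floats(0, 100),
        add_p=st.floats(0, 50),
        add_s=st.floats(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_elemental_conservation(self, add_n, add_p, add_s):
        """Salt masses decomposed back into elements return the request."""
        try:
            salts = sd.salt_formulation(add_n, add_p, add_s)
        except sd.InfeasibleFormulationError:
            return
        n, p, s = salts.elemental_masses()
        assert n == pytest.approx(add_n, rel=1e-9, abs=1e-9)
        assert p == pytest.approx(add_p, rel=1e-9, abs=1e-9)
        assert s == pytest.approx(add_s, rel=1e-9, abs=1e-9)


def test_design_table_covers_published_targets():
    table = sd.design_table()
    assert list(table["treatment"]) == ["NPS0", "NPS1", "NPS2", "NPS3"]
    got = table.set_index("treatment")[
        ["ratio_n_int", "ratio_p_int", "ratio_s_int"]
    ]
    for trt in ("NPS1", "NPS2", "NPS3"):
        assert tuple(got.loc[trt]) == K.PUBLISHED_RATIOS[trt]
    # Solved additions agree with the published solution concentrations
    # at the 1 mL dose, to the printed 2-decimal precision.
    sol = table.set_index("treatment")[
        ["sol_n_g_per_l", "sol_p_g_per_l", "sol_s_g_per_l"]
    ].round(2)
    for trt, printed in K.PUBLISHED_ADDITIONS.items():
        assert tuple(sol.loc[trt]) == pytest.approx(printed, abs=0.011)
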