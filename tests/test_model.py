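"""Core growth model: network construction, folding curve, genotype
application, growth-rate bisection, and calibration anchors."""

import copy

import numpy as np
import pytest

from fluxscape.atp import compute_fractions
from fluxscape.model import (
    ATP_REGISTRY,
    CAL_MAX_FATPS_BAND,
    Condition,
    ConfigurationError,
    InputError,
    ModelSpec,
    ReactionSpec,
    EnzymeSpec,
    apply_genotype,
    build_default_model,
    calibrate_wildtype,
    folded_fraction,
    max_stoichiometric_fatps,
    solve_growth,
    stability_curve,
)
from fluxscape.sampling import StrainGenotype


class TestBuildDefaultModel:
    def test_registry_fixed_order(self, model):
        assert tuple(model.atp_registry) == ATP_REGISTRY
        assert len(model.atp_registry) == 8

    def test_alternative_nadh_dehydrogenases_share_the_quinone_step(self, model):
        nuo = model.reaction("NADH_NUO").stoichiometry
        ndh = model.reaction("NADH_NDH").stoichiometry
        for met in ("nadh", "q8h2"):
            assert nuo[met] == ndh[met]
        assert nuo.get("chg", 0) > 0 and ndh.get("chg", 0) == 0

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            build_default_model({"not_a_parameter": 1.0})

    def test_override_applied(self):
        m = build_default_model({"ngam": 7.5})
        assert m.ngam == 7.5

    def test_closed_system_admits_only_zero_flux(self, model):
        closed = copy.deepcopy(model)
        closed.ngam = 0.0
        for r in closed.reactions:
            if r.pathway_tag == "exchange":
                r.lb = r.ub = 0.0
        sol = solve_growth(closed, Condition(temperature=37.0))
        assert sol.feasible
        assert sol.mu == pytest.approx(0.0, abs=1e-9)
        assert max(abs(v) for v in sol.fluxes.values()) < 1e-9


class TestFoldedFraction:
    def test_strongly_stable_protein_fully_folded(self):
        assert folded_fraction(20.0, 37.0) > 0.999

    def test_midpoint_at_zero_stability(self):
        # the curve is anchored at 37 C, so dG_ref = 0 puts the midpoint there
        assert folded_fraction(0.0, 37.0) == pytest.approx(0.5, abs=1e-9)
        assert stability_curve(0.0, 37.0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("dg", [1.0, 3.0, 5.0, 8.0])
    def test_temperature_scan_nonincreasing_after_maximum(self, dg):
        temps = np.linspace(25, 46, 85)
        f = np.array([folded_fraction(dg, t) for t in temps])
        imax = int(np.argmax(f))
        assert np.all(np.diff(f[imax:]) <= 1e-12)

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(InputError):
            folded_fraction(5.0, 60.0)


class TestApplyGenotype:
    def test_empty_genotype_identity(self, model):
        out = apply_genotype(model, StrainGenotype(strain_id="wt"))
        for a, b in zip(model.enzymes, out.enzymes):
            assert a == b
        assert out.knockouts == set()

    def test_keff_factor_halves_proteome_cost(self, model):
        g = StrainGenotype(strain_id="s", mutations=[("pgk", 2.0, -1.0)])
        out = apply_genotype(model, g)
        assert out.enzyme("Pgk").k_eff == pytest.approx(2 * model.enzyme("Pgk").k_eff)
        assert out.enzyme("Pgk").dG_ref == pytest.approx(model.enzyme("Pgk").dG_ref - 1)

    def test_multiple_hits_compose_multiplicatively_and_additively(self, model):
        # oracle: compose two mutations on genes of one complex by hand
        g = StrainGenotype(
            strain_id="s",
            mutations=[("nuoA", 1.5, -0.4), ("nuoB", 1.2, -0.9)],
        )
        out = apply_genotype(model, g)
        assert out.enzyme("Nuo").k_eff == pytest.approx(
            model.enzyme("Nuo").k_eff * 1.5 * 1.2
        )
        assert out.enzyme("Nuo").dG_ref == pytest.approx(
            model.enzyme("Nuo").dG_ref - 1.3
        )

    def test_composed_factor_clipped_to_fold_range(self, model):
        g = StrainGenotype(
            strain_id="s",
            mutations=[("nuoA", 1.9, -0.1), ("nuoB", 1.9, -0.1)],
            fold_range=(0.5, 2.0),
        )
        out = apply_genotype(model, g)
        assert out.enzyme("Nuo").k_eff == pytest.approx(2.0 * model.enzyme("Nuo").k_eff)

    def test_catalog_gene_outside_model_is_silent(self, model):
        g = StrainGenotype(strain_id="s", mutations=[("y0042", 2.0, -1.0)])
        out = apply_genotype(model, g)
        for a, b in zip(model.enzymes, out.enzymes):
            assert a == b

    def test_unknown_knockout_enzyme_rejected(self, model):
        with pytest.raises(InputError):
            apply_genotype(model, StrainGenotype(strain_id="s", knockouts={"Nope"}))


def _toy_model(budget=0.1, kappa=5.0, demand=2.0, mw=100.0, keff=50.0):
    """Uptake -> ATP -> biomass with one enzyme; mu* has a closed form."""
    m = ModelSpec(
        metabolites=["s", "atp"],
        reactions=[
            ReactionSpec("EX_s", "substrate", {"s": 1.0}),
            ReactionSpec("CAT", "catabolism", {"s": -1.0, "atp": 1.0},
                         enzyme_id="E1", pathway_tag="glycolysis"),
            ReactionSpec("BIOMASS", "biomass", {"atp": -demand},
                         pathway_tag="biomass"),
        ],
        enzymes=[EnzymeSpec("E1", ["e1"], mw, 1, keff, 20.0)],
        phi_max=budget, kappa_t=kappa, gam=0.0, ngam=0.0,
    )
    return m


class TestSolveGrowth:
    def test_zero_budget_gives_no_growth(self, model):
        m = copy.deepcopy(model)
        m.phi_max = 0.0
        sol = solve_growth(m, Condition(temperature=37.0))
        assert (not sol.feasible) or sol.mu == pytest.approx(0.0, abs=1e-6)

    def test_toy_model_matches_closed_form(self):
        m = _toy_model()
        cost = 100.0 / (50.0 * 3600.0 * folded_fraction(20.0, 37.0))
        expected = m.phi_max / (cost * 2.0 + 1.0 / m.kappa_t)
        sol = solve_growth(m, Condition(temperature=37.0))
        assert sol.feasible
        assert sol.mu == pytest.approx(expected, abs=2e-6)

    def test_feasible_solution_obeys_budget(self, model, wt37):
        total = sum(wt37.enzyme_phi.values()) + wt37.ribosome_phi
        assert total <= model.phi_max + 1e-9

    def test_mass_balance_residual(self, model, wt37):
        # recompute the balance independently from the reaction stoichiometry
        balance: dict[str, float] = {met: 0.0 for met in model.metabolites}
        for r in model.reactions:
            v = wt37.fluxes[r.id]
            for met, coeff in r.stoichiometry.items():
                balance[met] += coeff * v
        balance["atp"] -= model.gam * wt37.mu
        assert max(abs(x) for x in balance.values()) < 1e-7

    def test_deterministic_flux_vectors(self, model):
        a = solve_growth(model, Condition(temperature=40.0))
        b = solve_growth(model, Condition(temperature=40.0))
        assert a.mu == b.mu
        assert a.fluxes == b.fluxes

    def test_growth_monotone_in_proteome_budget(self, model):
        mus = []
        for phi in (0.25, 0.30, 0.36, 0.45):
            m = copy.deepcopy(model)
            m.phi_max = phi
            mus.append(solve_growth(m, Condition(temperature=37.0)).mu)
        assert all(b >= a - 1e-6 for a, b in zip(mus, mus[1:]))

    def test_fixed_growth_rate_is_honored(self, model):
        sol = solve_growth(
            model, Condition(temperature=37.0, fixed_growth_rate=0.3)
        )
        assert sol.feasible and sol.mu == 0.3
        assert sol.fluxes["BIOMASS"] == pytest.approx(0.3, abs=1e-9)

    def test_oxidase_knockouts_abolish_synthase_flux(self, model):
        g = StrainGenotype(
            strain_id="ko", knockouts={"Cyd", "Cyo", "AppBC", "YgiN"}
        )
        sol = solve_growth(apply_genotype(model, g), Condition(temperature=37.0))
        assert sol.feasible
        assert sol.fluxes["ATPS4rpp"] == pytest.approx(0.0, abs=1e-9)
        assert compute_fractions(sol, model).f_ATPS == 0.0

class TestCalibration:
    def test_max_fraction_in_band(self, model):
        assert (
            CAL_MAX_FATPS_BAND[0]
            <= max_stoichiometric_fatps(model)
            <= CAL_MAX_FATPS_BAND[1]
        )

    def test_wildtype_sits_in_top_band(self, model, wt37):
        assert compute_fractions(wt37, model).f_ATPS >= 0.60

    def test_calibration_idempotent(self, model):
        once = calibrate_wildtype(model)
        twice = calibrate_wildtype(once)
        assert once.parameters == twice.parameters
        for a, b in zip(once.enzymes, twice.enzymes):
            assert a == b
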