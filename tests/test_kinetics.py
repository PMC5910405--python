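"""Rate laws, steady-state solving, calibration and LHS robustness."""

import numpy as np
import pytest

from monolignol.kinetics import (
    CalibrationError,
    CompiledModel,
    calibrate_phenylalanine,
    lhs_robustness,
    reaction_rate,
    solve_steady_state,
)
from monolignol.pathway import (
    ComplexSpec,
    Inhibition,
    KineticParameterSet,
    PathwayDefinition,
    Reaction,
)

from conftest import toy_chain_doc


def _single_reaction_setup(mechanism="competitive"):
    """Toy chain with an optional inhibitor of reaction 1 (inhibitor is the
    product metabolite 2, so its concentration can be set freely)."""
    pathway, params = toy_chain_doc()
    inh = Inhibition(inhibitor=2, reaction=1, mechanism=mechanism)
    pathway = PathwayDefinition(
        pathway.metabolites, pathway.reactions, (inh,), pathway.gene_families
    )
    params = KineticParameterSet(
        params.reaction_params, {(2, 1): 5.0}, None  # Ki = 5 µM
    )
    return pathway, params


class TestReactionRate:
    KCAT, KM = 4.0, 10.0

    def rate(self, pathway, params, s, i=0.0, e=2.0):
        return reaction_rate(
            pathway.reaction(1), {"E1": e, "E2": 1.0}, {1: s, 2: i},
            params, pathway,
        )

    def test_zero_enzyme_zero_rate(self, toy_chain):
        pathway, params = toy_chain
        assert self.rate(pathway, params, s=50.0, e=0.0) == 0.0

    def test_half_saturation_identity(self, toy_chain):
        pathway, params = toy_chain
        v = self.rate(pathway, params, s=self.KM, e=2.0)
        assert v == pytest.approx(self.KCAT * 2.0 / 2.0, rel=1e-12)

    def test_competitive_inhibitor_at_ki_doubles_km(self):
        pathway, params = _single_reaction_setup("competitive")
        # at S = Km and I = Ki the rate drops to kcat*E/3
        v = self.rate(pathway, params, s=self.KM, i=5.0, e=3.0)
        assert v == pytest.approx(self.KCAT * 3.0 / 3.0, rel=1e-12)

    def test_uncompetitive_inhibitor_formula(self):
        pathway, params = _single_reaction_setup("uncompetitive")
        v = self.rate(pathway, params, s=20.0, i=10.0, e=1.0)
        expect = self.KCAT * 20.0 / (self.KM + 20.0 * (1 + 10.0 / 5.0))
        assert v == pytest.approx(expect, rel=1e-12)

    def test_noncompetitive_inhibitor_formula(self):
        pathway, params = _single_reaction_setup("noncompetitive")
        v = self.rate(pathway, params, s=20.0, i=10.0, e=1.0)
        expect = self.KCAT * 20.0 / (self.KM + 20.0) / (1 + 10.0 / 5.0)
        assert v == pytest.approx(expect, rel=1e-12)

    def test_saturation_limit(self, toy_chain):
        pathway, params = toy_chain
        v = self.rate(pathway, params, s=1e4 * self.KM, e=2.0)
        assert v == pytest.approx(self.KCAT * 2.0, rel=1e-3)

    @pytest.mark.parametrize("factor", [1.0, 1.5, 3.0, 10.0])
    def test_rate_monotone_in_enzyme(self, toy_chain, factor):
        pathway, params = toy_chain
        assert self.rate(pathway, params, s=7.0, e=2.0 * factor) >= \
            self.rate(pathway, params, s=7.0, e=2.0)

    def test_inactive_reaction_rate_zero(self, pathway, kinetics, wt_proteins):
        r16 = pathway.reaction(16)
        conc = {m: 10.0 for m in pathway.metabolite_ids}
        assert reaction_rate(r16, wt_proteins, conc, kinetics, pathway) == 0.0


class TestComplexPool:
    def _params(self, leftover_active):
        pathway, base = toy_chain_doc()
        cs = ComplexSpec(
            stoichiometry={"E1": 3, "E2": 1}, reactions=(1,),
            params={1: (10.0, 2.0)}, leftover_active=leftover_active,
        )
        params = KineticParameterSet(base.reaction_params, {}, cs)
        return pathway, params

    def test_exact_stoichiometry_consumes_all_monomer(self):
        pathway, params = self._params(leftover_active=True)
        # E1=3c, E2=c -> complex pool c, no leftovers; rate at saturation = kcat_c*c
        v = reaction_rate(pathway.reaction(1), {"E1": 6.0, "E2": 2.0},
                          {1: 1e5}, params, pathway)
        assert v == pytest.approx(10.0 * 2.0, rel=1e-3)

    def test_leftover_monomer_adds_activity(self):
        pathway, on = self._params(leftover_active=True)
        _, off = self._params(leftover_active=False)
        enzymes = {"E1": 9.0, "E2": 2.0}  # pool 2, leftover E1 = 3
        conc = {1: 50.0}
        v_on = reaction_rate(pathway.reaction(1), enzymes, conc, on, pathway)
        v_off = reaction_rate(pathway.reaction(1), enzymes, conc, off, pathway)
        assert v_on > v_off


class TestSteadyState:
    def test_toy_chain_matches_closed_form(self, toy_chain):
        pathway, params = toy_chain
        e1, e2, s = 2.0, 1.5, 8.0
        ss = solve_steady_state(pathway, params, {"E1": e1, "E2": e2}, s)
        v1 = 4.0 * e1 * s / (10.0 + s)
        vmax2 = 9.0 * e2
        m_expected = 25.0 * v1 / (vmax2 - v1)
        assert ss.converged
        assert ss.metabolite_conc[2] == pytest.approx(m_expected, rel=1e-6)
        assert ss.fluxes[1] == pytest.approx(v1, rel=1e-6)
        assert ss.fluxes[2] == pytest.approx(v1, rel=1e-6)

    def test_zero_phenylalanine_empty_pathway(self, pathway, kinetics, wt_proteins):
        ss = solve_steady_state(pathway, kinetics, wt_proteins, 0.0)
        assert ss.converged
        for m in pathway.internal_metabolites:
            assert ss.metabolite_conc[m] == 0.0
        assert all(v == 0.0 for v in ss.fluxes.values())

    def test_wildtype_steady_state(self, pathway, kinetics, wt_proteins):
        ss = solve_steady_state(pathway, kinetics, wt_proteins, 1.4)
        assert ss.converged and ss.residual < 1e-6
        assert all(v >= 0 for v in ss.fluxes.values())
        assert all(c >= 0 for c in ss.metabolite_conc.values())
        assert ss.sg_ratio == pytest.approx(2.16, abs=1e-3)

    def test_inactive_fluxes_zero_at_steady_state(self, pathway, kinetics,
                                                  wt_proteins):
        ss = solve_steady_state(pathway, kinetics, wt_proteins, 1.4)
        for rid in (16, 20, 21, 26):
            assert ss.fluxes[rid] == 0.0

    def test_mass_balance_at_steady_state(self, pathway, kinetics, wt_proteins):
        ss = solve_steady_state(pathway, kinetics, wt_proteins, 1.4)
        for mid in pathway.internal_metabolites:
            inflow = sum(ss.fluxes[r.id] for r in pathway.reactions
                         if r.product == mid)
            outflow = sum(ss.fluxes[r.id] for r in pathway.reactions
                          if r.substrate == mid)
            assert abs(inflow - outflow) <= 1e-6 * max(inflow, 1e-12)

    def test_nonconvergence_reported_not_raised(self, toy_chain):
        pathway, params = toy_chain
        # inflow exceeds the consuming reaction's capacity: M grows forever
        ss = solve_steady_state(pathway, params, {"E1": 100.0, "E2": 1e-4}, 50.0)
        assert not ss.converged
        assert np.isfinite(ss.residual) and ss.residual >= 1e-6


class TestCalibration:
    def test_fixed_point_identity(self, pathway, kinetics, wt_proteins):
        target = solve_steady_state(pathway, kinetics, wt_proteins, 5.0).sg_ratio
        phe = calibrate_phenylalanine(pathway, kinetics, wt_proteins, target)
        # the contract is in S/G space: the returned phe reproduces the target
        sg = solve_steady_state(pathway, kinetics, wt_proteins, phe).sg_ratio
        assert sg == pytest.approx(target, rel=1e-3)
        assert phe == pytest.approx(5.0, rel=0.1)

    def test_matches_dense_grid_scan(self, pathway, kinetics, wt_proteins):
        target = 2.16
        phe = calibrate_phenylalanine(pathway, kinetics, wt_proteins, target)
        grid = np.geomspace(0.5, 4.0, 40)
        sg = [solve_steady_state(pathway, kinetics, wt_proteins, p).sg_ratio
              for p in grid]
        best = grid[int(np.argmin(np.abs(np.array(sg) - target)))]
        assert phe == pytest.approx(best, rel=0.1)

    def test_unreachable_target_reports_range(self, pathway, kinetics,
                                              wt_proteins):
        with pytest.raises(CalibrationError, match="scanned S/G range"):
            calibrate_phenylalanine(pathway, kinetics, wt_proteins, 1e6,
                                    n_scan=5)


class TestLHSRobustness:
    def test_unique_attractor_fraction_one(self, toy_chain):
        pathway, params = toy_chain
        frac = lhs_robustness(pathway, params, {"E1": 2.0, "E2": 1.5}, 8.0,
                              n_samples=20, seed=3)
        assert frac == 1.0

    def test_deterministic_under_seed(self, toy_chain):
        pathway, params = toy_chain
        args = (pathway, params, {"E1": 2.0, "E2": 1.5}, 8.0)
        a = lhs_robustness(*args, n_samples=10, seed=11)
        b = lhs_robustness(*args, n_samples=10, seed=11)
        assert a == b

    def test_wildtype_robustness(self, pathway, kinetics, wt_proteins):
        frac = lhs_robustness(pathway, kinetics, wt_proteins, 1.4,
                              n_samples=10, seed=0)
        assert frac == 1.0
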