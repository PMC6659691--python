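"""Rate laws, derivative assembly, stiff integration and percent-change readout."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mcsim import (
    AgonistDose,
    KineticParams,
    PathwayNetwork,
    Reaction,
    SimulationSettings,
    Species,
    apply_agonist,
    assemble_derivatives,
    conserved_moieties,
    percent_change_readout,
    reaction_flux,
    simulate,
)
from mcsim.fixtures import build_gpcr_fixture, jitter_network


def synth_deg_network(k0=2.0, kd=0.5, x0=0.0):
    return PathwayNetwork(
        "toy",
        species=[Species("X", initial_amount=x0)],
        reactions=[
            Reaction("src", "synthesis", [], [("X", 1)], [], KineticParams(kf=k0)),
            Reaction("snk", "degradation", [("X", 1)], [], [], KineticParams(kf=kd)),
        ],
        output_markers=["X"],
    )


class TestReactionFlux:
    def test_smm_induced_closed_form(self):
        # v = Vmax * [M]/(Ka+[M]) * [S]/(Km+[S]) = 10 * 1/2 * 2/4 = 2.5
        rxn = Reaction("r", "smm_induced", [("S", 1)], [("P", 1)], [("M", "activator")],
                       KineticParams(vmax=10.0, ka=1.0, km=2.0))
        assert reaction_flux(rxn, {"S": 2.0, "M": 1.0}) == pytest.approx(2.5)

    def test_mass_action_irrev_closed_form(self):
        rxn = Reaction("r", "mass_action_irrev", [("A", 1), ("B", 1)], [("C", 1)], [],
                       KineticParams(kf=0.1))
        assert reaction_flux(rxn, {"A": 2.0, "B": 3.0}) == pytest.approx(0.6)

    def test_mass_action_rev_net_flux(self):
        rxn = Reaction("r", "mass_action_rev", [("A", 1)], [("B", 1)], [],
                       KineticParams(kf=1.0, kr=0.25))
        assert reaction_flux(rxn, {"A": 2.0, "B": 4.0}) == pytest.approx(2.0 - 1.0)

    @pytest.mark.parametrize(
        "kind,subs,mods,params",
        [
            ("smm_induced", [("S", 1)], [("M", "activator")], dict(vmax=1.0, ka=1.0, km=1.0)),
            ("smm_summed", [("S", 1)], [("M", "activator"), ("N", "activator")],
             dict(vmax=[1.0, 2.0], ka=[1.0, 1.0], km=1.0)),
            ("smm_inhibited", [("S", 1)], [("I", "inhibitor")], dict(vmax=1.0, km=1.0, ki=1.0)),
            ("mass_action_irrev", [("S", 1)], [], dict(kf=1.0)),
            ("mass_action_rev", [("S", 1)], [], dict(kf=1.0, kr=1.0)),
            ("degradation", [("S", 1)], [], dict(kf=1.0)),
        ],
    )
    def test_zero_state_gives_zero_flux(self, kind, subs, mods, params):
        rxn = Reaction("r", kind, subs, [("P", 1)], mods, KineticParams(**params))
        state = {sid: 0.0 for sid in ("S", "P", "M", "N", "I")}
        assert reaction_flux(rxn, state) == 0.0

    def test_summed_smm_is_sum_of_single_terms(self):
        both = Reaction("r", "smm_summed", [("S", 1)], [("P", 1)],
                        [("M", "activator"), ("N", "activator")],
                        KineticParams(vmax=[4.0, 2.0], ka=[1.0, 2.0], km=3.0))
        only_m = Reaction("r", "smm_induced", [("S", 1)], [("P", 1)], [("M", "activator")],
                          KineticParams(vmax=4.0, ka=1.0, km=3.0))
        only_n = Reaction("r", "smm_induced", [("S", 1)], [("P", 1)], [("N", "activator")],
                          KineticParams(vmax=2.0, ka=2.0, km=3.0))
        state = {"S": 5.0, "M": 0.7, "N": 2.3}
        assert reaction_flux(both, state) == pytest.approx(
            reaction_flux(only_m, state) + reaction_flux(only_n, state)
        )

    def test_kcat_form_uses_enzyme_concentration(self):
        rxn = Reaction("r", "smm_induced", [("S", 1)], [("P", 1)], [("E", "activator")],
                       KineticParams(kcat=2.0, km=20.0))
        # v = kcat*[E] * [S]/(Km+[S]) = 2*3 * 100/120
        assert reaction_flux(rxn, {"S": 100.0, "E": 3.0}) == pytest.approx(6.0 * 100 / 120)

    def test_activity_scale_multiplies_catalysed_flux(self):
        rxn = Reaction("r", "smm_induced", [("S", 1)], [("P", 1)], [("M", "activator")],
                       KineticParams(vmax=10.0, ka=1.0, km=2.0))
        state = {"S": 2.0, "M": 1.0}
        base = reaction_flux(rxn, state)
        doubled = reaction_flux(rxn, state, activity_scale={"M": 2.0})
        assert doubled == pytest.approx(2.0 * base)

    def test_inhibitor_activity_scale_strengthens_inhibition(self):
        rxn = Reaction("r", "smm_inhibited", [("S", 1)], [("P", 1)], [("I", "inhibitor")],
                       KineticParams(vmax=1.0, km=1.0, ki=1.0))
        state = {"S": 10.0, "I": 1.0}
        assert reaction_flux(rxn, state, activity_scale={"I": 3.0}) < reaction_flux(rxn, state)


class TestAssembly:
    def test_synthesis_degradation_rhs(self):
        rhs = assemble_derivatives(synth_deg_network())
        assert rhs(0.0, np.array([0.0]))[0] == pytest.approx(2.0)
        assert rhs(0.0, np.array([4.0]))[0] == pytest.approx(0.0)
        assert rhs(0.0, np.array([8.0]))[0] == pytest.approx(-2.0)

    def test_dimerization_stoichiometry(self):
        net = PathwayNetwork(
            "toy",
            species=[Species("A", initial_amount=3.0), Species("D")],
            reactions=[Reaction("dim", "mass_action_irrev", [("A", 2)], [("D", 1)], [],
                                KineticParams(kf=0.2))],
        )
        dx = assemble_derivatives(net)(0.0, np.array([3.0, 0.0]))
        assert dx[0] == pytest.approx(-2 * 0.2 * 9)  # -3.6
        assert dx[1] == pytest.approx(0.2 * 9)  # +1.8

    def test_moiety_weighted_derivatives_vanish(self, gpcr_net):
        rhs = assemble_derivatives(gpcr_net)
        idx = gpcr_net.species_index()
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 5.0, size=len(gpcr_net.species))
        dx = rhs(0.0, x)
        g_moieties = [
            m for m in conserved_moieties(gpcr_net) if "GDP_GNAS_GNBC" in m or "GDP_GNAI_GNBC" in m
        ]
        assert g_moieties
        for m in g_moieties:
            total = sum(float(w) * dx[idx[sid]] for sid, w in m.items())
            assert total == pytest.approx(0.0, abs=1e-10)


class TestSimulate:
    def test_closed_form_steady_state(self, settings):
        res = simulate(synth_deg_network(), settings)
        assert float(res.endpoint["X"]) == pytest.approx(4.0, rel=1e-5)
        assert res.steady_state_reached

    def test_report_grid(self, settings):
        res = simulate(synth_deg_network(), settings)
        assert list(res.times) == [0.0, 16.0, 32.0, 64.0]
        assert (res.trajectories.iloc[-1] == res.endpoint).all()

    def test_solver_cross_check_analytic_and_explicit(self):
        # x(t) = (k0/kd)(1 - exp(-kd t)); also cross-checked against DOP853
        k0, kd, t_end = 2.0, 0.5, 10.0
        net = synth_deg_network(k0, kd)
        res = simulate(net, SimulationSettings(t_end=t_end, report_grid=(t_end,)))
        exact = (k0 / kd) * (1 - math.exp(-kd * t_end))
        assert float(res.endpoint["X"]) == pytest.approx(exact, rel=1e-5)
        ref = solve_ivp(lambda t, x: [k0 - kd * x[0]], (0, t_end), [0.0],
                        method="DOP853", rtol=1e-10, atol=1e-12)
        assert float(res.endpoint["X"]) == pytest.approx(ref.y[0, -1], rel=1e-4)

    def test_zero_dose_leaves_activated_species_at_baseline(self, ifng_net, settings):
        res = simulate(ifng_net, settings)
        for sid in ("IFNGR_JAK_act", "FYN_act", "GAB2_act", "IRS2_act", "PIK3CA_act",
                    "NFKB_nuc", "STAT1_act", "STAT1_dimer"):
            assert abs(float(res.endpoint[sid])) <= settings.atol

    def test_dose_monotone_stat1_dimer(self, ifng_net, settings):
        doses = (0.5, 2.0, 10.0)
        vals = [
            float(simulate(apply_agonist(ifng_net, AgonistDose("IFNG", d)), settings)
                  .endpoint["STAT1_dimer"])
            for d in doses
        ]
        assert vals[0] <= vals[1] <= vals[2]
        assert vals[2] > vals[0]  # the response is not flat

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_nonnegativity_under_parameter_jitter(self, seed, settings):
        rng = np.random.default_rng(seed)
        net = jitter_network(build_gpcr_fixture(), rng)
        dosed = apply_agonist(net, AgonistDose("PGE2", 10.0))
        res = simulate(dosed, settings)
        assert res.trajectories.values.min() >= -settings.atol

    def test_conservation_over_64h(self, gpcr_net, settings):
        net = gpcr_net.copy()
        net.reactions = [r for r in net.reactions
                         if r.kind not in ("synthesis", "degradation", "secretion")]
        res = simulate(apply_agonist(net, AgonistDose("PGE2", 10.0)), settings)
        for m in conserved_moieties(net):
            total = sum(float(w) * res.trajectories[sid] for sid, w in m.items())
            drift = (total.max() - total.min()) / abs(total.iloc[0])
            assert drift < 1e-6

    def test_bit_identical_reruns(self, gpcr_net, settings):
        dosed = apply_agonist(gpcr_net, AgonistDose("PGE2", 10.0))
        a = simulate(dosed, settings)
        b = simulate(dosed, settings)
        assert (a.trajectories.values == b.trajectories.values).all()


class TestPercentChange:
    def test_direct_arithmetic(self, settings):
        net = synth_deg_network()
        ctrl = simulate(net, settings)
        boosted = synth_deg_network(k0=2.0 * 1.8363)
        stim = simulate(boosted, settings)
        (resp,) = percent_change_readout(ctrl, stim, ["X"])
        assert resp.percent_change == pytest.approx(83.63, abs=0.01)
        assert resp.trend == "up"

    def test_control_vs_itself_is_zero(self, gpcr_net, settings):
        res = simulate(gpcr_net, settings)
        (resp,) = percent_change_readout(res, res, ["cAMP"])
        assert resp.percent_change == 0.0
        assert resp.trend == "no_change"

    def test_zero_dose_equals_control(self, gpcr_net, settings):
        ctrl = simulate(gpcr_net, settings)
        dosed = simulate(apply_agonist(gpcr_net, AgonistDose("PGE2", 0.0)), settings)
        (resp,) = percent_change_readout(ctrl, dosed, ["cAMP"])
        assert resp.percent_change == 0.0

    def test_zero_control_floor_branch(self, settings):
        net = PathwayNetwork("toy", species=[Species("X")], output_markers=["X"])
        ctrl = simulate(net, settings)
        stim_net = synth_deg_network(k0=0.5, kd=0.1)
        stim = simulate(stim_net, settings)
        (resp,) = percent_change_readout(ctrl, stim, ["X"])
        assert math.isnan(resp.percent_change)
        assert resp.trend == "up"

    def test_unknown_marker_raises(self, settings):
        res = simulate(synth_deg_network(), settings)
        with pytest.raises(KeyError, match="NOPE"):
            percent_change_readout(res, res, ["NOPE"])
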