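"""Co-culture composition, medium coupling and staged feed-forward runs."""

import pytest

from mcsim import (
    AgonistDose,
    CouplingMap,
    KineticParams,
    NetworkError,
    PathwayNetwork,
    Secretion,
    SimulationSettings,
    Species,
    Uptake,
    apply_agonist,
    apply_genomic_profile,
    compose_coculture,
    parse_coupling,
    run_feedforward,
    serialize_coupling,
    simulate,
)


def _zero_secretions(coupling):
    return CouplingMap(
        secretions=tuple(
            Secretion(s.cell_id, s.species, s.medium_species, 0.0) for s in coupling.secretions
        ),
        uptakes=(),
        medium_degradation=coupling.medium_degradation,
        volume_ratio=coupling.volume_ratio,
    )


class TestCompose:
    def test_state_dimension_bookkeeping(self, trio):
        cells, coupling, _ = trio
        model = compose_coculture(cells, coupling)
        assert len(model.network.species) == sum(len(c.species) for c in cells) + len(model.medium)
        assert len(model.medium) == 10

    def test_decoupled_cells_match_isolated_runs(self, trio, settings):
        cells, coupling, _ = trio
        model = compose_coculture(cells, _zero_secretions(coupling))
        combined = simulate(apply_agonist(model.network, AgonistDose("LPS", 10.0)), settings)
        for cell in cells[:2]:  # the two LPS-responsive cells
            solo = simulate(apply_agonist(cell, AgonistDose("LPS", 10.0)), settings)
            for sp in cell.species:
                a = float(solo.endpoint[sp.id])
                b = float(combined.endpoint[f"{cell.cell_id}.{sp.id}"])
                assert b == pytest.approx(a, rel=1e-8, abs=1e-8)

    def test_single_cell_with_empty_medium_is_lone_network(self, gpcr_net, settings):
        model = compose_coculture([gpcr_net], CouplingMap())
        a = simulate(gpcr_net, settings).endpoint
        b = simulate(model.network, settings).endpoint
        for sp in gpcr_net.species:
            assert float(b[f"gpcr_cell.{sp.id}"]) == pytest.approx(float(a[sp.id]), rel=1e-12)

    def test_duplicate_cell_ids_rejected(self, gpcr_net):
        with pytest.raises(NetworkError, match="unique"):
            compose_coculture([gpcr_net, gpcr_net], CouplingMap())

    def test_missing_species_in_coupling_rejected(self, gpcr_net):
        bad = CouplingMap(secretions=(Secretion("gpcr_cell", "NOPE", "med_X", 0.1),))
        with pytest.raises(NetworkError, match="NOPE"):
            compose_coculture([gpcr_net], bad)

    def test_permuting_cell_order_preserves_endpoints(self, trio, settings):
        cells, coupling, _ = trio
        m1 = compose_coculture(cells, coupling)
        m2 = compose_coculture(list(reversed(cells)), coupling)
        r1 = simulate(apply_agonist(m1.network, AgonistDose("LPS", 10.0)), settings)
        r2 = simulate(apply_agonist(m2.network, AgonistDose("LPS", 10.0)), settings)
        for marker in m1.output_markers:
            assert float(r2.endpoint[marker]) == pytest.approx(
                float(r1.endpoint[marker]), rel=1e-6, abs=1e-9
            )

    def test_mass_bookkeeping_with_volume_ratio(self, settings):
        # with degradation off, intracellular + volume-weighted medium is conserved
        cell = PathwayNetwork(
            "A", species=[Species("X", initial_amount=5.0, role="secreted_marker")],
            output_markers=["X"],
        )
        coupling = CouplingMap(secretions=(Secretion("A", "X", "med_X", 0.3),), volume_ratio=2.0)
        model = compose_coculture([cell], coupling)
        res = simulate(model.network, settings)
        total = res.trajectories["A.X"] + res.trajectories["med_X"] / 2.0
        drift = (total.max() - total.min()) / abs(total.iloc[0])
        assert drift < 1e-6

    def test_as_transport_conserves_mass(self, settings):
        src = PathwayNetwork(
            "A", species=[Species("X", initial_amount=5.0, role="secreted_marker")],
        )
        sink = PathwayNetwork(
            "B",
            species=[
                Species("L", role="ligand"),
                Species("R", role="receptor", initial_amount=1.0),
                Species("R_act", role="receptor_active"),
            ],
            reactions=[],
        )
        coupling = CouplingMap(
            secretions=(Secretion("A", "X", "med_X", 0.3),),
            uptakes=(Uptake("med_X", "B", "L", "as_transport", ku=0.2),),
            volume_ratio=1.0,
        )
        model = compose_coculture([src, sink], coupling)
        res = simulate(model.network, settings)
        total = res.trajectories["A.X"] + res.trajectories["med_X"] + res.trajectories["B.L"]
        assert (total.max() - total.min()) / total.iloc[0] < 1e-6

    def test_autocrine_loop_permitted(self, trio, settings):
        # HTL secretes IL1A and also senses medium IL1A: a legal autocrine loop
        cells, coupling, _ = trio
        model = compose_coculture(cells, coupling)
        assert any(
            u.cell_id == "HTL" and u.medium_species == "med_IL1A" for u in coupling.uptakes
        )
        simulate(model.network, SimulationSettings(t_end=4.0))  # integrates cleanly

    def test_coupling_yaml_roundtrip(self, trio):
        _, coupling, _ = trio
        text = serialize_coupling(coupling)
        assert serialize_coupling(parse_coupling(text)) == text


class TestFeedForward:
    def _perturber(self, mm_dc, label):
        def f(net):
            out, _ = apply_genomic_profile(net, mm_dc.profiles[label], mm_dc.effect_library)
            return out
        return f

    def test_immunosuppressive_profile_inhibits_all_dc_markers(self, mm_dc, settings):
        resp = run_feedforward(
            [mm_dc.mm], mm_dc.dc, mm_dc.coupling, mm_dc.mapping, settings,
            perturb_sources=self._perturber(mm_dc, "strong"),
        )
        assert [r.marker for r in resp] == ["CD80", "CD86", "IL2", "IFNG", "IL12B"]
        assert all(r.trend == "down" for r in resp)

    def test_stronger_profile_inhibits_at_least_as_much(self, mm_dc, settings):
        weak = run_feedforward([mm_dc.mm], mm_dc.dc, mm_dc.coupling, mm_dc.mapping, settings,
                               perturb_sources=self._perturber(mm_dc, "weak"))
        strong = run_feedforward([mm_dc.mm], mm_dc.dc, mm_dc.coupling, mm_dc.mapping, settings,
                                 perturb_sources=self._perturber(mm_dc, "strong"))
        for w, s in zip(weak, strong):
            assert s.percent_change <= w.percent_change <= 0.0

    def test_zero_secretions_give_zero_percent(self, mm_dc, settings):
        resp = run_feedforward(
            [mm_dc.mm], mm_dc.dc, _zero_secretions(mm_dc.coupling), mm_dc.mapping, settings,
            perturb_sources=self._perturber(mm_dc, "strong"),
        )
        assert all(r.percent_change == 0.0 for r in resp)

    def test_unmapped_medium_species_is_error(self, mm_dc, settings):
        bad_map = (("med_NOPE", "IL10_in"),)
        with pytest.raises(NetworkError, match="med_NOPE"):
            run_feedforward([mm_dc.mm], mm_dc.dc, mm_dc.coupling, bad_map, settings)

    def test_unknown_target_ligand_is_error(self, mm_dc, settings):
        bad_map = (("med_IL10", "NOPE"),)
        with pytest.raises(NetworkError, match="NOPE"):
            run_feedforward([mm_dc.mm], mm_dc.dc, mm_dc.coupling, bad_map, settings)

    def test_unperturbed_sources_give_zero_percent(self, mm_dc, settings):
        resp = run_feedforward([mm_dc.mm], mm_dc.dc, mm_dc.coupling, mm_dc.mapping, settings)
        assert all(r.percent_change == 0.0 for r in resp)
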