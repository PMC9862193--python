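"""13C labelled-fraction layer: splitting, toy oracles, conservation."""
import numpy as np
import pytest
from scipy.integrate import odeint

from yeastff import GlycogenTables, YeastModel
from yeastff.labeling import (
    labelled_derivative,
    ode_rhs_labelled,
    simulate_enrichment,
    split_reversible,
)
from yeastff.network import Network, Reaction, Species


class TestSplit:
    def test_sign_split(self):
        f, b = split_reversible(np.array([2.0, -3.0, 0.0]))
        np.testing.assert_array_equal(f, [2.0, 0.0, 0.0])
        np.testing.assert_array_equal(b, [0.0, 3.0, 0.0])

    def test_reconstruction_bitwise(self, rng):
        v = rng.normal(0, 5, 1000)
        f, b = split_reversible(v)
        assert np.all(f >= 0) and np.all(b >= 0)
        np.testing.assert_array_equal(f - b, v)
        # exactly one member of each pair is nonzero
        assert np.all((f == 0) | (b == 0))


class TestTwoPoolWashout:
    def test_enrichment_follows_closed_form(self):
        """A -> B at constant flux with A held fully labelled:
        e_B(t) = 1 - exp(-v t / B_total)."""
        species = (Species("A", 6, "cyt"), Species("B", 6, "cyt"))
        rxns = (
            Reaction("AB", {"A": -1, "B": 1}, reversible=False,
                     carbon_in={"A": 1}, carbon_out={"B": 1}),
            # constant turnover of B keeps its total at steady state
            Reaction("Bout", {"B": -1}, reversible=False,
                     carbon_in={"B": 1}, extra_out_carbons=6.0),
        )
        net = Network(species, rxns, volume_state=False)
        v = np.array([0.3, 0.3])
        totals = np.array([5.0, 2.0])

        def rhs(L, t):
            L_held = np.array([totals[0], L[1]])  # A stays fully labelled
            dL = labelled_derivative(net, v, totals, L_held)
            return [0.0, dL[1]]

        t = np.linspace(0.0, 20.0, 201)
        L = odeint(rhs, [totals[0], 0.0], t, rtol=1e-10, atol=1e-12)
        e_b = L[:, 1] / totals[1]
        expected = 1.0 - np.exp(-v[0] * t / totals[1])
        np.testing.assert_allclose(e_b, expected, atol=1e-6)


class TestLimits:
    def test_fully_labelled_limit_matches_total_derivatives(
            self, calibrated_model, chemostat_state, calibrated_params,
            protocol):
        """With every pool fully labelled and feed fraction 1, labelled
        derivatives equal the total derivatives for every carbon species."""
        m = calibrated_model
        y = chemostat_state
        L = np.array([y[m.i[n]] for n in m.net.labelled_names])
        dL = ode_rhs_labelled(y, L, 10.0, calibrated_params, protocol, 1.0)
        dy = m.rhs(y, 10.0, protocol.flow_at(10.0, y[-1], 1.0))
        for name in m.net.labelled_names:
            assert dL[m.net.l_index[name]] == pytest.approx(
                dy[m.i[name]], rel=1e-9, abs=1e-12)

    def test_zero_label_zero_feed_fraction(self, calibrated_model,
                                           chemostat_state, calibrated_params,
                                           protocol):
        m = calibrated_model
        L = np.zeros(m.net.n_labelled)
        dL = ode_rhs_labelled(chemostat_state, L, 10.0, calibrated_params,
                              protocol, 0.0)
        np.testing.assert_allclose(dL, 0.0, atol=1e-15)

    def test_label_fraction_bounds_checked(self, chemostat_state,
                                           calibrated_params, protocol,
                                           calibrated_model):
        L = np.zeros(calibrated_model.net.n_labelled)
        with pytest.raises(ValueError, match="label fraction"):
            ode_rhs_labelled(chemostat_state, L, 0.0, calibrated_params,
                             protocol, 1.5)


class TestCleavageConservation:
    def test_aldolase_conserves_labelled_carbon(self, calibrated_model, rng):
        m = calibrated_model
        y = np.abs(rng.uniform(0.1, 5.0, m.i_vol))
        L = y * rng.uniform(0, 1, m.i_vol)
        Lsub = np.array([L[m.i[n]] for n in m.net.labelled_names])
        v = np.zeros(m.net.n_reactions)
        v[m.net.r_index["FBA"]] = 1.5
        dL = labelled_derivative(m.net, v, y, Lsub)
        carbons = np.array([m.net.carbons[n] for n in m.net.labelled_names])
        assert abs(dL @ carbons) < 1e-12

    def test_condensation_conserves_labelled_carbon(self, calibrated_model, rng):
        m = calibrated_model
        y = np.abs(rng.uniform(0.1, 5.0, m.i_vol))
        L = y * rng.uniform(0, 1, m.i_vol)
        Lsub = np.array([L[m.i[n]] for n in m.net.labelled_names])
        v = np.zeros(m.net.n_reactions)
        v[m.net.r_index["TPS1"]] = 0.7
        dL = labelled_derivative(m.net, v, y, Lsub)
        carbons = np.array([m.net.carbons[n] for n in m.net.labelled_names])
        assert abs(dL @ carbons) < 1e-12


@pytest.fixture(scope="module")
def enrich_traj(short_traj, calibrated_params, protocol, calibrated_model):
    return simulate_enrichment(short_traj.Y[-1], calibrated_params, protocol,
                               label_fraction=0.99, n_cycles=1,
                               model=calibrated_model)


class TestEnrichmentRun:
    def test_labelled_below_total_everywhere(self, enrich_traj):
        for name in enrich_traj.model.net.labelled_names:
            lab = enrich_traj.labelled(name)
            tot = enrich_traj.species(name)
            assert np.all(lab >= -1e-8)
            assert np.all(lab <= tot + 1e-8)

    def test_enrichment_rises_then_decays_glycolysis(self, enrich_traj):
        # storage recirculation dilutes the late cycle
        e = enrich_traj.enrichment("G6P")
        t = enrich_traj.times
        assert e[t == 100][0] > 60.0
        assert e.max() > e[-1]

    def test_zero_label_fraction_stays_zero(self, short_traj,
                                            calibrated_params, protocol,
                                            calibrated_model):
        traj = simulate_enrichment(short_traj.Y[-1], calibrated_params,
                                   protocol, label_fraction=0.0, n_cycles=1,
                                   model=calibrated_model, t_res=4.0)
        assert np.max(np.abs(traj.L)) < 1e-12

    def test_storage_off_enrichment_monotone(self, chemostat_state,
                                             calibrated_params, protocol):
        """No storage recirculation -> glycolytic enrichment never decreases
        on its way toward the feed fraction."""
        storage_off = calibrated_params.replace({
            "TPS1.Vmax": 0.0, "TPS2.Vmax": 0.0, "NTH1.Vmax": 0.0,
            "AGT1.Vmax": 0.0, "VACT.Vmax": 0.0, "ATH1.Vmax": 0.0,
            "GLYS.v_chemostat": 0.0, "GLYD.v_chemostat": 0.0,
            "UGP.Vmax": 1e-9, "PGM1.Vmax": 1e-9})
        model = YeastModel(storage_off, protocol.biomass_gdw_per_l,
                           protocol.vacuole_fraction,
                           glycogen=GlycogenTables.zero())
        traj = simulate_enrichment(chemostat_state, storage_off, protocol,
                                   label_fraction=0.99, n_cycles=1,
                                   model=model, t_res=2.0)
        for sp_name in ("G6P", "FBP", "PYR"):
            e = traj.enrichment(sp_name)  # percent; tolerance at solver noise
            assert np.all(np.diff(e) > -1e-4), sp_name

    def test_total_labelled_carbon_balance_closes(self, enrich_traj, protocol):
        """d(labelled carbon amount)/dt integrates to inflow minus the
        enrichment-weighted outflows, within 0.5% of the labelled inflow."""
        m = enrich_traj.model
        net = m.net
        t = enrich_traj.times
        vol = enrich_traj.volume
        phi = np.array([{"cyt": m.phi_cyt,
                         "vac": m.phi_cyt / m.cyt_over_vac,
                         "ec": 1.0}[net.compartment[n]]
                        for n in net.labelled_names])
        carbons = np.array([net.carbons[n] for n in net.labelled_names])
        amount = (enrich_traj.L * phi * carbons).sum(axis=1) * vol

        outflow = np.zeros(len(t))
        for k, (tc, y) in enumerate(zip(enrich_traj.cycle_time, enrich_traj.Y)):
            v = m.fluxes(y, tc)
            vf, vb = np.maximum(v, 0), np.maximum(-v, 0)
            Lrow = enrich_traj.L[k]
            e = np.zeros(net.n_labelled)
            for name, l in net.l_index.items():
                tot = y[m.i[name]]
                e[l] = Lrow[l] / tot if tot > 1e-30 else 0.0
            loss = 0.0
            for j, table in enumerate(net._carbon_tables):
                cin, cout, in_c, out_c, denom_f, denom_b = table
                if vf[j] and in_c:
                    mix_in = sum(cn * e[l] for l, cn in in_c)
                    if denom_f > 0:
                        loss += vf[j] * mix_in * (
                            net.reactions[j].extra_out_carbons / denom_f)
                    else:
                        loss += vf[j] * mix_in
            outflow[k] = loss * m.phi_cyt * y[-1]
            if protocol.feed_s < tc <= protocol.outflow_end_s:
                gain = protocol.feed_pump_rate(y[-1]) * protocol.feed_s
                q_out = gain / (protocol.outflow_end_s - protocol.feed_s)
                outflow[k] += q_out * amount[k] / y[-1]

        from scipy.integrate import cumulative_trapezoid

        # the feed inflow is a step function: integrate it analytically to
        # avoid half-trapezoid artifacts at the phase boundary
        pump = protocol.feed_pump_rate(vol[0])
        in_rate = pump * protocol.label_fraction * protocol.feed_conc_mm * 6.0
        inflow_cum = in_rate * np.clip(t, 0.0, protocol.feed_s)
        lhs = amount - amount[0]
        rhs = inflow_cum - cumulative_trapezoid(outflow, t, initial=0.0)
        total_in = inflow_cum[-1]
        assert abs(lhs[-1] - rhs[-1]) <= 0.005 * total_in
        np.testing.assert_allclose(lhs, rhs, atol=0.005 * total_in)


class TestJointIntegration:
    def test_split_fluxes_reconstruct_at_output_steps(self, enrich_traj):
        fx = enrich_traj.flux_table()
        f, b = split_reversible(fx)
        np.testing.assert_array_equal(f - b, fx)
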