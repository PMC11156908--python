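"""Transient EMU simulation, isotopomer oracle, natural abundance."""

import numpy as np
import pytest

from picoflux.emu import EMU, decompose
from picoflux.network import FluxVector, parse_network
from picoflux.simulate import (
    FLUX_UNIT,
    LabelInput,
    SimulationError,
    add_natural_abundance,
    brute_force_isotopomer,
    correct_natural_abundance,
    natural_abundance_matrix,
    simulate_labeling,
    steady_state_mids,
)

TIMES = (0.0, 30.0, 60.0, 180.0, 300.0, 600.0)


def _full_targets(net):
    return [s for s in net.balanced_species if net.species[s].carbons > 0]


class TestBasics:
    def test_initial_condition_unlabeled(self, scn_small, emunet_small):
        sim = simulate_labeling(
            scn_small.network, emunet_small, scn_small.fluxes, scn_small.pools,
            scn_small.label, times=TIMES,
        )
        for arr in sim.data.values():
            assert arr[0, 0] == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(arr[0, 1:], 0.0, atol=1e-9)

    def test_single_pool_washout_closed_form(self):
        """One 1-carbon pool fed fully labeled input: M+1(t) = 1 - exp(-k t)
        with k = v*FLUX_UNIT/P; at t = ln(2)/k the pool is half labeled."""
        net = parse_network("#! external: S.x\nsrc\tS.x (a) -> A (a)\t0\nout\tA ->\t0")
        emunet = decompose(net, ["A"])
        v, P = 10.0, 5.0
        k = v * FLUX_UNIT / P
        t_half = np.log(2.0) / k
        label = LabelInput("S.x", purity=1.0, unlabeled_fraction=0.0)
        sim = simulate_labeling(
            net, emunet, FluxVector(net={"src": v, "out": v}), {"A": P},
            label, times=(0.0, t_half, 5 * t_half), method="ivp",
        )
        m1 = sim.data[EMU("A", (1,))][:, 1]
        assert m1[1] == pytest.approx(0.5, abs=1e-7)
        assert m1[2] == pytest.approx(1 - 2.0**-5, abs=1e-6)

    def test_rows_sum_to_one_at_all_times(self, scn_small, emunet_small):
        sim = simulate_labeling(
            scn_small.network, emunet_small, scn_small.fluxes, scn_small.pools,
            scn_small.label, times=TIMES, natural_abundance=0.0107,
        )
        for arr in sim.data.values():
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_enrichment_without_exchange(self, toy_setups):
        """With fully labeled input and no exchange fluxes the atom fraction
        sum_k k*MID_k never decreases."""
        net, fluxes, pools, label = toy_setups["chain"]
        label = LabelInput(label.species, purity=1.0, unlabeled_fraction=0.0)
        emunet = decompose(net, _full_targets(net))
        times = np.linspace(0, 600, 25)
        sim = simulate_labeling(net, emunet, fluxes, pools, label, times=times,
                                method="ivp")
        for emu, arr in sim.data.items():
            frac = arr @ np.arange(arr.shape[1])
            assert np.all(np.diff(frac) > -1e-6), str(emu)

    def test_nonsteady_fluxes_rejected(self, toy_setups):
        net, fluxes, pools, label = toy_setups["chain"]
        bad = FluxVector(net=dict(fluxes.net, r1=99.0), exchange={})
        emunet = decompose(net, _full_targets(net))
        with pytest.raises(SimulationError, match="steady state"):
            simulate_labeling(net, emunet, bad, pools, label, times=TIMES)

    def test_zero_pool_with_throughput_rejected(self, toy_setups):
        net, fluxes, pools, label = toy_setups["chain"]
        emunet = decompose(net, _full_targets(net))
        with pytest.raises(SimulationError, match="pool"):
            simulate_labeling(net, emunet, fluxes, {"A": 0.0, "B": 1, "C": 1},
                              label, times=TIMES)


class TestOracleEquivalence:
    @pytest.mark.parametrize("toy", ["chain", "cond", "sym", "rev"])
    def test_emu_matches_isotopomer_oracle(self, toy, toy_setups):
        """EMU cascade vs exhaustive isotopomer integration on the bundled
        toys at the experimental time points."""
        net, fluxes, pools, label = toy_setups[toy]
        emunet = decompose(net, _full_targets(net))
        sim = simulate_labeling(net, emunet, fluxes, pools, label,
                                times=TIMES, method="ivp")
        oracle = brute_force_isotopomer(net, fluxes, pools, label, times=TIMES)
        for emu, arr in oracle.data.items():
            assert np.abs(sim.data[emu] - arr).max() < 1e-6, str(emu)

    def test_fixed_grid_integrator_tracks_reference(self, toy_setups):
        net, fluxes, pools, label = toy_setups["rev"]
        emunet = decompose(net, _full_targets(net))
        fast = simulate_labeling(net, emunet, fluxes, pools, label, times=TIMES)
        ref = simulate_labeling(net, emunet, fluxes, pools, label, times=TIMES,
                                method="ivp")
        for emu in ref.data:
            assert np.abs(fast.data[emu] - ref.data[emu]).max() < 2e-3

    def test_oracle_conserves_probability(self, toy_setups):
        net, fluxes, pools, label = toy_setups["cond"]
        oracle = brute_force_isotopomer(net, fluxes, pools, label, times=TIMES)
        for arr in oracle.data.values():
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-7)

    def test_symmetric_pool_scrambles_positions(self, toy_setups):
        """Only carbon 1 enters labeled; downstream of the symmetric pool,
        positions 1 and 4 must carry equal enrichment."""
        net, fluxes, pools, label = toy_setups["sym"]
        emunet = decompose(net, [("M", (1,)), ("M", (4,)), ("A", (1,)), ("A", (4,))])
        sim = simulate_labeling(net, emunet, fluxes, pools, label,
                                times=TIMES, method="ivp")
        m1 = sim.data[EMU("M", (1,))][:, 1]
        m4 = sim.data[EMU("M", (4,))][:, 1]
        assert np.abs(m1 - m4).max() < 1e-9
        # upstream of the symmetric pool the positions are distinct
        a1 = sim.data[EMU("A", (1,))][-1, 1]
        a4 = sim.data[EMU("A", (4,))][-1, 1]
        assert abs(a1 - a4) > 0.1

    def test_carbon_cap_enforced(self, scn_tg2):
        with pytest.raises(SimulationError, match="cap"):
            brute_force_isotopomer(
                scn_tg2.network, scn_tg2.fluxes, scn_tg2.pools, scn_tg2.label,
                times=TIMES, carbon_cap=4,
            )


class TestSteadyState:
    def test_fully_labeled_limit(self, toy_setups):
        net, fluxes, pools, _ = toy_setups["chain"]
        label = LabelInput("S.x", purity=1.0, unlabeled_fraction=0.0)
        emunet = decompose(net, _full_targets(net))
        ss = steady_state_mids(net, emunet, fluxes, label)
        for emu, arr in ss.data.items():
            assert arr[0, -1] == pytest.approx(1.0, abs=1e-9), str(emu)

    def test_dilution_mixes_toward_unlabeled(self, toy_setups):
        net, fluxes, pools, _ = toy_setups["chain"]
        label = LabelInput("S.x", purity=1.0, unlabeled_fraction=0.0)
        emunet = decompose(net, _full_targets(net))
        ss = steady_state_mids(net, emunet, fluxes, label, dilution={"C": 0.3})
        arr = ss.data[EMU("C", (1, 2))]
        assert arr[0, -1] == pytest.approx(0.7, abs=1e-9)
        assert arr[0, 0] == pytest.approx(0.3, abs=1e-9)

    def test_transient_relaxes_to_steady_state(self, toy_setups):
        net, fluxes, pools, label = toy_setups["rev"]
        emunet = decompose(net, _full_targets(net))
        # 50 relaxation times of the slowest pool
        t_relax = 50 * max(pools.values()) * 3.6 / min(
            v for v in fluxes.net.values() if v > 0
        )
        sim = simulate_labeling(net, emunet, fluxes, pools, label,
                                times=(0.0, t_relax), method="ivp")
        ss = steady_state_mids(net, emunet, fluxes, label)
        for emu in ss.data:
            assert np.abs(sim.data[emu][-1] - ss.data[emu][0]).max() < 1e-4

    def test_fast_cbb_pools_label_before_amino_acid_pools(self, scn_tg2, emunet_tg2):
        """CBB intermediates (small pools, high flux) reach 50% atom
        enrichment before the TCA-derived amino-acid precursors."""
        scn = scn_tg2
        times = np.linspace(0, 600, 121)
        sim = simulate_labeling(scn.network, emunet_tg2, scn.fluxes, scn.pools,
                                scn.label, times=times)

        def t50(species):
            arr = sim.mid(species)
            frac = arr @ np.arange(arr.shape[1]) / (arr.shape[1] - 1)
            idx = np.argmax(frac >= 0.5 * frac[-1])
            return times[idx]

        assert t50("PGA.h") < t50("AKG.m")
        assert t50("TP.h") < t50("AKG.m")


class TestNaturalAbundance:
    def test_p13_zero_is_identity(self):
        mid = np.array([0.2, 0.5, 0.3])
        assert np.allclose(add_natural_abundance(mid, 0.0), mid)
        assert np.allclose(correct_natural_abundance(mid, 0.0), mid)

    def test_unlabeled_two_carbon_binomial(self):
        out = add_natural_abundance([1.0, 0.0, 0.0], 0.0107)
        assert out[0] == pytest.approx((1 - 0.0107) ** 2, rel=1e-9)
        assert out[1] == pytest.approx(2 * 0.0107 * (1 - 0.0107), rel=1e-9)
        assert out[2] == pytest.approx(0.0107**2, rel=1e-9)
        back = correct_natural_abundance(out, 0.0107)
        assert np.allclose(back, [1.0, 0.0, 0.0], atol=1e-12)

    def test_roundtrip_is_identity(self):
        rng = np.random.default_rng(3)
        for n in (2, 4, 6):
            mid = rng.dirichlet(np.ones(n + 1))
            out = correct_natural_abundance(add_natural_abundance(mid), clip="raise")
            assert np.allclose(out, mid, atol=1e-10)

    def test_matrix_columns_are_distributions(self):
        M = natural_abundance_matrix(5, 0.0107)
        assert np.allclose(M.sum(axis=0), 1.0)
        assert np.all(M >= 0)

    def test_implausible_p13_rejected(self):
        with pytest.raises(ValueError):
            natural_abundance_matrix(3, 0.2)
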