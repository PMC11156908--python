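"""Network parsing, stoichiometry, and flux parameterization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from picoflux.network import (
    InfeasibleError,
    ParseError,
    attach_biomass_sink,
    free_flux_basis,
    parse_network,
    parse_reaction,
    positive_solution_exists,
    stoichiometric_matrix,
    theta_bounds_lp,
    write_network,
)
from picoflux import synthetic as syn


class TestParsing:
    def test_identity_atom_map(self):
        net = parse_network("v1\tA (ab) -> B (ab)\t0")
        assert len(net.reactions) == 1
        rxn = net.reactions[0]
        assert rxn.kind == "internal"
        assert rxn.reactants[0].atoms == "ab"
        assert net.species["A"].carbons == 2

    def test_decarboxylation_atom_multisets_balance(self):
        rxn = parse_reaction("v2", "OAA (abcd) -> PEP (abc) + CO2 (d)")
        reac_atoms = sorted(a for t in rxn.reactants for a in t.atoms)
        prod_atoms = sorted(a for t in rxn.products for a in t.atoms)
        assert reac_atoms == prod_atoms  # every carbon accounted for exactly once

    def test_carbon_count_mismatch_names_the_row(self):
        with pytest.raises(ParseError, match="v3.*carbon-count mismatch"):
            parse_network("v3\tA (ab) -> B (abc)\t0")

    def test_duplicate_atom_label_rejected(self):
        with pytest.raises(ParseError, match="used twice"):
            parse_reaction("bad", "A (aa) -> B (aa)")

    def test_duplicate_reaction_id_rejected(self):
        text = "r1\tA (a) -> B (a)\t0\nr1\tB (a) -> C (a)\t0"
        with pytest.raises(ParseError, match="duplicated"):
            parse_network(text)

    def test_directives_parsed(self):
        net = syn.load_bundled_network("full")
        assert net.species["CO2.x"].external
        assert net.species["SUC.m"].symmetric
        assert "PGA.h" in net.dilution_species

    def test_transport_and_sink_kinds_inferred(self):
        net = syn.load_bundled_network("core")
        kinds = {r.id: r.kind for r in net.reactions}
        assert kinds["tpt"] == "transport"
        assert kinds["src"] == "source"

    def test_roundtrip_writer(self, tmp_path):
        net = syn.load_bundled_network("core")
        path = tmp_path / "net.tsv"
        write_network(net, path)
        net2 = parse_network(str(path))
        assert net2.reaction_ids == net.reaction_ids
        assert net2.species.keys() == net.species.keys()
        for r1, r2 in zip(net.reactions, net2.reactions):
            assert r1 == r2


class TestStoichiometry:
    def test_linear_chain_matrix(self):
        net = parse_network("r1\tA (a) -> B (a)\t0\nout\tB ->\t0")
        S, species, rxns = stoichiometric_matrix(net)
        assert species == ["A", "B"]
        assert S.tolist() == [[-1.0, 0.0], [1.0, -1.0]]

    def test_empty_network(self):
        net = parse_network("")
        S, species, rxns = stoichiometric_matrix(net)
        assert S.shape == (0, 0)

    @pytest.mark.parametrize("name", ["core", "full", "small"])
    def test_carbon_weighted_columns_balance(self, name):
        """Atom-mapped internal reactions conserve carbon: the carbon-weighted
        stoichiometry column sums to zero (checked by brute atom count)."""
        net = syn.load_bundled_network(name)
        for rxn in net.reactions:
            if not rxn.has_atom_map:
                continue
            n_reac = sum(len(t.atoms) * t.coef for t in rxn.reactants)
            n_prod = sum(len(t.atoms) * t.coef for t in rxn.products)
            assert n_reac == n_prod, rxn.id

    @pytest.mark.parametrize("name", ["tg1", "tg2", "tg2-small"])
    def test_positive_flux_solution_exists(self, name):
        scn = syn.scenario(name)
        assert positive_solution_exists(scn.network)


class TestFreeFluxBasis:
    def test_linear_chain_one_free_flux(self):
        net = parse_network(
            "#! external: S.x\nsrc\tS.x (a) -> A (a)\t0\n"
            "r1\tA (a) -> B (a)\t0\nout\tB ->\t0"
        )
        basis = free_flux_basis(net)
        assert basis.dim == 1

    def test_cycle_dimension_matches_rank_oracle(self):
        # A -> B -> C -> A cycle plus a source/sink thread
        text = (
            "src\tS.x (a) -> A (a)\t0\n"
            "r1\tA (a) -> B (a)\t0\n"
            "r2\tB (a) -> C (a)\t0\n"
            "r3\tC (a) -> A (a)\t0\n"
            "out\tB ->\t0\n"
        )
        net = parse_network("#! external: S.x\n" + text)
        S, _, rxns = stoichiometric_matrix(net)
        rank = np.linalg.matrix_rank(S)  # independent row-reduction oracle
        basis = free_flux_basis(net)
        assert basis.dim == len(rxns) - rank == 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=2))
    def test_random_theta_satisfies_steady_state(self, theta):
        scn = syn.scenario("tg2-small")
        basis = free_flux_basis(scn.network, prefer=["akgsuc", "me"])
        v = basis.flux_array(np.array(theta))
        S, _, rxns = stoichiometric_matrix(scn.network)
        fixed = scn.network.fixed_sink_fluxes
        assert np.linalg.norm(S @ v, np.inf) < 1e-10
        for rid, val in fixed.items():
            assert v[rxns.index(rid)] == pytest.approx(val, abs=1e-10)

    def test_reconstruction_reproduces_any_feasible_vector(self, scn_small):
        basis = free_flux_basis(scn_small.network, prefer=["akgsuc", "me"])
        v_true = scn_small.fluxes.as_array(basis.reaction_ids)
        theta = np.array([scn_small.fluxes.net[r] for r in basis.free_reactions])
        assert np.allclose(basis.flux_array(theta), v_true, atol=1e-10)

    def test_infeasible_demand_lists_species(self):
        net = parse_network("r1\tA (a) -> B (a)\t0\nout\tB ->\t0")
        with pytest.raises(InfeasibleError):
            # A cannot be produced, so demanding net production is impossible
            free_flux_basis(net, rhs={"A": 1.0}, fixed_fluxes={"r1": 0.0, "out": 1.0})

    def test_lp_bounds_bracket_truth(self, scn_small):
        basis = free_flux_basis(scn_small.network, prefer=["akgsuc", "me"])
        box = theta_bounds_lp(basis, scn_small.network)
        for (lo, hi), rid in zip(box, basis.free_reactions):
            assert lo <= scn_small.fluxes.net[rid] <= hi


class TestBiomassSink:
    def test_zero_growth_zeroes_sink_fluxes(self):
        net = syn.load_bundled_network("core")
        out = attach_biomass_sink(net, {"carbohydrate": {"G1P.h": 2.77}}, growth_rate=0.0)
        assert out.fixed_sink_fluxes["sink_carbohydrate"] == 0.0

    def test_carbohydrate_rich_composition_raises_g1p_coefficient(self):
        from picoflux import biomass as bm

        monomers = bm.load_monomer_table()
        rich = bm.correct_composition(dict(fame=11.8, protein=29.9, carbohydrate=44.9,
                                           dna=3.4, rna=7.66, chla=2.3))
        poor = bm.correct_composition(dict(fame=16.9, protein=50.8, carbohydrate=16.0,
                                           dna=3.9, rna=8.6, chla=2.6))
        d_rich = bm.precursor_demands(rich, monomers, aa_profile={"ala_like": 1.0})
        d_poor = bm.precursor_demands(poor, monomers, aa_profile={"ala_like": 1.0})
        assert d_rich["carbohydrate"]["G1P.h"] > 2 * d_poor["carbohydrate"]["G1P.h"]

    def test_swapping_aa_profile_changes_only_protein_sink(self):
        from picoflux import biomass as bm

        monomers = bm.load_monomer_table()
        comp = bm.correct_composition(dict(fame=10, protein=50, carbohydrate=25,
                                           dna=4, rna=8, chla=3))
        d1 = bm.precursor_demands(comp, monomers, aa_profile={"ala_like": 0.5, "glu_like": 0.5})
        d2 = bm.precursor_demands(comp, monomers, aa_profile={"ala_like": 0.2, "glu_like": 0.8})
        assert d1["protein"] != d2["protein"]
        for cls in ("carbohydrate", "fame", "dna", "rna", "chla"):
            assert d1[cls] == d2[cls]

    def test_demand_on_unknown_species_rejected(self):
        net = syn.load_bundled_network("core")
        from picoflux.network import NetworkError

        with pytest.raises(NetworkError, match="unknown species"):
            attach_biomass_sink(net, {"carbohydrate": {"NOPE": 1.0}}, growth_rate=0.1)
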