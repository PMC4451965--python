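import pytest

from dsrloops import (
    Circuit,
    InfluenceError,
    InfluenceMatrix,
    Verdict,
    build_dsr_graph,
    enumerate_circuits,
    find_relevant_loops,
    get_fixture,
    injectivity_polynomial,
    mass_action_influence,
    motif_signature,
    nuclei_for_term,
    nucleus_expansion,
    nucleus_sign,
    parse_network,
    random_network,
    stoichiometric_matrix,
    wrong_sign,
    wrong_sign_terms,
)
from dsrloops.dsr import REACTION, SPECIES, reaction_node, species_node
from _oracles import brute_force_nuclei, dfs_simple_cycles
from conftest import MITOSIS_TEXT


@pytest.fixture(scope="module")
def mitosis_graph():
    fx = get_fixture("mitosis_z1")
    A = stoichiometric_matrix(fx.network)
    return build_dsr_graph(A, fx.influence), A, fx.influence


class TestBuildGraph:
    def test_mitosis_z1_counts(self, mitosis_graph):
        G, A, Z = mitosis_graph
        assert G.number_of_nodes() == 7
        influence_edges = [e for e in G.edges if e[0][0] == SPECIES]
        stoich_edges = [e for e in G.edges if e[0][0] == REACTION]
        assert len(influence_edges) == 5
        assert len(stoich_edges) == 8

    def test_z2_graph_is_one_edge_smaller(self, mitosis_graph):
        G1, A, _ = mitosis_graph
        fx2 = get_fixture("mitosis_z2")
        G2 = build_dsr_graph(A, fx2.influence)
        assert set(G2.edges) == set(G1.edges) - {(species_node(3), reaction_node(3))}

    def test_all_zero_influence(self):
        net = parse_network(MITOSIS_TEXT)
        A = stoichiometric_matrix(net)
        Z = InfluenceMatrix(tuple(tuple(0 for _ in range(4)) for _ in range(3)))
        G = build_dsr_graph(A, Z)
        assert not [e for e in G.edges if e[0][0] == SPECIES]

    def test_edge_supports_mirror_matrices(self):
        for seed in range(10):
            net, Z = random_network(seed)
            A = stoichiometric_matrix(net)
            G = build_dsr_graph(A, Z)
            nnz_a = sum(1 for row in A.entries for v in row if v)
            assert len([e for e in G.edges if e[0][0] == SPECIES]) == Z.nnz
            assert len([e for e in G.edges if e[0][0] == REACTION]) == nnz_a

    def test_dimension_mismatch(self):
        A = stoichiometric_matrix(parse_network("r1: A -> B\n"))
        with pytest.raises(InfluenceError):
            build_dsr_graph(A, InfluenceMatrix(((1,),)))


class TestCircuits:
    def test_mitosis_counts_and_signs(self, mitosis_graph):
        G, _, _ = mitosis_graph
        circuits = enumerate_circuits(G)
        assert len(circuits) == 7
        assert sum(1 for c in circuits if c.sign > 0) == 3

    def test_red_self_activation_circuit_positive(self, mitosis_graph):
        G, _, _ = mitosis_graph
        red = Circuit.from_cycle(G, (species_node(3), reaction_node(3)))
        assert red.sign == 1
        assert red.species_count == 1

    def test_matches_dfs_oracle(self, mitosis_graph):
        G, _, _ = mitosis_graph
        expected = dfs_simple_cycles(set(G.edges))
        got = {min(tuple(c.nodes[k:] + c.nodes[:k]) for k in range(len(c.nodes)))
               for c in enumerate_circuits(G)}
        assert got == expected

    def test_matches_dfs_oracle_random(self):
        for seed in range(15):
            net, Z = random_network(seed)
            G = build_dsr_graph(stoichiometric_matrix(net), Z)
            expected = dfs_simple_cycles(set(G.edges))
            assert len(enumerate_circuits(G)) == len(expected)

    def test_canonical_rotation_invariance(self, mitosis_graph):
        G, _, _ = mitosis_graph
        cycle = (species_node(2), reaction_node(2), species_node(1), reaction_node(1))
        rotations = [cycle[k:] + cycle[:k] for k in range(4)]
        canon = {Circuit.from_cycle(G, rot) for rot in rotations}
        assert len(canon) == 1
        assert next(iter(canon)).nodes[0] == reaction_node(1)


class TestNuclei:
    def test_wrong_term_has_single_nucleus(self, mitosis_graph):
        G, _, _ = mitosis_graph
        nuclei = nuclei_for_term(G, [(2, 2), (3, 3)])
        assert len(nuclei) == 1
        D = nuclei[0]
        assert {c.nodes for c in D.circuits} == {
            (reaction_node(2), species_node(2)),
            (reaction_node(3), species_node(3)),
        }
        assert D.a1 == 2 and D.a2 == 0
        assert nucleus_sign(D, 2) == -1 == wrong_sign(2)

    def test_both_wrong_terms_give_two_nuclei_sharing_the_red_circuit(self, mitosis_graph):
        G, _, _ = mitosis_graph
        red = (reaction_node(3), species_node(3))
        nuclei = nuclei_for_term(G, [(2, 2), (3, 3)]) + nuclei_for_term(G, [(1, 1), (3, 3)])
        assert len(nuclei) == 2
        for D in nuclei:
            assert red in {c.nodes for c in D.circuits}
            positives = [c for c in D.circuits if c.sign > 0]
            negatives = [c for c in D.circuits if c.sign < 0]
            assert len(positives) == len(negatives) == 1

    def test_term_without_matching_gives_empty_list(self):
        # A is a catalyst of r1: it influences r1 but has net stoichiometry
        # zero, so no r1 -> A edge exists to close the 2-nucleus.
        net = parse_network("r1: A + B -> A + C\n")
        A = stoichiometric_matrix(net)
        Z = mass_action_influence(net)
        G = build_dsr_graph(A, Z)
        assert net.species_index("A") == 0
        assert nuclei_for_term(G, [(1, 1)]) == []

    def test_unknown_influence_edge_rejected(self, mitosis_graph):
        G, _, _ = mitosis_graph
        with pytest.raises(ValueError, match="not an influence edge"):
            nuclei_for_term(G, [(1, 2)])

    def test_nucleus_covers_2s_nodes_with_degree_one(self, mitosis_graph):
        G, A, Z = mitosis_graph
        p = injectivity_polynomial(A, Z)
        for mono, _ in p.items():
            for D in nuclei_for_term(G, mono):
                assert D.node_count == 2 * A.rank
                nodes = [v for c in D.circuits for v in c.nodes]
                assert len(nodes) == len(set(nodes))
                # its influence edges are exactly the queried term
                pairs = {pair for c in D.circuits for pair in c.influence_pairs()}
                assert pairs == set(mono)

    def test_matches_brute_force_edge_subsets(self, mitosis_graph):
        G, A, Z = mitosis_graph
        p = injectivity_polynomial(A, Z)
        for mono, _ in p.items():
            expected = brute_force_nuclei(G, mono, species_node, reaction_node)
            got = set()
            for D in nuclei_for_term(G, mono):
                edges = set()
                for c in D.circuits:
                    size = len(c.nodes)
                    edges.update(
                        (c.nodes[t], c.nodes[(t + 1) % size]) for t in range(size)
                    )
                got.add(frozenset(edges))
            assert got == expected

    def test_all_negative_nucleus_has_right_sign(self):
        # sign law: a nucleus without positive circuits has sign (-1)**s
        for seed in range(25):
            net, Z = random_network(seed)
            A = stoichiometric_matrix(net)
            G = build_dsr_graph(A, Z)
            p = injectivity_polynomial(A, Z)
            for mono, _ in p.items():
                for D in nuclei_for_term(G, mono):
                    if all(c.sign < 0 for c in D.circuits):
                        assert D.sign == (1 if A.rank % 2 == 0 else -1)


class TestNucleusExpansion:
    def test_mitosis_z1_equals_polynomial(self, mitosis_graph):
        G, A, Z = mitosis_graph
        assert nucleus_expansion(G, 2) == injectivity_polynomial(A, Z)

    def test_mitosis_z2_equals_polynomial(self):
        fx = get_fixture("mitosis_z2")
        A = stoichiometric_matrix(fx.network)
        G = build_dsr_graph(A, fx.influence)
        assert nucleus_expansion(G, 2) == injectivity_polynomial(A, fx.influence)

    def test_random_networks(self):
        for seed in range(40):
            net, Z = random_network(seed)
            A = stoichiometric_matrix(net)
            G = build_dsr_graph(A, Z)
            assert nucleus_expansion(G, A.rank) == injectivity_polynomial(A, Z)


class TestMotifSignature:
    def test_self_activation_signature(self, mitosis_graph):
        G, _, _ = mitosis_graph
        red = Circuit.from_cycle(G, (species_node(3), reaction_node(3)))
        assert motif_signature(red) == "(+,+)"

    def test_rotation_by_node_pairs_is_identified(self):
        a = Circuit(
            (reaction_node(1), species_node(1), reaction_node(2), species_node(2)),
            (-1, -1, 1, 1),
        )
        b = Circuit(
            (reaction_node(1), species_node(1), reaction_node(2), species_node(2)),
            (1, 1, -1, -1),
        )
        assert motif_signature(a) == motif_signature(b) == "(+,+,-,-)"

    def test_all_plus_cycle_is_fixed_point(self):
        c = Circuit(
            (reaction_node(1), species_node(1), reaction_node(2), species_node(2)),
            (1, 1, 1, 1),
        )
        assert motif_signature(c) == "(+,+,+,+)"

    def test_signature_follows_canonical_rotation(self, mitosis_graph):
        G, _, _ = mitosis_graph
        cycle = (species_node(2), reaction_node(2), species_node(1), reaction_node(1))
        for k in range(4):
            rot = cycle[k:] + cycle[:k]
            assert motif_signature(Circuit.from_cycle(G, rot)) == "(+,+,+,+)"


class TestFindRelevantLoops:
    def test_mitosis_z1(self):
        fx = get_fixture("mitosis_z1")
        report = find_relevant_loops(fx.network, fx.influence)
        assert report.verdict is Verdict.INCONCLUSIVE
        assert len(report.relevant_loops) == 1
        assert len(report.all_positive_loops) == 3
        loop = report.relevant_loops[0]
        assert loop.nodes == (reaction_node(3), species_node(3))
        assert [report.node_name(v) for v in loop.nodes] == ["r3", "Xnucp"]

    def test_mitosis_z2(self):
        fx = get_fixture("mitosis_z2")
        report = find_relevant_loops(fx.network, fx.influence)
        assert report.verdict is Verdict.INJECTIVE
        assert report.relevant_loops == ()
        assert report.wrong_terms == ()

    def test_two_site_phosphorylation(self):
        fx = get_fixture("phospho_two_site")
        report = find_relevant_loops(fx.network, fx.influence)
        assert len(report.relevant_loops) == 2
        by_species = {c.species_count: c for c in report.relevant_loops}
        assert set(by_species) == {2, 4}
        mm = by_species[2]
        assert {report.node_name(v) for v in mm.nodes if v[0] == SPECIES} == {"E", "ES1"}
        four = by_species[4]
        assert sum(1 for s in four.edge_signs if s < 0) == 2

    def test_relevant_subset_of_positive(self):
        for name in ("mitosis_z1", "phospho_two_site", "apoptosis"):
            fx = get_fixture(name)
            report = find_relevant_loops(fx.network, fx.influence)
            assert set(report.relevant_loops) <= set(report.all_positive_loops)

    def test_wrong_sign_nuclei_contain_a_positive_circuit(self):
        for name in ("mitosis_z1", "apoptosis"):
            fx = get_fixture(name)
            report = find_relevant_loops(fx.network, fx.influence)
            for _, nuclei in report.wrong_nuclei:
                for D in nuclei:
                    assert any(c.sign > 0 for c in D.circuits)

    def test_report_serialization_consistency(self):
        fx = get_fixture("mitosis_z1")
        report = find_relevant_loops(fx.network, fx.influence)
        payload = report.to_dict()
        assert payload["schema_version"] == 1
        assert payload["verdict"] == "INCONCLUSIVE"
        assert len(payload["relevant_loops"]) == len(report.relevant_loops)
        text = report.to_text(all_loops=True)
        assert "relevant positive feedback loops (1 of 3 positive loops)" in text
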