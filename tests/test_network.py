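import itertools

import numpy as np
import pytest

from pdznet.network import (
    NetworkError,
    PdzNetwork,
    PpiEdge,
    build_pdznet,
    compare_paralog_fractions,
    confirmed_score_cutoff,
    extract_pdz_mediated,
    filter_domain_domain,
    filter_other_motif_domains,
    integrate_ppi,
    network_summary,
    paralog_fraction,
    project_bipartite,
    random_subnetwork,
)


def _net(edges):
    net = PdzNetwork()
    for pdz, lig in edges:
        net.add_interaction(pdz, lig)
    return net


def _random_bipartite(rng, n_pdz, n_lig, p):
    edges = [
        (f"P{i}", f"L{j}")
        for i in range(n_pdz)
        for j in range(n_lig)
        if rng.random() < p
    ]
    return _net(edges), edges


class TestIntegrate:
    def test_symmetric_dedupe_merges_evidence(self):
        l1 = [PpiEdge("A", "B", frozenset({"db1"}), True)]
        l2 = [PpiEdge("B", "A", frozenset({"db2"}), True)]
        unified, skipped = integrate_ppi([l1, l2])
        assert len(unified) == 1 and skipped == 0
        assert unified[0].evidence == {"db1", "db2"}

    def test_non_direct_evidence_dropped(self):
        unified, skipped = integrate_ppi([[PpiEdge("A", "B", frozenset(), False)]])
        assert unified == [] and skipped == 1

    def test_union_size_matches_hand_enumeration(self):
        l1 = [PpiEdge("A", "B"), PpiEdge("A", "C")]
        l2 = [PpiEdge("B", "A"), PpiEdge("C", "D")]
        l3 = [PpiEdge("D", "C"), PpiEdge("E", "E")]
        unified, skipped = integrate_ppi([l1, l2, l3])
        assert {e.pair for e in unified} == {("A", "B"), ("A", "C"), ("C", "D")}
        assert skipped == 1  # the self-loop


class TestExtract:
    def test_star_keeps_all_pdz_edges(self):
        edges = [PpiEdge("PDZ1", f"L{i}") for i in range(4)]
        cands = extract_pdz_mediated(edges, {"PDZ1"})
        assert len(cands) == 4

    def test_non_pdz_edge_excluded(self):
        cands = extract_pdz_mediated([PpiEdge("X", "Y")], {"PDZ1"})
        assert cands == []

    def test_retained_count_matches_scan(self):
        rng = np.random.default_rng(0)
        names = [f"N{i}" for i in range(12)]
        pdz = set(names[:4])
        edges = [
            PpiEdge(a, b)
            for a, b in itertools.combinations(names, 2)
            if rng.random() < 0.3
        ]
        cands = extract_pdz_mediated(edges, pdz)
        brute = sum(
            (e.protein_a in pdz) + (e.protein_b in pdz) for e in edges
        )
        assert len(cands) == brute

    def test_motif_annotation_from_ctermini(self):
        cands = extract_pdz_mediated(
            [PpiEdge("PDZ1", "LIG")], {"PDZ1"}, {"LIG": "AAAAAADSWV"}
        )
        assert cands[0]["motif"] == "DSWV"


class TestDomainDomainFilter:
    ANNOT = {
        "PDZ1": {"PDZ", "SH3"},
        "L1": {"ProRich"},
        "L2": {"ProRich"},
        "L3": {"Kinase"},
    }
    CATALOG = {("SH3", "ProRich")}

    def _cands(self):
        return [
            {"pdz": "PDZ1", "ligand": l, "motif": "", "evidence": frozenset()}
            for l in ("L1", "L2", "L3", "L4")
        ]

    def test_planted_counts(self):
        """Of 2 catalogued-DDI edges, only the low-scoring one is removed."""
        scores = {("PDZ1", "L1"): -1.0, ("PDZ1", "L2"): 5.0, ("PDZ1", "L3"): -2.0}
        kept, removed, warnings = filter_domain_domain(
            self._cands(), self.CATALOG, self.ANNOT, scores, cutoff=0.5
        )
        assert [c["ligand"] for c in removed] == ["L1"]  # DDI + below cutoff
        assert {c["ligand"] for c in kept} == {"L2", "L3", "L4"}
        assert any("L4" in w for w in warnings)  # unannotated -> kept + warning

    def test_idempotent(self):
        scores = {("PDZ1", "L1"): -1.0}
        kept, _, _ = filter_domain_domain(
            self._cands(), self.CATALOG, self.ANNOT, scores, cutoff=0.5
        )
        again, removed2, _ = filter_domain_domain(
            kept, self.CATALOG, self.ANNOT, scores, cutoff=0.5
        )
        assert again == kept and removed2 == []


class TestOtherMotifFilter:
    def test_cutoff_is_min_confirmed(self):
        assert confirmed_score_cutoff([2.1, 0.4, 3.3]) == pytest.approx(0.4)

    def test_planted_counts(self):
        cands = [
            {"pdz": "P", "ligand": f"L{i}", "motif": "", "evidence": frozenset()}
            for i in range(6)
        ]
        flags = {("P", f"L{i}"): i < 5 for i in range(6)}
        scores = {("P", f"L{i}"): s for i, s in enumerate([0.1, 0.2, 0.3, 1.0, 2.0, -9.0])}
        kept, removed, cutoff = filter_other_motif_domains(
            cands, flags, scores, confirmed_scores=[2.1, 0.4, 3.3]
        )
        assert cutoff == pytest.approx(0.4)
        assert {c["ligand"] for c in removed} == {"L0", "L1", "L2"}
        # L5 scores below cutoff but carries no other-motif flag
        assert {c["ligand"] for c in kept} == {"L3", "L4", "L5"}

    def test_empty_confirmed_errors(self):
        with pytest.raises(NetworkError):
            filter_other_motif_domains([], {}, {}, confirmed_scores=[])


class TestProjection:
    def test_shared_ligand_connects_pdz_pair(self):
        net = _net([("LAP2", "ARVC"), ("LAP2", "CTND2")])
        pln = project_bipartite(net, "pln")
        assert pln.has_edge("ARVC", "CTND2")
        assert pln.edges["ARVC", "CTND2"]["weight"] == 1

    def test_star_projects_to_clique(self):
        m = 5
        net = _net([("P1", f"L{i}") for i in range(m)])
        pln = project_bipartite(net, "pln")
        assert pln.number_of_edges() == m * (m - 1) // 2

    @pytest.mark.parametrize("mode", ["ppn", "pln"])
    def test_matches_brute_force_intersection(self, mode):
        """Projection equals pairwise partner-set intersection, graphs <= 50 nodes."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            n_pdz = int(rng.integers(2, 15))
            n_lig = int(rng.integers(2, 35))
            net, edges = _random_bipartite(rng, n_pdz, n_lig, 0.2)
            proj = project_bipartite(net, mode)
            partners = {}
            for pdz, lig in edges:
                u, v = (pdz, lig) if mode == "ppn" else (lig, pdz)
                partners.setdefault(u, set()).add(v)
            for u, v in itertools.combinations(sorted(partners), 2):
                shared = len(partners[u] & partners[v])
                if shared:
                    assert proj.edges[u, v]["weight"] == shared
                else:
                    assert not proj.has_edge(u, v)
            for u, v, d in proj.edges(data=True):
                assert d["weight"] == len(partners[u] & partners[v]) >= 1


class TestSummary:
    def test_one_pdz_three_ligands(self):
        s = network_summary(_net([("P1", "L1"), ("P1", "L2"), ("P1", "L3")]))
        assert s["mean_pdz_degree"] == 3.0
        assert s["mean_ligand_degree"] == 1.0
        assert s["largest_component_fraction"] == 1.0

    def test_empty_network_zeros(self):
        s = network_summary(PdzNetwork())
        assert s["n_interactions"] == 0 and s["mean_pdz_degree"] == 0.0

    def test_matches_recount(self):
        rng = np.random.default_rng(2)
        net, edges = _random_bipartite(rng, 6, 20, 0.25)
        s = network_summary(net)
        assert s["n_interactions"] == len(edges)
        assert s["mean_pdz_degree"] == pytest.approx(len(edges) / len({e[0] for e in edges}))


class TestParalogFraction:
    def test_no_paralogs_fraction_zero(self):
        net = _net([("P1", "L1"), ("P2", "L1"), ("P3", "L1")])
        frac, pairs = paralog_fraction(net, set(), "pdz")
        assert frac == 0.0 and len(pairs) == 3

    def test_all_paralogous_fraction_one(self):
        net = _net([("P1", "L1"), ("P2", "L1")])
        net.add_interaction("P3", "L2")
        net.add_interaction("P1", "L2")
        pairs = {("P1", "P2"), ("P1", "P3")}
        frac, _ = paralog_fraction(net, pairs, "pdz")
        assert frac == 1.0

    def test_enumeration_oracle(self):
        # 4 PDZ proteins around 2 shared ligands -> 6 sharing pairs, 2 paralogous
        net = _net(
            [("P1", "L1"), ("P2", "L1"), ("P3", "L1"), ("P3", "L2"), ("P4", "L2"),
             ("P1", "L2"), ("P2", "L2"), ("P4", "L1")]
        )
        frac, pairs = paralog_fraction(net, {("P1", "P2"), ("P3", "P4")}, "pdz")
        assert len(pairs) == 6
        assert frac == pytest.approx(2 / 6)

    def test_undefined_with_single_sharing_pair(self):
        net = _net([("P1", "L1"), ("P2", "L1")])
        with pytest.raises(NetworkError):
            paralog_fraction(net, set(), "pdz")

    def test_world_asymmetry_and_wilcoxon(self, world):
        """The planted PDZ-side > ligand-side paralog asymmetry is detected."""
        res = compare_paralog_fractions(world.network, world.paralog_pairs)
        assert res["fraction_pdz"] > res["fraction_ligand"]
        assert res["p_value"] < 0.05


class TestRobustness:
    @pytest.mark.parametrize("unit", ["nodes", "edges"])
    def test_deletion_preserves_planted_ordering(self, world, unit):
        """20% random deletion keeps PDZ-side paralog fraction above ligand-side."""
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            sub = random_subnetwork(world.network, 0.2, unit, rng)
            f_pdz, _ = paralog_fraction(sub, world.paralog_pairs, "pdz")
            f_lig, _ = paralog_fraction(sub, world.paralog_pairs, "ligand")
            assert f_pdz > f_lig


def test_build_pdznet_round_trip():
    cands = [
        {"pdz": "P1", "ligand": "L1", "motif": "ETDV", "evidence": frozenset({"x"})},
        {"pdz": "P1", "ligand": "L1", "motif": "ETDV", "evidence": frozenset({"y"})},
    ]
    net = build_pdznet(cands, scores={("P1", "L1"): 3.2})
    assert net.graph.number_of_edges() == 1
    assert net.graph.edges["P1", "L1"]["evidence"] == {"x", "y"}
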