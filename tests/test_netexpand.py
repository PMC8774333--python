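"""Min/max expansion vs its exhaustive oracle, and enrichment statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from striatnet import netexpand as ne
from striatnet.covariation import CorrelationEdge, CovariationNetwork
from striatnet.iofmt import AnnotationMap, EvidenceNetwork, GeneSet


def _evidence(edges):
    net = EvidenceNetwork()
    for e in edges:
        a, b = e[:2]
        s = e[2] if len(e) > 2 else 0.9
        net.add_edge(a, b, s)
    return net


def _cov(pairs, tau=0.8, p=1e-5):
    edges = [CorrelationEdge(min(a, b), max(a, b), tau, p, 18) for a, b in pairs]
    return CovariationNetwork(edges=edges, r_min=0.6, p_max=1e-3)


def _params(**kw):
    kw.setdefault("family_inclusion", False)
    return ne.ExpansionParams(**kw)


class TestExpansionExamples:
    def test_supported_bridge_is_included(self):
        ev = _evidence([("Sa", "Xx"), ("Xx", "Sb")])
        cov = _cov([("Sa", "Xx")])
        nb = ne.expand_neighborhood_minmax(GeneSet(name="s", genes=["Sa", "Sb"]), ev, cov, _params())
        assert set(nb.nodes) == {"Sa", "Sb", "Xx"}
        assert nb.seeds_covered == 2
        assert nb.nodes["Xx"] == "covariation-supported"
        oracle = ne.brute_force_expansion(GeneSet(name="s", genes=["Sa", "Sb"]), ev, cov, _params())
        assert oracle.node_set() == nb.node_set()

    def test_directly_linked_seeds_stay_minimal(self):
        ev = _evidence([("Sa", "Sb"), ("Sa", "Xx"), ("Xx", "Sb")])
        cov = _cov([("Sa", "Xx")])
        nb = ne.expand_neighborhood_minmax(GeneSet(name="s", genes=["Sa", "Sb"]), ev, cov, _params())
        assert set(nb.nodes) == {"Sa", "Sb"}

    def test_isolated_seed_reported_uncovered(self):
        ev = _evidence([("Sa", "Xx"), ("Xx", "Sb"), ("Qq", "Rr")])
        cov = _cov([("Sa", "Xx")])
        nb = ne.expand_neighborhood_minmax(
            GeneSet(name="s", genes=["Sa", "Sb", "Sc"]), ev, cov, _params()
        )
        assert nb.seeds_covered == 2
        assert nb.uncovered_seeds == ["Sc"]
        assert nb.connected

    def test_single_seed_returns_itself(self):
        ev = _evidence([("Sa", "Xx")])
        nb = ne.brute_force_expansion(GeneSet(name="s", genes=["Sa"]), ev, None, _params())
        assert set(nb.nodes) == {"Sa"}

    def test_complete_graph_all_supported_gives_seeds_only(self):
        nodes = ["Sa", "Sb", "Sc", "Xa", "Xb"]
        ev = _evidence([(a, b) for a, b in itertools.combinations(nodes, 2)])
        cov = _cov([("Sa", "Xa"), ("Sa", "Xb")])
        nb = ne.brute_force_expansion(GeneSet(name="s", genes=["Sa", "Sb", "Sc"]), ev, cov, _params())
        assert set(nb.nodes) == {"Sa", "Sb", "Sc"}

    def test_no_seed_in_evidence_is_error(self):
        ev = _evidence([("Aa", "Bb")])
        with pytest.raises(ValueError, match="seed"):
            ne.expand_neighborhood_minmax(GeneSet(name="s", genes=["Zz"]), ev, None, _params())

    def test_empty_cov_no_family_degrades_to_seed_component(self):
        ev = _evidence([("Sa", "Sb"), ("Sb", "Xx"), ("Xx", "Sc")])
        cov = CovariationNetwork(edges=[], r_min=0.6, p_max=1e-3)
        nb = ne.expand_neighborhood_minmax(
            GeneSet(name="s", genes=["Sa", "Sb", "Sc"]), ev, cov, _params()
        )
        assert set(nb.nodes) == {"Sa", "Sb"}
        assert nb.uncovered_seeds == ["Sc"]

    def test_family_mate_can_serve_as_connector(self):
        # Sfa2 shares the 3-prefix family with seed Sfa1; with family
        # inclusion on, it becomes admissible and bridges the two seeds
        ev = _evidence([("Sfa1", "Sfa2"), ("Sfa2", "Tfb1")])
        cov = CovariationNetwork(edges=[], r_min=0.6, p_max=1e-3)
        seeds = GeneSet(name="s", genes=["Sfa1", "Tfb1"])
        with_family = ne.expand_neighborhood_minmax(
            seeds, ev, cov, ne.ExpansionParams(family_inclusion=True, max_path_len=1)
        )
        assert with_family.nodes.get("Sfa2") == "family-included"
        assert with_family.seeds_covered == 2


def _random_instance(rng, n_nodes):
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    edges = []
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < 0.30:
            edges.append((a, b, float(rng.uniform(0.4, 1.0))))
    ev = EvidenceNetwork()
    for a, b, s in edges:
        ev.add_edge(a, b, s)
    if ev.n_edges == 0:
        ev.add_edge(nodes[0], nodes[1], 0.9)
    present = ev.nodes()
    k = int(rng.integers(2, min(5, len(present)) + 1))
    seeds = list(rng.choice(present, size=k, replace=False))
    non_seeds = [n for n in present if n not in seeds]
    supported = [n for n in non_seeds if rng.random() < 0.5]
    cov = _cov([(s, n) for n in supported for s in seeds[:1]])
    return GeneSet(name="s", genes=sorted(seeds)), ev, cov


class TestHeuristicVsOracle:
    def test_heuristic_matches_oracle_on_random_instances(self):
        """(coverage, size) of the heuristic vs exhaustive enumeration."""
        rng = np.random.default_rng(123)
        n_match = n_total = 0
        for _ in range(60):
            seeds, ev, cov = _random_instance(rng, int(rng.integers(6, 12)))
            params = _params(max_path_len=int(rng.integers(1, 4)),
                             exact_solver_node_limit=0)
            try:
                heur = ne.expand_neighborhood_minmax(seeds, ev, cov, params)
                oracle = ne.brute_force_expansion(seeds, ev, cov, params)
            except ValueError:
                continue
            n_total += 1
            assert heur.seeds_covered >= oracle.seeds_covered
            n_match += (heur.seeds_covered, heur.total_nodes) == (
                oracle.seeds_covered, oracle.total_nodes,
            )
        assert n_total >= 40
        assert n_match / n_total >= 0.95

    def test_exact_path_always_equals_oracle(self):
        rng = np.random.default_rng(321)
        for _ in range(40):
            seeds, ev, cov = _random_instance(rng, int(rng.integers(5, 10)))
            params = _params(exact_solver_node_limit=14)
            try:
                exact = ne.expand_neighborhood_minmax(seeds, ev, cov, params)
                oracle = ne.brute_force_expansion(seeds, ev, cov, params)
            except ValueError:
                continue
            if len(exact.node_set() | oracle.node_set()) <= 14:
                assert exact.node_set() == oracle.node_set()

    def test_relaxing_r_min_never_decreases_coverage(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            seeds, ev, _ = _random_instance(rng, 9)
            non_seeds = [n for n in ev.nodes() if n not in set(seeds.genes)]
            taus = {n: float(rng.uniform(0.3, 0.95)) for n in non_seeds}
            cov = CovariationNetwork(
                edges=[CorrelationEdge(min(s, n), max(s, n), taus[n], 1e-5, 18)
                       for n in non_seeds for s in seeds.genes[:1]],
                r_min=0.0, p_max=1e-3,
            )
            covered = []
            for r_min in (0.9, 0.6, 0.3):
                params = _params(r_min=r_min, max_path_len=2)
                nb = ne.expand_neighborhood_minmax(seeds, ev, cov, params)
                covered.append(nb.seeds_covered)
            assert covered == sorted(covered)

    def test_too_large_instance_rejected_by_oracle(self):
        nodes = [f"N{i:02d}" for i in range(25)]
        ev = _evidence([(nodes[i], nodes[i + 1]) for i in range(24)])
        cov = _cov([(nodes[0], n) for n in nodes[1:-1]])
        with pytest.raises(ValueError, match="brute force"):
            ne.brute_force_expansion(
                GeneSet(name="s", genes=[nodes[0], nodes[-1]]), ev, cov,
                _params(max_path_len=30),
            )


class TestEvidenceKNeighborhood:
    def test_k_zero_is_just_the_seed(self):
        ev = _evidence([("Hub1", "Aa", 0.8)])
        assert ne.evidence_k_neighborhood("Hub1", ev, 0).genes == ["Hub1"]

    def test_top_k_by_score_with_name_ties(self):
        ev = EvidenceNetwork()
        for i in range(10):
            ev.add_edge("Hub1", f"Nn{i}", 0.5 + 0.05 * i)
        gs = ne.evidence_k_neighborhood("Hub1", ev, 7)
        assert gs.genes == ["Hub1"] + [f"Nn{i}" for i in range(9, 2, -1)]

    def test_absent_seed_is_error(self):
        ev = _evidence([("Aa", "Bb")])
        with pytest.raises(KeyError):
            ne.evidence_k_neighborhood("Zz", ev, 3)

    def test_planted_hub_recovers_circadian_module(self, study_fixture):
        gs = ne.evidence_k_neighborhood("Cir1", study_fixture.evidence, 7)
        assert sorted(gs.genes) == [f"Cir{i}" for i in range(1, 9)]


class TestPPIEnrichment:
    def test_seven_observed_vs_one_expected(self):
        """P(Poisson(1) >= 7) ~ 8.3e-5 under the density null."""
        rng = np.random.default_rng(9)
        ev = EvidenceNetwork()
        # background sized so that a 13-gene set expects ~1 internal edge
        nodes = [f"Bg{i:03d}" for i in range(120)]
        target = 0.0128  # density
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < target:
                ev.add_edge(a, b, 0.9)
        genes = GeneSet(name="g", genes=nodes[:13])
        obs, exp, p = ne.ppi_enrichment(genes, ev)
        manual = stats.poisson.sf(obs - 1, exp)
        assert p == pytest.approx(float(manual), rel=1e-12)
        ref = stats.poisson.sf(6, 1.0)
        assert ref == pytest.approx(8.3e-5, rel=0.01)

    def test_empty_intersection_gives_p_one(self):
        ev = _evidence([("Aa", "Bb")])
        obs, exp, p = ne.ppi_enrichment(GeneSet(name="g", genes=["Xx", "Yy"]), ev)
        assert obs == 0
        assert p == 1.0

    def test_whole_background_is_consistent(self):
        ev = _evidence([("Aa", "Bb"), ("Bb", "Cc"), ("Cc", "Aa"), ("Aa", "Dd")])
        obs, exp, p = ne.ppi_enrichment(GeneSet(name="g", genes=ev.nodes()), ev)
        assert obs == ev.n_edges
        assert exp == pytest.approx(ev.n_edges)
        assert 0.3 < p < 0.7


class TestTermEnrichment:
    def test_hand_computed_hypergeometric(self):
        """(N=20, K=5, n=5, k=3) -> 1126/15504 by direct combinatorial sum."""
        bg = GeneSet(name="bg", genes=[f"Gg{i:02d}" for i in range(20)])
        term_genes = bg.genes[:5]
        query = GeneSet(name="q", genes=bg.genes[:3] + bg.genes[10:12])
        am = AnnotationMap(terms={"T1": ("term one", list(term_genes))})
        (row,) = ne.term_enrichment(query, am, bg)
        expected = (
            math.comb(5, 3) * math.comb(15, 2)
            + math.comb(5, 4) * math.comb(15, 1)
            + math.comb(5, 5)
        ) / math.comb(20, 5)
        assert row.k == 3 and row.K == 5
        assert row.p_value == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1126 / 15504, rel=1e-12)

    def test_exact_term_match_probability(self):
        bg = GeneSet(name="bg", genes=[f"Gg{i:04d}" for i in range(1000)])
        query = GeneSet(name="q", genes=bg.genes[:4])
        am = AnnotationMap(terms={"T1": ("exact", list(query.genes))})
        (row,) = ne.term_enrichment(query, am, bg)
        assert row.p_value == pytest.approx(1 / math.comb(1000, 4), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        bg = GeneSet(name="bg", genes=[f"Gg{i:02d}" for i in range(30)])
        am = AnnotationMap(terms={"T1": ("t", bg.genes[20:25])})
        query = GeneSet(name="q", genes=bg.genes[:5])
        (row,) = ne.term_enrichment(query, am, bg)
        assert row.k == 0
        assert row.p_value == pytest.approx(1.0)

    def test_matches_brute_force_mass_function_on_small_cases(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            N = int(rng.integers(8, 30))
            bg = GeneSet(name="bg", genes=[f"Gg{i:02d}" for i in range(N)])
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            term = list(rng.choice(bg.genes, size=K, replace=False))
            query = list(rng.choice(bg.genes, size=n, replace=False))
            am = AnnotationMap(terms={"T1": ("t", term)})
            (row,) = ne.term_enrichment(GeneSet(name="q", genes=query), am, bg)
            k = row.k
            brute = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
                if n - j <= N - K
            ) / math.comb(N, n)
            assert row.p_value == pytest.approx(brute, rel=1e-10)

    def test_background_smaller_than_query_is_error(self):
        bg = GeneSet(name="bg", genes=["Aa", "Bb"])
        q = GeneSet(name="q", genes=["Aa", "Bb", "Cc"])
        am = AnnotationMap(terms={"T1": ("t", ["Aa"])})
        with pytest.raises(ValueError, match="background"):
            ne.term_enrichment(q, am, bg)
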