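"""Similarity graph and Markov clustering: hit generation, OrthoMCL edge
classification and normalization, MCL behaviour, selection, query mapping."""

import math
import random

import numpy as np
import pytest

from cladespec import similarity_clustering as sc
from cladespec import synthetic_data as sd
from cladespec.orf_extraction import SequenceRecord


def rand_seq(rng, n):
    return "".join(sd.AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


def mutate(rng, seq, n):
    out = list(seq)
    for pos in rng.choice(len(out), size=n, replace=False):
        out[pos] = sd.AMINO_ACIDS[(sd.AMINO_ACIDS.index(out[pos]) + int(rng.integers(1, 20))) % 20]
    return "".join(out)


class TestAllVsAll:
    def test_identical_pair_reciprocal_full_match(self):
        rng = np.random.default_rng(0)
        seq = rand_seq(rng, 100)
        recs = [SequenceRecord("1|ncbi|a", seq), SequenceRecord("2|ncbi|b", seq)]
        hits = sc.all_vs_all_similarity(recs, e_cutoff=10.0)
        assert {(h.query, h.subject) for h in hits} == {
            ("1|ncbi|a", "2|ncbi|b"), ("2|ncbi|b", "1|ncbi|a")}
        assert all(h.percent_match == 1.0 for h in hits)

    def test_unrelated_random_pairs_mostly_hitless(self):
        rng = np.random.default_rng(1)
        hitless = 0
        for _ in range(100):
            recs = [SequenceRecord("1|ncbi|a", rand_seq(rng, 60)),
                    SequenceRecord("2|ncbi|b", rand_seq(rng, 60))]
            hits = sc.all_vs_all_similarity(recs, e_cutoff=1e-5, min_shared_kmers=0)
            hitless += not hits
        assert hitless >= 95

    def test_e_value_formula(self):
        cfg = sc.AlignerConfig(db_size=50000)
        assert cfg.e_value(100, 200, 50000) == pytest.approx(
            0.041 * 200 * 50000 * math.exp(-0.267 * 100))

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            sc.all_vs_all_similarity([SequenceRecord("1|ncbi|a", "ACDEF")])

    def test_prescreen_matches_exhaustive_on_family_fixture(self):
        rng = np.random.default_rng(2)
        recs = []
        for fam in range(4):
            base = rand_seq(rng, 90)
            for k in range(4):
                recs.append(SequenceRecord(f"{1000+k}|ncbi|f{fam}", mutate(rng, base, 8)))
        fast = sc.all_vs_all_similarity(recs, e_cutoff=1e-5)
        full = sc.all_vs_all_similarity(recs, e_cutoff=1e-5, min_shared_kmers=0)
        assert fast == full


class TestOrthomclGraph:
    def _toy_hits(self):
        """Three-species, five-gene instance with hand-derivable classes.

        a1,a2: close in-paralogs in species 1; b1 in species 2 orthologous to
        a1; c1,c2: in-paralogs in species 3, unrelated to the others.
        """
        rng = np.random.default_rng(3)
        base = rand_seq(rng, 80)
        other = rand_seq(rng, 80)
        recs = [
            SequenceRecord("1|ncbi|a1", base),
            SequenceRecord("1|ncbi|a2", mutate(rng, base, 2)),
            SequenceRecord("2|ncbi|b1", mutate(rng, base, 8)),
            SequenceRecord("3|ncbi|c1", other),
            SequenceRecord("3|ncbi|c2", mutate(rng, other, 3)),
        ]
        return sc.all_vs_all_similarity(recs, e_cutoff=1e-5, min_shared_kmers=0)

    def test_toy_edge_classes_match_hand_derivation(self):
        edges = {(e.a, e.b): e.edge_class for e in sc.build_orthomcl_graph(self._toy_hits())}
        # reciprocal best hits across species 1-2 -> ortholog a1-b1 (a1 is
        # nearer to b1 than a2 by construction)
        assert edges[("1|ncbi|a1", "2|ncbi|b1")] == "ortholog"
        # mutual same-species pairs closer than any cross-species hit
        assert edges[("1|ncbi|a1", "1|ncbi|a2")] == "inparalog"
        assert edges[("3|ncbi|c1", "3|ncbi|c2")] == "inparalog"
        # a2 reaches b1 through the a1 duplication -> co-ortholog
        assert edges[("1|ncbi|a2", "2|ncbi|b1")] == "coortholog"
        assert len(edges) == 4

    def test_single_ortholog_edge_self_normalizes_to_one(self):
        rng = np.random.default_rng(4)
        seq = rand_seq(rng, 100)
        recs = [SequenceRecord("1|ncbi|a", seq), SequenceRecord("2|ncbi|b", mutate(rng, seq, 5))]
        edges = sc.build_orthomcl_graph(sc.all_vs_all_similarity(recs, e_cutoff=1e-5))
        assert len(edges) == 1
        assert edges[0].edge_class == "ortholog"
        assert edges[0].weight == pytest.approx(1.0)

    def test_same_species_pair_without_cross_hits_is_inparalog(self):
        rng = np.random.default_rng(5)
        seq = rand_seq(rng, 100)
        recs = [SequenceRecord("1|ncbi|a", seq), SequenceRecord("1|ncbi|b", mutate(rng, seq, 3))]
        edges = sc.build_orthomcl_graph(sc.all_vs_all_similarity(recs, e_cutoff=1e-5))
        assert [e.edge_class for e in edges] == ["inparalog"]

    def test_hit_order_invariance(self):
        hits = self._toy_hits()
        shuffled = list(hits)
        random.Random(0).shuffle(shuffled)
        assert sc.build_orthomcl_graph(hits) == sc.build_orthomcl_graph(shuffled)


def naive_mcl(nodes, weight, inflation, expansion=2, prune=1e-5, tol=1e-6, iters=200):
    """Independent dense-matrix oracle following the textbook iteration."""
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in weight.items():
        i, j = nodes.index(a), nodes.index(b)
        M[i, j] = M[j, i] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    for i in range(n):
        M[i, i] = loop[i]
    M = M / M.sum(axis=0)
    for _ in range(iters):
        prev = M.copy()
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M[M < prune] = 0.0
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        M = M / s
        if np.abs(M - prev).max() < tol:
            break
    clusters = []
    for i in range(n):
        if M[i, i] > prune:
            members = {nodes[j] for j in np.nonzero(M[i] > prune)[0]}
            for c in clusters:
                if c & members:
                    c |= members
                    break
            else:
                clusters.append(members)
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    assigned = set().union(*clusters) if clusters else set()
    clusters.extend({nodes[i]} for i in range(n) if nodes[i] not in assigned)
    return {frozenset(c) for c in clusters}


def edges_from_weights(weight):
    return [sc.WeightedEdge(a, b, "ortholog", w) for (a, b), w in weight.items()]


class TestMcl:
    def test_two_disjoint_cliques(self):
        weight = {}
        for base in ("a", "b"):
            for i in range(4):
                for j in range(i + 1, 4):
                    weight[(f"{base}{i}", f"{base}{j}")] = 1.0
        groups = sc.mcl_cluster(edges_from_weights(weight))
        assert sorted(len(g.members) for g in groups) == [4, 4]

    def test_barbell_splits(self):
        weight = {}
        for base in ("a", "b"):
            for i in range(6):
                for j in range(i + 1, 6):
                    weight[(f"{base}{i}", f"{base}{j}")] = 1.0
        weight[("a0", "b0")] = 0.1
        groups = sc.mcl_cluster(edges_from_weights(weight), sc.MclConfig(inflation=1.5))
        assert sorted(len(g.members) for g in groups) == [6, 6]

    def test_matches_dense_oracle_on_seeded_graphs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 20))
            nodes = [f"n{i}" for i in range(n)]
            weight = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        weight[(nodes[i], nodes[j])] = float(rng.uniform(0.1, 2.0))
            if not weight:
                continue
            got = sc.mcl_cluster(edges_from_weights(weight), keep_singletons=True)
            expect = naive_mcl(sorted({x for p in weight for x in p}), weight, 1.5)
            assert {frozenset(g.members) for g in got} == expect

    def test_cluster_count_nondecreasing_in_inflation(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 14
            nodes = [f"n{i}" for i in range(n)]
            weight = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        weight[(nodes[i], nodes[j])] = float(rng.uniform(0.2, 1.5))
            if not weight:
                continue
            counts = [
                len(sc.mcl_cluster(edges_from_weights(weight),
                                   sc.MclConfig(inflation=i), keep_singletons=True))
                for i in (1.2, 1.5, 2.0, 4.0, 6.0)
            ]
            assert counts == sorted(counts)

    def test_clusters_never_span_components(self):
        weight = {("a0", "a1"): 1.0, ("a1", "a2"): 1.0, ("b0", "b1"): 1.0}
        groups = sc.mcl_cluster(edges_from_weights(weight), keep_singletons=True)
        comp_a = {"a0", "a1", "a2"}
        for g in groups:
            assert set(g.members) <= comp_a or set(g.members) <= {"b0", "b1"}
        # clusters partition the node set
        all_members = sorted(m for g in groups for m in g.members)
        assert all_members == sorted(set(all_members))

    def test_subfamily_fixture_splits_at_high_inflation(self):
        # two dense subfamilies bridged moderately: one cluster at I=1.5,
        # two at I=4.0 (oracle-confirmed refinement)
        weight = {}
        for base in ("a", "b"):
            for i in range(5):
                for j in range(i + 1, 5):
                    weight[(f"{base}{i}", f"{base}{j}")] = 1.0
        for i in range(5):
            weight[(f"a{i}", f"b{i}")] = 0.7
        low = sc.mcl_cluster(edges_from_weights(weight), sc.MclConfig(inflation=1.5))
        high = sc.mcl_cluster(edges_from_weights(weight), sc.MclConfig(inflation=4.0))
        assert len(low) == 1
        assert sorted(len(g.members) for g in high) == [5, 5]
        nodes = sorted({x for p in weight for x in p})
        assert {frozenset(g.members) for g in high} == naive_mcl(nodes, weight, 4.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            sc.mcl_cluster([])

    def test_og_ids_ordered_by_size_then_member(self):
        weight = {("a0", "a1"): 1.0, ("b0", "b1"): 1.0, ("b1", "b2"): 1.0, ("b0", "b2"): 1.0}
        groups = sc.mcl_cluster(edges_from_weights(weight))
        assert groups[0].og_id == "OG_1" and len(groups[0].members) == 3
        assert groups[1].og_id == "OG_2"


class TestSelection:
    def _group(self, og_id, taxa):
        return sc.Orthogroup(og_id, frozenset(f"{t}|ncbi|x{i}" for i, t in enumerate(taxa)))

    def test_species_threshold(self):
        g10 = self._group("OG_1", range(10))
        g9 = self._group("OG_2", list(range(9)) + [8])  # 9 species, 10 members
        assert sc.select_orthogroups([g10, g9], min_species=10) == [g10]

    def test_min_species_one_is_identity(self):
        gs = [self._group(f"OG_{i}", range(i + 2)) for i in range(5)]
        assert sc.select_orthogroups(gs, min_species=1) == gs

    def test_simulated_counts_match_ground_truth(self, small_simulation):
        _, truth = small_simulation
        groups = [
            sc.Orthogroup(f"OG_{i}", frozenset(t.members))
            for i, t in enumerate(truth.families.values())
        ]
        kept = sc.select_orthogroups(groups, min_species=10)
        expected = sum(1 for t in truth.families.values()
                       if len(t.surviving_species) >= 10)
        assert len(kept) == expected


class TestMapExternalQueries:
    def _db(self):
        rng = np.random.default_rng(9)
        seq = rand_seq(rng, 150)
        records = [SequenceRecord(f"{1000+i}|ncbi|m{i}", mutate(rng, seq, 3))
                   for i in range(80)]
        big = sc.Orthogroup("OG_1", frozenset(r.id for r in records))
        small_seq = rand_seq(rng, 150)
        small_recs = [SequenceRecord(f"{2000+i}|ncbi|s{i}", mutate(rng, small_seq, 3))
                      for i in range(10)]
        small = sc.Orthogroup("OG_2", frozenset(r.id for r in small_recs))
        return records + small_recs, [big, small], records[0], small_recs[0]

    def test_identity_and_size_rules(self):
        db, groups, member_big, member_small = self._db()
        q_ok = SequenceRecord("9606|ncbi|q1", member_big.residues)
        q_small_group = SequenceRecord("9606|ncbi|q2", member_small.residues)
        q_short = SequenceRecord("9606|ncbi|q3", member_big.residues[:90])
        mapping, unmapped = sc.map_external_queries(
            [q_ok, q_small_group, q_short], db, groups, min_species=75)
        assert mapping == {"9606|ncbi|q1": "OG_1"}
        assert set(unmapped) == {"9606|ncbi|q2", "9606|ncbi|q3"}


class TestGroupsFile:
    def test_roundtrip(self, tmp_path):
        groups = [sc.Orthogroup("OG_1", frozenset({"1|ncbi|a", "2|orf|b"})),
                  sc.Orthogroup("OG_2", frozenset({"3|tx|c", "4|ncbi|d"}))]
        path = tmp_path / "groups.txt"
        sc.write_groups_file(groups, path)
        text = path.read_text()
        assert "OG_1: 1|ncbi|a 2|orf|b" in text
        assert sc.read_groups_file(path) == groups
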