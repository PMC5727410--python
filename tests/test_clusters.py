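"""Pairwise identity, greedy clustering, co-occurrence network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rhskit.clusters import (
    GAP_SCORE,
    MATCH_SCORE,
    MISMATCH_SCORE,
    build_network,
    greedy_cluster,
    pairwise_identity,
    sharing_stats,
)

NT = "ACGT"


def nw_oracle(a, b):
    """Full DP oracle, no banding: end-gap-free global alignment maximising
    (score, identities) lexicographically; returns (score, identities).

    Semi-global convention: first row/column zero (free leading gaps), all
    internal moves penalised, answer = max over the last row and column
    (free trailing gaps)."""
    n, m = len(a), len(b)
    H = [[(0.0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sdiag, iddiag = H[i - 1][j - 1]
            match = a[i - 1] == b[j - 1]
            diag = (sdiag + (MATCH_SCORE if match else MISMATCH_SCORE),
                    iddiag + int(match))
            up = (H[i - 1][j][0] + GAP_SCORE, H[i - 1][j][1])
            left = (H[i][j - 1][0] + GAP_SCORE, H[i][j - 1][1])
            H[i][j] = max(diag, up, left)
    return max(max(H[i][m] for i in range(n + 1)),
               max(H[n][j] for j in range(m + 1)))


def rand_nt(rng, n):
    return "".join(NT[i] for i in rng.integers(0, 4, n))


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 1.0

    def test_one_mismatch(self):
        assert pairwise_identity("ACGTACGTAC", "ACGAACGTAC") == pytest.approx(0.9)

    def test_nested_duplicate(self):
        assert pairwise_identity("ACGTACGT", "TTACGTACGTTT") == 1.0

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a, b = rand_nt(rng, 60), rand_nt(rng, 80)
            x = pairwise_identity(a, b)
            assert x == pytest.approx(pairwise_identity(b, a))
            assert 0.0 <= x <= 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_full_dp_oracle(self, rng):
        """Identity equals a full (unbanded) DP oracle on random pairs."""
        for _ in range(60):
            la, lb = rng.integers(20, 70, 2)
            a, b = rand_nt(rng, la), rand_nt(rng, lb)
            if rng.random() < 0.5:  # include related pairs
                b = list(a)
                for p in rng.integers(0, len(a), 4):
                    b[p] = NT[rng.integers(0, 4)]
                b = "".join(b)
            osc, oid = nw_oracle(a, b)
            got = pairwise_identity(a, b)
            assert got == pytest.approx(oid / min(len(a), len(b)), abs=1e-12)


class TestGreedyCluster:
    def test_basic_partition(self, rng):
        a = rand_nt(rng, 100)
        a_copy = a
        b = rand_nt(rng, 100)
        cls = greedy_cluster({"A": a, "Acopy": a_copy, "B": b})
        assert sorted(sorted(c.member_ids) for c in cls) == [
            ["A", "Acopy"], ["B"]]

    def test_boundary_identity_joins(self):
        # exactly at threshold: >= rule, the pair joins
        a = "ACGTACGTAC"
        b = "ACGAACGTAC"  # identity 0.9
        cls = greedy_cluster({"a": a, "b": b}, threshold=0.90)
        assert len(cls) == 1

    def test_partition_properties(self, rng):
        seqs = {}
        for i in range(8):
            base = rand_nt(rng, 90)
            seqs[f"p{i}"] = base
            mut = list(base)
            for p in rng.integers(0, 90, 3):
                mut[p] = NT[rng.integers(0, 4)]
            seqs[f"p{i}m"] = "".join(mut)
        cls = greedy_cluster(seqs, threshold=0.9)
        members = [m for c in cls for m in c.member_ids]
        assert sorted(members) == sorted(seqs)  # exact partition
        for c in cls:
            rep = seqs[c.representative_id]
            for m in c.member_ids:
                assert pairwise_identity(seqs[m], rep) >= 0.9

    @given(st.randoms(use_true_random=False))
    def test_input_order_invariance(self, pyrandom):
        rng = np.random.default_rng(77)
        seqs = {f"s{i}": rand_nt(rng, 60) for i in range(10)}
        items = list(seqs.items())
        pyrandom.shuffle(items)
        ref = [sorted(c.member_ids) for c in greedy_cluster(seqs)]
        got = [sorted(c.member_ids) for c in greedy_cluster(dict(items))]
        assert sorted(ref) == sorted(got)

    def test_threshold_one_exact_duplicates(self, rng):
        a, b = rand_nt(rng, 50), rand_nt(rng, 50)
        seqs = {"a1": a, "a2": a, "b1": b}
        cls = greedy_cluster(seqs, threshold=1.0)
        groups = sorted(sorted(c.member_ids) for c in cls)
        assert groups == [["a1", "a2"], ["b1"]]

    def test_recovers_planted_partition(self, small_sim):
        from sklearn.metrics import adjusted_rand_score

        from rhskit.domains import extract_cterm
        from rhskit.genes import call_rhs_genes

        _, strains, truth = small_sim
        tt = truth.genes[truth.genes.kind == "rhs_toxin"]
        proto_by_key = {(r.strain_id, int(r.start)): int(r.prototype)
                        for r in tt.itertuples()}
        doms, labels = [], {}
        for s in strains:
            for g in call_rhs_genes(s):
                d, _ = extract_cterm(g)
                if d is not None:
                    doms.append(d)
                    labels[d.domain_id] = proto_by_key[(s.strain_id, g.orf.start)]
        cls = greedy_cluster(doms, threshold=0.9)
        got = {m: c.cluster_id for c in cls for m in c.member_ids}
        ids = sorted(labels)
        ari = adjusted_rand_score([labels[i] for i in ids],
                                  [got[i] for i in ids])
        assert ari == 1.0


class TestNetwork:
    def _clusters(self):
        from rhskit.clusters import ToxinCluster

        return [
            ToxinCluster("C1", "d1", ["d1", "d2"]),
            ToxinCluster("C2", "d3", ["d3"]),
        ]

    def test_shared_cluster_edges(self):
        strain_of = {"d1": "s1", "d2": "s2", "d3": "s1"}
        g = build_network(self._clusters(), strain_of)
        assert g.has_edge("s1", "C1") and g.has_edge("s2", "C1")
        assert g.has_edge("s1", "C2")
        assert g["s1"]["C1"]["weight"] == 1

    def test_unknown_strain_raises(self):
        with pytest.raises(KeyError):
            build_network(self._clusters(), {"d1": "s1"})

    def test_sharing_stats_species_regions(self):
        strain_of = {"d1": "s1", "d2": "s2", "d3": "s1"}
        table = pd.DataFrame([
            dict(strain_id="s1", species="A", host="h", region="NA"),
            dict(strain_id="s2", species="B", host="h", region="SEA"),
        ])
        g = build_network(self._clusters(), strain_of, table)
        per_cluster, summary = sharing_stats(g)
        row = per_cluster.set_index("cluster_id").loc["C1"]
        assert row.n_species == 2 and row.shared_between_species
        assert summary["n_shared_between_species"] == 1
        assert summary["region_pair_sharing"] == {"NA|SEA": True}

    def test_single_species_no_between(self):
        strain_of = {"d1": "s1", "d2": "s2", "d3": "s1"}
        table = pd.DataFrame([
            dict(strain_id="s1", species="A", host="h", region="NA"),
            dict(strain_id="s2", species="A", host="h", region="NA"),
        ])
        _, summary = sharing_stats(build_network(self._clusters(), strain_of, table))
        assert summary["n_shared_between_species"] == 0
        assert summary["n_shared_within_species"] == 1

    def test_empty_network(self):
        import networkx as nx

        per_cluster, summary = sharing_stats(nx.Graph())
        assert len(per_cluster) == 0
        assert summary["n_clusters"] == 0

    def test_simulated_sharing_matches_truth(self, small_sim):
        from rhskit.domains import extract_cterm
        from rhskit.genes import call_rhs_genes

        _, strains, truth = small_sim
        doms = []
        for s in strains:
            for g in call_rhs_genes(s):
                d, _ = extract_cterm(g)
                if d is not None:
                    doms.append(d)
        cls = greedy_cluster(doms, threshold=0.9)
        g = build_network(cls, {d.domain_id: d.strain_id for d in doms})
        # every (strain, prototype) pair with an intact toxin in the truth
        # must appear as one strain-cluster edge; pseudogenes may or may not
        # retain an extractable domain
        tt = truth.genes[truth.genes.kind == "rhs_toxin"].copy()
        tt["pseudogene"] = tt.pseudogene.astype(bool)
        intact = tt[~tt.pseudogene & (tt.prototype >= 0)]
        n_expected = len({(r.strain_id, int(r.prototype))
                          for r in intact.itertuples()})
        n_graph_edges = g.number_of_edges()
        n_pseudo = int(tt.pseudogene.sum())
        assert n_expected <= n_graph_edges <= n_expected + n_pseudo
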