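"""Presence/absence screening: best hits, matrices, T6SS status,
toxin-immunity co-occurrence."""

import numpy as np
import pandas as pd
import pytest

from rhskit.screen import (
    best_hit,
    interlocus_mean_identity,
    local_alignment,
    presence_matrix,
    rhs_count_by_t6ss_group,
    t6ss_status,
    toxin_immunity_cooccurrence,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"

# BLOSUM62 with affine gaps (open -11, extend -1), mirroring the package
_OPEN, _EXT = -11.0, -1.0


def _blosum():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def sw_oracle(q, t):
    """Independent full Smith-Waterman DP (affine gaps, no banding);
    returns the optimal local score."""
    B = _blosum()
    n, m = len(q), len(t)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in q (move along t)
    F = np.full((n + 1, m + 1), NEG)  # gap in t
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + _OPEN, E[i][j - 1] + _EXT)
            F[i][j] = max(H[i - 1][j] + _OPEN, F[i - 1][j] + _EXT)
            s = B[q[i - 1], t[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def rand_aa(rng, n):
    return "".join(AAS[i] for i in rng.integers(0, 20, n))


class TestLocalAlignment:
    def test_identical(self):
        score, ident, cov = local_alignment("MKLVINSGHH", "MKLVINSGHH")
        assert ident == 1.0 and cov == 1.0

    def test_half_query_matches(self, rng):
        half = rand_aa(rng, 40)
        query = half + rand_aa(rng, 40)
        score, ident, cov = local_alignment(query, "EE" + half + "EE")
        assert ident == 1.0
        assert cov == pytest.approx(0.5, abs=0.05)

    def test_score_matches_sw_oracle(self, rng):
        """Optimal local score equals a full DP oracle on random and
        related pairs."""
        for k in range(30):
            q, t = rand_aa(rng, 45), rand_aa(rng, 55)
            if k % 2:
                t = q[5:40]  # related pair
            score, _, _ = local_alignment(q, t)
            assert score == pytest.approx(sw_oracle(q, t))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            local_alignment("", "MKL")


class TestBestHit:
    def test_exact_target(self, rng):
        prot = {f"p{i}": rand_aa(rng, 80) for i in range(5)}
        hit = best_hit(prot["p3"], prot)
        assert hit.target_id == "p3"
        assert hit.identity == 1.0 and hit.coverage == 1.0

    def test_no_hit_below_floors(self, rng):
        prot = {"a": rand_aa(rng, 80)}
        q = rand_aa(rng, 80)
        assert best_hit(q, prot, id_floor=0.9, cov_floor=0.9) is None

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            best_hit("", {"a": "MKL"})
        with pytest.raises(ValueError):
            best_hit("MKL", {})


class TestPresenceMatrix:
    def _world(self, rng):
        targets = {f"g{i}": rand_aa(rng, 100) for i in range(4)}
        genomes = {
            "G1": dict(targets),
            "G2": {k: v for k, v in targets.items() if k != "g0"},
        }
        return targets, genomes

    def test_presence_pattern(self, rng):
        queries, genomes = self._world(rng)
        pm = presence_matrix(queries, genomes)
        assert pm.is_present("g0", "G1")
        assert not pm.is_present("g0", "G2")
        assert all(pm.is_present(q, "G1") for q in queries)

    def test_score_is_identity_times_coverage(self, rng):
        queries, genomes = self._world(rng)
        pm = presence_matrix(queries, genomes)
        t = pm.table
        assert np.allclose(t.score, t.identity * t.coverage)
        assert ((t.identity >= 0) & (t.identity <= 1)).all()

    def test_per_query_override(self, rng):
        """tssH-style rule: a 60%-identity hit passes the default cutoff but
        fails its per-query 70% override."""
        base = rand_aa(rng, 100)
        mut = list(base)
        for p in rng.choice(100, 40, replace=False):
            mut[p] = AAS[(AAS.index(mut[p]) + 1) % 20]
        genomes = {"G": {"t": "".join(mut)}}
        queries = {"tssH": base}
        pm_default = presence_matrix(queries, genomes)
        ident = pm_default.table.identity.iloc[0]
        assert 0.5 < ident < 0.7
        assert pm_default.is_present("tssH", "G")
        pm_strict = presence_matrix(
            queries, genomes, per_query_thresholds={"tssH": (0.70, 0.50)})
        assert not pm_strict.is_present("tssH", "G")

    def test_monotone_in_thresholds(self, rng):
        queries, genomes = self._world(rng)
        loose = presence_matrix(queries, genomes, id_min=0.3, cov_min=0.3)
        tight = presence_matrix(queries, genomes, id_min=0.9, cov_min=0.9)
        assert tight.table.present.sum() <= loose.table.present.sum()


class TestT6ssStatus:
    def _pm(self, present_queries, all_queries, genome="G"):
        rows = [dict(query_id=q, genome_id=genome, target_id=None,
                     identity=1.0, coverage=1.0, score=1.0,
                     present=q in present_queries) for q in all_queries]
        from rhskit.screen import PresenceMatrix

        return PresenceMatrix(pd.DataFrame(rows))

    def test_all_core_present(self):
        core = [f"c{i}" for i in range(13)]
        assert t6ss_status(self._pm(set(core), core), core, "G") == "present"

    def test_none_present(self):
        core = [f"c{i}" for i in range(13)]
        assert t6ss_status(self._pm(set(), core), core, "G") == "absent"

    def test_partial(self):
        core = [f"c{i}" for i in range(13)]
        some = set(core[:5])
        assert t6ss_status(self._pm(some, core), core, "G") == "partial"

    def test_simulated_status_matches_truth(self, small_sim):
        from Bio.Seq import Seq

        from rhskit.genes import find_orfs

        _, strains, truth = small_sim
        proteomes = {}
        for s in strains:
            proteomes[s.strain_id] = {
                o.orf_id: o.aa_seq
                for cid, seq in sorted(s.contigs.items())
                for o in find_orfs(seq, contig_id=cid)}
        queries = {k: str(Seq("ATG" + v).translate(table=11))
                   for k, v in {**truth.t6ss1_genes, **truth.t6ss23_genes}.items()}
        pm = presence_matrix(queries, proteomes)
        for r in truth.strains.itertuples():
            s1 = t6ss_status(pm, sorted(truth.t6ss1_genes), r.strain_id)
            s23 = t6ss_status(pm, sorted(truth.t6ss23_genes), r.strain_id)
            assert (s1 == "present") == bool(r.t6ss1)
            assert (s23 == "present") == bool(r.t6ss23)


class TestCooccurrence:
    def test_simulated_pairs_no_violations(self, small_sim):
        """Immunity is present wherever the toxin is; the reverse pattern
        (toxin without immunity) never occurs."""
        from Bio.Seq import Seq

        from rhskit.genes import find_orfs

        _, strains, truth = small_sim
        proteomes = {
            s.strain_id: {o.orf_id: o.aa_seq
                          for cid, seq in sorted(s.contigs.items())
                          for o in find_orfs(seq, contig_id=cid)}
            for s in strains}
        queries, pairs = {}, []
        for i in range(len(truth.pool_toxins)):
            tq, iq = f"TOX{i + 1:03d}", f"IMMQ{i + 1:03d}"
            queries[tq] = str(Seq(truth.pool_toxins[i]).translate(table=11))
            queries[iq] = str(Seq(truth.pool_immunity[i]).translate(table=11))
            pairs.append((tq, iq))
        cooc = toxin_immunity_cooccurrence(pairs, queries, proteomes)
        assert int(cooc.violation.sum()) == 0
        # intact toxins are all found with their immunity
        tt = truth.genes[truth.genes.kind == "rhs_toxin"].copy()
        tt["pseudogene"] = tt.pseudogene.astype(bool)
        intact = tt[~tt.pseudogene & (tt.prototype >= 0)]
        cell = cooc.set_index(["toxin_query", "genome_id"])
        for r in intact.itertuples():
            row = cell.loc[(f"TOX{int(r.prototype) + 1:03d}", r.strain_id)]
            assert bool(row.toxin_present) and bool(row.immunity_present)

    def test_orphan_events_are_immunity_only(self, orphan_world):
        from Bio.Seq import Seq

        from rhskit.genes import find_orfs

        strains, truth = orphan_world
        proteomes = {
            s.strain_id: {o.orf_id: o.aa_seq
                          for cid, seq in sorted(s.contigs.items())
                          for o in find_orfs(seq, contig_id=cid)}
            for s in strains}
        queries, pairs = {}, []
        for i in range(len(truth.pool_toxins)):
            tq, iq = f"TOX{i + 1:03d}", f"IMMQ{i + 1:03d}"
            queries[tq] = str(Seq(truth.pool_toxins[i]).translate(table=11))
            queries[iq] = str(Seq(truth.pool_immunity[i]).translate(table=11))
            pairs.append((tq, iq))
        cooc = toxin_immunity_cooccurrence(pairs, queries, proteomes)
        assert int(cooc.violation.sum()) == 0
        imm = truth.genes[truth.genes.kind == "immunity"]
        orphans = imm[imm.orphan_immunity == True]  # noqa: E712
        assert len(orphans) > 0
        cell = cooc.set_index(["toxin_query", "genome_id"])
        for r in orphans.itertuples():
            row = cell.loc[(f"TOX{int(r.prototype) + 1:03d}", r.strain_id)]
            assert not bool(row.toxin_present)
            assert bool(row.immunity_present)


class TestInterlocusIdentity:
    def test_identical_loci(self, rng):
        locus = {f"g{i}": rand_aa(rng, 90) for i in range(4)}
        assert interlocus_mean_identity(locus, dict(locus)) == pytest.approx(1.0)

    def test_disjoint_random_loci(self, rng):
        a = {f"a{i}": rand_aa(rng, 90) for i in range(3)}
        b = {f"b{i}": rand_aa(rng, 90) for i in range(3)}
        assert interlocus_mean_identity(a, b, min_score=60.0) is None

    def test_half_identity_construction(self, rng):
        """Half of each query aligns perfectly: value = 1.0 identity x 0.5
        coverage per gene."""
        a, b = {}, {}
        for i in range(3):
            half = rand_aa(rng, 60)
            a[f"g{i}"] = half + rand_aa(rng, 60)
            b[f"g{i}"] = half
        val = interlocus_mean_identity(a, b)
        assert val == pytest.approx(0.5, abs=0.05)


class TestRhsCountGrouping:
    def test_group_labels_and_counts(self):
        gene_table = pd.DataFrame(
            dict(strain_id=["s1"] * 5 + ["s2"] * 2 + ["s3"] * 1))
        statuses = {
            "s1": {"T6SS-1": "present", "T6SS-2/3": "absent"},
            "s2": {"T6SS-1": "absent", "T6SS-2/3": "present"},
            "s3": {"T6SS-1": "present", "T6SS-2/3": "present"},
            "s4": {"T6SS-1": "absent", "T6SS-2/3": "absent"},
        }
        out = rhs_count_by_t6ss_group(gene_table, statuses).set_index("strain_id")
        assert out.loc["s1"].group == "T6SS-1 only" and out.loc["s1"].n_rhs == 5
        assert out.loc["s2"].group == "T6SS-2/3 only"
        assert out.loc["s3"].group == "both"
        assert out.loc["s4"].group == "neither" and out.loc["s4"].n_rhs == 0

    def test_empty_input(self):
        out = rhs_count_by_t6ss_group(pd.DataFrame(columns=["strain_id"]), {})
        assert len(out) == 0
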