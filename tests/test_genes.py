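"""ORF finding, Rhs detection, locus assembly, architecture classes."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from rhskit.genes import (
    RHS_REPEAT_PATTERN,
    assemble_loci,
    call_rhs_genes,
    classify_architecture,
    detect_paar,
    find_orfs,
    scan_rhs_core,
)
from rhskit.io import StrainRecord

from .conftest import truth_toxins

NT = "ACGT"
STARTS = ("ATG", "GTG", "TTG")
STOPS = ("TAA", "TAG", "TGA")


def brute_force_orfs(seq, min_aa_len):
    """Independent six-frame oracle: walk codon lists on each strand/frame,
    first start after each stop, report forward coordinates."""
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            start = None
            for k, codon in enumerate(codons):
                if start is None and codon in STARTS:
                    start = k
                if codon in STOPS:
                    if start is not None and k - start >= min_aa_len:
                        a = frame + 3 * start
                        b = frame + 3 * (k + 1)
                        if strand == "+":
                            out.add((a, b, "+"))
                        else:
                            out.add((n - b, n - a, "-"))
                    start = None
    return out


def random_nt(rng, n):
    return "".join(NT[i] for i in rng.integers(0, 4, n))


class TestFindOrfs:
    def test_minimal(self):
        (orf,) = find_orfs("ATGAAATAA", min_aa_len=2)
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")
        assert orf.aa_seq == "MK"

    def test_reverse_complement_symmetry(self):
        rc = str(Seq("ATGAAATAA").reverse_complement())
        (orf,) = find_orfs(rc, min_aa_len=2)
        assert orf.strand == "-"
        assert orf.aa_seq == "MK"
        assert (orf.start, orf.end) == (0, 9)

    def test_matches_six_frame_oracle(self, rng):
        for _ in range(20):
            seq = random_nt(rng, 3000)
            got = {(o.start, o.end, o.strand) for o in find_orfs(seq, min_aa_len=20)}
            assert got == brute_force_orfs(seq, min_aa_len=20)

    def test_invariants(self):
        seq = "".join(
            "ACGT"[i] for i in np.random.default_rng(5).integers(0, 4, 2000)
        )
        for o in find_orfs(seq, min_aa_len=10):
            assert (o.end - o.start) % 3 == 0
            assert len(o.aa_seq) == (o.end - o.start) // 3 - 1
            assert 0 <= o.start < o.end <= len(seq)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            find_orfs("ATGXXXTAA")


class TestMotifScans:
    def test_planted_repeats(self, rng):
        rep = "AAGSTYRYDAAGRLVE"
        assert re.fullmatch(RHS_REPEAT_PATTERN, rep)
        prot = ("M" + "".join(rep + "QWERT" for _ in range(5)))
        span, count = scan_rhs_core(prot, min_repeats=4)
        assert count == 5
        assert span == (1, 1 + 4 * (len(rep) + 5) + len(rep))

    def test_decoy_absent(self):
        assert scan_rhs_core("M" + "A" * 200, min_repeats=4) is None

    def test_count_equals_regex_oracle(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(100):
            prot = "".join(aas[i] for i in rng.integers(0, 20, 400))
            res = scan_rhs_core(prot, min_repeats=1)
            oracle = len(re.findall(RHS_REPEAT_PATTERN, prot))
            assert (0 if res is None else res[1]) == oracle

    def test_paar(self):
        assert detect_paar("MAAPAARSVVV") == (3, 8)
        assert detect_paar("MAAVVV") is None


class TestCallRhsGenes:
    def test_counts_match_truth(self, small_sim):
        _, strains, truth = small_sim
        for s in strains:
            tt = truth_toxins(truth, s.strain_id)
            calls = call_rhs_genes(s)
            assert len(calls) == len(tt)
            # precision & recall 1.0: same gene starts
            assert {c.orf.start for c in calls} == set(tt.start.astype(int))

    def test_exact_coords_without_events(self, quiet_sim):
        _, strains, truth = quiet_sim
        for s in strains:
            tt = truth_toxins(truth, s.strain_id)
            calls = call_rhs_genes(s)
            got = {(c.orf.start, c.orf.end) for c in calls}
            assert got == set(zip(tt.start.astype(int), tt.end.astype(int)))

    def test_empty_genome(self):
        s = StrainRecord(strain_id="e", contigs={"c": "ACGT" * 50})
        assert call_rhs_genes(s) == []

    def test_architecture_against_truth(self, quiet_sim):
        # without pseudogenes, per-strain classification is exact
        _, strains, truth = quiet_sim
        for s in strains:
            tt = truth_toxins(truth, s.strain_id)
            arch = {int(r.start): r.architecture for r in tt.itertuples()}
            for c in call_rhs_genes(s):
                assert c.architecture == arch[c.orf.start]

    def test_locus_partition_matches_truth(self, small_sim):
        _, strains, truth = small_sim
        for s in strains:
            tt = truth_toxins(truth, s.strain_id)
            calls = call_rhs_genes(s)
            true_part = {}
            for r in tt.itertuples():
                true_part.setdefault(r.locus_id, set()).add(int(r.start))
            got_part = {}
            for c in calls:
                got_part.setdefault(c.locus_id, set()).add(c.orf.start)
            assert sorted(map(sorted, true_part.values())) == sorted(
                map(sorted, got_part.values()))


class TestAssembleLoci:
    def _gene(self, start, end, contig="c", strand="+"):
        from rhskit.genes import Orf, RhsGene

        orf = Orf(contig_id=contig, start=start, end=end, strand=strand,
                  nt_seq="A" * (end - start), aa_seq="A" * ((end - start) // 3 - 1))
        return RhsGene(orf=orf, core_span=(0, 10), n_core_repeats=5,
                       has_paar=False)

    def test_single_locus_positions(self):
        genes = [self._gene(0, 3000), self._gene(4000, 7000),
                 self._gene(8000, 11000)]
        out = assemble_loci(genes, max_gap_nt=5000)
        assert len({g.locus_id for g in out}) == 1
        assert [g.position_in_locus for g in out] == [0, 1, 2]

    def test_distant_genes_split(self):
        genes = [self._gene(0, 3000), self._gene(53000, 56000)]
        out = assemble_loci(genes)
        assert len({g.locus_id for g in out}) == 2

    @given(st.permutations(range(4)))
    def test_order_invariance(self, perm):
        coords = [(0, 3000), (4000, 7000), (20000, 23000), (60000, 63000)]
        genes = [self._gene(*coords[i]) for i in perm]
        out = assemble_loci(genes)
        partition = {}
        for g in out:
            partition.setdefault(g.locus_id, set()).add(g.orf.start)
        assert sorted(map(sorted, partition.values())) == [
            [0, 4000], [20000], [60000]]

    def test_minus_strand_positions_follow_lead(self):
        genes = [self._gene(0, 3000, strand="-"), self._gene(4000, 7000, strand="-")]
        out = assemble_loci(genes)
        # locus on minus strand: 5'->3' runs right to left
        by_start = {g.orf.start: g.position_in_locus for g in out}
        assert by_start == {4000: 0, 0: 1}


class TestClassify:
    def _gene(self, paar, toxin, reps, pseudo=False):
        from rhskit.genes import Orf, RhsGene

        orf = Orf(contig_id="c", start=0, end=300, strand="+",
                  nt_seq="A" * 300, aa_seq="A" * 99)
        return RhsGene(orf=orf, core_span=(0, 50), n_core_repeats=reps,
                       has_paar=paar, toxin_domain_span=toxin,
                       pseudogene=pseudo)

    @pytest.mark.parametrize(
        "paar,toxin,reps,pseudo,expected",
        [
            (True, (60, 99), 8, False, "lead"),
            (False, (60, 99), 6, False, "orphan"),
            (False, None, 6, False, "toxinless"),
            (False, (60, 99), 4, False, "n_truncated"),
            (True, (60, 99), 8, True, "pseudogene"),
        ],
    )
    def test_labels(self, paar, toxin, reps, pseudo, expected):
        g = self._gene(paar, toxin, reps, pseudo)
        assert classify_architecture(g, lead_repeat_count=8) == expected
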