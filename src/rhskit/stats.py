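"""Supporting statistics: TPM, rank correlation, ANOVA/Tukey, NG86 dN/dS,
distance trees and tree congruence.

The selection statistic is the Nei-Gojobori (1986) counting estimate of
dN/dS with Jukes-Cantor correction — a self-contained surrogate for
likelihood codon models, adequate for contrasting purifying (<1) against
neutral (~1) regimes.  Phylogenetic congruence is measured as the
Robinson-Foulds distance between neighbor-joining trees built from pairwise
sequence distances; RF = 0 means topological agreement.
"""

from __future__ import annotations

import io as _io
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.Data import CodonTable

__all__ = [
    "tpm",
    "spearman",
    "anova_tukey",
    "AnovaTukeyResult",
    "CodonAlignment",
    "ng86_dnds",
    "DnDsResult",
    "pdistance_matrix",
    "nj_tree",
    "rf_distance",
    "position_expression_correlation",
]


# ---------------------------------------------------------------- expression

def tpm(counts: pd.DataFrame, lengths_nt: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalisation.

    ``counts`` is genes x replicates (non-negative integers), ``lengths_nt``
    per-gene lengths in nt.  TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6,
    so every replicate column sums to 1e6.
    """
    lengths = lengths_nt.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise ValueError("negative counts")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise ValueError(f"all-zero replicate(s): {bad}")
    return rate.div(denom, axis=1) * 1e6


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and two-sided
    t-approximation p-value.  Returns (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def position_expression_correlation(
    mean_expr: Mapping[str, float],
    positions: Mapping[str, int],
    loci: Mapping[str, str],
) -> pd.DataFrame:
    """Per-locus Spearman correlation of 5'->3' gene position against
    expression, the position-expression trend of Rhs loci."""
    rows = []
    by_locus: dict[str, list[str]] = {}
    for gid, locus in loci.items():
        by_locus.setdefault(locus, []).append(gid)
    for locus in sorted(by_locus):
        gids = [g for g in by_locus[locus] if g in mean_expr and g in positions]
        if len(gids) < 3:
            continue
        rho, p = spearman([positions[g] for g in gids],
                          [mean_expr[g] for g in gids])
        rows.append(dict(locus=locus, n=len(gids), rho=rho, p=p))
    return pd.DataFrame(rows, columns=["locus", "n", "rho", "p"])


# ----------------------------------------------------------------- ANOVA/HSD

@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    pairwise: pd.DataFrame  # group1, group2, diff, p_adj


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD multiple-test correction.

    Tukey-adjusted pairwise p-values come from the studentized-range
    distribution with N - k degrees of freedom; unequal group sizes are
    handled by the Tukey-Kramer form.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(a.size for a in arrays) - len(arrays) < 1:
        raise ValueError("not enough degrees of freedom")
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical data everywhere: F = 0, all p = 1
        pairwise = pd.DataFrame(
            [dict(group1=a, group2=b, diff=0.0, p_adj=1.0)
             for a, b in itertools.combinations(names, 2)])
        return AnovaTukeyResult(F=0.0, p=1.0, pairwise=pairwise)
    F, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(dict(
            group1=names[i], group2=names[j],
            diff=float(arrays[i].mean() - arrays[j].mean()),
            p_adj=float(hsd.pvalue[i, j]),
        ))
    return AnovaTukeyResult(F=float(F), p=float(p), pairwise=pd.DataFrame(rows))


# -------------------------------------------------------------------- NG86

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_CODON_TABLE.stop_codons)
_NT = "ACGT"


def _aa(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _CODON_TABLE.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3), stop-codon mutations
    excluded from the possible-change count."""
    s = 0.0
    ref = _aa(codon)
    for pos in range(3):
        syn = tot = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            tot += 1
            if _aa(alt) == ref:
                syn += 1
        if tot:
            s += syn / tot
    return s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all
    mutational pathways between two codons, skipping pathways through
    stop codons (all pathways used if every one hits a stop)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                valid = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:  # fall back: count through-stop steps as nonsynonymous
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in _STOPS or _aa(nxt) != _aa(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class DnDsResult:
    dN: float | None
    dS: float | None
    omega: float | None
    reason: str  # "ok", "no_divergence", "dS_zero", "saturated_s", "saturated_n"
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0


class CodonAlignment:
    """In-frame aligned coding sequences with gap-free codon columns flagged.

    Sequences must be equal length, divisible by 3.  A codon column is
    usable when neither sequence has a gap there; internal stop codons in
    usable columns are rejected.
    """

    def __init__(self, seqs: Mapping[str, str]):
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        (self.length,) = lengths
        if self.length % 3:
            raise ValueError("alignment length must be divisible by 3")
        self.seqs = {k: v.upper() for k, v in seqs.items()}

    def ungapped_columns(self, id1: str, id2: str) -> list[int]:
        a, b = self.seqs[id1], self.seqs[id2]
        cols = []
        for i in range(self.length // 3):
            ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
            if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
                continue
            if ca in _STOPS or cb in _STOPS:
                raise ValueError(f"internal stop codon at codon {i}")
            cols.append(i)
        return cols

    def pair(self, id1: str, id2: str) -> "DnDsResult":
        return ng86_dnds(self, (id1, id2))


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(aln, pair: tuple[str, str] | None = None) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.

    ``aln`` may be a :class:`CodonAlignment` with ``pair=(id1, id2)`` or a
    plain ``(seq1, seq2)`` tuple of equal-length in-frame sequences.
    Synonymous/nonsynonymous site counts are averaged between the two
    sequences; difference counts average equally over mutational pathways.
    omega is reported as None with an explanatory reason when dS = 0 or
    when either proportion saturates (p >= 3/4).
    """
    if isinstance(aln, CodonAlignment):
        if pair is None:
            raise ValueError("pair of sequence ids required")
        a, b = aln.seqs[pair[0]], aln.seqs[pair[1]]
        cols = aln.ungapped_columns(*pair)
    else:
        a, b = aln if pair is None else (aln.seqs[pair[0]], aln.seqs[pair[1]])
        a, b = a.upper(), b.upper()
        ca = CodonAlignment({"a": a, "b": b})
        cols = ca.ungapped_columns("a", "b")
        a, b = ca.seqs["a"], ca.seqs["b"]
    if not cols:
        raise ValueError("no ungapped codon columns")
    S = N = Sd = Nd = 0.0
    for i in cols:
        c1, c2 = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        S += (s1 + s2) / 2
        N += 3 - (s1 + s2) / 2
        if c1 != c2:
            sd, nd = _path_counts(c1, c2)
            Sd += sd
            Nd += nd
    if Sd == 0 and Nd == 0:
        return DnDsResult(dN=0.0, dS=0.0, omega=None, reason="no_divergence",
                          S=S, N=N, Sd=Sd, Nd=Nd)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc(pS)
    dN = _jc(pN)
    if dS is None:
        return DnDsResult(dN=dN, dS=None, omega=None, reason="saturated_s",
                          S=S, N=N, Sd=Sd, Nd=Nd)
    if dN is None:
        return DnDsResult(dN=None, dS=dS, omega=None, reason="saturated_n",
                          S=S, N=N, Sd=Sd, Nd=Nd)
    if dS == 0.0:
        return DnDsResult(dN=dN, dS=0.0, omega=None, reason="dS_zero",
                          S=S, N=N, Sd=Sd, Nd=Nd)
    return DnDsResult(dN=dN, dS=dS, omega=dN / dS, reason="ok",
                      S=S, N=N, Sd=Sd, Nd=Nd)


# ------------------------------------------------------------------- trees

def pdistance_matrix(
    seqs: Mapping[str, str], correction: str | None = None
) -> pd.DataFrame:
    """Pairwise p-distance matrix over equal-length aligned sequences.

    Positions with a gap or N in either sequence are ignored.  With
    ``correction="jc"`` the Jukes-Cantor transform is applied (required for
    additivity when distances are appreciable).
    """
    names = sorted(seqs)
    lengths = {len(seqs[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    arrs = {n: np.frombuffer(seqs[n].upper().encode(), dtype="S1") for n in names}
    skip = {b"-", b"N"}
    mat = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        a, b = arrs[names[i]], arrs[names[j]]
        ok = np.array([x not in skip and y not in skip for x, y in zip(a, b)])
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise ValueError("no comparable sites")
        p = float((a[ok] != b[ok]).sum()) / n_ok
        if correction == "jc":
            d = _jc(p)
            if d is None:
                raise ValueError("saturated distance")
            p = d
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=names, columns=names)


def nj_tree(dm: pd.DataFrame) -> str:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix; returns
    an unrooted tree as a newick string."""
    if dm.shape[0] < 3:
        raise ValueError("NJ needs >= 3 taxa")
    buf = _io.StringIO()
    dm.to_csv(buf)
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def rf_distance(newick1: str, newick2: str) -> int:
    """Robinson-Foulds (symmetric-difference) distance between two unrooted
    trees over the same leaf set."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    l1 = {x.taxon.label for x in t1.leaf_node_iter()}
    l2 = {x.taxon.label for x in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
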