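"""Query-versus-genome presence/absence screening.

Each query protein is searched against the ORF proteome of each genome by
local protein alignment (BLOSUM62, affine gaps), standing in for the
published translated-genome searches.  The presence heuristic is the
identity x coverage score of the best hit: identity is counted over aligned
columns of the best local alignment, coverage is the fraction of the query
spanned by it.  Default presence cutoffs are 50% identity and 50% coverage,
with per-query overrides (the tssH-style 70% identity rule); toxin-immunity
co-occurrence uses the stricter 70%/70% amino-acid cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "local_alignment",
    "best_hit",
    "PresenceMatrix",
    "presence_matrix",
    "t6ss_status",
    "toxin_immunity_cooccurrence",
    "interlocus_mean_identity",
    "rhs_count_by_t6ss_group",
]


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


_PALIGNER = _protein_aligner()
_KMER = 5


@dataclass
class Hit:
    """Best local-alignment hit of a query against a proteome."""

    target_id: str
    score: float
    identity: float
    coverage: float


def local_alignment(query_aa: str, target_aa: str) -> tuple[float, float, float]:
    """Score one query/target pair by local protein alignment.

    Returns ``(score, identity, coverage)`` where identity is identical
    residues over aligned columns (gap columns included, BLAST-style) of the
    best local alignment and coverage is the query span of that alignment
    divided by the query length.
    """
    if not query_aa or not target_aa:
        raise ValueError("empty sequence")
    score = _PALIGNER.score(query_aa, target_aa)
    if score <= 0:
        return 0.0, 0.0, 0.0
    aln = _PALIGNER.align(query_aa, target_aa)[0]
    c = aln.counts()
    ncols = c.identities + c.mismatches + c.gaps
    identity = c.identities / ncols if ncols else 0.0
    qblocks = aln.aligned[0]
    qspan = int(qblocks[-1][1] - qblocks[0][0])
    return float(score), identity, qspan / len(query_aa)


def _kmers(seq: str, k: int = _KMER) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_hit(
    query_aa: str,
    proteome: Mapping[str, str],
    id_floor: float = 0.0,
    cov_floor: float = 0.0,
    min_score: float = 1.0,
) -> Hit | None:
    """Highest-scoring local alignment of a query against a proteome.

    Targets sharing no ``k``-mer with the query are skipped (a lossless
    filter at the identity levels of interest).  Returns None when no target
    reaches the configured floors.
    """
    if not query_aa:
        raise ValueError("empty query")
    if not proteome:
        raise ValueError("empty proteome")
    use_filter = len(query_aa) >= 4 * _KMER
    qk = _kmers(query_aa) if use_filter else None
    best_id, best_score = None, 0.0
    for tid in sorted(proteome):
        t = proteome[tid]
        if not t:
            continue
        if use_filter and qk is not None and qk.isdisjoint(_kmers(t)):
            continue
        s = _PALIGNER.score(query_aa, t)
        if s > best_score:
            best_id, best_score = tid, s
    if best_id is None or best_score < min_score:
        return None
    score, identity, coverage = local_alignment(query_aa, proteome[best_id])
    if identity < id_floor or coverage < cov_floor:
        return None
    return Hit(target_id=best_id, score=score, identity=identity, coverage=coverage)


@dataclass
class PresenceMatrix:
    """Long-form query x genome table of best-hit identity/coverage scores.

    ``table`` has columns query_id, genome_id, target_id, identity,
    coverage, score (= identity x coverage) and present.
    """

    table: pd.DataFrame
    id_min: float = 0.5
    cov_min: float = 0.5

    def wide(self, value: str = "score") -> pd.DataFrame:
        return self.table.pivot(index="query_id", columns="genome_id", values=value)

    def is_present(self, query_id: str, genome_id: str) -> bool:
        sel = self.table[
            (self.table.query_id == query_id) & (self.table.genome_id == genome_id)
        ]
        return bool(sel.present.iloc[0]) if len(sel) else False


def presence_matrix(
    queries: Mapping[str, str],
    proteomes: Mapping[str, Mapping[str, str]],
    id_min: float = 0.50,
    cov_min: float = 0.50,
    per_query_thresholds: Mapping[str, tuple[float, float]] | None = None,
) -> PresenceMatrix:
    """Screen every query against every genome proteome.

    ``per_query_thresholds`` maps query id -> (id_min, cov_min) overrides,
    e.g. the 70% identity cutoff applied to tssH.  Identity/coverage of the
    best hit are recorded even when below threshold; ``present`` applies the
    cutoffs.
    """
    rows = []
    overrides = per_query_thresholds or {}
    for qid in sorted(queries):
        q_id_min, q_cov_min = overrides.get(qid, (id_min, cov_min))
        for gid in sorted(proteomes):
            hit = best_hit(queries[qid], proteomes[gid]) if proteomes[gid] else None
            if hit is None:
                rows.append(dict(query_id=qid, genome_id=gid, target_id=None,
                                 identity=0.0, coverage=0.0, score=0.0,
                                 present=False))
            else:
                rows.append(dict(
                    query_id=qid, genome_id=gid, target_id=hit.target_id,
                    identity=hit.identity, coverage=hit.coverage,
                    score=hit.identity * hit.coverage,
                    present=hit.identity >= q_id_min and hit.coverage >= q_cov_min,
                ))
    return PresenceMatrix(pd.DataFrame(rows), id_min=id_min, cov_min=cov_min)


def t6ss_status(
    matrix: PresenceMatrix,
    core_genes: Sequence[str],
    genome_id: str,
    min_frac: float = 0.8,
) -> str:
    """Call a T6SS as present / partial / absent in one genome.

    Present when at least ``min_frac`` of the system's core genes are
    present; partial when any but fewer are; absent when none is.
    """
    if not core_genes:
        raise ValueError("core gene list is empty")
    n_present = sum(matrix.is_present(q, genome_id) for q in core_genes)
    if n_present >= min_frac * len(core_genes):
        return "present"
    if n_present > 0:
        return "partial"
    return "absent"


def toxin_immunity_cooccurrence(
    pairs: Sequence[tuple[str, str]],
    queries: Mapping[str, str],
    proteomes: Mapping[str, Mapping[str, str]],
    id_min: float = 0.70,
    cov_min: float = 0.70,
) -> pd.DataFrame:
    """Joint presence/absence of toxin domains and their cognate immunity.

    ``pairs`` lists (toxin_query_id, immunity_query_id); toxinless genes
    have no entry.  Presence uses the 70% coverage / 70% amino-acid identity
    cutoffs.  ``violation`` flags cells with the toxin but not the immunity
    gene — the configuration never observed in nature.
    """
    rows = []
    for tox_q, imm_q in pairs:
        for gid in sorted(proteomes):
            th = best_hit(queries[tox_q], proteomes[gid],
                          id_floor=id_min, cov_floor=cov_min)
            ih = best_hit(queries[imm_q], proteomes[gid],
                          id_floor=id_min, cov_floor=cov_min)
            tox_present, imm_present = th is not None, ih is not None
            rows.append(dict(
                toxin_query=tox_q, immunity_query=imm_q, genome_id=gid,
                toxin_present=tox_present, immunity_present=imm_present,
                violation=tox_present and not imm_present,
            ))
    return pd.DataFrame(rows)


def interlocus_mean_identity(
    locus_a: Mapping[str, str],
    locus_b: Mapping[str, str],
    min_score: float = 40.0,
) -> float | None:
    """Average coverage-normalised identity between two gene sets.

    For each protein of locus A the best hit in locus B above a permissive
    score floor contributes identity x (aligned query fraction); genes with
    no hit are skipped.  Returns None when nothing matches.
    """
    values = []
    for qid in sorted(locus_a):
        hit = best_hit(locus_a[qid], locus_b, min_score=min_score)
        if hit is not None:
            values.append(hit.identity * hit.coverage)
    return sum(values) / len(values) if values else None


def rhs_count_by_t6ss_group(
    gene_table: pd.DataFrame,
    statuses: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Per-strain Rhs gene counts labelled by T6SS repertoire group.

    ``gene_table`` has one row per Rhs gene with a ``strain_id`` column;
    ``statuses`` maps strain -> {"T6SS-1": status, "T6SS-2/3": status}.
    Groups are "T6SS-1 only", "T6SS-2/3 only", "both" and "neither"; only
    full "present" calls count.  Strains with zero Rhs genes are included.
    """
    counts = (
        gene_table.groupby("strain_id").size() if len(gene_table) else pd.Series(dtype=int)
    )
    rows = []
    for strain in sorted(statuses):
        st = statuses[strain]
        has1 = st.get("T6SS-1") == "present"
        has23 = st.get("T6SS-2/3") == "present"
        group = ("both" if has1 and has23 else
                 "T6SS-1 only" if has1 else
                 "T6SS-2/3 only" if has23 else "neither")
        rows.append(dict(strain_id=strain, n_rhs=int(counts.get(strain, 0)),
                         group=group))
    return pd.DataFrame(rows, columns=["strain_id", "n_rhs", "group"])
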