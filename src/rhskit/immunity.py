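"""Toxin-immunity pairing, orphan immunity genes, pseudogene flagging.

Immunity genes neutralise their cognate Rhs toxin and sit immediately
downstream of it; they share essentially no sequence signature with each
other, so de novo identification is purely positional (nearest co-oriented
downstream ORF), while homology against a reference immunity set is used to
find orphan immunity genes — immunity retained after the cognate toxin was
lost.  The converse configuration, a toxin without its immunity gene, is
never expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .genes import Orf, RhsGene, STOP_CODONS
from . import screen as _screen

#: Operationalisation of "immediately downstream" (nt).
DEFAULT_MAX_INTERGENIC_NT = 200


@dataclass
class ImmunityCall:
    """An immunity gene call, linked to a toxin or orphan."""

    orf: Orf
    toxin_gene_id: str | None
    distance_nt: int | None
    orphan: bool = False
    pseudogene: bool = False
    pseudogene_indeterminate: bool = False
    reference_id: str | None = None
    strain_id: str | None = None


def pair_immunity(
    gene: RhsGene,
    orfs: Sequence[Orf],
    max_intergenic_nt: int = DEFAULT_MAX_INTERGENIC_NT,
    rhs_orf_ids: frozenset | set | None = None,
) -> ImmunityCall | None:
    """Pair one Rhs toxin with its downstream immunity gene.

    The partner is the nearest same-strand, same-contig ORF whose start lies
    within ``max_intergenic_nt`` downstream of the toxin stop and which is
    not itself an Rhs gene.  Toxinless genes get no partner.  Distance ties
    are broken by ORF length (longest wins).
    """
    if gene.toxin_domain_span is None:
        return None
    rhs_ids = rhs_orf_ids or frozenset()
    candidates: list[tuple[int, Orf]] = []
    for orf in orfs:
        if orf.contig_id != gene.orf.contig_id or orf.strand != gene.orf.strand:
            continue
        if orf.orf_id in rhs_ids or orf.orf_id == gene.orf.orf_id:
            continue
        if gene.orf.strand == "+":
            dist = orf.start - gene.orf.end
        else:
            dist = gene.orf.start - orf.end
        if 0 <= dist <= max_intergenic_nt:
            candidates.append((dist, orf))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], -(c[1].end - c[1].start), c[1].start))
    dist, orf = candidates[0]
    return ImmunityCall(
        orf=orf,
        toxin_gene_id=gene.gene_id,
        distance_nt=dist,
        strain_id=gene.strain_id,
    )


def flag_pseudogene(
    orf: Orf,
    full_length_homolog_aa: str,
    contig_seq: str,
    length_fraction: float = 0.9,
) -> tuple[bool | None, list[int]]:
    """Decide whether an ORF is a pseudogenized copy of a longer homolog.

    The reading frame of the ORF is extended co-frame along the genome for
    the length of the homolog; the call is True iff at least one stop codon
    occurs before ``length_fraction`` of the homolog length is reached.
    Lesion positions are returned as codon indices from the ORF start.
    Returns ``(None, [])`` (indeterminate) when no alignable region exists
    (homolog shorter than the minimum overlap), and ``(False, [])`` when the
    homolog is not longer than the ORF.
    """
    orf_aa_len = (orf.end - orf.start) // 3 - 1
    hom_len = len(full_length_homolog_aa)
    if hom_len < 10:
        return None, []
    if orf_aa_len >= length_fraction * hom_len:
        return False, []
    # walk the genomic frame from the ORF start across its stop codon
    if orf.strand == "+":
        frame_seq = contig_seq[orf.start :]
    else:
        from .genes import _revcomp

        frame_seq = _revcomp(contig_seq[: orf.end])
    limit = int(length_fraction * hom_len)
    lesions = []
    for i in range(min(limit, len(frame_seq) // 3)):
        codon = frame_seq[3 * i : 3 * i + 3].upper()
        if codon in STOP_CODONS:
            lesions.append(i)
    return (True, lesions) if lesions else (False, [])


def _extension_matches_homolog(
    orf: Orf,
    homolog_aa: str,
    contig_seq: str,
    min_identity: float = 0.4,
) -> bool:
    """Does the co-frame extension beyond the ORF stop still look like the
    homolog?

    A genuine pseudogene is a full-length gene interrupted by a stop: the
    remnant downstream of the lesion keeps matching the homolog.  A gene
    that is merely shorter than its homolog (e.g. carries a shorter toxin
    domain) is followed by unrelated intergenic sequence instead.
    """
    from .genes import _revcomp
    from Bio.Seq import Seq

    orf_aa_len = (orf.end - orf.start) // 3 - 1
    if orf.strand == "+":
        frame_seq = contig_seq[orf.start :]
    else:
        frame_seq = _revcomp(contig_seq[: orf.end])
    n_codons = min(len(homolog_aa), len(frame_seq) // 3)
    tail_start = orf_aa_len + 1  # skip the premature stop codon itself
    if n_codons - tail_start < 10:
        return True  # nearly full length; nothing to compare
    ident = total = 0
    for i in range(tail_start, n_codons):
        codon = frame_seq[3 * i : 3 * i + 3].upper()
        if codon in STOP_CODONS:
            continue
        total += 1
        ident += str(Seq(codon).translate(table=11)) == homolog_aa[i]
    return total > 0 and ident / total >= min_identity


def refine_pseudogene_flags(
    genes_by_strain: Mapping[str, Sequence[RhsGene]],
    contigs_by_strain: Mapping[str, Mapping[str, str]],
    k: int = 16,
    min_kmer_frac: float = 0.2,
    trunc_fraction: float = 0.6,
) -> None:
    """Cross-strain pseudogene refinement of Rhs gene calls.

    A truncated gene cannot be recognised as a pseudogene from one genome
    alone; here each gene is compared against its best full-length homolog
    from the other strains (candidates found by shared nucleotide k-mers,
    which separates homologous gene copies from unrelated Rhs genes) and
    re-flagged via :func:`flag_pseudogene`.  Architecture labels are
    updated in place (pseudogene overrides all other classes).
    """
    from .genes import _classify_all

    entries = []
    for strain in sorted(genes_by_strain):
        for g in genes_by_strain[strain]:
            kmers = {g.orf.nt_seq[i : i + k]
                     for i in range(0, len(g.orf.nt_seq) - k + 1, 4)}
            entries.append((strain, g, kmers))
    for strain, g, kmers in entries:
        candidates = []
        for other_strain, h, hkmers in entries:
            if other_strain == strain:
                continue
            if len(h.orf.aa_seq) <= len(g.orf.aa_seq):
                continue
            denom = min(len(kmers), len(hkmers)) or 1
            if len(kmers & hkmers) / denom < min_kmer_frac:
                continue
            candidates.append(h)
        contig = contigs_by_strain[strain][g.orf.contig_id]
        for h in sorted(candidates, key=lambda x: -len(x.orf.aa_seq)):
            flag, lesions = flag_pseudogene(g.orf, h.orf.aa_seq, contig)
            if flag and _extension_matches_homolog(g.orf, h.orf.aa_seq, contig):
                g.pseudogene = True
                g.lesions = tuple(lesions)
                break
    for strain in sorted(genes_by_strain):
        _classify_all(list(genes_by_strain[strain]), trunc_fraction=trunc_fraction)


def find_orphan_immunity(
    strain,
    orfs: Sequence[Orf],
    rhs_genes: Sequence[RhsGene],
    reference_immunity: Mapping[str, str],
    id_threshold: float = 0.70,
    cov_threshold: float = 0.70,
    max_intergenic_nt: int = DEFAULT_MAX_INTERGENIC_NT,
) -> list[ImmunityCall]:
    """Find immunity genes whose cognate toxin is gone.

    ORFs matching a reference immunity protein at >= ``id_threshold``
    identity and >= ``cov_threshold`` coverage, with no intact-toxin Rhs
    gene ending within ``max_intergenic_nt`` upstream, are flagged orphan.
    The pseudogene flag marks orphans that are themselves decaying
    (truncated relative to their reference).
    """
    if not reference_immunity:
        raise ValueError("reference immunity set is empty")
    intact_by_contig: dict[str, list[RhsGene]] = {}
    rhs_ids = {g.orf.orf_id for g in rhs_genes}
    for g in rhs_genes:
        if g.toxin_domain_span is not None and not g.pseudogene:
            intact_by_contig.setdefault(g.orf.contig_id, []).append(g)
    out: list[ImmunityCall] = []
    for orf in orfs:
        if orf.orf_id in rhs_ids:
            continue
        match_id = None
        for rid in sorted(reference_immunity):
            ref = reference_immunity[rid]
            hit = _screen.best_hit(ref, {"x": orf.aa_seq})
            if hit and hit.identity >= id_threshold and hit.coverage >= cov_threshold:
                match_id = rid
                ref_aa = ref
                break
        if match_id is None:
            continue
        upstream_toxin = None
        for g in intact_by_contig.get(orf.contig_id, []):
            if g.orf.strand != orf.strand:
                continue
            dist = (orf.start - g.orf.end) if orf.strand == "+" else (g.orf.start - orf.end)
            if 0 <= dist <= max_intergenic_nt:
                upstream_toxin = g
                break
        if upstream_toxin is not None:
            continue
        pseudo, _ = flag_pseudogene(
            orf, ref_aa, strain.contigs[orf.contig_id]
        )
        out.append(
            ImmunityCall(
                orf=orf,
                toxin_gene_id=None,
                distance_nt=None,
                orphan=True,
                pseudogene=bool(pseudo),
                pseudogene_indeterminate=pseudo is None,
                reference_id=match_id,
                strain_id=getattr(strain, "strain_id", None),
            )
        )
    return out
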