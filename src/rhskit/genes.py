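"""ORF finding, Rhs-family gene detection and locus assembly.

Rhs ("rearrangement hotspot") toxins are large polymorphic proteins built
from a conserved, YD-repeat-rich core followed by a hypervariable C-terminal
toxin domain.  Lead genes additionally carry a PAAR motif that docks the
toxin onto the VgrG spike of a type VI secretion system.  This module finds
open reading frames in genome assemblies, flags the ones that look like Rhs
genes (enough core repeats), groups neighbouring Rhs genes into loci and
assigns each gene an architecture class (lead / orphan / toxinless /
N-truncated / pseudogene).

HMM-based domain detection (TIGR03696 Rhs core, PF05488 PAAR) is replaced by
configurable degenerate-pattern scans, which are exact on synthetic data and
keep the package self-contained; precomputed domain tables for real genomes
can be fed in via :func:`call_rhs_genes`'s ``precomputed_cores`` hook.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from . import domains as _domains

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: Degenerate YD-repeat pattern standing in for the TIGR03696 Rhs core model.
RHS_REPEAT_PATTERN = r"..G..Y.YD..GRL.."

#: Degenerate pattern standing in for the PF05488 PAAR motif model.
PAAR_PATTERN = r"PAAR[PS]"

_VALID_NT = set("ACGTN")

ARCHITECTURES = ("lead", "orphan", "toxinless", "n_truncated", "pseudogene")


@dataclass
class Orf:
    """A maximal start-to-stop open reading frame.

    Coordinates are 0-based, half-open, on the forward strand of the contig
    and include the stop codon, so ``(end - start)`` is divisible by 3 and
    ``len(aa_seq) == (end - start) // 3 - 1``.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str
    internal_stop: bool = False

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


@dataclass
class RhsGene:
    """A detected Rhs-family gene with its core/PAAR/motif annotation.

    Spans are amino-acid intervals (0-based, half-open) on the translated
    ORF.  ``locus_id`` / ``position_in_locus`` are filled in by
    :func:`assemble_loci`; ``architecture`` by :func:`classify_architecture`.
    """

    orf: Orf
    core_span: tuple[int, int]
    n_core_repeats: int
    has_paar: bool
    paar_span: tuple[int, int] | None = None
    dpxg_span: tuple[int, int] | None = None
    toxin_domain_span: tuple[int, int] | None = None
    locus_id: str | None = None
    position_in_locus: int | None = None
    architecture: str | None = None
    pseudogene: bool = False
    lesions: tuple[int, ...] = ()
    strain_id: str | None = None

    @property
    def gene_id(self) -> str:
        prefix = f"{self.strain_id}|" if self.strain_id else ""
        return prefix + self.orf.orf_id


def _check_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _orfs_one_strand(
    seq: str, contig_len: int, strand: str, min_aa_len: int, genetic_code: int
) -> list[Orf]:
    """Maximal ORFs on one strand; ``seq`` is already strand-oriented."""
    out: list[Orf] = []
    n = len(seq)
    for frame in range(3):
        start_idx: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if start_idx is None and codon in START_CODONS:
                start_idx = pos
            if codon in STOP_CODONS:
                if start_idx is not None:
                    aa_len = (pos - start_idx) // 3
                    if aa_len >= min_aa_len:
                        nt = seq[start_idx : pos + 3]
                        aa = str(Seq(nt[:-3]).translate(table=genetic_code))
                        if strand == "+":
                            s, e = start_idx, pos + 3
                        else:
                            s, e = contig_len - (pos + 3), contig_len - start_idx
                        out.append(Orf(contig_id="", start=s, end=e, strand=strand,
                                       nt_seq=nt, aa_seq=aa))
                start_idx = None
            pos += 3
    return out


def find_orfs(
    contig_seq: str,
    min_aa_len: int = 60,
    genetic_code: int = 11,
    contig_id: str = "",
) -> list[Orf]:
    """Find all maximal start-to-stop ORFs on both strands.

    An ORF runs from the first start codon (ATG/GTG/TTG) after the previous
    in-frame stop to the next stop codon, i.e. nested ORFs are reported only
    as the longest one per stop per frame.  ORFs without a stop codon inside
    the contig are not reported.  Reverse-strand ORFs are reported in forward
    coordinates with ``strand == '-'``.

    Parameters
    ----------
    contig_seq : nucleotide sequence over {A,C,G,T,N}.
    min_aa_len : minimum protein length (excluding the stop), default 60.
    genetic_code : NCBI translation table id, default 11 (bacterial).
    """
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    seq = contig_seq.upper()
    _check_alphabet(seq)
    n = len(seq)
    orfs = _orfs_one_strand(seq, n, "+", min_aa_len, genetic_code)
    orfs += _orfs_one_strand(_revcomp(seq), n, "-", min_aa_len, genetic_code)
    for o in orfs:
        o.contig_id = contig_id
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def scan_rhs_core(
    aa_seq: str,
    repeat_pattern: str = RHS_REPEAT_PATTERN,
    min_repeats: int = 4,
) -> tuple[tuple[int, int], int] | None:
    """Scan a protein for Rhs/YD core repeats.

    Returns ``((first_match_start, last_match_end), n_matches)`` when at
    least ``min_repeats`` non-overlapping matches of the degenerate repeat
    pattern are found, else None.
    """
    if not repeat_pattern:
        raise ValueError("empty repeat pattern")
    matches = list(re.finditer(repeat_pattern, aa_seq))
    if len(matches) < min_repeats:
        return None
    return (matches[0].start(), matches[-1].end()), len(matches)


def detect_paar(aa_seq: str, paar_pattern: str = PAAR_PATTERN) -> tuple[int, int] | None:
    """Return the span of the first PAAR motif match, or None."""
    if not paar_pattern:
        raise ValueError("empty PAAR pattern")
    m = re.search(paar_pattern, aa_seq)
    return (m.start(), m.end()) if m else None


def count_pattern(aa_seq: str, pattern: str) -> int:
    """Number of non-overlapping matches of a degenerate pattern."""
    return len(list(re.finditer(pattern, aa_seq)))


def call_rhs_genes(
    strain,
    min_aa_len: int = 60,
    repeat_pattern: str = RHS_REPEAT_PATTERN,
    min_repeats: int = 4,
    paar_pattern: str = PAAR_PATTERN,
    motif_mode: str = "default",
    max_gap_nt: int = 5000,
    trunc_fraction: float = 0.6,
    orfs_by_contig: Mapping[str, Sequence[Orf]] | None = None,
) -> list[RhsGene]:
    """Detect Rhs genes in one strain and annotate loci + architecture.

    ``strain`` needs ``strain_id`` and ``contigs`` (mapping contig id ->
    sequence) attributes (see :class:`rhskit.io.StrainRecord`).  Precomputed
    ORFs can be passed via ``orfs_by_contig`` to avoid rescanning.
    """
    genes: list[RhsGene] = []
    for contig_id in sorted(strain.contigs):
        seq = strain.contigs[contig_id]
        if orfs_by_contig is not None and contig_id in orfs_by_contig:
            orfs = orfs_by_contig[contig_id]
        else:
            orfs = find_orfs(seq, min_aa_len=min_aa_len, contig_id=contig_id)
        for orf in orfs:
            core = scan_rhs_core(orf.aa_seq, repeat_pattern, min_repeats)
            if core is None:
                continue
            core_span, n_rep = core
            paar = detect_paar(orf.aa_seq, paar_pattern)
            dpxg = _domains.locate_dpxg(orf.aa_seq, mode=motif_mode)
            tox_span = None
            if dpxg is not None and dpxg[1] < len(orf.aa_seq):
                tox_span = (dpxg[1], len(orf.aa_seq))
            genes.append(
                RhsGene(
                    orf=orf,
                    core_span=core_span,
                    n_core_repeats=n_rep,
                    has_paar=paar is not None,
                    paar_span=paar,
                    dpxg_span=dpxg,
                    toxin_domain_span=tox_span,
                    strain_id=getattr(strain, "strain_id", None),
                )
            )
    genes = assemble_loci(genes, max_gap_nt=max_gap_nt)
    _classify_all(genes, trunc_fraction=trunc_fraction)
    return genes


def assemble_loci(genes: Iterable[RhsGene], max_gap_nt: int = 5000) -> list[RhsGene]:
    """Group neighbouring Rhs genes into loci.

    Consecutive Rhs genes on one contig whose gap is at most ``max_gap_nt``
    share a locus.  Positions are numbered 5'->3' in the locus orientation,
    taken from the strand of the locus's first (lead-most) gene.  The
    partition is invariant to the input order.
    """
    genes = sorted(genes, key=lambda g: (g.orf.contig_id, g.orf.start, g.orf.end))
    out: list[RhsGene] = []
    locus: list[RhsGene] = []
    locus_n = 0

    def _flush() -> None:
        nonlocal locus_n
        if not locus:
            return
        locus_n += 1
        strain = locus[0].strain_id or "strain"
        lid = f"{strain}_L{locus_n}"
        orientation = locus[0].orf.strand
        ordered = locus if orientation == "+" else list(reversed(locus))
        for i, g in enumerate(ordered):
            g.locus_id = lid
            g.position_in_locus = i
        out.extend(locus)
        locus.clear()

    prev: RhsGene | None = None
    for g in genes:
        if prev is not None and (
            g.orf.contig_id != prev.orf.contig_id
            or g.orf.start - prev.orf.end > max_gap_nt
        ):
            _flush()
        locus.append(g)
        prev = g
    _flush()
    return out


def classify_architecture(
    gene: RhsGene,
    lead_repeat_count: int | None = None,
    trunc_fraction: float = 0.6,
) -> str:
    """Assign one architecture label to a gene.

    Precedence: pseudogene (internal stop relative to a full-length homolog)
    overrides everything; then toxinless (no DPXG motif / no C-terminal
    domain, the rhs8/rhs9-style genes); then N-truncated (core repeat count
    below ``trunc_fraction`` of the locus lead's count); finally lead
    (PAAR-bearing) versus orphan.
    """
    if gene.pseudogene:
        return "pseudogene"
    if gene.toxin_domain_span is None:
        return "toxinless"
    if (
        lead_repeat_count
        and gene.n_core_repeats < trunc_fraction * lead_repeat_count
    ):
        return "n_truncated"
    return "lead" if gene.has_paar else "orphan"


def _classify_all(genes: Sequence[RhsGene], trunc_fraction: float = 0.6) -> None:
    by_locus: dict[str | None, list[RhsGene]] = {}
    for g in genes:
        by_locus.setdefault(g.locus_id, []).append(g)
    for members in by_locus.values():
        leads = [g for g in members if g.has_paar]
        if leads:
            ref = max(g.n_core_repeats for g in leads)
        else:
            ref = max(g.n_core_repeats for g in members)
        for g in members:
            g.architecture = classify_architecture(
                g, lead_repeat_count=ref, trunc_fraction=trunc_fraction
            )
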