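"""Delimiting Rhs C-terminal toxin domains at the DPXG(18)DPXG motif.

The Rhs core ends in a highly conserved amino-acid motif of two DPXG tetrads
separated by 18 arbitrary residues.  The residue after the second tetrad is
taken as the start of the C-terminal toxin domain (configurable via
``include_motif``).  Two stringency modes are supported: the default mode
tolerates one mismatch across the six conserved positions and drops domains
shorter than 40 nt; the stringent mode requires a perfect motif and at least
200 nt of domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .genes import RhsGene

#: (tetrad) D P x G .. 18 residues .. D P x G
MOTIF_LEN = 26
_CONSERVED = {0: "D", 1: "P", 3: "G", 22: "D", 23: "P", 25: "G"}

#: Minimum domain length in nt; shorter predictions are discarded.
DEFAULT_MIN_NT = 40
STRINGENT_MIN_NT = 200

MODES = ("default", "stringent")


@dataclass
class ToxinDomain:
    """An extracted C-terminal toxin domain.

    ``nt_seq`` is the exact in-frame suffix of the source ORF (stop codon
    excluded), so ``length_nt == 3 * len(aa_seq)``.  ``start_aa`` is the
    index of the first domain residue on the translated ORF.
    """

    gene_id: str
    aa_seq: str
    nt_seq: str
    start_aa: int
    mode: str
    strain_id: str | None = None

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)

    @property
    def domain_id(self) -> str:
        return self.gene_id


def locate_dpxg(aa_seq: str, mode: str = "default") -> tuple[int, int] | None:
    """Locate the DPXG(18)DPXG motif in a protein.

    The default mode allows at most one mismatch across the six conserved
    positions (D, P, G of each tetrad); stringent mode allows none.  When
    several windows match, the most C-terminal one is returned, since the
    motif marks the *end* of the conserved core.

    Returns the (start, end) amino-acid span of the 26-residue motif, or
    None.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not aa_seq:
        return None
    max_mm = 1 if mode == "default" else 0
    best: tuple[int, int] | None = None
    for i in range(len(aa_seq) - MOTIF_LEN + 1):
        mm = 0
        for off, res in _CONSERVED.items():
            if aa_seq[i + off] != res:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            best = (i, i + MOTIF_LEN)
    return best


def extract_cterm(
    gene: "RhsGene",
    mode: str = "default",
    min_nt: int | None = None,
    include_motif: bool = False,
) -> tuple[ToxinDomain | None, str]:
    """Split off the C-terminal toxin domain of an Rhs gene.

    Returns ``(domain, "ok")`` on success, else ``(None, reason)`` with
    reason ``"no_motif"`` or ``"too_short"``.  ``min_nt`` defaults to 40 nt
    (default mode) or 200 nt (stringent), after the published length
    filters.
    """
    if min_nt is None:
        min_nt = DEFAULT_MIN_NT if mode == "default" else STRINGENT_MIN_NT
    span = gene.dpxg_span
    if mode == "stringent" or span is None:
        span = locate_dpxg(gene.orf.aa_seq, mode=mode)
    if span is None:
        return None, "no_motif"
    start_aa = span[0] if include_motif else span[1]
    aa = gene.orf.aa_seq[start_aa:]
    if 3 * len(aa) < min_nt:
        return None, "too_short"
    # in-frame suffix of the ORF, stop codon excluded
    nt = gene.orf.nt_seq[3 * start_aa : 3 * len(gene.orf.aa_seq)]
    return (
        ToxinDomain(
            gene_id=gene.gene_id,
            aa_seq=aa,
            nt_seq=nt,
            start_aa=start_aa,
            mode=mode,
            strain_id=gene.strain_id,
        ),
        "ok",
    )


def extract_core(gene: "RhsGene", mode: str = "default") -> tuple[str, str]:
    """Return the (nt, aa) conserved-core region of an Rhs gene.

    The core runs from the start of the repeat region to the end of the
    DPXG motif, or to the end of the ORF for toxinless genes.
    """
    span = gene.dpxg_span or locate_dpxg(gene.orf.aa_seq, mode=mode)
    start_aa = gene.core_span[0]
    end_aa = span[1] if span is not None else len(gene.orf.aa_seq)
    aa = gene.orf.aa_seq[start_aa:end_aa]
    nt = gene.orf.nt_seq[3 * start_aa : 3 * end_aa]
    return nt, aa
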