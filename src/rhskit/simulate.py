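"""Synthetic strain genomes under the C-terminal displacement model.

The generator emits a set of bacterial strains related by a known tree.
Each strain carries Rhs loci with the canonical architecture — a PAAR-bearing
lead gene with a full repeat-rich core, the DPXG(18)DPXG motif and a
C-terminal toxin domain, followed by its cognate immunity gene and then
orphan toxin genes (no PAAR, shorter cores), each with its own immunity
gene — plus T6SS core-gene loci, housekeeping genes and decoy ORFs.  Toxin
domains are drawn from a shared prototype pool and spread both vertically
(inherited along the tree with point mutations) and horizontally (domain
swap events importing a fresh pool prototype).  Pseudogenization introduces
a single premature stop; orphan-immunity events delete a toxin but keep its
immunity gene.

Ground truth (coordinates, architecture classes, domain/cluster labels,
toxin-immunity pairings, tree, per-strain T6SS status) is recorded so every
downstream detection stage can be scored exactly.  To keep that truth
unambiguous, intergenic spacers flanking planted genes are stop-codon walls
with no start codons, and point mutations are resampled when they would
create an in-frame stop, touch a protected motif position, or give rise to
a spurious DPXG motif (the "motif-preserving" mutation mode); setting
``motif_degrading=True`` lifts the motif protections.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import domains as _domains
from . import genes as _genes
from .clusters import pairwise_identity
from .io import StrainRecord, write_fasta, write_gff3, write_genome_fasta

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

_REPEAT_CONSERVED = {2: "G", 5: "Y", 7: "Y", 8: "D", 11: "G", 12: "R", 13: "L"}
_REPEAT_LEN = 16
_MOTIF_CONSERVED = {0: "D", 1: "P", 3: "G", 22: "D", 23: "P", 25: "G"}
_MOTIF_LEN = 26
_PAAR_CORE = "PAARS"

_MAX_ATTEMPTS = 50


class SeparabilityError(RuntimeError):
    """Raised when a separable toxin pool cannot be generated."""


@dataclass
class SimulationConfig:
    """Stated world of the generator.  All randomness derives from ``seed``."""

    n_strains: int = 20
    tree_mode: str = "random_bifurcating"  # or "fixed_newick"
    fixed_newick: str | None = None
    pool_size: int = 50
    domain_length_range: tuple[int, int] = (120, 900)  # nt
    core_length_range: tuple[int, int] = (250, 400)  # aa
    repeats_per_core: int = 8
    #: expected substitutions/site accumulated from root to any leaf
    #: (tree height is normalised to 1, so this is also the per-unit-branch
    #: rate); default keeps within-prototype pairwise divergence around 3%.
    per_branch_substitution_rate: float = 0.015
    p_pseudogenize: float = 0.05
    p_orphan_immunity: float = 0.05
    p_hgt: float = 0.10
    loci_per_strain_range: tuple[int, int] = (2, 4)
    orphans_per_locus_range: tuple[int, int] = (1, 3)
    n_decoy_orfs: int = 30
    n_short_domain_controls: int = 0  # per genome, domains < 40 nt
    p_toxinless: float = 0.15
    p_n_truncated: float = 0.10
    n_housekeeping: int = 5
    n_t6ss1_genes: int = 13
    n_t6ss23_genes: int = 8
    p_t6ss_loss: float = 0.10  # per branch per system
    t6ss_transfer: bool = False  # plant one horizontal T6SS-1 transfer
    immunity_spacer_nt: int = 30
    immunity_length_range: tuple[int, int] = (300, 600)  # nt
    cluster_threshold: float = 0.90
    separability_margin: float = 0.05
    randomize_strand: bool = False
    motif_degrading: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for name in ("p_pseudogenize", "p_orphan_immunity", "p_hgt",
                     "p_t6ss_loss", "p_toxinless", "p_n_truncated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        lo, hi = self.domain_length_range
        if lo < 12 or hi < lo:
            raise ValueError("invalid domain_length_range")
        if self.loci_per_strain_range[0] < 1:
            raise ValueError("need at least one locus per strain")
        if self.separability_margin < 0.05:
            raise ValueError("separability margin must be >= 5 percentage points")


# ------------------------------------------------------------------ helpers

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream])


def _wall(n: int) -> str:
    """Stop-codon wall: stops in every frame, no start codons."""
    return ("TTAA" * (n // 4 + 1))[:n]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=n))


def _build_syn_table() -> dict[str, list[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[11].forward_table
    syn: dict[str, list[str]] = {}
    for codon, aa in sorted(table.items()):
        syn.setdefault(aa, []).append(codon)
    return syn


_SYN = _build_syn_table()
_SENSE_CODONS = sorted(c for codons in _SYN.values() for c in codons)


def _encode_aa(rng: np.random.Generator, aa: str) -> str:
    """Random synonymous codon encoding of a protein."""
    return "".join(_SYN[a][rng.integers(0, len(_SYN[a]))] for a in aa)


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _translate(nt: str) -> str:
    return str(Seq(nt).translate(table=11))


# ---------------------------------------------------------------- gene model

@dataclass
class _Gene:
    gene_id: str
    kind: str  # rhs | immunity | t6ss1 | t6ss23 | housekeeping | decoy
    nt: np.ndarray  # uint8 indices into ACGT
    protected: np.ndarray
    meta: dict = field(default_factory=dict)

    def copy(self) -> "_Gene":
        return _Gene(self.gene_id, self.kind, self.nt.copy(),
                     self.protected, dict(self.meta))

    @property
    def seq(self) -> str:
        return "".join(_NT[i] for i in self.nt)

    def protein(self) -> str:
        return _translate(self.seq[:-3])


def _s2a(seq: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(_NT)}
    return np.array([lut[c] for c in seq], dtype=np.uint8)


def _coding_gene(gene_id: str, kind: str, body_nt: str, meta=None) -> _Gene:
    nt = "ATG" + body_nt + "TAA"
    protected = np.zeros(len(nt), dtype=bool)
    protected[:3] = True
    protected[-3:] = True
    return _Gene(gene_id, kind, _s2a(nt), protected, meta or {})


def _rhs_gene_valid(gene: _Gene) -> bool:
    """Check that the detectable landmarks still equal the planted ones."""
    m = gene.meta
    prot = gene.protein()
    core = _genes.scan_rhs_core(prot, min_repeats=1)
    if core is None or core[1] != m["n_repeats"]:
        return False
    if (_genes.detect_paar(prot) is not None) != m["has_paar"]:
        return False
    span = _domains.locate_dpxg(prot, mode="default")
    if m.get("motif_aa_start") is None:
        return span is None
    return span == (m["motif_aa_start"], m["motif_aa_start"] + _MOTIF_LEN)


def _build_rhs_gene(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    gene_id: str,
    role: str,
    n_repeats: int,
    has_paar: bool,
    domain_nt: str | None,
    prototype: int,
) -> _Gene:
    """Assemble one Rhs gene; retries until the planted landmarks are the
    only detectable ones (no spurious motif/repeat/PAAR matches)."""
    for _ in range(_MAX_ATTEMPTS):
        aa_parts: list[str] = []
        protected_aa: list[bool] = []
        landmarks: dict = {}

        def add(chunk: str, prot: Sequence[bool] | None = None) -> int:
            start = 1 + sum(len(p) for p in aa_parts)  # +1 for leading Met
            aa_parts.append(chunk)
            protected_aa.extend(prot if prot is not None else [False] * len(chunk))
            return start

        if has_paar:
            nterm = list(_random_aa(rng, 24))
            pos = 8
            nterm[pos : pos + len(_PAAR_CORE)] = list(_PAAR_CORE)
            prot = [False] * 24
            for k in range(len(_PAAR_CORE)):
                prot[pos + k] = True
            add("".join(nterm), prot)
        else:
            add(_random_aa(rng, 5))

        core_target = int(rng.integers(*cfg.core_length_range))
        spacer_total = max(core_target - _REPEAT_LEN * n_repeats, 4 * n_repeats)
        first_rep = None
        for r in range(n_repeats):
            rep = [
                _REPEAT_CONSERVED.get(i) or _AA20[rng.integers(0, 20)]
                for i in range(_REPEAT_LEN)
            ]
            start = add("".join(rep), [i in _REPEAT_CONSERVED for i in range(_REPEAT_LEN)])
            if first_rep is None:
                first_rep = start
            if r < n_repeats - 1:
                add(_random_aa(rng, max(4, spacer_total // n_repeats)))
        landmarks["core_aa_start"] = first_rep
        landmarks["n_repeats"] = n_repeats
        landmarks["has_paar"] = has_paar

        if domain_nt is not None:
            add(_random_aa(rng, 4))  # linker
            motif = [
                _MOTIF_CONSERVED.get(i) or _AA20[rng.integers(0, 20)]
                for i in range(_MOTIF_LEN)
            ]
            mstart = add("".join(motif), [i in _MOTIF_CONSERVED for i in range(_MOTIF_LEN)])
            landmarks["motif_aa_start"] = mstart
        else:
            landmarks["motif_aa_start"] = None

        aa_rest = "".join(aa_parts)
        body = _encode_aa(rng, aa_rest)
        prot_nt = np.zeros(len(body), dtype=bool)
        for i, p in enumerate(protected_aa):
            if p:
                prot_nt[3 * i : 3 * i + 3] = True
        nt = "ATG" + body + (domain_nt or "") + "TAA"
        protected = np.concatenate([
            np.ones(3, dtype=bool),
            prot_nt,
            np.zeros(len(domain_nt) if domain_nt else 0, dtype=bool),
            np.ones(3, dtype=bool),
        ])
        if cfg.motif_degrading:
            protected = np.zeros(len(nt), dtype=bool)
            protected[:3] = protected[-3:] = True
        meta = dict(
            role=role,
            prototype=prototype,
            n_repeats=n_repeats,
            has_paar=has_paar,
            motif_aa_start=landmarks["motif_aa_start"],
            domain_len_nt=len(domain_nt) if domain_nt else 0,
            pseudogene=False,
            lesion_aa=None,
            hgt=False,
            deleted=False,
            short_control=role == "short_control",
        )
        gene = _Gene(gene_id, "rhs", _s2a(nt), protected, meta)
        if _rhs_gene_valid(gene):
            return gene
    raise RuntimeError(f"could not build a clean Rhs gene after {_MAX_ATTEMPTS} tries")


# ---------------------------------------------------------------- toxin pool

def _generate_pool(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    """Toxin-domain prototypes and their cognate immunity gene bodies."""
    rng = _rng(cfg.seed, 1)
    lo, hi = cfg.domain_length_range

    def draw_domain() -> str:
        for _ in range(_MAX_ATTEMPTS):
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            nt = _random_codons(rng, n_codons)
            aa = _translate(nt)
            if _domains.locate_dpxg(aa) is not None:
                continue
            if _genes.count_pattern(aa, _genes.RHS_REPEAT_PATTERN):
                continue
            if _genes.detect_paar(aa) is not None:
                continue
            # a spurious motif window can start at the planted motif's second
            # tetrad (exact DPxG, zero mismatches) and close on domain
            # residues 18/19/21; such a domain would poison every gene built
            # around it, so reject it here
            if len(aa) >= 22 and (
                (aa[18] == "D") + (aa[19] == "P") + (aa[21] == "G") >= 2
            ):
                continue
            return nt
        raise SeparabilityError("cannot draw a clean toxin domain")

    pool = [draw_domain() for _ in range(cfg.pool_size)]
    limit = cfg.cluster_threshold - cfg.separability_margin
    for _round in range(20):
        clash = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if pairwise_identity(pool[i], pool[j]) >= limit:
                    clash = j
                    break
            if clash is not None:
                break
        if clash is None:
            break
        pool[clash] = draw_domain()
    else:
        raise SeparabilityError(
            "toxin pool not separable at "
            f"{limit:.2f} after bounded regeneration; shrink pool_size or "
            "widen domain_length_range"
        )
    ilo, ihi = cfg.immunity_length_range
    immunities = [
        _random_codons(rng, int(rng.integers(ilo // 3, ihi // 3 + 1)))
        for _ in range(cfg.pool_size)
    ]
    return pool, immunities


def generate_toxin_pool(config: SimulationConfig) -> list[str]:
    """Generate the pool of distinct toxin-domain prototypes (nt).

    Deterministic for a given seed; pairwise identities are verified to sit
    below ``cluster_threshold - separability_margin`` so planted clusters
    are recoverable, with bounded regeneration (raises
    :class:`SeparabilityError` when unsatisfiable).
    """
    return _generate_pool(config)[0]


# ---------------------------------------------------------------------- tree

@dataclass
class _Node:
    name: str | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _random_tree(rng: np.random.Generator, n: int) -> _Node:
    nodes = [_Node(name=f"S{i + 1:02d}") for i in range(n)]
    for nd in nodes:
        nd.length = 0.2 + rng.exponential(0.8)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _Node(length=0.2 + rng.exponential(0.8),
                       children=[nodes[i], nodes[j]])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    _normalize_height(root)
    return root


def _height(node: _Node) -> float:
    if not node.children:
        return node.length
    return node.length + max(_height(c) for c in node.children)


def _scale(node: _Node, f: float) -> None:
    node.length *= f
    for c in node.children:
        _scale(c, f)


def _normalize_height(root: _Node) -> None:
    h = max((_height(c) for c in root.children), default=0.0)
    if h > 0:
        for c in root.children:
            _scale(c, 1.0 / h)


def _parse_newick(newick: str) -> _Node:
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")

    def conv(nd) -> _Node:
        out = _Node(
            name=nd.taxon.label if nd.taxon else None,
            length=nd.edge.length if nd.edge.length is not None else 1.0,
            children=[conv(c) for c in nd.child_nodes()],
        )
        return out

    root = conv(t.seed_node)
    root.length = 0.0
    _normalize_height(root)
    return root


def _newick(node: _Node) -> str:
    def rec(nd: _Node) -> str:
        if not nd.children:
            return f"{nd.name}:{nd.length:.6f}"
        inner = ",".join(rec(c) for c in nd.children)
        return f"({inner}):{nd.length:.6f}"

    return rec(node)[: -len(f":{node.length:.6f}")] + ";"


# ------------------------------------------------------------------ mutation

def _mutate_inplace(
    rng: np.random.Generator, gene: _Gene, rate: float, bl: float
) -> None:
    """Apply Poisson point substitutions to one gene copy along one branch.

    Substitutions avoid protected positions and are resampled when they
    would create an in-frame stop codon (all planted genes are coding);
    for Rhs genes the whole branch is retried if a spurious motif appears.
    """
    n_sites = int((~gene.protected).sum())
    n_mut = rng.poisson(rate * bl * n_sites)
    if n_mut == 0:
        return
    parent_nt = gene.nt.copy()
    for _attempt in range(_MAX_ATTEMPTS):
        gene.nt = parent_nt.copy()
        free = np.flatnonzero(~gene.protected)
        for _ in range(n_mut):
            for _try in range(20):
                pos = int(free[rng.integers(0, len(free))])
                new = int(rng.integers(0, 4))
                if new == gene.nt[pos]:
                    new = (new + 1 + int(rng.integers(0, 3))) % 4
                old = gene.nt[pos]
                gene.nt[pos] = new
                codon_i = pos // 3
                codon = "".join(_NT[b] for b in gene.nt[3 * codon_i : 3 * codon_i + 3])
                if codon in _STOPS:
                    gene.nt[pos] = old  # would truncate the gene; resample
                    continue
                break
        if gene.kind != "rhs" or gene.meta.get("pseudogene") or _rhs_gene_valid(gene):
            return
    raise RuntimeError("could not apply motif-preserving mutations")


def _pseudogenize(rng: np.random.Generator, gene: _Gene) -> None:
    """Introduce one premature stop downstream of the repeat region."""
    prot = gene.protein()
    core = _genes.scan_rhs_core(prot, min_repeats=1)
    first_ok = (core[0][1] if core else 10) + 1
    n_codons = len(gene.nt) // 3
    eligible = [
        i for i in range(first_ok, n_codons - 1)
        if not gene.protected[3 * i : 3 * i + 3].any()
    ]
    if not eligible:
        raise RuntimeError("no eligible codon for pseudogenization")
    order = rng.permutation(len(eligible))
    target: tuple[int, str] | None = None
    for k in order:  # prefer a codon one substitution away from a stop
        i = eligible[int(k)]
        codon = "".join(_NT[b] for b in gene.nt[3 * i : 3 * i + 3])
        for pos in range(3):
            for nt in _NT:
                cand = codon[:pos] + nt + codon[pos + 1 :]
                if cand != codon and cand in _STOPS:
                    target = (i, cand)
                    break
            if target:
                break
        if target:
            break
    if target is None:
        target = (eligible[int(order[0])], "TAA")
    i, stop = target
    gene.nt[3 * i : 3 * i + 3] = _s2a(stop)
    gene.meta["pseudogene"] = True
    gene.meta["lesion_aa"] = i


# ------------------------------------------------------------------- truth

@dataclass
class SimulationTruth:
    """Ground truth of one simulation run."""

    tree_newick: str
    strains: pd.DataFrame  # strain_id, species, host, region, t6ss1, t6ss23
    genes: pd.DataFrame  # one row per planted gene (toxins, immunity, ...)
    pool_toxins: list[str]
    pool_immunity: list[str]
    t6ss1_genes: dict[str, str]
    t6ss23_genes: dict[str, str]
    housekeeping_genes: dict[str, str]
    config: SimulationConfig

    @property
    def sharing(self) -> pd.DataFrame:
        """strain x prototype counts of toxin genes present in the genome."""
        tox = self.genes[(self.genes.kind == "rhs_toxin")]
        tab = tox.pivot_table(index="strain_id", columns="prototype",
                              values="gene_id", aggfunc="count", fill_value=0)
        return tab.reindex(self.strains.strain_id, fill_value=0)

    def to_json(self) -> str:
        payload = {
            "tree_newick": self.tree_newick,
            "strains": self.strains.to_dict(orient="records"),
            "genes": self.genes.where(pd.notna(self.genes), None)
            .to_dict(orient="records"),
            "pool_toxins": self.pool_toxins,
            "pool_immunity": self.pool_immunity,
            "t6ss1_genes": self.t6ss1_genes,
            "t6ss23_genes": self.t6ss23_genes,
            "housekeeping_genes": self.housekeeping_genes,
            "config": asdict(self.config),
        }

        def default(o):
            if isinstance(o, (np.integer, np.floating, np.bool_)):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(payload, indent=1, default=default)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        cfg = d["config"]
        for k, v in list(cfg.items()):
            if isinstance(v, list):
                cfg[k] = tuple(v)
        return cls(
            tree_newick=d["tree_newick"],
            strains=pd.DataFrame(d["strains"]),
            genes=pd.DataFrame(d["genes"]),
            pool_toxins=d["pool_toxins"],
            pool_immunity=d["pool_immunity"],
            t6ss1_genes=d["t6ss1_genes"],
            t6ss23_genes=d["t6ss23_genes"],
            housekeeping_genes=d["housekeeping_genes"],
            config=SimulationConfig(**cfg),
        )


# ------------------------------------------------------------ main generator

def _root_genome(cfg: SimulationConfig, pool, immunities, rng):
    """Plan and build the ancestral gene complement."""
    hk = {f"HK{i + 1:02d}": _random_codons(rng, int(rng.integers(300, 500)))
          for i in range(cfg.n_housekeeping)}
    t1 = {f"T1G{i + 1:02d}": _random_codons(rng, int(rng.integers(200, 500)))
          for i in range(cfg.n_t6ss1_genes)}
    t23 = {f"T23G{i + 1:02d}": _random_codons(rng, int(rng.integers(200, 500)))
           for i in range(cfg.n_t6ss23_genes)}

    genes: list[_Gene] = []
    for gid, body in hk.items():
        genes.append(_coding_gene(gid, "housekeeping", body))
    for gid, body in t1.items():
        genes.append(_coding_gene(gid, "t6ss1", body))
    for gid, body in t23.items():
        genes.append(_coding_gene(gid, "t6ss23", body))

    n_loci = int(rng.integers(cfg.loci_per_strain_range[0],
                              cfg.loci_per_strain_range[1] + 1))
    proto_order = list(rng.permutation(cfg.pool_size))
    proto_iter = iter(proto_order)
    orphan_reps = max(4, math.ceil(0.75 * cfg.repeats_per_core))
    trunc_reps = max(4, cfg.repeats_per_core // 2)

    short_rng_lengths = [int(rng.integers(4, 13)) * 3
                         for _ in range(cfg.n_short_domain_controls)]
    short_domains = [_random_codons(rng, n // 3) for n in short_rng_lengths]
    short_imms = [_random_codons(rng, int(rng.integers(100, 160)))
                  for _ in short_domains]

    def next_proto() -> int:
        try:
            return int(next(proto_iter))
        except StopIteration:
            raise ValueError(
                "pool_size too small for the sampled locus plan; "
                "increase pool_size or reduce loci/orphans"
            ) from None

    gnum = 0
    for li in range(n_loci):
        slots = 1 + int(rng.integers(cfg.orphans_per_locus_range[0],
                                     cfg.orphans_per_locus_range[1] + 1))
        trunc_slot = None
        if slots > 1 and rng.random() < cfg.p_n_truncated:
            trunc_slot = 1 + int(rng.integers(0, slots - 1))
        for si in range(slots):
            gnum += 1
            proto = next_proto()
            if si == 0:
                role, reps, paar = "lead", cfg.repeats_per_core, True
            elif si == trunc_slot:
                role, reps, paar = "n_truncated", trunc_reps, False
            else:
                role, reps, paar = "orphan", orphan_reps, False
            tox = _build_rhs_gene(rng, cfg, f"RHS{gnum:03d}", role, reps, paar,
                                  pool[proto], proto)
            tox.meta.update(locus=li, slot=si)
            genes.append(tox)
            imm = _coding_gene(f"IMM{gnum:03d}", "immunity", immunities[proto],
                               dict(prototype=proto, locus=li, slot=si,
                                    partner=tox.gene_id, cognate_state="intact"))
            genes.append(imm)
        if li == 0:
            for sd, (dom, ibody) in enumerate(zip(short_domains, short_imms)):
                gnum += 1
                tox = _build_rhs_gene(rng, cfg, f"RHS{gnum:03d}", "short_control",
                                      orphan_reps, False, dom, -(sd + 1))
                tox.meta.update(locus=li, slot=slots + sd)
                genes.append(tox)
                genes.append(_coding_gene(
                    f"IMM{gnum:03d}", "immunity", ibody,
                    dict(prototype=-(sd + 1), locus=li, slot=slots + sd,
                         partner=tox.gene_id, cognate_state="intact")))
        if rng.random() < cfg.p_toxinless:
            gnum += 1
            tox = _build_rhs_gene(rng, cfg, f"RHS{gnum:03d}", "toxinless",
                                  orphan_reps, False, None, -999)
            tox.meta.update(locus=li, slot=99)  # 3' end of the locus
            genes.append(tox)
    return genes, hk, t1, t23, n_loci


def _leaf_events(cfg: SimulationConfig, rng, genes: list[_Gene],
                 pool: list[str], immunities: list[str]) -> None:
    rhs = [g for g in genes if g.kind == "rhs"]
    imm_by_slot = {(g.meta["locus"], g.meta["slot"]): g
                   for g in genes if g.kind == "immunity"}
    loci = sorted({g.meta["locus"] for g in rhs})
    present_protos = {g.meta["prototype"] for g in rhs
                      if not g.meta["deleted"] and g.meta["prototype"] >= 0}
    pool_n = cfg.pool_size
    # horizontal domain import
    for li in loci:
        if rng.random() >= cfg.p_hgt:
            continue
        slots = [g for g in rhs
                 if g.meta["locus"] == li and g.meta["domain_len_nt"] >= 40
                 and not g.meta["short_control"] and not g.meta["deleted"]]
        if not slots:
            continue
        target = slots[int(rng.integers(0, len(slots)))]
        candidates = [p for p in range(pool_n) if p not in present_protos]
        if not candidates:
            continue
        newp = candidates[int(rng.integers(0, len(candidates)))]
        dom = pool[newp]
        m = target.meta
        dstart = len(target.nt) - 3 - m["domain_len_nt"]
        nt = target.seq
        new_nt = nt[:dstart] + dom + nt[-3:]
        new_prot = np.concatenate([
            target.protected[:dstart],
            np.zeros(len(dom), dtype=bool),
            target.protected[-3:],
        ])
        present_protos.discard(m["prototype"])
        present_protos.add(newp)
        target.nt = _s2a(new_nt)
        target.protected = new_prot
        m.update(prototype=newp, domain_len_nt=len(dom), hgt=True)
        imm = imm_by_slot.get((m["locus"], m["slot"]))
        if imm is not None:
            fresh = _coding_gene(imm.gene_id, "immunity", immunities[newp],
                                 dict(imm.meta, prototype=newp))
            imm.nt, imm.protected, imm.meta = fresh.nt, fresh.protected, fresh.meta
    # orphan immunity: drop the toxin, keep the immunity gene
    for g in rhs:
        if g.meta["role"] in ("orphan", "n_truncated") and not g.meta["deleted"]:
            if rng.random() < cfg.p_orphan_immunity:
                g.meta["deleted"] = True
                imm = imm_by_slot.get((g.meta["locus"], g.meta["slot"]))
                if imm is not None:
                    imm.meta["cognate_state"] = "deleted"
    # pseudogenization
    for g in rhs:
        if g.meta["deleted"] or g.meta["short_control"] or g.meta["pseudogene"]:
            continue
        if g.meta["role"] == "toxinless":
            continue
        if rng.random() < cfg.p_pseudogenize:
            _pseudogenize(rng, g)
            imm = imm_by_slot.get((g.meta["locus"], g.meta["slot"]))
            if imm is not None:
                imm.meta["cognate_state"] = "pseudogene"


def simulate_strains(
    config: SimulationConfig,
) -> tuple[list[StrainRecord], SimulationTruth]:
    """Generate strain genomes plus full ground truth.

    Deterministic: identical config (including seed) gives byte-identical
    genomes and truth.
    """
    cfg = config
    pool, immunities = _generate_pool(cfg)

    tree_rng = _rng(cfg.seed, 2)
    if cfg.tree_mode == "fixed_newick":
        if not cfg.fixed_newick:
            raise ValueError("fixed_newick tree_mode needs a newick string")
        root = _parse_newick(cfg.fixed_newick)
        if len(root.leaves()) != cfg.n_strains:
            raise ValueError("fixed tree leaf count != n_strains")
    elif cfg.n_strains == 1:
        root = _Node(name="S01")
    else:
        root = _random_tree(tree_rng, cfg.n_strains)

    root_rng = _rng(cfg.seed, 3)
    genes0, hk, t1, t23, n_loci = _root_genome(cfg, pool, immunities, root_rng)
    if not genes0:
        raise ValueError("empty locus configuration")

    evo_rng = _rng(cfg.seed, 4)
    event_rng = _rng(cfg.seed, 6)
    rate = cfg.per_branch_substitution_rate
    leaf_state: dict[str, tuple[list[_Gene], bool, bool]] = {}

    def descend(node: _Node, genes: list[_Gene], has1: bool, has23: bool,
                at_root: bool) -> None:
        genes = [g.copy() for g in genes]
        if not at_root:
            for g in genes:
                _mutate_inplace(evo_rng, g, rate, node.length)
            if has1 and evo_rng.random() < cfg.p_t6ss_loss:
                has1 = False
            if has23 and evo_rng.random() < cfg.p_t6ss_loss:
                has23 = False
        if not node.children:
            _leaf_events(cfg, event_rng, genes, pool, immunities)
            leaf_state[node.name] = (genes, has1, has23)
            return
        for c in node.children:
            descend(c, genes, has1, has23, False)

    descend(root, genes0, True, True, True)

    leaf_names = [nd.name for nd in root.leaves()]
    # optional planted horizontal T6SS-1 transfer between the two root clades
    if cfg.t6ss_transfer and len(root.children) == 2:
        # plant the transfer between maximally distant lineages so the
        # resulting incongruence is topologically detectable
        def depth_leaves(node, d=0):
            if not node.children:
                return [(d, node.name)]
            out = []
            for c in node.children:
                out.extend(depth_leaves(c, d + 1))
            return out

        donor = max(depth_leaves(root.children[0]))[1]
        recip = max(depth_leaves(root.children[1]))[1]
        dmap = {g.gene_id: g for g in leaf_state[donor][0] if g.kind == "t6ss1"}
        rgenes, r1, r23 = leaf_state[recip]
        for g in rgenes:
            if g.kind == "t6ss1" and g.gene_id in dmap:
                g.nt = dmap[g.gene_id].nt.copy()
        leaf_state[recip] = (rgenes, True, r23)
        leaf_state[donor] = (leaf_state[donor][0], True, leaf_state[donor][1])

    # strain metadata from the two root clades
    cladeA = {nd.name for nd in (root.children[0].leaves() if root.children else [root])}
    hosts = ("Apis", "Bombus")
    meta_rows = []
    for i, name in enumerate(leaf_names):
        in_a = name in cladeA
        meta_rows.append(dict(
            strain_id=name,
            species="speciesA" if in_a else "speciesB",
            host=hosts[i % 2],
            region="NorthAmerica" if in_a else "SoutheastAsia",
            t6ss1=leaf_state[name][1],
            t6ss23=leaf_state[name][2],
        ))
    strains_df = pd.DataFrame(meta_rows)

    asm_rng = _rng(cfg.seed, 5)
    strain_records: list[StrainRecord] = []
    gene_rows: list[dict] = []
    for name in leaf_names:
        genes, has1, has23 = leaf_state[name]
        contig_id = f"{name}_c1"
        pieces: list[str] = []
        cursor = 0

        def emit(seq: str) -> tuple[int, int]:
            nonlocal cursor
            pieces.append(seq)
            start = cursor
            cursor += len(seq)
            return start, cursor

        def emit_junk(lo: int, hi: int) -> None:
            emit(_random_nt(asm_rng, int(asm_rng.integers(lo, hi))))

        def place_gene(g: _Gene, extra: dict) -> None:
            strand = "+"
            seq = g.seq
            if cfg.randomize_strand and asm_rng.random() < 0.5:
                strand = "-"
                seq = str(Seq(seq).reverse_complement())
            emit(_wall(12))
            start, end = emit(seq)
            emit(_wall(12))
            row = dict(
                strain_id=name, contig_id=contig_id, gene_id=f"{name}|{g.gene_id}",
                kind=extra.pop("kind", g.kind), start=start, end=end,
                strand=strand, **extra,
            )
            gene_rows.append(row)

        emit_junk(300, 600)
        for g in genes:
            if g.kind == "housekeeping":
                place_gene(g, dict(kind="housekeeping"))
                emit_junk(150, 400)
        emit_junk(300, 500)
        if has1:
            for g in genes:
                if g.kind == "t6ss1":
                    place_gene(g, dict(kind="t6ss1"))
                    emit_junk(30, 60)
            emit_junk(400, 600)
        if has23:
            for g in genes:
                if g.kind == "t6ss23":
                    place_gene(g, dict(kind="t6ss23"))
                    emit_junk(30, 60)
            emit_junk(400, 600)

        rhs = [g for g in genes if g.kind == "rhs"]
        imm_by_slot = {(g.meta["locus"], g.meta["slot"]): g
                       for g in genes if g.kind == "immunity"}
        loci = sorted({g.meta["locus"] for g in rhs})
        for li in loci:
            emit_junk(6000, 8000)
            members = sorted((g for g in rhs if g.meta["locus"] == li),
                             key=lambda g: g.meta["slot"])
            locus_id = f"{name}_L{li + 1}"
            # build the locus as one block (relative coords), then place it,
            # optionally reverse-complemented as a unit
            block: list[str] = []
            rel = 0
            rel_rows: list[tuple[dict, int, int]] = []

            def bemit(seq: str) -> tuple[int, int]:
                nonlocal rel
                block.append(seq)
                s = rel
                rel += len(seq)
                return s, rel

            for pos, g in enumerate(members):
                m = g.meta
                arch = ("pseudogene" if m["pseudogene"] else
                        "orphan" if m["role"] == "short_control" else m["role"])
                if not m["deleted"]:
                    bemit(_wall(12))
                    rs, re_ = bemit(g.seq)
                    rel_rows.append((dict(
                        gene_id=f"{name}|{g.gene_id}",
                        kind="rhs_toxin", locus_id=locus_id, position=pos,
                        architecture=arch, prototype=m["prototype"],
                        pseudogene=m["pseudogene"], lesion_aa=m["lesion_aa"],
                        hgt=m["hgt"], short_control=m["short_control"],
                        role=m["role"], n_repeats=m["n_repeats"],
                        has_paar=m["has_paar"],
                        motif_aa_start=m["motif_aa_start"],
                        domain_len_nt=m["domain_len_nt"],
                    ), rs, re_))
                imm = imm_by_slot.get((li, g.meta["slot"]))
                if imm is not None:
                    bemit(_wall(cfg.immunity_spacer_nt))
                    rs, re_ = bemit(imm.seq)
                    bemit(_wall(12))
                    rel_rows.append((dict(
                        gene_id=f"{name}|{imm.gene_id}", kind="immunity",
                        locus_id=locus_id, position=pos,
                        prototype=imm.meta["prototype"],
                        partner_id=f"{name}|{imm.meta['partner']}",
                        cognate_state=imm.meta["cognate_state"],
                        orphan_immunity=imm.meta["cognate_state"] == "deleted",
                    ), rs, re_))
                bemit(_random_nt(asm_rng, int(asm_rng.integers(120, 250))))
            block_seq = "".join(block)
            locus_strand = "+"
            if cfg.randomize_strand and asm_rng.random() < 0.5:
                locus_strand = "-"
                block_seq = str(Seq(block_seq).reverse_complement())
            block_start, _ = emit(block_seq)
            n_block = len(block_seq)
            for row, rs, re_ in rel_rows:
                if locus_strand == "+":
                    start, end = block_start + rs, block_start + re_
                else:
                    start, end = block_start + n_block - re_, block_start + n_block - rs
                gene_rows.append(dict(strain_id=name, contig_id=contig_id,
                                      start=start, end=end,
                                      strand=locus_strand, **row))
        emit_junk(400, 600)
        for i in range(cfg.n_decoy_orfs):
            for _ in range(_MAX_ATTEMPTS):
                aa = _random_aa(asm_rng, int(asm_rng.integers(100, 250)))
                if not _genes.count_pattern(aa, _genes.RHS_REPEAT_PATTERN):
                    break
            decoy = _coding_gene(f"DEC{i + 1:03d}", "decoy",
                                 _encode_aa(asm_rng, aa))
            emit(_wall(12))
            start, end = emit(decoy.seq)
            emit(_wall(12))
            gene_rows.append(dict(strain_id=name, contig_id=contig_id,
                                  gene_id=f"{name}|{decoy.gene_id}",
                                  kind="decoy", start=start, end=end,
                                  strand="+"))
            emit_junk(150, 400)
        emit_junk(200, 400)

        contig = "".join(pieces)
        if not contig:
            raise ValueError("zero-length genome")
        md = strains_df[strains_df.strain_id == name].iloc[0]
        strain_records.append(StrainRecord(
            strain_id=name, contigs={contig_id: contig},
            species=md.species, host=md.host, region=md.region,
        ))

    genes_df = pd.DataFrame(gene_rows)
    truth = SimulationTruth(
        tree_newick=_newick(root) if root.children else f"{root.name};",
        strains=strains_df,
        genes=genes_df,
        pool_toxins=pool,
        pool_immunity=immunities,
        t6ss1_genes=t1,
        t6ss23_genes=t23,
        housekeeping_genes=hk,
        config=cfg,
    )
    _check_truth_invariants(truth)
    return strain_records, truth


def _check_truth_invariants(truth: SimulationTruth) -> None:
    g = truth.genes
    toxins = g[(g.kind == "rhs_toxin") & (g.get("pseudogene") == False)  # noqa: E712
               & (g.get("role") != "toxinless")]
    imm = g[g.kind == "immunity"]
    paired = set(imm.partner_id)
    missing = set(toxins.gene_id) - paired
    if missing:
        raise AssertionError(f"intact toxins without immunity: {sorted(missing)[:3]}")
    orphans = imm[imm.get("orphan_immunity") == True]  # noqa: E712
    intact_ids = set(toxins.gene_id)
    bad = set(orphans.partner_id) & intact_ids
    if bad:
        raise AssertionError("orphan immunity with intact cognate toxin")


# -------------------------------------------------------------- expression

def simulate_expression(
    truth: SimulationTruth,
    strain_id: str | None = None,
    n_replicates: int = 3,
    decay: float = 0.6,
    depth: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Synthetic read counts for Rhs toxin genes of one strain.

    Expression decreases exponentially with 5'->3' position in the locus
    (rate ``decay`` per position), emulating the promoter-proximal
    expression trend of Rhs loci.  Returns (counts genes x replicates,
    lengths, gene table with locus/position).
    """
    rng = _rng(truth.config.seed, 7)
    g = truth.genes
    if strain_id is None:
        strain_id = truth.strains.strain_id.iloc[0]
    tox = g[(g.kind == "rhs_toxin") & (g.strain_id == strain_id)].copy()
    if not len(tox):
        raise ValueError(f"no toxin genes for strain {strain_id}")
    lengths = pd.Series((tox.end - tox.start).to_numpy(), index=tox.gene_id,
                        name="length_nt")
    counts = {}
    rel = np.exp(-decay * tox.position.to_numpy(dtype=float))
    for r in range(n_replicates):
        lam = rel * lengths.to_numpy() / 1000.0 * depth
        counts[f"rep{r + 1}"] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=tox.gene_id)
    table = tox[["gene_id", "locus_id", "position"]].set_index("gene_id")
    return counts_df, lengths, table


# ------------------------------------------------------- codon-pair evolver

def evolve_codon_pair(
    n_codons: int,
    subs_per_site: float = 0.15,
    omega_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Evolve two coding sequences from a common ancestor.

    Proposed substitutions are uniform; synonymous ones are always accepted,
    nonsynonymous ones with probability ``omega_scale`` (1 = neutral, <1 =
    purifying).  Mutations creating stop codons are rejected.  Used to
    calibrate the NG86 estimator.
    """
    rng = rng or np.random.default_rng()
    anc = _random_codons(rng, n_codons)

    def evolve(seq: str) -> str:
        arr = list(seq)
        n_prop = rng.poisson(subs_per_site * len(seq))
        for _ in range(n_prop):
            pos = int(rng.integers(0, len(arr)))
            new = _NT[int(rng.integers(0, 4))]
            if new == arr[pos]:
                continue
            ci = pos // 3
            old_codon = "".join(arr[3 * ci : 3 * ci + 3])
            cand = list(old_codon)
            cand[pos % 3] = new
            cand = "".join(cand)
            if cand in _STOPS:
                continue
            syn = _translate(cand) == _translate(old_codon)
            if syn or rng.random() < omega_scale:
                arr[pos] = new
        return "".join(arr)

    return evolve(anc), evolve(anc)


# ----------------------------------------------------------------- writers

def write_truth(truth: SimulationTruth, out_dir: str | Path) -> None:
    """Emit truth as JSON + GFF3 (1-based inclusive) + newick + metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth.json").write_text(truth.to_json())
    (out / "tree.newick").write_text(truth.tree_newick + "\n")
    truth.strains.to_csv(out / "metadata.tsv", sep="\t", index=False)
    g = truth.genes
    if len(g):
        feats = pd.DataFrame({
            "seqid": g.contig_id,
            "source": "rhskit_sim",
            "type": "gene",
            "start0": g.start,
            "end": g.end,
            "strand": g.strand,
            "attributes": [
                f"ID={r.gene_id};kind={r.kind}" for r in g.itertuples()
            ],
        })
    else:
        feats = pd.DataFrame(columns=["seqid", "source", "type", "start0",
                                      "end", "strand", "attributes"])
    write_gff3(feats, out / "truth.gff3")


def read_truth(out_dir: str | Path) -> SimulationTruth:
    return SimulationTruth.from_json((Path(out_dir) / "truth.json").read_text())


def write_genomes(strains: Sequence[StrainRecord], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in strains:
        p = out / f"{s.strain_id}.fasta"
        write_genome_fasta(s, p)
        paths.append(p)
    return paths


def write_queries(truth: SimulationTruth, out_dir: str | Path) -> None:
    """Reference query FASTAs (ancestral prototypes) for screening."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tox_nt = {f"TOX{i + 1:03d}": s for i, s in enumerate(truth.pool_toxins)}
    write_fasta(tox_nt, out / "toxin_domains.fna")
    write_fasta({k: _translate(v) for k, v in tox_nt.items()},
                out / "toxin_domains.faa")
    imm_nt = {f"IMMQ{i + 1:03d}": "ATG" + s + "TAA"
              for i, s in enumerate(truth.pool_immunity)}
    write_fasta({k: _translate(v[:-3]) for k, v in imm_nt.items()},
                out / "immunity.faa")
    write_fasta({k: _translate("ATG" + v) for k, v in truth.t6ss1_genes.items()},
                out / "t6ss1.faa")
    write_fasta({k: _translate("ATG" + v) for k, v in truth.t6ss23_genes.items()},
                out / "t6ss23.faa")
    write_fasta({k: "ATG" + v + "TAA"
                 for k, v in truth.housekeeping_genes.items()},
                out / "housekeeping.fna")
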