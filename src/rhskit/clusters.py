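"""Greedy identity-threshold clustering of toxin domains and the
strain-toxin co-occurrence network.

Clustering follows the semantics of greedy incremental tools such as
CD-HIT-est: sequences are sorted longest-first, the first sequence founds a
cluster, and every subsequent sequence joins the first existing
representative it matches at or above the identity threshold (member versus
representative, not all-pairs), otherwise it founds a new cluster.  Identity
between two sequences is the number of identical aligned positions in the
alignment that maximises them (gaps and mismatches cost nothing, end gaps
free), normalised by the length of the shorter sequence — the
shorter-sequence normalisation used by the cited tool.  The result is
deterministic and invariant to the input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "pairwise_identity",
    "ToxinCluster",
    "greedy_cluster",
    "build_network",
    "sharing_stats",
]


#: Scoring of the end-gap-free global (semi-global) nucleotide alignment
#: behind :func:`pairwise_identity`: linear gaps so the optimum is a plain
#: Needleman-Wunsch recurrence.
MATCH_SCORE = 2.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0


# combined DP key: score * _KEY_SCALE + identities; identities of any
# alignment fit below _KEY_SCALE, so lexicographic (score, identities)
# comparisons reduce to integer comparisons
_KEY_SCALE = 1 << 20


def _max_identities(a: str, b: str) -> int:
    """Maximum identical aligned positions over all score-optimal
    semi-global (end-gap-free) alignments; row-vectorised NW DP with a
    linear gap penalty."""
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    m = len(B)
    match = int(MATCH_SCORE) * _KEY_SCALE + 1
    mismatch = int(MISMATCH_SCORE) * _KEY_SCALE
    gap = int(GAP_SCORE) * _KEY_SCALE
    j_gap = gap * np.arange(m + 1, dtype=np.int64)
    prev = np.zeros(m + 1, dtype=np.int64)  # leading gaps free
    best_last_col = np.iinfo(np.int64).min
    tmp = np.empty(m + 1, dtype=np.int64)
    for i in range(len(A)):
        delta = np.where(B == A[i], match, mismatch)
        tmp[0] = 0  # leading gaps in `a` are free
        np.maximum(prev[:-1] + delta, prev[1:] + gap, out=tmp[1:])
        # left moves with linear gaps via a prefix max:
        # H[j] = gap*j + max_{k<=j}(tmp[k] - gap*k)
        cur = j_gap + np.maximum.accumulate(tmp - j_gap)
        best_last_col = max(best_last_col, int(cur[m]))
        prev = cur.copy()
    best = max(best_last_col, int(prev.max()))  # trailing gaps free
    return best % _KEY_SCALE


def pairwise_identity(a: str, b: str) -> float:
    """Identical aligned positions in the optimal end-gap-free global
    alignment, normalised by the shorter sequence.

    The alignment maximises match +2 / mismatch -1 / gap -2 with free end
    gaps; among co-optimal alignments the one with the most identities
    defines the count, which makes the value unambiguous and symmetric.
    1.0 for identical sequences and for a sequence nested inside a longer
    one — the shorter-sequence normalisation of greedy clustering tools.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    return _max_identities(a, b) / min(len(a), len(b))


def _hamming_identity(a: str, b: str) -> float:
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a)


@dataclass
class ToxinCluster:
    """One cluster of C-terminal toxin domains at an identity threshold."""

    cluster_id: str
    representative_id: str
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _as_items(domains) -> list[tuple[str, str]]:
    if isinstance(domains, Mapping):
        return [(str(k), str(v)) for k, v in domains.items()]
    items = []
    for d in domains:
        if isinstance(d, tuple):
            items.append((str(d[0]), str(d[1])))
        else:  # duck-typed ToxinDomain
            items.append((d.domain_id, d.nt_seq))
    return items


def greedy_cluster(domains, threshold: float = 0.90) -> list[ToxinCluster]:
    """Greedy longest-first clustering at a nucleotide-identity threshold.

    ``domains`` is a mapping id -> sequence, an iterable of (id, sequence)
    pairs, or an iterable of :class:`rhskit.domains.ToxinDomain`.  A domain
    whose identity to a representative equals the threshold exactly joins
    that cluster (>= rule).
    """
    items = _as_items(domains)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []
    clusters: list[ToxinCluster] = []
    for did, seq in items:
        placed = False
        for ci, (rid, rseq) in enumerate(reps):
            # substitution-only fast path: equal-length Hamming identity is a
            # lower bound on alignment identity
            if len(seq) == len(rseq) and _hamming_identity(seq, rseq) >= threshold:
                ident = 1.0
            else:
                ident = pairwise_identity(seq, rseq)
            if ident >= threshold:
                clusters[ci].member_ids.append(did)
                placed = True
                break
        if not placed:
            reps.append((did, seq))
            clusters.append(
                ToxinCluster(
                    cluster_id=f"C{len(clusters) + 1:04d}",
                    representative_id=did,
                    member_ids=[did],
                )
            )
    return clusters


def build_network(
    clusters: Sequence[ToxinCluster],
    strain_of: Mapping[str, str],
    strain_table: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the bipartite strain <-> toxin-cluster co-occurrence graph.

    ``strain_of`` maps each member domain id to its strain.  Strain nodes
    carry species/host/region attributes when ``strain_table`` (indexed by
    or containing a ``strain_id`` column) is given; edges carry
    ``weight`` = number of member domains of that cluster in that strain.
    """
    meta: dict[str, dict] = {}
    if strain_table is not None:
        df = strain_table
        if "strain_id" in df.columns:
            df = df.set_index("strain_id")
        meta = df.to_dict(orient="index")
    g = nx.Graph()
    strains = sorted(set(strain_of.values()))
    for s in strains:
        g.add_node(s, bipartite="strain", **{
            k: v for k, v in meta.get(s, {}).items()
            if k in ("species", "host", "region")
        })
    for c in clusters:
        g.add_node(c.cluster_id, bipartite="cluster", size=c.size,
                   representative=c.representative_id)
        counts: dict[str, int] = {}
        for m in c.member_ids:
            if m not in strain_of:
                raise KeyError(f"domain {m!r} has no strain assignment")
            counts[strain_of[m]] = counts.get(strain_of[m], 0) + 1
        for s, w in counts.items():
            if s not in g:
                g.add_node(s, bipartite="strain", **{
                    k: v for k, v in meta.get(s, {}).items()
                    if k in ("species", "host", "region")
                })
            g.add_edge(s, c.cluster_id, weight=w)
    return g


def sharing_stats(network: nx.Graph) -> tuple[pd.DataFrame, dict]:
    """Summarise toxin sharing within and between species and regions.

    Returns a per-cluster table (n_strains, n_species, shared within/between
    species flags) and a global summary with category counts plus a
    region-pair sharing map (True where strains from two regions share at
    least one cluster).
    """
    cluster_nodes = [n for n, d in network.nodes(data=True)
                     if d.get("bipartite") == "cluster"]
    rows = []
    region_pairs: dict[tuple[str, str], bool] = {}
    strain_nodes = [n for n, d in network.nodes(data=True)
                    if d.get("bipartite") == "strain"]
    regions = sorted({network.nodes[s].get("region") for s in strain_nodes
                      if network.nodes[s].get("region") is not None})
    for r1 in regions:
        for r2 in regions:
            if r1 < r2:
                region_pairs[(r1, r2)] = False
    for c in sorted(cluster_nodes):
        strains = sorted(network.neighbors(c))
        species = {network.nodes[s].get("species") for s in strains}
        species.discard(None)
        cregions = {network.nodes[s].get("region") for s in strains}
        cregions.discard(None)
        for r1 in cregions:
            for r2 in cregions:
                if r1 < r2:
                    region_pairs[(r1, r2)] = True
        rows.append({
            "cluster_id": c,
            "n_strains": len(strains),
            "n_species": len(species),
            "shared_within_species": len(strains) > 1 and len(species) <= 1,
            "shared_between_species": len(species) > 1,
        })
    per_cluster = pd.DataFrame(
        rows, columns=["cluster_id", "n_strains", "n_species",
                       "shared_within_species", "shared_between_species"])
    summary = {
        "n_clusters": len(rows),
        "n_singleton": int((per_cluster["n_strains"] == 1).sum()) if rows else 0,
        "n_shared_within_species": int(per_cluster["shared_within_species"].sum()) if rows else 0,
        "n_shared_between_species": int(per_cluster["shared_between_species"].sum()) if rows else 0,
        "region_pair_sharing": {f"{a}|{b}": v for (a, b), v in region_pairs.items()},
    }
    return per_cluster, summary
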