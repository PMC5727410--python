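"""End-to-end orchestration: simulate/ingest -> genes -> domains -> immunity
-> clusters -> screen -> stats -> report.

Every stage writes plain TSV/JSON/FASTA artifacts into the run directory, a
manifest records the config hash and seed, and re-running with the same
config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clusters as _clusters
from . import domains as _domains
from . import genes as _genes
from . import immunity as _immunity
from . import screen as _screen
from . import simulate as _simulate
from . import stats as _stats
from .io import StrainRecord, read_genome_fasta, write_fasta


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, plus the generator configuration."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    genomes_dir: str | None = None  # ingest instead of simulate
    min_aa_len: int = 60
    min_repeats: int = 4
    motif_mode: str = "default"
    max_gap_nt: int = 5000
    max_intergenic_nt: int = 200
    cluster_threshold: float = 0.90
    screen_id_min: float = 0.50
    screen_cov_min: float = 0.50
    pair_id_min: float = 0.70
    pair_cov_min: float = 0.70
    t6ss_min_frac: float = 0.8
    trunc_fraction: float = 0.6

    def __post_init__(self) -> None:
        for name in ("cluster_threshold", "screen_id_min", "screen_cov_min",
                     "pair_id_min", "pair_cov_min", "t6ss_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("max_gap_nt", "max_intergenic_nt", "min_aa_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate(table=11))


def run(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    # ------------------------------------------------ simulate or ingest
    truth = None
    if config.genomes_dir:
        paths = sorted(Path(config.genomes_dir).glob("*.fasta"))
        strains = [read_genome_fasta(p) for p in paths]
        if not strains:
            raise FileNotFoundError(f"no FASTA genomes in {config.genomes_dir}")
    else:
        sim_cfg = _simulate.SimulationConfig(
            **{"seed": config.seed, **config.simulate})
        strains, truth = _simulate.simulate_strains(sim_cfg)
        _simulate.write_genomes(strains, out / "genomes")
        _simulate.write_truth(truth, out / "truth")
        _simulate.write_queries(truth, out / "queries")
    stages.append("simulate" if truth is not None else "ingest")

    # --------------------------------------------------------------- genes
    orfs_by_strain: dict[str, dict] = {}
    genes_by_strain: dict[str, list] = {}
    for s in strains:
        orfs = {cid: _genes.find_orfs(seq, min_aa_len=config.min_aa_len,
                                      contig_id=cid)
                for cid, seq in sorted(s.contigs.items())}
        orfs_by_strain[s.strain_id] = orfs
        genes_by_strain[s.strain_id] = _genes.call_rhs_genes(
            s, min_aa_len=config.min_aa_len, min_repeats=config.min_repeats,
            motif_mode=config.motif_mode, max_gap_nt=config.max_gap_nt,
            trunc_fraction=config.trunc_fraction, orfs_by_contig=orfs)
    _immunity.refine_pseudogene_flags(
        genes_by_strain, {s.strain_id: s.contigs for s in strains},
        trunc_fraction=config.trunc_fraction)
    gene_rows = []
    for sid in sorted(genes_by_strain):
        for g in genes_by_strain[sid]:
            gene_rows.append(dict(
                strain_id=sid, contig_id=g.orf.contig_id, gene_id=g.gene_id,
                start=g.orf.start, end=g.orf.end, strand=g.orf.strand,
                locus_id=g.locus_id, position=g.position_in_locus,
                architecture=g.architecture, n_repeats=g.n_core_repeats,
                has_paar=g.has_paar, pseudogene=g.pseudogene,
            ))
    gene_table = pd.DataFrame(gene_rows)
    gene_table.to_csv(out / "genes.tsv", sep="\t", index=False)
    stages.append("genes")

    # ------------------------------------------------------------- domains
    dom_rows, dom_seqs = [], {}
    all_domains = []
    for sid in sorted(genes_by_strain):
        for g in genes_by_strain[sid]:
            dom, reason = _domains.extract_cterm(g, mode=config.motif_mode)
            dom_rows.append(dict(strain_id=sid, gene_id=g.gene_id,
                                 reason=reason,
                                 length_nt=dom.length_nt if dom else 0))
            if dom is not None:
                all_domains.append(dom)
                dom_seqs[dom.domain_id] = dom.nt_seq
    pd.DataFrame(dom_rows).to_csv(out / "domains.tsv", sep="\t", index=False)
    write_fasta(dom_seqs, out / "domains.fna")
    stages.append("domains")

    # ------------------------------------------------------------ immunity
    imm_rows = []
    for s in strains:
        sid = s.strain_id
        orfs_flat = [o for cid in sorted(orfs_by_strain[sid])
                     for o in orfs_by_strain[sid][cid]]
        rhs_ids = frozenset(g.orf.orf_id for g in genes_by_strain[sid])
        for g in genes_by_strain[sid]:
            call = _immunity.pair_immunity(
                g, orfs_flat, max_intergenic_nt=config.max_intergenic_nt,
                rhs_orf_ids=rhs_ids)
            if call is not None:
                imm_rows.append(dict(
                    strain_id=sid, toxin_id=g.gene_id,
                    immunity_orf=call.orf.orf_id,
                    distance_nt=call.distance_nt, orphan=False,
                    pseudogene=call.pseudogene))
        if truth is not None:
            refs = {f"IMMQ{i + 1:03d}": _translate(body)
                    for i, body in enumerate(truth.pool_immunity)}
            for call in _immunity.find_orphan_immunity(
                    s, orfs_flat, genes_by_strain[sid], refs,
                    id_threshold=config.pair_id_min,
                    cov_threshold=config.pair_cov_min,
                    max_intergenic_nt=config.max_intergenic_nt):
                imm_rows.append(dict(
                    strain_id=sid, toxin_id=None,
                    immunity_orf=call.orf.orf_id, distance_nt=None,
                    orphan=True, pseudogene=call.pseudogene))
    pd.DataFrame(imm_rows).to_csv(out / "immunity.tsv", sep="\t", index=False)
    stages.append("immunity")

    # ------------------------------------------------------------ clusters
    clusters = _clusters.greedy_cluster(all_domains,
                                        threshold=config.cluster_threshold)
    strain_of = {d.domain_id: d.strain_id for d in all_domains}
    strain_table = pd.DataFrame(
        [dict(strain_id=s.strain_id, species=s.species, host=s.host,
              region=s.region) for s in strains])
    network = _clusters.build_network(clusters, strain_of, strain_table)
    per_cluster, sharing_summary = _clusters.sharing_stats(network)
    cl_rows = [dict(cluster_id=c.cluster_id, representative=c.representative_id,
                    size=c.size, members=",".join(c.member_ids))
               for c in clusters]
    pd.DataFrame(cl_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    per_cluster.to_csv(out / "cluster_sharing.tsv", sep="\t", index=False)
    write_fasta({c.cluster_id: dom_seqs[c.representative_id] for c in clusters},
                out / "representatives.fna")
    gml = nx.Graph()
    for n, d in network.nodes(data=True):
        gml.add_node(n, **{k: ("" if v is None else v) for k, v in d.items()})
    gml.add_edges_from(network.edges(data=True))
    nx.write_graphml(gml, out / "network.graphml")
    nx.to_pandas_edgelist(network).to_csv(out / "network_edges.tsv",
                                          sep="\t", index=False)
    stages.append("clusters")

    # -------------------------------------------------------------- screen
    screen_out: dict = {}
    if truth is not None:
        proteomes = {
            s.strain_id: {o.orf_id: o.aa_seq
                          for cid in sorted(orfs_by_strain[s.strain_id])
                          for o in orfs_by_strain[s.strain_id][cid]}
            for s in strains}
        t6ss_queries = {k: _translate("ATG" + v)
                        for k, v in {**truth.t6ss1_genes,
                                     **truth.t6ss23_genes}.items()}
        pm = _screen.presence_matrix(
            t6ss_queries, proteomes,
            id_min=config.screen_id_min, cov_min=config.screen_cov_min)
        pm.table.to_csv(out / "presence.tsv", sep="\t", index=False)
        statuses = {}
        for s in strains:
            statuses[s.strain_id] = {
                "T6SS-1": _screen.t6ss_status(
                    pm, sorted(truth.t6ss1_genes), s.strain_id,
                    min_frac=config.t6ss_min_frac),
                "T6SS-2/3": _screen.t6ss_status(
                    pm, sorted(truth.t6ss23_genes), s.strain_id,
                    min_frac=config.t6ss_min_frac),
            }
        pd.DataFrame([dict(strain_id=k, **v) for k, v in statuses.items()]) \
            .to_csv(out / "t6ss_status.tsv", sep="\t", index=False)
        pair_queries = {}
        pairs = []
        for i in range(len(truth.pool_toxins)):
            tq, iq = f"TOX{i + 1:03d}", f"IMMQ{i + 1:03d}"
            pair_queries[tq] = _translate(truth.pool_toxins[i])
            pair_queries[iq] = _translate(truth.pool_immunity[i])
            pairs.append((tq, iq))
        cooc = _screen.toxin_immunity_cooccurrence(
            pairs, pair_queries, proteomes,
            id_min=config.pair_id_min, cov_min=config.pair_cov_min)
        cooc.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
        counts = _screen.rhs_count_by_t6ss_group(gene_table, statuses)
        counts.to_csv(out / "rhs_counts.tsv", sep="\t", index=False)
        screen_out = dict(statuses=statuses,
                          n_violations=int(cooc.violation.sum()))
        stages.append("screen")

    # --------------------------------------------------------------- stats
    stats_out: dict = {}
    if truth is not None:
        groups = {g: sub.n_rhs.tolist()
                  for g, sub in counts.groupby("group") if len(sub) >= 2}
        if len(groups) >= 2:
            res = _stats.anova_tukey(groups)
            stats_out["rhs_anova"] = dict(
                F=res.F, p=res.p,
                pairwise=res.pairwise.to_dict(orient="records"))
        counts_df, lengths, gtab = _simulate.simulate_expression(truth)
        tpm_df = _stats.tpm(counts_df, lengths)
        tpm_df.to_csv(out / "tpm.tsv", sep="\t")
        corr = _stats.position_expression_correlation(
            tpm_df.mean(axis=1).to_dict(),
            gtab.position.to_dict(), gtab.locus_id.to_dict())
        stats_out["position_expression"] = corr.to_dict(orient="records")
        # congruence: housekeeping vs T6SS-1 gene trees
        hk_queries = {k: _translate("ATG" + v)
                      for k, v in truth.housekeeping_genes.items()}
        hk_seqs, t6_seqs = {}, {}
        with_t6 = [s.strain_id for s in strains
                   if statuses[s.strain_id]["T6SS-1"] == "present"]
        orf_nt = {
            s.strain_id: {o.orf_id: o.nt_seq
                          for cid in sorted(orfs_by_strain[s.strain_id])
                          for o in orfs_by_strain[s.strain_id][cid]}
            for s in strains}
        for sid in with_t6:
            hk_parts, t6_parts = [], []
            ok = True
            for q in sorted(hk_queries):
                hit = _screen.best_hit(hk_queries[q], proteomes[sid])
                if hit is None:
                    ok = False
                    break
                hk_parts.append(orf_nt[sid][hit.target_id][:-3])
            for q in sorted(truth.t6ss1_genes):
                hit = _screen.best_hit(
                    _translate("ATG" + truth.t6ss1_genes[q]), proteomes[sid])
                if hit is None:
                    ok = False
                    break
                t6_parts.append(orf_nt[sid][hit.target_id][:-3])
            if ok:
                hk_seqs[sid] = "".join(hk_parts)
                t6_seqs[sid] = "".join(t6_parts)
        if len(hk_seqs) >= 4 and len({len(v) for v in hk_seqs.values()}) == 1 \
                and len({len(v) for v in t6_seqs.values()}) == 1:
            hk_tree = _stats.nj_tree(_stats.pdistance_matrix(hk_seqs, "jc"))
            t6_tree = _stats.nj_tree(_stats.pdistance_matrix(t6_seqs, "jc"))
            (out / "hk_tree.newick").write_text(hk_tree + "\n")
            (out / "t6ss1_tree.newick").write_text(t6_tree + "\n")
            stats_out["congruence_rf"] = _stats.rf_distance(hk_tree, t6_tree)
            stats_out["congruence_n_strains"] = len(hk_seqs)
        (out / "stats.json").write_text(json.dumps(stats_out, indent=1))
        stages.append("stats")

    # -------------------------------------------------------------- report
    rep = {
        "n_strains": len(strains),
        "rhs_per_strain": {sid: len(genes_by_strain[sid])
                           for sid in sorted(genes_by_strain)},
        "n_domains": len(all_domains),
        "n_clusters": len(clusters),
        "sharing": sharing_summary,
        "screen": screen_out,
    }
    (out / "report.json").write_text(json.dumps(rep, indent=1))
    stages.append("report")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(run_dir: str | Path) -> dict:
    """Load the summary report of a completed run."""
    p = Path(run_dir) / "report.json"
    if not p.exists():
        raise FileNotFoundError(f"incomplete run: {p} missing")
    return json.loads(p.read_text())
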