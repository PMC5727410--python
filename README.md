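# rhskit

Comparative-genomics toolkit for **type VI secretion system (T6SS)
Rhs toxin/immunity repertoires** in bacterial genomes, built for questions
like those raised by the bee-gut symbionts *Snodgrassella alvi* and
*Gilliamella apicola*: how many Rhs toxins does each strain carry, how are
their hypervariable C-terminal toxin domains shared within and between
species, and do toxin and immunity genes travel together?

Rhs ("rearrangement hotspot") toxins are large polymorphic T6SS effectors:
a conserved, YD-repeat-rich core ends in the conserved **DPXG(18)DPXG**
amino-acid motif, after which a hypervariable C-terminal toxin domain
begins.  Lead genes carry a PAAR motif that docks them onto the T6SS
needle; shorter "orphan" genes downstream lack it.  Under the C-terminal
displacement model, recombination between conserved cores swaps toxin
domains, so each strain samples a large shared domain pool.  Each intact
toxin is neutralised by a cognate immunity gene immediately downstream;
immunity genes are routinely found orphaned (toxin lost), while the
converse — a toxin without its immunity gene — is not observed.

## What the package does

| module | role |
| --- | --- |
| `rhskit.simulate` | synthetic strain genomes under the C-terminal displacement model, with full ground truth (tree, coordinates, domain pool labels, pairings, T6SS status) |
| `rhskit.genes` | ORF finding, Rhs gene detection (degenerate YD-repeat / PAAR scans), locus assembly, architecture classes (lead / orphan / toxinless / N-truncated / pseudogene) |
| `rhskit.domains` | DPXG(18)DPXG motif location and core/toxin-domain splitting (40-nt default / 200-nt stringent length filters) |
| `rhskit.immunity` | toxin-immunity pairing, orphan-immunity detection, pseudogene flagging against full-length homologs |
| `rhskit.clusters` | greedy 90%-nucleotide-identity clustering of toxin domains; bipartite strain-toxin co-occurrence network and sharing statistics |
| `rhskit.screen` | best-hit identity x coverage presence screening, T6SS status calls, toxin-immunity co-occurrence at 70%/70%, inter-locus mean identity |
| `rhskit.stats` | TPM, Spearman position-expression trend, one-way ANOVA + Tukey HSD, NG86 dN/dS, p-distance / neighbor-joining / Robinson-Foulds congruence |
| `rhskit.pipeline` + `rhskit` CLI | end-to-end orchestration with a YAML config, manifest and reproducible TSV/JSON/GraphML outputs |

## Worked example

Run the whole pipeline on a small simulated world (4 strains, 12-domain
pool):

```sh
rhskit run -o demo --seed 5        # defaults; or -c config.yaml
rhskit report demo
```

Programmatically:

```python
from rhskit.pipeline import PipelineConfig, run, report

cfg = PipelineConfig(seed=5, simulate=dict(n_strains=4, pool_size=12,
                                           n_decoy_orfs=5))
run(cfg, "demo")
print(report("demo"))
```

The report printed for this config (abridged):

```json
{
 "n_strains": 4,
 "rhs_per_strain": {"S01": 8, "S02": 8, "S03": 8, "S04": 8},
 "n_domains": 32,
 "n_clusters": 10,
 "sharing": {
  "n_clusters": 10,
  "n_singleton": 2,
  "n_shared_between_species": 8,
  "region_pair_sharing": {"NorthAmerica|SoutheastAsia": true}
 },
 "screen": {"statuses": {"S04": {"T6SS-1": "present", "T6SS-2/3": "present"},
                         "S03": {"T6SS-1": "absent", "T6SS-2/3": "present"},
                         "...": "..."},
            "n_violations": 0}
}
```

Reading it: each strain encodes 8 Rhs genes; their 32 extractable
C-terminal domains collapse into 10 clusters at 90% nucleotide identity,
8 of which are shared across the two simulated species (the world plants
horizontal domain transfer); `n_violations: 0` means no genome anywhere
carries a toxin domain without its cognate immunity gene at the 70%/70%
screening cutoffs.  Strains S01-S03 have lost the T6SS-1 locus along the
tree, which the identity x coverage screen reports as `absent`.  The run
directory also contains per-gene tables (`genes.tsv`), domain FASTA,
pairing tables, the GraphML network, presence matrices and `stats.json`
(position-expression Spearman rho of -1.0 for the 5'->3' expression decay
in this world, tree-congruence RF distance when estimable).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete default analysis (20 simulated strains, 50-domain
pool: simulation, gene detection, domain splitting, immunity pairing,
clustering/network, presence and co-occurrence screening, statistics) from
scratch, prints a one-line run summary to stderr and writes the results
JSON to `--out`; run artifacts are left in `<out-dir>/acceptance_run/`.

## Scope notes

Read trimming/mapping, differential expression, genome assembly,
annotation, HMM database searches and Bayesian/ML phylogenetics are out of
scope; counts tables, annotations and (optionally) precomputed domain
tables are accepted as inputs instead, and congruence is assessed with
native NJ trees + RF distances.  See `docs/methods.md` for the model,
parameter defaults and known limitations.
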