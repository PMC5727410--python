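# Methods

## The analysis

The package operationalises a comparative survey of T6SS-associated Rhs
toxin/immunity repertoires:

1. **Gene detection.**  ORFs are called on both strands (starts ATG/GTG/
   TTG, bacterial table 11, longest ORF per stop per frame, stop codon
   included in coordinates).  An ORF is an Rhs gene when its translation
   contains at least `min_repeats` (default 4) matches of a degenerate
   YD-repeat pattern (`..G..Y.YDxxGRLxx`-style; configurable).  This
   pattern scan replaces profile-HMM searches for the Rhs core and PAAR
   domains so the package is self-contained; hooks accept precomputed
   domain tables for real genomes, where pattern scans are cruder than
   HMMs.  Neighbouring Rhs genes within `max_gap_nt` (default 5000, the
   notion of a "locus" is not standardised) on one contig form a locus.

2. **Architecture classes.**  pseudogene (premature stop relative to a
   full-length homolog) overrides toxinless (no DPXG motif / no domain),
   which overrides N-truncated (core repeat count < 60% of the locus
   lead's — a stand-in rule, the literature gives no numeric criterion),
   then lead (PAAR-bearing) versus orphan.  Pseudogene calls need a
   cross-genome comparison: a gene is flagged when the co-frame genomic
   extension of its ORF hits a stop before 90% of the homolog length *and*
   the sequence beyond the stop still matches the homolog (without the
   second condition, a homolog that simply carries a longer toxin domain
   would masquerade as evidence of decay).

3. **Domain splitting.**  The DPXG(18)DPXG motif (two DPxG tetrads, 18
   arbitrary residues apart) is located allowing ≤1 mismatch across the six
   conserved residues (default) or 0 (stringent).  When several windows
   match, the most C-terminal wins, since the motif closes the conserved
   core.  The toxin domain is the in-frame suffix after the motif
   (configurable to include it); predictions under 40 nt (default) or
   200 nt (stringent) are discarded.  Whether the length filter should be
   applied before or after alignment-based trimming is ambiguous in the
   source material; it is applied at extraction here.

4. **Immunity pairing.**  Immunity genes have no usable sequence
   signature, so de novo pairing is positional: the nearest co-oriented
   ORF starting within `max_intergenic_nt` (default 200 — the
   operationalisation of "immediately downstream") of the toxin stop.
   Orphan immunity genes are found by homology (70% identity / 70%
   coverage) against a reference immunity set, requiring no intact toxin
   immediately upstream.

5. **Clustering and network.**  Nucleotide identity between two domains is
   the number of identical aligned positions in the optimal end-gap-free
   global alignment (match +2, mismatch −1, gap −2; among co-optimal
   alignments the one with the most identities defines the count, making
   the value unambiguous), normalised by the shorter sequence — the
   shorter-sequence semantics of greedy clustering tools, so a domain
   nested in a longer one scores 1.0.  Clustering is greedy longest-first
   at threshold 0.90 with membership decided against representatives only;
   it is deterministic and invariant to input order.  The co-occurrence
   network is the bipartite strain <-> cluster graph with per-strain
   multiplicities; sharing statistics count within- versus between-species
   clusters and report per-region-pair sharing.

6. **Screening.**  Queries are searched against each genome's ORF proteome
   by local protein alignment (BLOSUM62, gap open −11 / extend −1),
   standing in for translated-genome BLAST; E-value cutoffs are replaced by
   the identity/coverage floors that carry the actual decisions.  A
   lossless k-mer prefilter (shared 5-mer required) skips hopeless targets.
   Identity is counted over aligned columns of the best local alignment,
   coverage is the query span fraction.  Presence needs identity ≥ 0.50
   and coverage ≥ 0.50 by default, with per-query overrides (e.g. a 70%
   identity rule for highly conserved queries like tssH); toxin/immunity
   co-occurrence uses 70%/70% amino-acid cutoffs.  A T6SS is "present"
   when ≥ 80% of its core genes are present, "partial" when some are.

7. **Statistics.**  TPM with exact per-replicate conservation (Σ = 1e6);
   Spearman rank correlation (average-rank ties, two-sided t
   approximation) for the 5'→3' position-expression trend; one-way ANOVA
   with Tukey HSD (studentized-range quantiles via scipy's numerical
   distribution; Tukey–Kramer for unequal n) for Rhs-count contrasts
   between T6SS repertoire groups; Nei–Gojobori (1986) counting dN/dS with
   Jukes–Cantor correction as a self-contained surrogate for ML codon
   models — adequate for the purifying-versus-neutral contrasts made here,
   not for per-branch inference.  Mutational pathways through stop codons
   are skipped (counted as nonsynonymous only if no stop-free pathway
   exists); changes *to* stop codons are excluded from site counts.  ω is
   reported as undefined, with a reason, when dS = 0 or a proportion
   saturates (p ≥ 3/4) — never fabricated.  Congruence between gene sets
   is the Robinson–Foulds distance between neighbor-joining trees built
   from (optionally Jukes–Cantor-corrected) p-distances.

## The simulator

`rhskit.simulate` generates the world the analysis claims to handle, with
exact ground truth:

- **Tree:** uniform random bifurcating topology, branch lengths
  0.2 + Exp(0.8), heights normalised to 1; `per_branch_substitution_rate`
  (default 0.015) is therefore the expected root-to-leaf substitutions per
  site, keeping within-prototype pairwise divergence near 3% (≤ 4%).
- **Toxin pool:** `pool_size` random in-frame domain prototypes
  (120–900 nt) paired with cognate immunity prototypes; pairwise identity
  is verified `< threshold − margin` (0.85 for the 0.90 threshold) with
  bounded regeneration, so planted clusters are separable by construction.
- **Loci:** per locus a PAAR-bearing lead gene (8 core repeats), then
  orphans (6 repeats, no PAAR), optional N-truncated (4 repeats) and
  toxinless 3'-end genes; every toxin is followed 30 nt downstream by its
  immunity gene.  T6SS-1/2-3 core-gene loci, housekeeping genes and decoy
  ORFs (verified free of repeat matches) complete the genome.
- **Events at the leaves:** horizontal domain import (fresh pool prototype
  not already in the strain, immunity swapped along), orphan-immunity
  (toxin deleted, immunity kept) and pseudogenization (a single
  substitution to a stop codon downstream of the repeat region).
- **Exactness guards:** intergenic spacers flanking genes are TTAA-repeat
  "stop walls" (stops in every frame, no start codons, self-reverse-
  complementary), so ORF coordinates equal planted coordinates exactly;
  mutations avoid conserved motif codons and start/stops, are resampled if
  they would create an in-frame stop, and a branch's mutations are redrawn
  if they create a spurious DPXG window.  Pool prototypes whose residues
  18/19/21 could complete a motif window starting at the planted second
  tetrad are rejected at generation.  This is the "motif-preserving"
  regime; `motif_degrading=True` lifts the motif protections.

What the generator does **not** emulate: sequencing error, assembly
fragmentation, indels, recombination breakpoints inside domains,
GC/codon-usage structure, and real intergenic sequence composition.  A
green test therefore certifies the algorithms against the stated model of
locus architecture and divergence — not performance on raw field data,
where HMM-based domain detection and alignment-based gene calling would be
needed upstream.

## Numerical and design choices

- Semi-global identity DP uses a combined integer key
  (score · 2²⁰ + identities), giving the lexicographic
  (score, identities) optimum in one vectorised pass.
- Identity exactly at the clustering threshold joins (≥ rule).
- Tie-breaks: multiple DPXG windows → most C-terminal; immunity-pairing
  distance ties → longest ORF; clustering input order → sorted by
  (length desc, id asc).
- The planted horizontal T6SS transfer used by the congruence checks picks
  maximally distant donor/recipient lineages; a transfer between
  root-adjacent lineages is topologically undetectable in principle.
- Congruence test worlds use 8 strains, rate 0.05 and ≥ 6 concatenated
  housekeeping genes so every internal branch expects ≫ 1 substitutions —
  chosen a priori for identifiability, not fitted.
- NG86 calibration on simulated codon evolution (1000 codons, ~0.08
  subs/site) has per-replicate ω noise of roughly ±0.15; calibration
  claims are made about the mean over 20 replicates.
- All randomness flows from a single integer seed through named
  `numpy` generator streams; identical config ⇒ byte-identical FASTA,
  truth and pipeline outputs.

## Known limitations

- Degenerate-pattern scans are weaker than profile HMMs on real, divergent
  genomes; supply precomputed domain tables there.
- Positional immunity pairing assumes co-orientation and ≤ 200 nt spacing;
  operonic rearrangements would break it.
- The pseudogene test requires a full-length homolog somewhere in the
  dataset; a family pseudogenized in every strain is reported intact.
- NG86 underestimates ω at high divergence and ignores transition/
  transversion bias and codon frequencies.
- NJ + RF congruence is a topology-level surrogate; it does not quantify
  branch-length concordance or support.
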