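# Methods

`cladespec` implements an end-to-end procedure for discovering
lineage-specific gene families — families restricted to one clade, such as
bilaterian-specific genes — from multi-species protein data, together with a
synthetic-data generator that makes every stage testable against a known
ground truth. This note describes the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## The pipeline

Stages run in method order:

1. **ORF preprocessing** (`orf_extraction`). Genome/transcriptome contigs
   are translated in six frames; maximal stop-free stretches of ≥ 25
   residues are ORFs (sequence ends count as boundaries; codons containing
   `N` translate to `X`). Runs of ≥ 9 `X` — sequencing gaps and masked
   repeats — split a sequence, and each flank with ≥ 35 valid residues is
   kept under a new identifier. Transcriptome contigs keep their three
   longest ORFs. ORFs with no local-alignment hit at E < 10 against a
   reference protein set are discarded, and redundancy is removed by greedy
   clustering at 90% identity (identity = matches in the optimal global
   alignment divided by the shorter sequence length; longest sequence
   founds each cluster). Coordinates are 0-based, half-open, forward-strand
   throughout.
2. **Similarity graph and clustering** (`similarity_clustering`).
   All-vs-all affine-gap Smith–Waterman (BLOSUM62, gap open 11 / extend 1)
   with Karlin–Altschul E-values, E = K·m·n·e^(−λS) (λ = 0.267, K = 0.041,
   n = effective database residues). A shared-4-mer prescreen skips pairs
   that cannot produce a significant hit. Hits are classified into the
   standard orthology-graph edge types: **orthologs** (cross-species
   reciprocal best hits per species pair), **in-paralogs** (same-species
   pairs mutually closer than either is to any other species), and
   **co-orthologs** (cross-species pairs connected through a duplication).
   Edge weights are averaged −log10 E (floored at 1e-180), normalized per
   species pair (orthologs/co-orthologs) or per species (in-paralogs) so
   that clade-wide rate differences do not dominate. Markov clustering
   (MCL) alternates expansion (matrix squaring) and inflation (entrywise
   power, default 1.5) on the column-stochastic matrix with self-loops set
   to each node's maximum incident weight; clusters come from attractor
   rows, and singletons are dropped by default.
3. **Taxonomy filtering** (`taxonomy_filters`). Each orthogroup's last
   common ancestor is found on a taxonomy table (NCBI taxdump dialect or a
   3-column TSV). Published composition rules select lineage-specific
   sets, e.g. bilaterian-specific: deuterostomes ≥ 7, lophotrochozoans ≥ 4
   or 0, ecdysozoans ≥ 4 or 0, and no non-bilaterian species. "Or 0" means
   the clade may be absent entirely, but if present must meet its minimum.
4. **Profile validation** (`profile_validation`). Every orthogroup gets a
   progressive multiple alignment (single-linkage identity guide tree,
   profile-profile merges) and a per-column emission profile. Profiles are
   searched all-vs-all with the log-odds co-emission score
   s(i,j) = log2(Σ_a p_i(a)·q_j(a)/f(a)) under local affine-gap dynamic
   programming (gap open 3 bits, extend 0.3 bits, ≥ 20 aligned columns). A
   lineage-specific candidate whose reciprocal best-hit partner contains
   species outside the focal clade betrays an older origin and is removed.
5. **Enrichment statistics** (`annotation_enrichment`). Domain-scan tables
   (PfamScan layout, E < 5e-5) yield transcription-factor counts (ten
   DNA-binding domain prefixes) and poly-zinc-finger counts (≥ 6 zf-C2H2
   copies). Enrichment is tested three ways: upper-tail normal probability
   against the mean ± sd of size-matched random control draws; a binomial
   tail; and a 2×2 Pearson χ² with Yates continuity correction.
6. **PPI statistics** (`network_stats`). STRING-style edge lists (combined
   score ≥ 400 on the 0–1000 scale) over age-annotated proteins give
   per-node degrees, bilaterian-partner fractions, median ± MAD (scaled by
   1.4826), a χ² of B–B/B–M/M–M counts against proportional random pairing
   (df 2; a degree-preserving permutation null is available), Mann-Whitney
   and Kruskal-Wallis comparisons, and seed-anchored subnetworks.

## The synthetic-data generator

`synthetic_data` builds a labelled opisthokont species tree on a fixed
consensus backbone (Fungi vs Metazoa; Porifera, Ctenophora, Cnidaria
outside Bilateria; Deuterostomia vs Protostomia; an arthropod subtree with
Chelicerata, Myriapoda, Crustacea, Insecta). Species counts requested at
internal clades are distributed round-robin over the terminal clades below
them, so fixtures are fully deterministic.

Gene families are born at named internal nodes and evolve down the tree:
per branch and per gene copy, loss with probability `loss_prob` (default
0.05), duplication with `dup_prob` (0.02, suffix `-d<k>`), and i.i.d.
per-site substitution to a uniformly chosen different amino acid with
probability `subst_rate` (0.05). Root sequences are i.i.d. uniform over the
20 amino acids, 100 residues by default. `stem_rate_boost` overrides the
substitution rate on the branch entering a named clade, modelling episodic
stem-lineage divergence. All randomness flows from one seed through named
substreams, so fixing the seed fixes every emitted byte.

The generator also back-translates proteomes into genome contigs (first
codon per amino acid, in-frame stops flanking each CDS, optional
codon-aligned N-runs, optional reverse-complementation) with an embedding
record for oracle tests, and emits domain-annotation and PPI fixtures with
configurable TF/poly-ZF content and within-age-class edge enrichment.

What the generator deliberately does **not** emulate: realistic codon
usage, selection, site-rate heterogeneity, indels (off by default),
residue-similarity structure in substitutions (a mutated site is a random
different amino acid), or genome synteny. Passing tests therefore show
that the pipeline's logic is correct under a clean evolutionary model;
they do not measure sensitivity on real proteins, where substitution
matrices carry much more signal.

## Study conditions and problem sizes

The standard fixture is 30 species (21 bilaterian, 5 non-bilaterian
metazoan, 4 fungi) with 200 families, 10% born at the bilaterian ancestor
and the rest spread over neighbouring nodes — about 2,400 sequences, small
enough that the exhaustive all-vs-all, alignment, and profile-search stages
complete in about a minute on one CPU while still exercising every rule.
The published composition minima and the ≥ 10-species orthogroup selection
presuppose the full 273-species roster, so the pipeline scales both with
fixture size: minima become `max(1, ceil(m · n/273))` and the selection
threshold `max(2, ceil(10 · n/273))`. The scaling factor is explicit in
the config (`rule_scale`, `scale_min_species`).

A lineage-specific call additionally requires the orthogroup's LCA to equal
the focal node. On a small fixture the proportionally scaled minima alone
would admit subclade-born families through the "or 0" clauses (for
example, a deuterostome-only group passes the bilaterian rule); determining
orthogroup ancestors is a first-class pipeline stage and carries that
discrimination.

Recovery is evaluated against birth-node labels, with one refinement: a
focal-born family whose loss history removed an entire side of the clade
(so the LCA of its survivors is no longer the focal node) is excluded from
the recall denominator. Such families are observationally indistinguishable
from subclade-born ones; no composition-based method could recover them.

## Numerical and statistical choices

- **Profile-hit significance.** The score threshold for counting a
  profile-profile hit is calibrated from an empirical null (column-shuffled
  profile pairs), with a Gumbel extreme-value fit and an expected-chance-hit
  budget (default 0.01) spread over all pairwise comparisons. A plain
  per-pair quantile is available but ignores the multiple-testing burden of
  an all-vs-all search.
- **Search-profile pseudocounts.** Profiles built for searching use
  pseudocount α = 5 (the `build_profile` default is α = 1). Under the
  generator's uniform substitution model, emission columns are over-sharp
  and carry no residue-similarity signal, so mismatched columns would cost
  ≈ −2.3 bits each and drown genuine remote homology; heavier smoothing
  brings mismatch costs to ≈ −1 bit while conserved columns keep ≈ +3 bits.
- **Match columns** are those with ≥ 50% occupancy; others are skipped.
- **Binomial tails** are summed in log space; the Yates correction
  subtracts min(0.5, |O−E|) so a balanced table scores exactly 0; control
  draws report the sample (n−1) standard deviation; MAD uses the 1.4826
  consistency constant; rank tests are two-sided, exact when sample sizes
  permit, tie-corrected asymptotic otherwise.
- **Tie-breaking** is deterministic everywhere: smaller E, then larger raw
  score, then lexicographic id for hits; earlier start then frame label for
  equal-length ORFs; lexicographically smallest pair in guide-tree merges.
- **MCL** prunes entries < 1e-5, stops when the maximum entry change is
  < 1e-6, and reports non-convergence (naming the component) after 200
  iterations.

## The over-splitting experiment

The validation stage exists to catch lineage-specific calls that are
fragments of older families. The bundled experiment constructs exactly
that situation: five metazoan-born families carry strong episodic
divergence on the branch into Bilateria (per-site substitution 0.55), and
clustering is run with an over-stringent E cutoff (1e-10). The sequence
graph then disconnects across the stem and each such family yields a
bilaterian-only cluster — which passes the composition filter — plus a
non-bilaterian cluster. Their profiles remain each other's reciprocal best
hits above the calibrated threshold, and the correction removes the
bilaterian fragments. Inflation alone does not reproduce this on the
generator's homogeneous-divergence families: the log-scale weights and the
per-species-pair normalization flatten bridge/clique contrast, so MCL
passes from no splitting directly to all-singletons as inflation grows.
The demonstrated mechanism (episodic divergence defeating sequence-level
search while profile comparison still links the halves) is the same
phenomenon the validation stage targets on real data.

## Known limitations

- The internal aligner and E-value model stand in for a full search tool;
  constants are fixed rather than estimated per scoring system.
- Profile search has no secondary-structure term and no analytic E-value;
  significance is purely empirical-null-based.
- The proportional-pairing null for the PPI class test ignores degree
  heterogeneity (the permutation null addresses this at extra cost); under
  sampling without replacement it is conservative.
- Progressive alignment has no iterative refinement; for deeply diverged
  families the guide tree is driven by noisy pairwise identities.
- The taxonomy table assumes unique clade-label names among the labels the
  rules reference.
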