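# Methods

This note records the models, conventions and design choices behind
`modevol`, in the order data flows through the pipeline.

## Simulator

### Species trees

`simulate_species_tree` draws a Yule (pure-birth) tree: speciation rate 1
per lineage, exponential waiting times, one extra waiting time after the
last speciation so tip branches have positive length. Branch lengths are in
**coalescent units** (time divided by effective population size); a
`branch_scale` multiplier adjusts overall depth and `subs_scale` converts
coalescent units to expected amino-acid substitutions per site for the
sequence layer. Any externally supplied rooted binary Newick tree with
positive branch lengths can be used instead.

### Module histories: duplication, loss, lineage sorting

Each family starts with `n_init_modules` module lineages at the species
root. The history has three layers:

1. **Ancestral paralogy.** With more than one ancestral module, the loci are
   joined by duplication nodes *above* the species root at fixed spacing
   (`ancestral_spacing`, default 10 coalescent units; join order random).
   This models ancestral modules as long-established paralog lineages —
   the situation of real peptaibiotic A-domain clades, whose divergence
   predates the sampled radiation. An earlier design that coalesced root
   lineages freely (exponential stems) was discarded: it leaves a
   substantial fraction of loci with near-zero stems, i.e. sub-families
   that no tree method could resolve, and it wrongly lets lineages of
   different loci coalesce.
2. **Locus tree (forward).** On every species branch each live module
   lineage experiences duplications (rate `dup_rate` λ) and losses (rate
   `loss_rate` μ) as independent Poisson processes per coalescent unit. A
   duplication inserts the copy immediately after its template in the
   gene's N→C module order; a loss removes the lineage outright (no
   truncated "relic" modules are modelled). At speciations surviving
   lineages copy into both daughters. Event times are measured from the
   rootward end of the branch; species branches are identified by the label
   of the branch's child node, with internal nodes auto-labelled by a hash
   of their sorted leaf set.
3. **Gene tree (backward).** One gene lineage per surviving tip module.
   Within every locus-tree branch, k lineages coalesce at rate k(k−1)/2 per
   coalescent unit. At a duplication node the daughter locus's lineages are
   forced to coalesce at the duplication instant and the resulting single
   lineage coalesces with a uniformly chosen resident lineage of the parent
   locus at that instant. This conditioning is deliberate: every copy of a
   new locus physically descends from one resident gene at the moment of
   duplication. The unconditioned variant (merge pools, coalesce freely)
   lets daughter lineages drift past the duplication and produces gene-tree
   topologies in which parsimony infers duplications that never happened —
   it distorts exactly the counts the downstream analysis studies. Lineages
   remaining at the family origin coalesce freely above it.

Ground truth exported per run: the event log (family, type, branch, time,
template and copy lineage ids), true gene trees with branch lengths in
coalescent units, tip architectures (ordered module lists per species per
family), and true ortholog pairs — cross-species module pairs whose
locus-tree MRCA is a speciation (the per-locus root node at the species
root counts as the root speciation; pairs meeting only at ancestral or
within-tree duplication nodes are paralogs).

Remaining idealisation: parsimony overcounting is still possible when a
duplication captures one of two not-yet-coalesced resident lineages; the
probability per duplication on an internal branch is ≈ (5/3)/τ for branch
length τ, which the no-ILS validation regime (below) makes negligible.

### Sequences

Root sequence uniform over the 20 amino acids; along each gene-tree branch
of length b the number of substitutions is Poisson(L · b · `subs_scale`),
each hit replacing the residue with a uniformly chosen different residue
(20-state Jukes–Cantor analogue). Expected observed proportion of differing
sites between sequences at distance d substitutions/site is
p = (19/20)(1 − e^(−20d/19)), which the tests check by simulation. No
indels, no rate heterogeneity across sites, no nucleotide layer.

## Domain mining

The profile is an ungapped position-specific log-odds score matrix rather
than a full profile HMM: downstream analysis needs module coordinates and a
column-for-column extraction, not insert/delete alignment subtleties. Match
columns are seed-alignment columns with < 50 % gaps; scores are base-2
log-odds against a uniform 0.05 background with pseudocount 1 (every score
finite). The scan slides a window of the profile length, keeps windows at or
above `threshold_frac × max_score` (default 0.5), resolves overlaps greedily
by descending score (ties to the smaller start coordinate), and discards
hits shorter than `min_len` = 100 residues — the standard short-fragment
filter, applied to amino-acid length. Unknown residues score 0 bits (the
background) with a warning. Coordinates are 1-based inclusive everywhere;
because hits are fixed-length windows, extracted modules are implicitly
aligned.

The threshold and the filter interact as intended: a profile shorter than
`min_len` can never produce an accepted hit.

## Tree building

Distances are Poisson-corrected, d = −ln(1 − p), with pairwise deletion of
gapped columns; p ≥ 1 or zero shared columns is an error naming the pair —
except inside bootstrap replicates, where saturated proportions are clipped
(`max_p` = 0.95) so a resample cannot abort a run. Neighbor joining is
delegated to scikit-bio's classic implementation (negative branch estimates
clamped to zero); it is consistent on additive matrices, which the tests
verify by recovering random trees exactly from their path distances.
Bootstrap supports are the integer percentage of column-resampled replicates
containing each internal bipartition of the point-estimate tree. ML
inference is intentionally not re-implemented: externally built trees
(e.g. RAxML with WAG+Γ) enter through Newick import, and every downstream
stage is agnostic to the tree's provenance. Missing supports are treated as
0 wherever a threshold is applied.

## Reconciliation conventions

* LCA mapping as usual; duplication iff a node maps to the species node of
  one of its children.
* Losses per gene edge (u parent of v):
  `dist(M(u), M(v)) − 1 + [u is a duplication]`, summed over edges. No
  losses are charged above the mapping of the gene root, so counts cover
  only the reconciled span.
* Deep-coalescence cost: per species branch, (gene lineages crossing under
  the LCA embedding − 1), floored at zero, summed. With these conventions
  `dc = losses − 2·duplications` holds exactly for single-copy gene trees
  covering every species (and the tests assert it on random instances).
* Unrooted input (trifurcating root representation) is reconciled under
  every one of the 2n − 3 rootings; the minimum of the chosen criterion
  (`dc` by default — the headline statistic; `dup` and `duploss` are
  available) is returned with deterministic tie-breaking: fewest
  duplications, then lexicographically smallest canonical (sorted,
  topology-only) Newick. All cost-optimal rootings are listed in the
  result. Rooted input is accepted as-is with a notice. Multifurcations are
  rejected rather than silently resolved.
* Coalescence depth of a cross-species module pair: the LCA-mapped species
  node of the pair's gene-tree MRCA, classified `at_mrca` iff it equals the
  species-tree MRCA of the two species, else `deeper`.

The brute-force references in `modevol.bruteforce` recompute the mapping by
scanning all species clades, the deep-coalescence cost by counting maximal
single-branch-contained gene subtrees per species branch, and losses by
walking explicit ancestor chains — deliberately different algorithms used
only as oracles.

## Topology test

`regraft` prunes a clade and reattaches it as sister to another clade,
suppressing the degree-2 node; affected branch lengths are set to 1, which
is irrelevant to parsimony reconciliation and keeps serialisations valid.
`compare_hypotheses` reconciles the same gene tree and leaf map under every
hypothesis (baseline: the hypothesis named `original`, else the first) and
reports counts, deltas and a structured verdict. The verdict encodes one
fixed piece of reasoning: an alternative topology that lowers the
deep-coalescence cost purely by requiring fewer losses, with the
duplication count unchanged, is *not* sufficient evidence of HGT, because
loss-absorbable discordance is equally compatible with ancestral
polymorphism and lineage sorting. No statistical topology test (AU/SH) is
attempted.

## Module mapping

Module orthology links operationalise support-threshold module homology:
for a cross-gene module pair, the smallest clade containing both must have
support ≥ threshold (default 50) and contain exactly one module from **at
least one** of the two genes. One-sided multiplicity marks a
lineage-specific duplication whose copies are each genuine orthologs of the
single partner module; two-sided multiplicity means the clade spans
paralogous sub-families and yields no link. Candidates are resolved
one-to-one per gene pair, greedily by higher support, then smaller clade,
then more N-terminal positions — all ties deterministic. Because clades
require a root, unrooted trees are midpoint-rooted first (the standard
rooting for distance trees without an outgroup); supports travel with their
bipartitions. Intragenic duplication groups are the maximal clades with
support ≥ threshold whose ≥ 2 leaves all belong to one gene. Clade
assignment gives each query the label of its nearest strict ancestor
(below the root) whose reference leaves carry a single label; genus tallies
parse the genus from the species field with a configurable regex (default:
prefix before the first underscore).

One-to-one links against a many-to-many ortholog relation put a ceiling on
recall whenever duplications are present; the validation experiment
measures against the full relation anyway and still clears its bar.

## Validation experiment conditions

All experiments are driven by a single seed; sizes were chosen to finish in
a few minutes on one CPU.

* **Oracle agreement / single-copy identity / rooting minimisation** —
  500 / 500 / 200 random instances, species trees ≤ 6 taxa, gene trees ≤ 8
  leaves, multi-copy leaf assignments (full coverage for the single-copy
  identity, where it is a theorem).
* **Coalescent calibration** — three-taxon species trees with internal
  branch τ ∈ {0.5, 1, 2}; 10,000 families each; observed discordance
  compared with (2/3)e^(−τ) at 3 Monte-Carlo SE.
* **Duplication recovery** — balanced six-taxon tree, τ = 1000 per branch,
  one ancestral module, λ = 2.5 × 10⁻⁵, μ = 0, 200 families. The rate and
  depth make the expected number of duplication–speciation boundary
  interactions over the whole experiment ≈ 0.03 (per-event probability
  ≈ (5/3)/τ), so exact parsimony recovery of every logged count is the
  overwhelmingly probable outcome — which is precisely what the no-ILS
  regime is meant to isolate. A null arm (λ = μ = 0, τ = 2) checks that
  concordant families reconcile to zero duplications and discordant
  families have positive deep-coalescence cost.
* **Synteny recovery** — balanced six-taxon tree, τ = 20,
  `subs_scale` = 0.004, three ancestral modules, λ = 5 × 10⁻⁴, μ = 0,
  500-column alignments, 100 bootstrap replicates, 200 families; links at
  threshold 50 scored against the full true ortholog relation.
* **Intragenic detection** — same tree, λ = 3 × 10⁻³ so that terminal-branch
  duplications are common; families conditioned on carrying at least one
  (the only duplications that leave a single-gene clade signature);
  detection succeeds when a reported group contains the template and its
  copy; 200 conditioned families.
* **Mining recovery** — 120-column profile from 8 seed sequences at 10 %
  divergence; 40 proteins with 1–3 planted modules at up to 20 % divergence
  plus 20 decoys; precision/recall of exact-position recovery; a separate
  80-column profile demonstrates the 100-residue filter.
* **Pipeline determinism** — the packaged fixture (6 species, 3 families)
  run twice into fresh directories; all TSV/Newick/FASTA/text outputs must
  be byte-identical.

## What passing these experiments does and does not show

The simulator produces ungapped, equal-length, rate-homogeneous modules
with clean headers; real A-domain data bring alignment uncertainty, indels,
rate variation, annotation errors and incomplete genomes, none of which are
modelled. Passing therefore validates the *logic* of each stage (scanning,
tree building, reconciliation arithmetic, link resolution) and its
determinism, not robustness to real-data noise. The reconciliation counts
of any one empirical study additionally depend on that study's exact tree
inference and reconciliation software conventions (e.g. root charging),
so published counts anchor report formats here, not regression values.

## Known limitations

* Parsimony reconciliation only; no probabilistic or dated reconciliation,
  and HGT enters solely as an alternative-topology comparison.
* The miner has no insert/delete states and no E-value calibration; heavily
  gapped or fragmented domains will score poorly.
* NJ+bootstrap is a fidelity floor, not a substitute for ML inference on
  real data.
* Losses remove whole modules; truncated relic domains are not simulated.
* Midpoint rooting can misplace the root under strong rate heterogeneity;
  supply rooted trees to `modmap` when an outgroup rooting is available.
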