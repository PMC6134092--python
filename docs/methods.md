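# Methods

## Clade universe and aggregation

A rooted OTU phylogeny defines the unit of analysis: every internal
node of out-degree ≥ 2, the root included. Out-degree-1 nodes are
collapsed on ingest (branch lengths summed); multifurcations are kept,
since reference-backbone trees contain them and each such node is still
a well-defined monophyletic group. Clade abundance per sample is the
sum of member-tip counts, computed in one post-order pass; presence is
abundance ≥ a detection threshold (default 1 count, i.e. any detection
counts), and prevalence over a sample set is the number of present
samples. Prevalence is therefore monotone under clade nesting, and the
root's prevalence equals the number of non-empty samples.

Clade identifiers are a pure function of topology and tip labels:
children are ordered by the lexicographically smallest descendant tip
label and internal nodes numbered `node_0`, `node_1`, … in preorder.
Re-parsing any sibling-reordered newick of the same tree reproduces the
same id ↔ tip-set map, so results are joinable across runs and
reorderings.

Midpoint rooting inserts the root at the centre of the longest
tip-to-tip path; ties between equally long paths are broken by the
lexicographically smallest tip pair, for determinism. Rooting and
pruning never change patristic distances among surviving tips (checked
by property tests against independent shortest-path computations).

## The conservation test

Null model: tip-to-community presence rows are reassigned to tips by a
uniform random permutation. This preserves the multiset of presence
rows — every tip-level prevalence, every sample's richness — while
breaking the association between presence pattern and position in the
tree. One shared permutation stream evaluates all clades per draw
(cost: n_perm tree aggregations, and the joint null is consistent
across clades). Defaults: n_perm = 1000; 100 is the documented fallback
for very large trees.

The per-clade null is summarised by its mean and **population** sd
(ddof = 0): the draws *are* the null distribution, not a sample from a
larger population; at n_perm ≥ 100 the distinction is numerically
negligible. The p-value is the parametric upper tail of the z score
(one-sided, "greater"); an empirical option
p = (1 + #{null ≥ obs}) / (n_perm + 1) is available behind a flag for
small n_perm. Degenerate nulls (σ₀ = 0, notably the all-tips root
clade) give p = 1 unless observed > mean (impossible for the root) and
are flagged. BH FDR is applied within one invocation's clade family —
each scan (one group, one tree) is corrected on its own, matching how
separate analyses are conventionally corrected separately. The
`conserved` call is q < α with α defaulting to 0.2.

## Group patterns, statistics, parsimony

*Exclusive* clades are detected in ≥ 1 group sample and in no sample
outside the group — relative to the samples of the invocation, not to
all conceivable hosts. *Uniquely conserved* clades are conserved in
exactly one tested group. The overlap table is the long-format Venn:
clade counts per exact combination of groups; its entries sum to the
size of the union of conserved sets.

Bray-Curtis uses scipy's pairwise implementation (binarising first for
the presence-absence variant); Shannon entropy is in nats. PERMANOVA is
the single-factor distance-based formulation (among/within sums of
squared distances; R² = SSA/SST; pseudo-F with a−1 and n−a df), with
label-permutation p-values on the add-one convention — the smallest
attainable p is 1/(n_perm+1). It is validated against the
Gower-centred-matrix algebra and scikit-bio's implementation. The
Mantel test is Pearson correlation of upper-triangle entries with
simultaneous row/column permutation, one-sided ("greater") by default
as in vegan. Host distances expand tip-level patristic distances to
samples via the species column (conspecifics at 0).

The clustering test compares pairwise patristic distances between
conserved clade nodes with a pooled null: n_boot draws of equally many
internal nodes sampled uniformly **without** size- or depth-matching
(the plain stated procedure; a stratified variant would be a
sensitivity knob), distances pooled across draws, two-sample two-sided
KS. Direction (clustered vs dispersed) is read off the mean distances
and reported alongside. `exclude_nested` drops conserved clades whose
parent is also conserved, a robustness check against signal propagating
along the tree. Clade-to-clade distance is node-to-node patristic
distance between the clades' root nodes.

Gain/loss imputation roots the host tree on the out-group's pendant
edge and runs Fitch parsimony per binary character (one clade's
conservation status across host groups; tips are groups, not samples).
The up-pass clamps the root to the out-group state — for binary
characters the out-group's state always lies in the root's down-pass
set, so the clamped reconstruction attains the Fitch score — and
resolves ambiguous nodes to the parent state (change-delaying). Gains
are 0→1 parent-to-child transitions, losses 1→0; the out-group's own
edge is reported as not assessed. Because ties between equally
parsimonious reconstructions are real, each edge also carries the
number of characters whose change on it appears in some but not all
most-parsimonious reconstructions, computed by exhaustive enumeration
over internal assignments (deduplicated by character pattern; host
trees here have ≤ 16 internal nodes).

## Synthetic data and what it shows

The generator emulates a grouped 16S-style survey: Yule topology with
exponential(1) branch lengths, tips `OTU_0001`…; per-tip occupancy
π_t ~ Beta(α, β) independent of the tree; presence Bernoulli(π_t) per
sample; positive counts 1 + Poisson(mean 10). Default occupancy is
Beta(1, 4) (mean 0.2) — tree-independent occupancy is exactly the
exchangeability assumption of the permutation null, so unplanted
scenarios are valid calibration data. The taxonomy is built by cutting
the tree at fixed fractions of the maximum tip depth per rank
(k__ 0.10 … s__ 0.92), making every rank label monophyletic and ranks
nested by construction. Planting forces a clade to a target prevalence
by giving one uniformly chosen member tip a positive count in each
lacking target sample, which distributes the signal across members the
way a jointly-covering conserved clade would look; exclusivity planting
zeroes members outside the target group. Every planted property is
re-verified from the emitted table and recorded in `truth.json`.

What the generator does **not** emulate: compositional (relative-
abundance) effects, sequencing error and chimeras, sample-depth
variation, or phylogenetically autocorrelated occupancy (a
Brownian-threshold stress scenario is a natural extension but is not a
default). Passing tests therefore demonstrate correctness of the
machinery and calibration under exchangeability, not robustness to
violated exchangeability in real surveys.

### Power depends on occupancy dispersion

A finding worth recording: with strongly overdispersed occupancy such
as Beta(1, 4), the z test has essentially no power at stringent FDR
thresholds, *regardless of sample count or tree size*. For a clade of
k tips the null coverage of a sample is c = 1 − Π(1 − π_t) over a
random tip subset, and the permutation sd of prevalence is dominated by
the between-subset spread of c; for large n_samples, z is capped near
(1 − E c)/sd(c). Under Beta(1, 4) this cap is ≈ 3.4 for cherries and
falls below 2 by k = 4 — observing a clade everywhere cannot exclude
the possibility that it simply drew high-occupancy tips, because such
tips are common under a heavy-tailed occupancy law. The null
false-positive rate remains correctly calibrated (~0.05 at p < 0.05)
throughout; only power collapses. With the same mean occupancy (0.2)
but moderate dispersion, Beta(4, 16), a planted cherry at 100%
prevalence is recovered at q < 0.05 in ~100% of replicates. The
built-in *detection* scenarios (`two_orders_one_planted`,
`three_orders_structure`, `hominids`) therefore use Beta(4, 16)
occupancy, while `null` and the calibration experiments keep the
Beta(1, 4) default. Practically: the test's sensitivity on real data
depends on how heavy-tailed the tip-prevalence distribution is, and a
planted-signal power analysis with the user's own occupancy profile is
advisable before interpreting negative results.

## Numerical and design choices

- Presence means count ≥ 1 by default; the threshold is a parameter
  and applies consistently to tips and clades.
- OTU filtering keeps OTUs present in ≥ 9 samples *and* with total
  count ≥ 10 (both bounds inclusive on the keep side); filtering is
  idempotent and monotone, and is applied to the table as read, before
  any sample subsetting.
- Missing branch lengths parse as 0 with a warning (topological toy
  inputs remain usable); negative lengths are errors.
- All randomness flows through numpy Generators seeded explicitly;
  identical inputs + seed give bit-identical outputs, including across
  the CLI (run manifests record seed, config and input checksums).
- Permutation p-values use the add-one convention; their resolution is
  1/(n_perm+1) by construction.
- Problem sizes in the test suite and acceptance script (64–96-tip
  trees, 20–48 samples, 100–1000 permutations, 100–200 replicates)
  were chosen as the smallest scales at which the measured properties
  are stable; all are parameters, and larger runs only tighten the
  Monte-Carlo error.

## Known limitations

- The permutation null conditions on the observed presence rows, so a
  planted ubiquitous tip contaminates the null of every small clade
  (it inflates σ₀); power is bounded as described above.
- PERMANOVA is single-factor only; no nested or multi-factor designs.
- The clustering null resamples internal nodes uniformly; clade size
  and depth are not matched, so significant clustering conflates
  position and size effects to the extent they correlate.
- Parsimony gain/loss is unweighted Fitch on group-level characters;
  no branch-length-aware or probabilistic ancestral reconstruction.
- Trees with more than a few thousand tips will be slow: aggregation
  is pure Python/numpy per permutation, and patristic matrices are
  O(n²).
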