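# Methods

`sympatree` implements a community-phylogenetics pipeline for asking whether
the spatial structure of phylogenetic turnover among tree communities is more
consistent with sympatric or with allopatric speciation, together with a
ground-truth simulator used to validate every stage end to end.

## Megatree assembly and age calibration

Community phylogenies are built by grafting a family/genus/species taxon list
onto a backbone megatree (`trees.graft_taxa`). A taxon whose genus matches a
backbone node (case-insensitively, whitespace/underscore-normalized) is
attached below it; a taxon whose genus is absent but whose family is present
gets a new genus node first. Congeners therefore form polytomies at the genus
node, and backbone nodes without grafted descendants are pruned. Taxa whose
family is missing are reported and skipped, never silently dropped.

Node ages (Myr) come from a two-column name/age table. `trees.calibrate_bladj`
fixes dated nodes at exactly their table age, sets tips to age 0, and places
every undated node on a path between two fixed ages so that successive ages
are evenly spaced: with `k` undated nodes between ages `a > b`, the `i`-th
gets `a − i·(a−b)/(k+1)`. When a fixed node has several dated descendants
reachable through undated nodes, paths are processed oldest-anchor-first and
oldest-terminal-first; assigned nodes immediately become anchors. This is
deterministic and tends to avoid order-dependent conflicts; a dated
descendant at least as old as its nearest dated ancestor is a hard
calibration error — ages are never clamped, because silent fixes corrupt
every downstream distance.

Polytomies can be re-resolved at random (`trees.resolve_polytomies`):
children are merged pairwise, drawn uniformly, until each node is binary
(each rooted resolution of a trichotomy has probability 1/3), unary nodes
left by pruning are spliced out, and all newly created nodes are re-aged by
the bladj rule while dated nodes keep their ages. A mandatory seed makes the
10k-replicate sensitivity analysis reproducible.

## Metrics

All metrics operate on presence–absence taxon sets over the cophenetic
matrix of the calibrated tree (tip-to-tip path distance = 2 × MRCA age).
Abundances are carried through the data structures but are not used by the
reproduction path, matching the definition of the indices over "different
taxa" with no weighting.

* **MPD** — mean distance over unordered pairs of distinct community members.
* **MNTD** — mean distance from each member to its nearest other member.
* **Jaccard** — |a∩b| / |a∪b|.
* **betaMPD** — mean distance over all ordered cross-community pairs; shared
  taxa contribute zero-distance pairs (the comdist convention). This matters:
  overlapping communities get systematically lower betaMPD/betaMNTD, so any
  distance decay of species overlap induces distance structure in these
  metrics even without phylogenetic signal (see the scenario study below).
* **betaMNTD** — mean, over members of both communities, of the distance to
  the nearest taxon in the opposite community (zero when shared).

**Null models.** betaNRI and betaNTI are the *negative* standardized effect
sizes of betaMPD and betaMNTD: `−(obs − mean(null)) / sd(null)`, so positive
values mean lower turnover than chance. The default null ("pool",
unconstrained) draws a random bijection of the species pool per
randomization: community sizes and the shared-taxon structure of the pair
are preserved exactly. An "independent" variant redraws each community
independently (breaking shared structure) because published wording on this
null is ambiguous; the pool model is the default. A zero-variance null (star
phylogeny) sets a degenerate flag instead of producing infinities, and
degenerate pairs are excluded from significance calls. The significance
threshold defaults to |SES| > 1.96. Each community pair derives its own
random stream from (run seed, CRC32 of the two community ids), so the pair
table is independent of community input order and can be resumed chunk by
chunk. The inner null loops are numba-compiled when numba is available, with
an identical pure-numpy fallback.

## Distance-matrix inference

`stats.mantel` correlates the n(n−1)/2 lower-triangle vectors (Pearson) and
permutes rows and columns of one matrix simultaneously; the p-value is
`(1 + #{|r*| ≥ |r|}) / (1 + n_perm)` (two-sided). `stats.partial_mantel`
residualizes both triangles on the conditioners' triangles (with intercept),
correlates the residuals, and permutes the residuals of one matrix *as a
matrix* (rows and columns together, the residual-permutation scheme); with a
single conditioner the statistic equals the closed-form first-order partial
correlation to machine precision. Default 9999 permutations (no published
count to match).

One-way ANOVA uses the classical `F = MS_between/MS_within`; grouping
letters come from all pairwise Welch t-tests with a Holm correction at the
chosen alpha, assembled by the insert-and-absorb compact-letter-display
algorithm. Welch+Holm was chosen over Tukey HSD because only "one-way ANOVA
(P < 0.05)" semantics are required; the choice is isolated in one function.

"GLM" means a Gaussian identity-link model fit by OLS on log10-transformed
responses (the transform is applied to achieve normal errors, checked by
Shapiro–Wilk; non-positive inputs are a hard error, no epsilon fudging).
`k` counts intercept + slopes + error variance. `stats.dredge` fits all 2^p
predictor subsets including the null model and ranks them by
`AICc = −2logL + 2k + 2k(k+1)/(n−k−1)` with Akaike weights. Multiple-
membership mixed models are out of scope; the fixed-effects analogue (pair
predictors plus a same-aggregation indicator) stands in, and no random-effect
variance decomposition is attempted.

## Spatial aggregations

Community pairs whose betaNTI (default; betaNRI selectable) exceeds 1.96 are
edges of an undirected graph; connected components are the spatial
aggregations. Components are the minimal formalization of reading clusters
off a map; communities in no significant pair stay singleton aggregations,
so one-survey groups remain representable. Grouped within/between summaries
report mean ± sd per aggregation pair with ANOVA letters.

## The simulator

`simulate.simulate_tree_and_ranges` grows a pure-birth (Yule) tree —
extinction would add nuisance variance without touching the logic under
test — over a landscape of `n_regions` region centres spaced
`region_spacing_deg` apart along a latitudinal arc (default 5 × 5.6°,
~620 km between centres, ~2500 km span), each with `communities_per_region`
communities jittered by `community_scatter_deg` (default 0.4°). Climate is
linear in position (MAT ~ latitude at 0.5 °C/°, MAP ~ longitude at
40 mm/°) plus Gaussian noise, so climate differences correlate with distance
by construction, as in the real gradient.

Each lineage carries a range (a set of communities). Founders (default 20)
are seeded round-robin across regions, occupying each community of their
region with probability `founder_occupancy` (0.4). At each of
`n_speciation` (280) events a uniformly chosen lineage splits:

* **sympatric** — both daughters inherit the parent's range (sisters
  co-occur);
* **allopatric** — one daughter keeps the range, the other is placed in a
  different region (sisters disjoint at birth);
* **mixed** — sympatric with probability `fraction_sympatric`.

After either kind of split both daughters may gain unoccupied communities
*within regions they already occupy* with probability `range_expansion`
(0.05) each — gain-only, so the sister co-occurrence/disjointness invariants
are preserved while ranges diffuse across their region over time. Split
times are Yule waiting times rescaled so the root sits at `root_age`
(100 Myr) and tips at 0. After the tree completes, every species colonizes
each unoccupied community independently with probability `exp(−d/λ)`, where
`d` is the km distance to its nearest occupied community and `λ` is
`dispersal_scale_km`. Empty communities trigger dispersal resampling (logged)
and, as a last resort, are seeded with the nearest species. Abundances are
geometric (p = 0.3) per presence.

Two canonical settings bracket the scenarios: strong dispersal limitation
(λ = 50 km, about a tenth of the inter-region spacing) and "near-complete"
dispersal (λ = 500,000 km, colonization probability ≥ 0.994 across the whole
landscape), the in-silico version of secondary contact with broadly
overlapping ranges. Intermediate λ values leave a range-overlap gradient
that betaMNTD detects through shared-taxon zeros *regardless of speciation
mode* — a property of the comdist convention worth keeping in mind when
interpreting betaMNTD–distance correlations on real data.

What the simulator does *not* emulate: real megatree topology and real
divergence-time uncertainty, habitat-driven community assembly (habitats are
decorative labels with a regional bias), abundance structure, sampling
effort differences between surveys, and taxonomic error. Passing the
recovery tests therefore shows that the pipeline detects the co-occurrence
signature of speciation mode when it is present and does not invent it when
absent — not that real data are free of the confounders listed above.

`simulate.taxonomy_from_tree` derives a synthetic taxonomy by cutting the
true tree at a genus age (default 20 Myr; maximal clades younger than the
cut are genera) and a family age (60 Myr), and returns a backbone megatree —
the true tree with genus clades collapsed to genus tips and every remaining
interior node dated at its true age — plus the taxon list. Grafting the
species back and recalibrating reproduces exactly the unresolved-megatree
situation: correct dated deep structure, polytomies at the genus level.

## Validation studies (scripts/acceptance.py, tests/test_acceptance.py)

Problem sizes are the package's own choices, scaled for a desk-size run:

* **Null calibration** — 1000 observed pairs (sizes 16 and 14) drawn from
  the tip pool of one 64-tip tree, 500 randomizations each (scaled down from
  the 10,000 used at publication scale): SES mean ≈ 0, sd ≈ 1, |1.96| flag
  rate ≈ 5%.
* **Mantel validity** — 1000 independent-matrix simulations (n = 20, 999
  permutations): type-I error within [0.035, 0.065]; partial Mantel equals
  the closed form to 1e-12 on 100 instances.
* **Model selection** — 500 repetitions of y = 2x + N(0,1), n = 100; AICc
  ranks the true one-predictor model above the null in ≥ 90%. With any
  spurious candidate predictor added, exact-recovery is capped near 86%
  (the familiar ~15% per-degree-of-freedom overfit rate of AIC-family
  criteria at ΔAICc ≈ 2.1); a unit test pins that retention rate instead of
  pretending it away.
* **Scenario recovery** — 50 sympatric replicates (5 × 10 communities, 300
  species, λ = 50 km, 200 randomizations per pair): betaMNTD–distance Mantel
  positive and significant in ≥ 90% and mean adjusted Rand index of detected
  aggregations vs true regions > 0.9; 50 allopatric near-complete-dispersal
  replicates: significantly positive Mantel in ≤ 20%.
* **Resolution sensitivity** — graft + calibrate the synthetic taxonomy,
  then 100 random resolutions: per-community MPD concordance (slope, r²)
  with the unresolved tree averages within [0.95, 1.05] and ≥ 0.95.

## Numerical choices and edge cases

* Great-circle distances use the haversine formula with R = 6371.0 km.
* Permutation p-values use the +1 convention and a 1e-12 tie tolerance.
* SES degeneracy threshold: null sd ≤ 1e-12.
* Collinear design matrices, constant vectors, non-positive log inputs,
  empty communities and unknown taxa are hard errors naming the offender.
* Ties in bladj path processing break deterministically (older terminal,
  then shorter chain, then traversal order).
* `large`-mode pooling keys morphotypes by (survey, genus-or-family, tag);
  `small` mode drops the survey key. Distinct tags never merge.

## Known limitations

* The bladj path-spacing heuristic is one of several defensible readings of
  even spacing with multiple dated descendants; chains (the common case)
  are unambiguous.
* Mixed (multiple-membership) models for pair data are not provided; the
  fixed-effects stand-in underestimates uncertainty from repeated community
  membership.
* The aggregation step inherits the fragility of connected components: a
  single false-positive edge merges two aggregations. The betaNTI index is
  used by default partly for this reason.
* Climate fields are linear gradients; no interpolation from station data is
  attempted (site climate is an input).
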