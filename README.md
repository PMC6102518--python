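# sympatree

Community phylogenetics of speciation mode: did the species in a set of
communities mostly arise *in place* (sympatric speciation, leaving closely
related species clustered in space) or *apart* (allopatric speciation,
scattering close relatives across the landscape)?

`sympatree` is for ecologists and evolutionary biologists who have (or want
to simulate) a set of community surveys, a backbone phylogeny and node ages,
and who want to run the standard community-phylogenetics argument end to
end:

1. **Megatree assembly** — graft a family/genus/species list onto a backbone
   megatree (phylomatic-style; congeners become polytomies) and calibrate
   node ages with the bladj rule (dated nodes fixed, undated nodes spaced
   evenly between them: with *k* undated nodes between ages *a* > *b*, the
   *i*-th gets *a − i·(a−b)/(k+1)*).
2. **Alpha structure** — MPD (mean pairwise distance) and MNTD (mean nearest
   taxon distance) per community.
3. **Turnover** — Jaccard similarity, betaMPD and betaMNTD per community
   pair, and their negative standardized effect sizes betaNRI/betaNTI
   against an unconstrained permutation null
   (SES = (obs − null mean)/null sd; positive betaNRI/betaNTI = lower
   turnover than chance; |SES| > 1.96 = significant).
4. **Spatial aggregations** — connected components of the graph whose edges
   are significantly-low-turnover pairs.
5. **Inference** — simple/partial Mantel tests of turnover against km
   distance and climate differences, one-way ANOVA with grouping letters,
   Gaussian GLMs ranked by AICc over all predictor subsets ("dredge"), and
   slope/r² concordance checks (dataset and tree-resolution sensitivity).
6. **Ground truth** — a simulator that assembles landscapes under sympatric
   vs allopatric speciation with exponential dispersal limitation
   (`exp(−d/λ)`), so every stage above can be validated against known
   regions and known speciation mode.

The expected signatures: under dispersal-limited **sympatric** speciation,
betaMNTD *increases* with distance, is lower within regions than between,
and low-turnover pairs trace the true regions; under **allopatric**
speciation with secondary contact (broadly overlapping ranges) that signal
is absent.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from sympatree import (
    ScenarioConfig, simulate_tree_and_ranges, cophenetic, all_pair_metrics,
    significant_low_pairs, connected_components, geo_distance_matrix,
    to_square, mantel,
)

config = ScenarioConfig(mode="sympatric", seed=7)   # 300 species, 5x10 communities
ds = simulate_tree_and_ranges(config)
D = cophenetic(ds.tree)
pairs, communities = all_pair_metrics(ds.matrix, D, n_rand=500, seed=1)
print(communities.head(3).round(2).to_string(index=False))

KM, _ = to_square(geo_distance_matrix(ds.sites), "km", ds.matrix.ids)
B, _ = to_square(pairs, "beta_mntd", ds.matrix.ids)
res = mantel(KM, B, n_perm=999, seed=0)
print(f"betaMNTD~distance Mantel: r = {res.r:.3f}, p = {res.p:.4f}")

edges = significant_low_pairs(pairs, index="beta_nti", threshold=1.96)
part = connected_components(ds.matrix.ids, edges)
truth = [ds.regions[c] for c in ds.matrix.ids]
ari = adjusted_rand_score(truth, [part[c] for c in ds.matrix.ids])
print(f"{len(edges)} low-turnover pairs, "
      f"{len(set(part.values()))} aggregations, ARI = {ari:.3f}")
```

prints

```
community  n_taxa    mpd  mntd  log10_mpd  log10_mntd
     c001      32 130.10 24.44       2.11        1.39
     c002      19 152.40 29.91       2.18        1.48
     c003      18 155.39 36.28       2.19        1.56
betaMNTD~distance Mantel: r = 0.589, p = 0.0010
176 low-turnover pairs, 5 aggregations, ARI = 1.000
```

Reading the numbers: each community's MPD (~130–155 Myr) and MNTD
(~24–36 Myr) are its mean pairwise and nearest-taxon cophenetic distances.
The Mantel r of 0.589 (p = 0.001 on 999 permutations) says phylogenetic
turnover toward the tips of the tree rises with geographic distance — the
sympatric signature. The 176 community pairs with betaNTI > 1.96 (turnover
significantly *lower* than the permutation null) form five connected
components that match the five true regions exactly (adjusted Rand = 1.0).

The same steps run from the shell on plain-text files (Newick, Phylocom
ages/sample files, CSV):

```bash
sympatree simulate --mode sympatric --seed 7 --out demo/
sympatree tree bladj --tree demo/tree.nwk --ages demo/ages.txt --out demo/cal.nwk
sympatree metrics beta --sample demo/sample.txt --tree demo/tree.nwk \
    --ages demo/ages.txt --nrand 500 --seed 1 --out demo/pairs.csv
sympatree aggregate detect --pairs demo/pairs.csv --out demo/aggregations.csv
```

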