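# Methods

`ncycomm` implements the statistical workflow used to ask how marine
nitrogen-cycling microbial communities assemble: are taxonomic and
functional-trait compositions governed by deterministic environmental
selection or by stochastic (neutral) processes? The package operates on
derived profile tables — a samples x taxa matrix and a samples x
gene-family ("trait") matrix with per-sample geo-environmental metadata —
and makes no attempt to process sequence data; profiling (read merging,
database search, taxonomic assignment) is upstream of its scope.

## Diversity and biogeography

Alpha diversity is the Shannon-Wiener index H = -sum p_i ln p_i (natural
log; configurable base), observed richness (features with abundance > 0)
and bias-corrected Chao1, S_obs + F1(F1-1)/(2(F2+1)), which requires raw
integer counts because singleton/doubleton tallies are destroyed by
normalization. Beta diversity is Bray-Curtis dissimilarity
D = sum|x-y| / sum(x+y); community similarity is C = 1 - D. Ordination is
PCoA on Bray-Curtis (default) or covariance PCA on centered abundances;
negative PCoA eigenvalues are reported but excluded from variance
fractions.

The latitudinal diversity gradient (LDG) is the OLS regression of
richness on absolute latitude. The distance-decay relationship (DDR)
regresses log10 C on log10 of great-circle distance (haversine, sphere
radius 6371.009 km) over unordered sample pairs. Two pair classes are
excluded from the DDR: same-station pairs (distance 0, log undefined —
vertical profiles are analyzed per layer instead) and pairs with C <= 0;
the count of exclusions is reported. Because pairs are not independent,
the parametric OLS p-value is supplemented with a Mantel-style
permutation p (sample-label shuffling, 999 permutations, add-one rule).

## Permutation tests

PERMANOVA (pseudo-F from within/between sums of squared distances),
ANOSIM (R from between-minus-within mean pair ranks, tie-averaged) and
MRPP (delta = group-size-weighted mean within-group distance;
chance-corrected A = 1 - delta/E[delta_perm]) all permute group labels
freely. Mantel and partial Mantel tests correlate unordered pair entries
(Pearson or Spearman; Spearman rank-transforms the pair multiset once,
which is permutation-invariant) with one-sided p by simultaneous
row/column permutation. Every permutation p uses
p = (#{permuted >= observed} + 1)/(n_perm + 1), so p is never 0 and the
test is exact-level for exchangeable nulls. Environmental distance is
Euclidean over z-scored variables — without standardization a variable
measured in large units (e.g. oxygen in umol/kg) would dominate degrees
Celsius. Per-pathway group contrasts use the two-sided Wilcoxon rank-sum
with Benjamini-Hochberg correction; the enrichment direction is the group
with the higher median. Factor importance fits a random-forest regressor
(500 trees) and scores factors by permutation importance (mean R^2 drop
over 10 shuffles), alongside each factor's univariate OLS r^2.

## PCNM, forward selection and variation partitioning

PCNM spatial eigenvectors are built by truncating the geographic distance
matrix at t = the longest minimum-spanning-tree edge (the smallest
threshold keeping the station graph connected), replacing larger
distances with 4t, double-centering -D^2/2 and keeping eigenvectors with
eigenvalue > 1e-8 x the largest. Scores are orthonormal eigenvectors and
match vegan's `pcnm` axes to numerical precision.

Constrained ordination supports two models. RDA (default) projects the
column-centered Hellinger-transformed relative abundances onto predictor
spaces; CCA projects the chi-square contingency residuals
Q = (P - rc')/sqrt(rc') with sqrt-row-weighted predictors. Explained
fractions are adjusted with Ezekiel's formula
1 - (1-R^2)(n-1)/(n-1-p); RDA/adjusted-R^2 is the default because the
resulting fractions are unbiased and additive (for CCA the same
adjustment is applied to inertia proportions as an approximation).

Forward selection admits, at each step, the candidate with the largest
conditional explained fraction iff its permutation p < alpha (default
0.05, 199 permutations). Two safeguards make the procedure well-behaved:

- the null distribution is that of the **maximum** conditional gain over
  all remaining candidates (computed on reduced-model residual
  permutations), so "best of k candidates" selection does not inflate the
  admission rate — a plain per-candidate test would spuriously admit from
  a 6-candidate noise pool roughly a quarter of the time;
- a plateau rule stops selection once the selected set explains >= 99% of
  what the full candidate model can explain (the operational meaning of
  "no improvement from adding variables").

Variation partitioning uses the three adjusted R^2 values [env], [space],
[env+space]: a = [env+space]-[space] (pure environment), c =
[env+space]-[env] (pure space), b = [env]+[space]-[env+space] (shared),
d = 1-[env+space]. The identity a+b+c+d = 1 holds by construction;
slightly negative a/b/c are a known adjusted-R^2 artifact and are
reported and flagged, never clamped. Fractions agree with vegan's
`varpart` to < 1e-6 on shared fixtures.

## Null models and the stochastic ratio

The null model constrains within-sample (local) and across-sample
(regional) richness. For each sample independently, exactly its observed
richness of features is drawn from the regional pool without replacement
with probability proportional to feature occupancy (number of samples
occupied) — the Raup-Crick convention, preserving regional richness in
expectation. A strict variant fixing occupancy exactly (curveball trades
on the presence matrix) is available via `selection="fixed_occupancy"`.

Richness constraints say nothing about abundances, which Bray-Curtis
needs. The default allocation assigns the sample's total by a multinomial
draw with probabilities proportional to the regional mean relative
abundance renormalized over the drawn features (a zero-count drawn
feature receives one unit from the largest to keep richness hard); for
non-integer tables allocation is deterministic-proportional. The
alternative `allocation="shuffle"` permutes the sample's own abundance
values onto the drawn features. Both preserve per-sample richness and
totals exactly; both are exposed because no single convention is
canonical.

The expected similarity E_ij is the mean of 1 - Bray-Curtis over the null
ensemble (default 1000 draws; tests and the acceptance script use 60-200
after checking that two independent 1000-draw ensembles agree to
max|dE| < 0.02 on a 10-sample table). Per pair:

    ST_ij^A = E_ij / C_ij              if C_ij >= E_ij
    ST_ij^B = (1 - E_ij) / (1 - C_ij)  if C_ij <  E_ij
    ST      = (sum ST^A + sum ST^B) / (n_A + n_B)

ST = 1 means observed similarity is indistinguishable from the null
(fully stochastic assembly); ST -> 0 means strong determinism. Degenerate
pairs C = E = 0 and C = E = 1 contribute 1 (the fixed point of both
branches). Layer-wise ST re-derives occupancies, pools and null draws
from the layer's samples only, since the regional pool of, e.g., the
mesopelagic differs from the global one.

A note on inclusion probabilities: weighted sampling without replacement
has inclusion probabilities exactly proportional to weights only when one
feature is drawn; for larger draws the proportionality is approximate
(high-occupancy features saturate). The distributional unit test
therefore checks the chi-square goodness of fit on richness-1 samples,
where the statement is exact.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
not ocean biology. Stations lie on a cruise-track transect (latitude and
longitude co-varying plus jitter) so that geographic distance couples to
the latitudinal environmental gradient — the prerequisite for distance
decay. Each station is sampled at 5 m (SRF), 70 m (DCM) and 600 m (MES).
Environmental variables are linear depth/latitude responses plus Gaussian
noise with the canonical sign structure: temperature falls with |latitude|
and depth, oxygen falls with depth, nitrate/phosphate/NO2NO3/silicate
rise with depth and against temperature (nitrate:phosphate coupled
16:1).

Community assembly works on a single composite depth-temperature niche
axis (z-scored). Each of the 30 traits occupies a tolerance band
(half-width 0.8 axis SD) around a uniform random center in [-1.8, 1.8];
each of its member taxa (5 per trait on average; every trait gets at
least one) draws an independent Gaussian niche optimum inside the band
(niche breadth sigma = 0.5). Expected taxon abundance in a sample is
(1 - w) x normalized niche response + w x regional-pool relative
abundance (lognormal meanlog 0, sdlog 1), with w the stochastic weight;
counts are one multinomial draw per sample at sequencing depth 20,000, so
row totals are exact and depth normalization is a no-op check. Trait
abundances are member sums.

Because member optima tile each trait's band, trait composition tracks
the environment more tightly than taxon composition: aggregated traits
are always less dissimilar than their taxa, decay more shallowly with
distance, carry a larger environmentally explained fraction in VPA, and
yield a lower stochastic ratio — the functional-redundancy signature the
pipeline is designed to detect. ST rises monotonically with w (verified
at w = 0.1/0.5/0.9, median over 5 seeds).

What the generator does **not** emulate: real richness gradients (at the
default deep sequencing all 150 taxa are detected nearly everywhere, so
the latitudinal richness slope is ~0 and LDG recovery is tested on
directly planted richness-latitude data instead), multi-dimensional
niches, taxon interactions, compositional overdispersion beyond
multinomial noise, and unassigned-taxonomy mass. Passing tests therefore
demonstrate correctness of the statistical machinery and directional
parameter recovery, not oceanographic realism.

## Problem sizes and determinism

Default analyses use 30 samples (10 stations x 3 layers), 150 taxa, 30
traits. Monte-Carlo studies use: 200 null datasets x 999 permutations
(type-I calibration, all four tests sharing each dataset), 5 seeds per
condition for directional medians, 60-200 null draws per ST estimate,
199 permutations inside forward selection. All randomness flows through
explicitly passed `numpy.random.Generator`s; the pipeline derives
per-stage child seeds from the global seed via `SeedSequence(seed,
spawn_key=(stage_index,))`, so identical configurations reproduce
bit-identical stage checksums and any stage can be re-run in isolation.

## Known limitations

- CCA adjusted fractions reuse Ezekiel's formula, which is exact only
  for RDA; vegan instead bootstraps. Fractions from the two models agree
  in ordering, not magnitude.
- The DDR permutation test shuffles sample labels of the similarity
  matrix jointly, which is the standard Mantel-style remedy but remains
  approximate when similarities and distances share station structure.
- The random-forest importances are training-data permutation
  importances; with strongly collinear factors the credit is split and
  individual values shrink (the univariate r^2 column is the guard).
- Chao1 on the synthetic default tables is uninformative (no rare-taxon
  tail at 20,000 reads over 150 taxa); it is exercised on count fixtures.
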