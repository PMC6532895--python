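# Methods

This note records the statistical model behind `econclusters`, the
numerical conventions the implementation fixes, what the synthetic-data
generator does and does not emulate, and the design choices made where
the method leaves room.

## The model

A population is assumed to contain a small number of latent economic
groups that manifest as characteristic combinations of categorical asset
answers (ownership items, cooking fuel, home financing, rural/urban
setting).  The task is to pick the `n_assets` questions (default 5) whose
weighted k-medoids clustering of the survey yields the most distinct
groups, so that the same few questions can later be asked of registry or
survey participants to place them on the population's economic scale.

**Profiles.** Households are collapsed into distinct answer profiles over
the candidate variables, each carrying the sum of its member households'
survey weights.  Clustering weighted profiles is exactly equivalent to
clustering households (tested against household-level computation); it
bounds instance sizes by the product of level-set sizes and makes the
exhaustive subset search affordable.

**Dissimilarity.** All model variables are treated as nominal, including
binary ownership and the rural/urban setting; Gower's coefficient then
reduces to simple matching, d(i,j) = #mismatches / #variables, with no
per-variable weights.  There is no numeric branch: no numeric variable is
ever clustered.

**Weighted PAM.** The k-medoids solver is BUILD+SWAP on the precomputed
dissimilarity matrix with case weights, run as a deterministic
multi-start: BUILD is seeded once with every profile forced as the first
medoid, duplicate seed sets are collapsed, best-improvement SWAP (strict
cost decreases only) runs to convergence from each seed, and the
lowest-cost solution wins, with ties resolved to the lexicographically
smallest medoid set.  A single-start SWAP is a local search and measurably
stalls in single-swap local optima on a few percent of small random
instances; the all-starts variant recovered the brute-force optimum on
every one of thousands of random instances (both simple-matching metrics
and adversarial non-metric matrices) while remaining polynomial.  Nearest-
medoid ties in labelling go to the lowest medoid index, making results
independent of evaluation order.  Sampling approximations (CLARA-style)
are deliberately out of scope: profile aggregation keeps instances small.

**Weighted silhouette.** Weights are treated as replicate counts:

    a_i = Σ_{j∈C(i)} w_j d(i,j) / (W_C − 1)
    b_i = min_{C'≠C(i)} Σ_{j∈C'} w_j d(i,j) / W_{C'}
    s_i = (b_i − a_i) / max(a_i, b_i)

with s_i = 0 when W_C ≤ 1 (an effectively singleton case) or when
max(a_i, b_i) = 0, and ASW = Σ w_i s_i / Σ w_i.  With integer weights this
equals the unweighted silhouette of the replicate-expanded matrix exactly,
and with unit weights the textbook silhouette — both are enforced by
oracle tests.  A consequence worth knowing: because of the W_C − 1
denominator, the ASW is a function of the absolute weight scale (weights
are counts, not relative weights); medoids, labels and the cost argmin are
scale-invariant.

**Selection.** Every subset of size `n_assets` containing the forced
variables (by default the rural/urban setting, which appears in the final
model of every population we target) is crossed with every K in
`k_range`.  Binary assets with survey-weighted ownership below
`min_prevalence` (default 10 %) are excluded up front — rare assets would
define economically meaningless micro-groups; multi-level variables always
remain eligible, and the filter can be disabled.  Households are
complete-case filtered once over the whole eligible set, mirroring the
way survey analyses report a single complete-case count.  Two selection
rules are exposed: the global ASW argmax, and the threshold rule — the
smallest K whose best ASW reaches `asw_threshold` (default 0.70), then
the ASW-best subset at that K, falling back to the argmax with an
explicit warning when no K qualifies.  All ties break lexicographically
(subset, then smaller K), so the search output is independent of
execution schedule, and infeasible candidates (fewer profiles than K)
are recorded, not fatal.

A structural note on the threshold rule: when a population contains G
well-separated groups, merging two of them with population shares p and q
still leaves the merged profiles with silhouette ≈ max(p,q)/(p+q), so the
best (G−1)-cluster partition retains ASW ≥ 0.75 and clears the 0.70
threshold.  The smallest-K scan therefore starts at the analyst's minimum
acceptable number of groups — the lower bound of `k_range` is a modelling
statement, not a technicality — exactly as a ≥5-group model is sought by
scanning K from 5 upward.

**Assignment.** A participant's non-missing answers are compared with
each medoid; a unique maximal agreement count decides the cluster.  On a
tie, the participant is compared with every complete-case reference
household (same agreement metric, not Gower over a wider set): unanimity
of the maximally similar households decides, anything else is UNASSIGNED.
Counting agreement over observed answers only is the minimal reading of
"most matching answers" under missingness; a participant with no observed
answers is UNASSIGNED.  There is no randomness anywhere in assignment.
The model file stores a fingerprint (row count + hash of sorted ids) of
the fitting table, and assignment against a different reference table
warns.

## Condensation, ranking, validation

Per-cluster outcome summaries use three wealth-graded indicators: child
height-for-age Z-score (child-level weights), women's literacy on the 0–2
reading scale, and the proportion of a woman's children who are deceased,
(sons died + daughters died) / children ever born, with childless women
excluded from the mortality outcome.

Clusters are condensed separately within the rural and urban strata
(wealth manifests as different assets in the two settings): the three
outcome means are standardized across each stratum's clusters (unweighted,
sd with one delta degree of freedom — the objects being clustered are the
cluster means themselves), Euclidean distances feed agglomerative
clustering, and both dendrograms are cut at the greatest common height
whose total group count lands in the target range (default 5–10).
Complete linkage is the default, with average and Ward as options; a
zero-variance outcome column is dropped from scaling with a warning, a
single-cluster stratum passes through uncut, and a `force_separate` list
lets subject-matter knowledge keep named clusters apart — it is an
explicit override, never automatic.

Ranking uses mean literacy ascending as the primary key — empirically the
most discriminating of the three indicators — and checks the two others
on every adjacent pair (HAZ should rise, the deceased proportion should
fall); disagreements and literacy ties are emitted as conflicts for the
analyst, never resolved silently.

Validation statistics are survey-aware throughout.  Weighted means carry
Taylor-linearized design-based standard errors when stratum/PSU columns
are supplied (with-replacement PSU approximation; singleton-PSU strata
contribute nothing) and precision-weight errors otherwise; with unit
weights and no design columns they reduce to s/√n exactly (tested in
closed form).  The one-way ANOVA is a design-based Wald test of equal
group means on the G−1 mean contrasts with independent design variances,
referred to an F distribution with design degrees of freedom; eta squared
is weighted between-group SS over weighted total SS, which with equal
weights is the classical ratio; adjacent pairs get Welch t-tests on the
design-based means and SEs with Satterthwaite degrees of freedom, tiered
at 0.05/0.01/0.005.  Degenerate groups (n < 2 or zero variance) are
excluded pairwise with warnings.

## The synthetic generator

`default_spec` encodes the canonical study population: four groups — two
rural (shares 0.30, 0.25) and two urban (0.25, 0.20) — over five
informative assets (three binary, two three-level), with every pair of
signatures disagreeing on at least three of the five.  Asset answers are
the group signature with independent per-variable corruption (default
0.02) to a uniformly random other level; the setting is a fixed group
attribute and is never corrupted.  Weights are lognormal (σ = 0.5,
normalized to mean 1) or constant.  Noise assets are drawn independently
of group with fixed marginals chosen to stay above the 10 % prevalence
filter, so the search genuinely has to reject them.  Outcomes follow a
monotone wealth gradient within each setting: HAZ means −1.8/−1.2
(rural) and −0.8/−0.2 (urban) with sd 1.1 — a realistic stunting-range
spread; literacy category probabilities shifting from (0.7, 0.2, 0.1) to
(0.1, 0.2, 0.7); child-death probabilities 0.15/0.10/0.06/0.03 applied
binomially over a Poisson(3) number of children ever born; children under
five per household Poisson(0.8) for the HAZ table; one woman per
household.  Everything is reproducible from the spec's single seed.

What the fixture does **not** emulate: multi-stage PSU sampling and
intra-cluster outcome correlation, household-level confounding between
assets and outcomes, item missingness patterns, or asset distributions
drifting over time.  Passing tests on this fixture demonstrate that the
algorithms recover structure that matches their assumptions — planted,
group-attached effects — not that real survey populations contain such
clean structure.

Default verification problem sizes: the end-to-end recovery runs at
5,000 households with five noise assets and K scanned 4–8 (a full search
is ~1,000 PAM fits and takes seconds to tens of seconds); PAM optimality
is checked on 200 random instances of up to 9 profiles against exhaustive
enumeration; silhouette oracles on 50 instances of up to 6 profiles with
integer weights ≤ 3; condensation against a naive O(n³) agglomerative
implementation on random 8-cluster instances.

## Known limitations

* The exhaustive search is combinatorial in the number of eligible
  variables; it is meant for the tens of assets a DHS-style survey
  carries, not hundreds.
* The replicate-count silhouette convention (W_C − 1) is one of several
  defensible weighted silhouettes; alternatives that divide by W_C differ
  at small cluster weights and are exactly scale-free.  The convention
  here is fixed by the replicate-expansion equivalence and documented.
* Design-based statistics use the with-replacement first-stage
  approximation; finite-population corrections are not implemented.
* Ordinal ranking assumes the three indicators are wealth-monotone;
  populations where they genuinely diverge will produce (intended)
  conflict reports rather than a forced total order.
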