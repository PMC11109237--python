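# Methods

This note documents the statistical model behind `cognet`, the conventions
that its numbers depend on, the design of the synthetic cohort generator,
and the package's known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Composite scoring

Each task contributes two measures per participant: accuracy (% correct,
in [0, 100]) and mean reaction time (ms, > 0). Scores with accuracy below
a threshold (default 50%) are removed **record-wise** — the participant's
other tasks are kept — because sub-chance accuracy indicates the task was
not performed meaningfully. Both measures are z-standardized per task over
a *scaling population* and averaged into a composite; RT is negated before
standardization so that larger composite always means better performance.

Conventions:

- **SD convention**: sample standard deviation (ddof = 1) everywhere.
- **Scaling population**: defaults to the full sample. For two-group
  analyses the pooled sample is used and then subset, so the two groups'
  mean composites are mirror images around zero — the behavior expected of
  a matched-group design scored on a common scale.
- Missing cells (excluded records) propagate as NaN and are handled
  pairwise-complete downstream, never imputed.
- Raw group differences are screened with two-sided Wilcoxon rank-sum
  (Mann–Whitney) tests — exact enumeration when both groups have n < 20
  and no ties, normal approximation with continuity correction otherwise —
  Bonferroni-corrected over all task × measure comparisons in the call
  (30 for 10 tasks × {accuracy, RT, composite}).

## Association matrices

Spearman ρ with midranks (average ranks for ties), computed as the Pearson
correlation of ranks; two-sided p-values from the t-approximation on n−2
degrees of freedom — the standard choice at cohort sizes of 75+ where exact
permutation is unnecessary. Multiplicity over the 45 unordered pairs of a
10-task battery is controlled with the Holm step-down procedure
(`adjusted_(i) = max_{j≤i} min(1, (m−j+1) p_(j))`), which is uniformly more
powerful than Bonferroni at the same familywise error rate. Pairs with
fewer than 4 complete observations are reported missing.

Significance is *descriptive*: the network filter consumes the full |ρ|
matrix, not only significant entries, so weak edges can be retained by the
filter while being flagged non-significant in the edge report.

## TMFG filtering

The triangulated maximally filtered graph keeps exactly 3n−6 of the
n(n−1)/2 candidate edges and is planar and chordal by construction. TMFG
variants in the literature differ in details; this implementation pins:

- **Seed clique**: exhaustive search over all C(n, 4) quadruples for the
  maximum sum of the 6 internal weights (cheap at n = 10; some published
  variants use row-sum heuristics instead, which can change a few edges).
- **Insertion rule**: at each step the (vertex, face) pair maximizing
  w(v,a)+w(v,b)+w(v,c) over all unplaced vertices and current faces.
- **Tie-breaking**: lexicographic — smallest vertex index first, then face
  creation order — making the construction deterministic and permutation
  equivariant on tie-free inputs (ties have probability zero for
  correlation matrices of continuous data).
- Zero weights are legal edge candidates; the structural edge set is
  tracked separately from the weight matrix so the 3n−6 guarantee survives
  zero-weight edges, while metric computations treat zero weight as absent.

The greedy filter is a heuristic for the (NP-hard) maximum-weight planar
subgraph; the test suite verifies the greedy total never exceeds the
exhaustive optimum on n ≤ 6 and that all structural invariants hold on
random inputs.

## Graph metrics

All metrics operate on the weighted adjacency matrix; conventions are
pinned because reported values depend on them:

- **Distance transform**: edge length = 1/weight (not −log w), the common
  convention in the brain-connectivity toolbox lineage.
- **Global efficiency**: mean of 1/distance over distinct node pairs;
  disconnected pairs contribute 0.
- **Clustering**: Onnela's weighted coefficient — weights normalized by the
  network maximum, triangle intensity = geometric mean of the three
  normalized weights; *global* clustering is the mean of node coefficients
  (not the transitivity ratio).
- **Local efficiency**: Latora–Marchiori — the global efficiency of the
  subgraph induced on a node's neighbors with original weights; 0 for
  degree < 2.
- **Modularity**: Louvain on weights, best partition over seeded restarts
  (default 100 for empirical networks); Q is always recomputed from the
  returned partition with the explicit Newman formula
  Q = (1/2m) Σ_ij (w_ij − s_i s_j / 2m) δ(c_i, c_j), never trusted from
  the optimizer.

## Case-wise bootstrap and group comparison

Participants (rows of the composite matrix) are resampled with replacement
to the original n; every replicate re-runs ranking → Spearman → TMFG → all
metrics, so each of the B replicate networks is a full re-analysis.
Replicates where a task column collapses to a constant are redrawn (the
count is logged; persistent degeneracy raises). Replicate b draws from the
deterministic substream `SeedSequence(seed, spawn_key=(b,))`, so enlarging
B extends the replicate set without changing earlier replicates.

- **Stability**: percentile CI95 (2.5th/97.5th, linear interpolation,
  requiring B ≥ 40); an empirical metric inside its CI95 is "stable".
  Percentile rather than bias-corrected intervals: the plain percentile
  interval is what the resampled-network stability convention uses.
- **Comparison**: Welch (unequal-variance) t-tests between the two groups'
  bootstrap distributions per metric, positive t meaning the second group
  is larger. Bonferroni families: the 4 global metrics form one family;
  each node-level metric type (strength, clustering, local efficiency) is
  a family of 10 nodes.
- **A deliberate caveat**: the comparison treats the B resamples as
  independent observations (df ≈ 2B−2). Bootstrap spread approximates the
  sampling noise of *one* cohort, so for two independently sampled cohorts
  from the same population this test rejects far above its nominal level —
  it is a statement about the two observed samples, not the populations.
  The convention is reproduced deliberately because it is what this family
  of analyses reports; users wanting population-level inference should
  treat the t values as descriptive effect sizes. The package's null
  calibration test therefore uses the exact-null configuration (the same
  cohort analyzed as both groups with independent resampling streams),
  under which the test is correctly calibrated.

Inside bootstrap replicates Louvain uses 10 restarts (vs 100 for empirical
networks): on a 10-node graph additional restarts almost never improve Q,
and the replicate loop dominates the pipeline's cost. Both counts are
configurable.

## Synthetic cohort generator

A Gaussian single-factor copula per task: participant latents
z ~ MVN(0, Σ) with a task × task correlation matrix Σ; accuracy and
negated RT each emit `sqrt(λ)·z + sqrt(1−λ)·ε` with independent noise ε
and shared loading λ (default 0.7), rescaled to per-task emission means and
SDs. Both measures co-load on the same latent so that the accuracy/RT
composite carries the latent correlation, attenuated to
`2λρ/(1+λ)` (Pearson) and thence `(6/π)·arcsin(·/2)` (Spearman of a
bivariate Gaussian) — the closed form the recovery tests check.

Defaults emulate a young-adult cohort on a 10-task language/executive
battery: per-task accuracy means 87–97% (SD 3.4–10.4), RT scales 347–2348
ms (SD 78–921), 75 participants per group. The default latent correlation
is block-structured — 0.55 within a cognitive domain (language: semantics,
syntax, phonology, prosody; executive: inhibition, working memory,
switching, attention; memory and theory-of-mind as singletons), 0.30
between — chosen so observed composite Spearman correlations land in
≈0.24–0.45, the range typical of inter-task correlations in healthy
adults, with a partly modular structure that gives community detection
something to find.

Other generator choices:

- Accuracy is clipped to [0, 100] and RT floored at 1 ms after emission
  (rare at default parameters; occurrences are logged). Clipping truncates
  the upper tail of high-accuracy tasks, so sample moments of near-ceiling
  tasks sit slightly below the nominal emission parameters — a feature of
  real percentage scores too.
- Σ inputs are repaired to the nearest valid correlation matrix by
  alternating projections between the PSD cone (eigenvalue clipping) and
  the unit-diagonal set (tolerance 1e−10, ≤ 1000 iterations, final
  eigenvalue clip + diagonal renormalization), a simple deterministic
  scheme cross-checked in tests against an independent implementation.
- **Matched cohorts** (`generate_matched_cohorts`) emulate a
  participant-matched design with common random numbers: both groups reuse
  the same underlying standard-normal draws and differ only in Σ. This
  isolates the planted between-group difference from cohort-level sampling
  noise, exactly as demographic matching is meant to; with no planted
  difference the two groups are identical — the exact-null configuration
  used for calibration. With *independently* drawn cohorts, the shared
  latent factor makes whole-matrix correlation levels fluctuate
  considerably between cohorts (at n = 75 the global strength varies with
  SD ≈ 2 across cohorts), which the B-as-n t-test then declares
  significant in either direction — the anti-conservativeness documented
  above, observable via the generator with distinct seeds.

What the generator does **not** emulate: trial-level response processes
(RT distributions within task, speed–accuracy trade-offs), missingness
mechanisms other than the sub-chance exclusion rule, demographic
covariates, or heavier-tailed score distributions. Passing tests therefore
demonstrate correctness of the pipeline's computations and calibration
under a Gaussian copula — not that any particular empirical dataset will
show stable or different networks.

## Problem sizes used in the automated checks

The acceptance checks run the planted-difference and null experiments at
75 participants per group with B = 200 over 20 seeds each, and the full
study in `scripts/acceptance.py` at B = 1000 — sizes at which the
Monte-Carlo properties being asserted (directional recovery, familywise
error under the exact null, CI95 coverage) are sharp while the whole suite
completes in a few minutes on one CPU.

## Known limitations

- The TMFG seed-clique and tie-break conventions are one of several in
  circulation; reproducing a table computed with different conventions can
  differ in a few edges and correspondingly in metric decimals.
- Holm-significant edge counts at α = 0.05 are familywise-calibrated per
  matrix; comparing counts across samples of different n conflates power
  with structure.
- The bootstrap comparison's population-level anti-conservativeness
  (above) is inherent to the B-as-n convention, not fixable by larger B.
- `nearest_valid_corr` minimizes Frobenius distance only up to the
  alternating-projection scheme's convergence; it is not the exact
  weighted nearest-correlation solution.
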