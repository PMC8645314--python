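# Methods

This note records the modelling choices behind `epmfaces`: what is simulated,
why the defaults are what they are, and where the codified procedures have
known limits.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The appearance model

A face is a point in an abstract feature space of dimension `d` (default 16;
the features carry no claim of correspondence to nameable facial
attributes).  Three processes generate a lifespan trajectory:

* **Base appearance.**  The walk starts at `base_norm ·u` for a random unit
  direction `u`.  The base norm matters only for direction-based (cosine)
  similarity: it anchors the identity on a stable appearance axis.  Zero by
  default; scenario templates use 8–12 (comparable to the jump magnitude) so
  that within-episode cosines stay near 1 while between-episode cosines
  drop.
* **Age-dependent drift.**  A Gaussian random walk with instantaneous
  per-year scale `σ(a) = σ₀/(1 + a/τ)`, encoding that facial change is
  strongest early in life and slows with age.  Any strictly decreasing
  positive law would serve; this hyperbolic one integrates in closed form
  (displacement variance `σ₀²τ[1/(1+a₀/τ) − 1/(1+a₁/τ)]`), which the
  Monte-Carlo variance test checks against.  Defaults `σ₀ = 0.25/√year`,
  `τ = 25` years give a lifetime drift displacement of ~4 feature units.
* **Jumps.**  Deterministic `(age, magnitude)` events displacing all later
  exemplars along a random unit direction.  Deterministic rather than
  Poisson so the ground-truth segmentation is exactly known for recovery
  tests.  Magnitudes are free parameters; templates use 12–14 units,
  several times the within-episode spread.

Likert similarity ratings are `clamp(round(7 − 6·D/max(D) + ε), 1, 7)` with
`ε ~ N(0, noise_sd)` drawn once per unordered pair.  The affine map is a
modelling convenience — nothing in the behavioural task pins down how
perceived similarity maps onto a 7-point scale — and a zero-range matrix
maps every pair to 7.

What the generator deliberately does *not* emulate: photographic nuisance
(lighting, pose, focus), expression or motion, named attribute channels, and
rater idiosyncrasies beyond i.i.d. Gaussian noise.  Tests passing on this
synthetic structure show that the pipeline recovers the structure the model
assumes, not that real rating data has that structure.

## Memory model

* **Similarity** is the cosine of probe and trace; a zero trace vector has
  similarity 0.  Activation is the sign-preserving cube `S³` — a continuous
  stand-in for the classic ternary-feature activation that keeps "more
  similar is weighted much higher" without losing sign.
* **Recency** is exponential with a configurable half-life `h`:
  `w = 2^(−Δt/h)`, `w ≡ 1` for `h = ∞`.  The functional form is a choice;
  only the demand for *some* temporal weighting is theory-driven.
* **Assimilation** assigns a new exemplar to the prototype minimising the
  maximum delta (not the nearest centroid), so the decision variable is
  exactly the quantity compared against the pre-fixed threshold.  Ties go to
  the most recently created prototype.  Centroids update as running means,
  so an exemplar's influence decays as 1/n with prototype size.  Prototypes
  are never merged or reassigned after the fact: genesis is a forward,
  order-dependent process, and the same stream in a different order can
  yield different prototypes.
* **Pure-leader variant.**  `MemoryStore(update_centroid=False)` freezes
  each centroid at its founding exemplar.  Neither variant guarantees a
  monotone prototype count in the threshold: on random streams, a larger
  threshold occasionally absorbs an exemplar that would otherwise have
  founded a prototype that later absorbs many others, so the count *rises*
  with the threshold on roughly 10% (leader) to 23% (max-delta) of random
  3-D streams we measured.  Only the extremes are guaranteed: a threshold at
  or above the stream diameter gives one prototype; a zero threshold gives
  one per distinct exemplar.
* **Echo scope.**  Prototypicality pools the echo over all traces;
  verification takes the maximum per-prototype echo ("matched to the
  representation with the strongest echo").  Both are exposed because the
  verbal model underdetermines the choice.
* **Latency linking** is `RT = base − slope·ln(max(strength, 10⁻⁶))`,
  clamped below at 200 ms — the same floor the RT outlier filter treats as
  the shortest valid decision time.  Defaults base = 800 ms, slope =
  100 ms give round-number latencies at strength 1 and e.  Only signs and
  orderings of simulated RT differences are meaningful; magnitudes depend
  entirely on these two free parameters.

The threshold delta has no empirically fixed value or unit; every scenario
calibrates it to its own jump structure (templates use Δ_thr = 8, between
the within-episode spread of ~3 and the jump size of 12–14).

## Cluster pipeline

Classical (Torgerson) scaling embeds a dissimilarity matrix by
double-centering; negative eigenvalues contribute zero coordinates.  Ward
linkage and k-means come from scipy/scikit-learn; within-groups SS for a
partition of a dissimilarity matrix uses the Euclidean identity
`W = Σ_c Σ_{i<j∈c} d²_ij / n_c`.

**Elbow.**  Suggested k maximises the second difference
`W_{k−1} − 2W_k + W_{k+1}`.  A "distinct" elbow requires the profile to
collapse somewhere (`W_{k+1}/W_k < 0.2`); smooth power-law profiles (e.g.
collinear equidistant points, where `W_k ∝ k⁻²` makes the k = 2 second
difference large without any visual elbow) fall back to the first k with
`W_k < 0.1·W₁`.  The collapse criterion is our codification — "distinct
drop" is not a formal rule anywhere.

**Gap statistic.**  References are uniform over the data's axis-aligned
bounding box (the simpler of the two published reference choices);
`s_k = sd_b(log W_kb)·√(1+1/B)`; chosen k is the smallest with
`Gap(k) ≥ Gap(k+1) − s_{k+1}`.  Two known consequences, measured here and
worth stating plainly:

1. *Small samples.*  With ~20 points, `s_k ≈ 0.16` while the Gap increments
   below the true k are of the same size, so the rule often stops at k = 1
   on well-separated clusters.  The method has power from roughly 50–60
   points upward; the end-to-end recovery test therefore uses either ≥60
   points or a constructed 4-episode layout verified to be in the method's
   working regime.
2. *Chain geometry.*  Episode centroids of a cumulative-jump trajectory form
   a random chain whose 2-split captures about as much variance as splitting
   the bounding box, flattening the Gap curve below the true k.  Compact,
   irregular episode layouts behave better than long chains.

A 20-exemplar lifespan is therefore genuinely hard for the codified
automatic k-selection — the familiar situation with real rating data of
this size, where the formal criteria disagree (gap below, dendrogram above)
and the final cluster count ends up adjudicated by inspection.  The study1
template reports
the automatic consensus honestly alongside the Ward cut at the known
segment count, which recovers the ground truth (ARI 1.0) robustly.

**Two-step consensus.**  Gap is primary; if the elbow disagrees by exactly
one, the larger k wins (a still-significant drop in W is taken seriously).
k-means starts from the Ward-cut means as its only initialisation, keeping
the routine deterministic; refinement can only lower W.  The 2-D embedding
is the reference path (mirroring plotted face spaces);
`use_embedding=False` clusters a full-rank embedding of the distances
instead.

**Outliers.**  Singleton clusters whose nearest-neighbour distance exceeds
the 95th percentile of all nearest-neighbour distances are flagged —
duplicates can never be flagged (their NN distance is 0).

## Scenario templates

All templates share the same design skeleton: 4 identities, 20
exemplars over ~60 years at ~3-year spacing (±0.5 years jitter), three
jumps at ages 15/30/45.  Per-study settings, all overridable:

* **study1** (unfamiliar-observer clustering): defaults as above; reports
  the per-identity two-step solutions, their ARI against the ground-truth
  segments, and the Ward cut at the true k.
* **study2** (lifelong relatives rating prototypicality): half-life 20
  years with encoding time = capture age; base norm 8 and jump magnitude 14
  sharpen episode contrast.  Checks: pooled prototypicality and per-episode
  match strength both strictly increase with episode recency.  The
  `half_life = ∞` control also sets `σ₀ = 0` so that *every* gradient
  source other than recency is removed; its checks are flat per-episode
  strengths (relative range ≤ 15%) and a recency-monotonicity flag that
  must not fire.  Flatness is asserted on per-prototype strengths, not the
  pooled echo: episode centroids of a jump chain have growing norms, which
  induces a small geometric gradient in the pooled echo even with all
  weights equal.
* **study3** (two exposure sets): the younger set is exemplars 3–10 (ages
  ~6–28) and the recent set exemplars 13–20 (ages ~38–60), a ~10-year gap.
  Check: the very first recent exposure spawns exactly one new prototype.
* **study4** (verification): half-life 240 years — all exemplars were
  learned within one session, so encoding recency is nearly uniform and
  only a mild chronological-relevance gradient remains; `d = 64` keeps the
  appearance-change directions near-orthogonal; uniform drift `σ₀ = 0.1`.
  Probes are leave-one-out versions of each episodic prototype (one per
  member) and of the exhaustive prototype (20).  Checks: every episodic
  condition verifies stronger and faster than the exhaustive one, and the
  benefit orders by recency.

These geometric calibrations (base norm vs jump size vs half-life) were set
by analysis of the cosine-echo geometry and then verified to hold across 30
seeds per scenario; they are the templates' definition of the study
conditions, not per-run tuning.

## Experiment sizes

The repeated-seed experiments use: threshold bracketing — 50 streams of 12
exemplars in 8 dimensions; jump recovery — 100 streams, 3 jumps of
magnitude 16 ≥ 10× the total drift scale `σ₀√(d·span)` ≈ 1.55, threshold 8;
gap recovery — 20 seeds of four 15-point planar blobs on a randomly rotated
circle (separation 14 between neighbours, SD 0.5), B = 50 references.
These sizes keep the full suite around a minute while leaving the rates far
from their acceptance bounds.

## Known limitations

* Assimilation is order-dependent by design; there is no prototype merging,
  so an adversarial presentation order can fragment episodes.
* Cosine similarity makes the origin meaningful; identities need a nonzero
  base appearance for within-episode similarity to saturate, and
  time-averaged (exhaustive) probes remain direction-correlated with recent
  episodes of a cumulative chain (cos ≈ 0.9), which bounds how much slower
  exhaustive verification can get.
* Automatic k-selection at 20 exemplars is unreliable (see above); the
  package reports diagnostics rather than pretending otherwise.
* Simulated latencies inherit their scale entirely from the linking
  parameters; only comparisons are interpretable.
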