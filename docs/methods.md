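# Methods

## The model

`tskfuzzy` trains a first-order Takagi–Sugeno–Kang (TSK) fuzzy classifier
for binary problems on continuous feature tables. Rule *k* has the form

    If x_1 is A_1^k ∧ … ∧ x_d is A_d^k
    then f^k(x) = p_0^k + p_1^k x_1 + … + p_d^k x_d

with Gaussian fuzzy sets A_j^k. The system output is the normalized
firing-strength weighted sum

    y(x) = Σ_k μ̃^k(x) f^k(x),     μ̃^k(x) = μ^k(x) / Σ_k' μ^k'(x),

where the firing strength μ^k(x) is the product of the rule's Gaussian
memberships exp(−(x_j − v_j^k)² / (2 σ_j^k)) over its **active** features
only. σ_j^k is a variance-like spread; inactive features contribute a
neutral factor 1, i.e. they are simply absent from the rule.

Writing each rule's contribution as μ̃^k(x)·(1, x_k) and concatenating the
blocks turns y(x) into an inner product p_gᵀ x_g(x), so once the antecedents
are fixed, learning the consequents is one ridge least-squares solve of
min Σ_n (y_n − p_gᵀ x_g(x_n))² + λ‖p_g‖² on labels encoded as ±1. The
decision rule is y(x) ≥ 0 → positive class.

## Antecedent learning by feature-weighted subspace clustering

Antecedents come from a fuzzy clustering in which each cluster *c* carries a
feature-weight vector w_c on the probability simplex:

    J(U, V, W) = Σ_c Σ_i μ_ci^m Σ_j w_cj (x_ij − v_cj)²
               + Σ_c δ_c Σ_j w_cj²,
    s.t. Σ_c μ_ci = 1 (per sample),  Σ_j w_cj = 1 (per cluster).

The number of clusters equals the number of rules K, so w_cj measures how
much feature *j* matters to rule *c*. Thresholding W at τ gives each rule's
active-feature mask; features a cluster is tight on receive weights above
1/d and survive, diffuse features drop out.

### Coordinate updates

All three optimized blocks have closed-form coordinate minimizers:

- **Weights.** The equality-constrained stationary point is
  w_cj = 1/d + (1/(2δ_c)) Σ_i μ_ci^m (‖x_i − v_c‖²/d − (x_ij − v_cj)²).
  Because J is an isotropic quadratic in w_c, the minimizer under
  w_cj ≥ 0 is the Euclidean projection of that point onto the simplex
  (sort-based threshold-and-clip). When no entry goes negative the two
  coincide exactly.
- **Memberships.** The standard power-ratio update
  μ_ci ∝ (Σ_j w_cj (x_ij − v_cj)²)^(−1/(m−1)), with crisp membership
  (ties split equally) when a sample lies within 1e-12 of a center.
- **Centers.** The membership-weighted mean. The weight w_cj cancels
  between numerator and denominator of the stationarity condition, and the
  cancelled form stays defined when a weight is clipped to zero (the
  objective is flat in that coordinate; the weighted mean is one of its
  minimizers).

### The per-cluster constant δ_c

δ_c balances the scatter term against the quadratic weight penalty: larger
δ_c pulls w_c toward uniform, smaller δ_c lets it concentrate. J is strictly
increasing in δ_c, so δ_c cannot be one of the alternately *minimized*
blocks — treating it as one both destroys the descent property of the loop
and has no optimizer-based target value. The package therefore treats δ_c
as a per-cluster **constant of the fit**: after seeding, two warm-up
membership/center sweeps run under uniform weights (classical fuzzy
c-means; the 1/d scaling cancels in the membership ratio), and δ_c is then
computed once as the scatter ratio

    δ_c = [Σ_i μ_ci^m Σ_j w_cj (x_ij − v_cj)²] / [Σ_j w_cj²]

at that partition (floored at 1e-12) and held fixed. The warm-up exists so
the regularizer's scale reflects an actual partition of the data rather
than the arbitrary seeding. With δ fixed, every sweep (W → U → V) is an
exact block minimization, so the recorded objective trajectory is
non-increasing and |J_t − J_{t−1}| < ε (default ε = 1e-5) is a sound
stopping rule; the sweep budget caps at 300.

### Initialization

Centers are K distinct data rows drawn by seeded squared-distance-weighted
(k-means++-style) sampling without replacement; uniform row sampling
frequently places two seeds in one true cluster, from which the alternation
rarely escapes. Weights start uniform at 1/d, δ_c at 1 (a placeholder until
the warm-up assigns its real value), and memberships follow from the
membership update. The default seed 0 is part of the public contract; every
fit is bit-reproducible given data and seed.

## From clustering to rules

Rule centers and spreads are membership-weighted moments of the training
data: v_j^k is the weighted mean and σ_j^k = h · (weighted population
variance), floored at 1e-8 so constant features stay usable. The
memberships enter with exponent 1 here, independent of the clustering
fuzzifier. h (default 0.5) scales all spreads linearly and is the one knob
controlling how local the rules are.

Activation applies active[k][j] = (w_kj ≥ τ); if a rule loses every
feature, its single maximum-weight feature is forced back on (ties toward
the lowest index), so each rule keeps at least one clause. τ = 0 recovers
the dense first-order TSK system with every feature in every rule.

Firing strengths are accumulated in log space and normalized after
subtracting the maximum, so inputs far from all rules cannot underflow the
normalization; if every log strength is −inf the normalized vector falls
back to uniform (unreachable with positive spreads and finite input, but
the contract is explicit).

## Consequents

Two layouts are supported. **reduced** (default) restricts rule *k*'s
linear function to its d_k active features — block length d_k + 1 — which
is the layout the parameter accounting below assumes. **full** keeps all
d + 1 coefficients per rule regardless of the antecedent mask. The solver
stacks the ridge-augmented system [D; √λ I] and calls a LAPACK
least-squares routine, so λ = 0 degrades gracefully to the minimum-norm
solution. λ defaults to 1e-4: heavily overlapping rules make the design
matrix nearly rank-deficient, and an unregularized solve is then
ill-conditioned. Labels map to ±1 with the positive class the
lexicographically larger label unless overridden.

`fit_consequents` also accepts continuous regression `targets` in place of
the encoded labels. This exists for round-trip validation — regressing on
the clean scores of a known generating model recovers its coefficients to
machine precision, whereas sign labels cannot and should not reproduce
them — and for any caller who wants the TSK system as a regressor.

## Model complexity and linguistic rendering

Model complexity (MC) is the total trainable-parameter count, the package's
interpretability proxy: each active feature of a rule costs 2 antecedent
parameters (center, spread), each rule's consequent costs d_k + 1 (reduced)
or d + 1 (full). For 15 rules with per-rule active counts
(1,3,1,1,5,1,1,1,4,2,1,1,3,5,1) the reduced total is 108; the dense
15-rule, 15-feature system costs 15·(30 + 16) = 690. MC is non-increasing
in τ for a fixed weight matrix.

Linguistic rendering maps each active rule center onto a five-term ordered
scale — by convention "Low" < "Lower" < "Medium" < "Higher" < "High", an
unusual ordering kept deliberately — by min–max normalizing the center
against the feature's training range and binning at (0.2, 0.4, 0.6, 0.8).
Out-of-range centers clamp to the extreme terms; a zero-range feature maps
to "Medium" with a warning. Term assignment is ultimately a domain-expert
judgement; the equal-width default is deterministic plumbing, and callers
may pass their own `LinguisticScale`.

## Synthetic data

Three generators, all pure functions of their parameters and seed:

- `generate_subspace_clusters` plants clusters that are tight (variance
  0.01 by default) on a small random subset of features around offsets
  spaced `center_separation` = 5 apart, and broad (variance 1.0) elsewhere.
  These defaults make weight recovery well-posed: informative features
  should end up with strictly larger weights than noise features in the
  matched cluster. Ground truth (assignments, centers, masks) is returned
  alongside so tests never re-derive it.
- `generate_tsk_labeled_data` draws inputs around a given model's rule
  centers, scores them with that model, optionally adds Gaussian score
  noise, and labels by sign. The clean scores are returned for margin
  filtering and for coefficient-recovery checks.
- `generate_adni_like_table` emits a 200 × 15 positive-valued two-class
  table with 15 latent unequal-size clusters, shaped like a region-mean
  brain-image intensity table after feature selection. It mimics shape and
  scale only — not real effect sizes, class overlap, scanner noise, or
  inter-regional correlation — so end-to-end tests passing on it show the
  pipeline is wired correctly, not that clinical accuracy would transfer.

Problem sizes in the test suite (N ≤ 400, d ≤ 15, K ≤ 15) were chosen as
the smallest at which the recovery properties are comfortably identifiable;
full fits at these sizes take well under a second.

## Numerical choices and degenerate inputs

- δ floor 1e-12 (all-coincident clusters), spread floor 1e-8 (constant
  features), zero-distance crisp memberships at 1e-12.
- Empty clusters (zero membership mass) are reseeded at the sample farthest
  in weighted distance from its best center.
- Simplex sums are maintained to 1e-10 and asserted in tests.
- Ties: activation fallback and feature-selection ranking break toward the
  lower index; a classification score of exactly 0 goes to the positive
  class.
- CSV writing uses %.17g so float64 tables round-trip bit-exactly (reading
  uses the slower correctly-rounded parser for the same reason).

## Scope and limitations

- Binary classification only; multi-class and rule-count reduction are out
  of scope.
- The ROI extractor pools per-region means from a volume/atlas pair that
  must already share a voxel grid; no registration, resampling, smoothing,
  or affine interpretation is performed, and the atlas label list is a
  parameter rather than a hard-coded region set.
- The Fisher-ratio feature selector is a deliberately simple univariate
  filter (between-class over within-class variance), provided as plumbing
  ahead of the classifier, not as a contribution.
- Published clinical accuracies for this model family depend on private
  imaging data and unreported evaluation protocols; nothing in this package
  claims to reproduce them. The test suite validates the algorithmic
  machinery on synthetic data with known ground truth instead.
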