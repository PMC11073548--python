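# Methods

## Model and procedure

A network is a weighted graph `G = (V, w)` on `q` nodes with a symmetric,
finite, zero-diagonal weight matrix. The graph filtration keeps edges with
`w_ij > ε` — **strictly** greater, so an edge is already absent at its own
weight. This matters only at event points, and switching to `≥` would shift
every Betti curve there; the strict convention is used throughout and is the
one the Betti-curve formulas assume.

The birth–death decomposition runs Kruskal's greedy algorithm on edges
sorted by *descending* weight with a union-find structure: an edge joining
two components is a birth (maximum-spanning-forest) edge, any other edge
closes a cycle and is a death edge. Some literature phrases this via the
minimum spanning tree of a dissimilarity; here the birth set is defined as
the maximum spanning forest of the weight matrix itself, which is the
orientation consistent with "large weight = strong connection" filtration
semantics. Two printed-source quirks are resolved deliberately: the
decomposition is a *disjoint* partition of the edge-weight multiset (birth
and death sets cannot share an edge — a uniqueness statement, despite
occasional typos to the contrary in the literature), and tie-breaking among
equal weights follows (weight desc, i asc, j asc), which makes runs
deterministic; the value multisets are tie-independent even when the edge
partition is not unique.

Betti curves come from the sorted sets alone: `β₀(ε) = q − #{births > ε}`,
`β₁(ε) = #{deaths > ε}`, equivalent to the Euler identity
`β₀ − β₁ = q − E(ε)`. No per-threshold component counting happens outside
the test oracles.

**Sparse networks.** A zero off-diagonal entry means "no edge" by default —
natural for tract-count matrices. An explicit boolean mask can override this
(the point-cloud generator marks its graphs complete because the affinity
transform can produce a legitimate zero weight). For disconnected graphs the
birth set is the maximum spanning *forest*, `|B| = q − c` with `c`
components, and the complete-graph cardinalities `q − 1` and
`(q−1)(q−2)/2` are properties of complete inputs only.

## Distances

`d0` and `d1` are sums of *squared* differences of order-matched sorted
birth/death values — the squared 2-Wasserstein form. No square root is
applied by default: the downstream ratio and permutation inference is
invariant to monotone transforms, and the squared form is what the
between/within sums aggregate. `root=True` exposes the metric variant.
Networks of unequal size (or unequal diagram sizes) are refused rather than
padded; diagram matching across different `q` is undefined for graph
filtrations. Two trees both have empty death sets and get `d1 = 0` by
convention.

## Inference

`l_W` sums each unordered within-group pair once; `l_B` sums the `m·n` cross
pairs; `φ = l_B / l_W`. The permutation null shuffles labels on the fixed
distance matrix (vectorised over resamples via a quadratic-form identity
`l_W = (g'Dg + h'Dh)/2`, `l_B = total − l_W`). The transposition test keeps
`(l_W, l_B)` as running state and updates them per swap using only the two
touched rows — `O(m+n)` per step, verified against from-scratch
recomputation to 1e−10 over 10⁴ steps — with a full random relabelling
replacing the state every 1,000 steps (configurable) to break serial
correlation. p-values are one-sided (`null ≥ observed`) with the add-one
rule, so `p ∈ (0, 1]` and the smallest attainable value is
`1/(1 + n_resamples)`.

The Z-test uses ordered-pair denominators, `m(m−1) + n(n−1)` within and
`mn` between, for all moments:

    Z = (L̄_B − L̄_W) / sqrt(V_B/(mn) + V_W/(m(m−1)+n(n−1))),

with a one-sided upper-tail normal p-value; the numerator uses means (the
reading consistent with those standard-error denominators). Negative
variances from floating-point cancellation are clipped to zero with a
warning.

**Calibration caveat (important).** The Z formula treats every ordered
within-pair distance as an independent observation. On a symmetric distance
matrix each within distance appears twice, so even with independent
per-pair distances the true variance of `L̄_W` is twice the formula's
within term; at `m = n` this inflates the null sd of Z to ≈ 1.16.
With distances computed from actual networks the shared-network dependence
distorts the null much further (measured sd ≈ 0.8 and strong
non-normality for i.i.d. random networks). Consequently the KS normality
check rejects N(0, 1) under matrix-derived exchangeable nulls; Z is
calibrated only under its own sampling assumptions — independent distance
draws with the formula's sample counts — which is exactly what
`z_from_distance_samples` lets one simulate, and what the calibration test
verifies. For real analyses the ratio statistic with the
permutation/transposition null is the trustworthy procedure; the Z-test is
provided as the parametric companion with this caveat documented. The KS
helper reports both statistic and p-value; a *small* p rejects normality.

## Covariance networks

Across-subject Pearson correlation (Spearman optional) with the diagonal
set to 0; zero-variance columns raise an error naming the node. Negative
correlations are kept and participate in the filtration over the full
weight range; an absolute-value transform exists but is off by default,
since truncation is a modelling decision the user should make explicitly.
Jackknife resampling is the standard leave-one-out scheme and is fully
deterministic.

## Synthetic generators and what they do (not) emulate

* `circle_pattern_networks` — the default pattern is two tangent unit
  circles (a figure-eight). Node phases sit on a fixed, evenly spaced
  lab-frame grid while the rotation is applied to the circle centres, with
  index blocks assigned to circles in canonical lab-frame order (greater-x
  centre first). This anchoring is deliberate: a rigid rotation of sampled
  points leaves all pairwise distances unchanged, so only a lab-anchored
  indexing lets a label-sensitive baseline (matrix L2) distinguish rotated
  groups while the topological distances — label-free by construction — do
  not. Rotation by π is an exact symmetry, so the two "horizontal" rotations
  (0, π) share one base geometry and the "vertical" ones (π/2, 3π/2)
  another. Defaults: 60 nodes, coordinate noise N(0, 0.3²), five networks
  per group. Distances are converted to affinities (`max − d`, per network)
  by default so that close node pairs carry large weights, matching the
  filtration polarity; the flag is exposed because raw distances are the
  opposite convention.
* `matched_weight_trees` — path/star (or random) trees sharing one sorted
  weight multiset drawn uniformly from (0.1, 1); the canonical example of
  topologically indistinguishable networks.
* `factor_model_table` — one shared standard-normal factor per subject:
  `x = sqrt(ρ)·f + sqrt(1−ρ)·e`, giving expected inter-node correlation ρ
  exactly. It produces exchangeable, homoscedastic Gaussian features with a
  *uniform* correlation structure — real morphometric tables have spatially
  structured correlations, site/age effects, and non-Gaussian tails, so
  passing tests demonstrate mechanism (higher ρ ⇒ fewer components, more
  cycles at a fixed threshold ⇒ detectable topological shift), not clinical
  realism.
* `random_complete_network` — i.i.d. uniform (or exponential) distinct edge
  weights; oracle fodder and the exchangeable null for calibration studies.

All generators accept ints or `numpy.random.Generator`s and are
byte-reproducible under fixed seeds; `2π` rotations reduce exactly to 0 via
IEEE remainder.

## Numerical and design choices

* Symmetry on ingest is exact for in-memory construction; file readers
  tolerate asymmetry up to 1e−8 (symmetrize + log) and refuse beyond.
* Grids: the linear threshold grid starts a hair (1e−9 of the range) below
  the minimum weight so the first point shows the intact graph; `exact`
  mode returns every distinct weight (the complete event set).
* Problem sizes in the validation suites (q ≤ 20 networks, m = n ≤ 25
  groups, 500-rep calibration with 2,000 resamples, 20-seed majority votes)
  are chosen so each study answers its statistical question — binomial CIs
  around nominal α, KS with 1,000 samples — while the full suite stays
  interactive (~10 s).
* Exhaustive spanning-tree enumeration oracles run at q ≤ 5; beyond that the
  independent check is networkx's maximum spanning tree, a separate
  implementation from the package's Kruskal.
* File formats print floats at `%.17g`, so write/read round-trips are exact;
  the pandas reader uses round-trip float parsing for the same reason.
* 1-based node indexing in file headers, 0-based internally.

## Known limitations

* Only the 1-skeleton is analysed: β₀ and β₁, no higher-dimensional homology,
  no Rips complexes beyond edges, no persistence pairing beyond the value
  sets.
* Distances require equal node counts and complete (or equal-size-diagram)
  inputs; no diagonal-matching optimal transport.
* Inference covers exactly two groups; no covariate adjustment. The ratio
  test is a global procedure over the whole filtration range, so no
  multiple-comparison correction is applied or needed.
* The Z-test's normal calibration holds only under its independence
  assumptions (see caveat above).
* Tractography-like networks that are mostly trees carry little 0D/1D
  information by design — the matched-weight tree example is the sharp
  statement of that limit.
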