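# topofilt

Topological data analysis of weighted networks via **graph filtration**, built
for group comparisons of brain connectivity — structural covariance networks
from morphometry (Jacobian determinants, FA values) as well as
tractography-based connectivity — but applicable to any collection of
symmetric weighted graphs.

Classical graph-theoretic analyses threshold a connectivity matrix at one
value and hope the conclusions do not depend on it. Persistent homology
removes the choice: a weighted graph `G = (V, w)` on `q` nodes is swept
through the nested family of binary graphs `G_ε` keeping edges with
`w_ij > ε`, and the topology of the whole sweep is the object of analysis.

## The method

**Birth–death decomposition.** As `ε` grows, edges disappear one at a time;
each disappearance either creates a new connected component (β₀ grows) or
destroys an independent cycle (β₁ shrinks). The edge weights therefore split
uniquely into

* a **birth set** `B_G = {ε_b1 < … < ε_b(q−1)}` — the weights of the maximum
  spanning forest (the 0D persistence diagram), and
* a **death set** `D_G = {ε_d1 < … < ε_dm1}`, `m₁ = (q−1)(q−2)/2` for a
  complete graph — all non-MSF weights (the 1D persistence diagram).

Both Betti curves follow from the sorted sets via the Euler characteristic
`β₀ − β₁ = q − E(ε)`; everything runs in `O(q² log q)`.

**Topological distances.** Because the diagrams are one-dimensional sorted
value sets, the 2-Wasserstein distances reduce to order statistics:

    d0(G1, G2) = Σᵢ (ε_bi¹ − ε_bi²)²,   d1(G1, G2) = Σᵢ (ε_di¹ − ε_di²)²,

combined as `d = w₀·d0 + w₁·d1` (equal weights by default). These are
label-free: relabelling nodes changes nothing, unlike the elementwise matrix
L2 norm.

**Inference.** Given two groups of networks, the ratio statistic
`φ = l_B / l_W` compares the between-group distance sum with the within-group
sum on a fixed pairwise-distance matrix. Its null distribution comes from
label permutations, or far faster from the **transposition test**, which
swaps one member of each group per step and updates `(l_W, l_B)`
incrementally in `O(m+n)` work, interspersing a full permutation every 1,000
steps. A parametric Z-test on the between/within distance means is also
provided, with a Kolmogorov–Smirnov helper to probe its normality.

**Covariance networks.** Subject × node feature tables become structural
covariance networks (across-subject correlation matrices); leave-one-out
jackknife resampling yields one group-level network per subject so that
group inference is possible even though each group has a single correlation
matrix.

## Worked example

```python
import topofilt as tf

# two trees, same sorted edge weights, different shapes
path_tree, star_tree = tf.matched_weight_trees(10, "path", "star", seed=0)
print("d0 =", tf.wasserstein0(path_tree, star_tree))
print("d1 =", tf.wasserstein1(path_tree, star_tree))
print("matrix L2 =", round(tf.matrix_euclidean_distance(path_tree, star_tree), 3))

# two-group covariance comparison: weak vs strong inter-node correlation
low = tf.factor_model_table(25, 30, rho=0.3, seed=1, subject_prefix="lo")
high = tf.factor_model_table(25, 30, rho=0.7, seed=2, subject_prefix="hi")
gdm = tf.pairwise_distances(tf.jackknife_networks(low), tf.jackknife_networks(high))
report = tf.transposition_test(gdm, n_transpositions=10_000, seed=3)
print("phi =", round(report.phi_observed, 2), " p =", round(report.p_value, 5))
```

prints

```
d0 = 0.0
d1 = 0.0
matrix L2 = 2.634
phi = 127.96  p = 0.0001
```

The first block shows the deliberate blind spot of graph-filtration
distances: two trees with identical sorted edge weights are topologically
indistinguishable (`d0 = d1 = 0` exactly) even though their weight matrices
are far apart — relevant for sparse tractography networks, which are mostly
one big tree. The second block shows the method's strength: jackknifed
covariance networks from a strongly correlated group (ρ = 0.7) differ
topologically from a weakly correlated one (ρ = 0.3), giving a large ratio
statistic and the smallest attainable add-one p-value, `1/10001`.

## Command line

`topofilt` exposes subcommands `decompose`, `betti`, `dist`, `test`,
`covnet`, `simulate`, and `pipeline` (YAML-configured end-to-end run writing
diagrams, Betti curves, distance matrices, a JSON report, and a log).

```sh
topofilt simulate --kind circles --n-networks 5 --seed 1 -o demo
topofilt betti demo -o demo
```

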