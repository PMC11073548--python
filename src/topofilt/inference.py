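"""Group-difference inference on a pairwise topological distance matrix.

Two procedures operate on a fixed ``(m+n) x (m+n)`` distance matrix with a
two-group labelling:

* the **ratio statistic** ``phi = l_B / l_W`` (between-group distance sum
  over within-group distance sum) with its null distribution obtained either
  by full label permutations or by the much cheaper *transposition test*,
  which swaps one member of each group per step and updates ``l_W``/``l_B``
  incrementally in O(m+n) work per step;
* a parametric **Z-test** comparing the average between- and within-group
  distances under an independence/normality approximation.

Distances are never recomputed during resampling — only the labelling moves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distance import GroupedDistanceMatrix
from .exceptions import (
    DegenerateDistanceError,
    DegenerateGroupingError,
    InvalidParameterError,
)

__all__ = [
    "RatioTestReport",
    "ZTestReport",
    "within_between_sums",
    "ratio_statistic",
    "permutation_test",
    "transposition_test",
    "transposition_update",
    "z_test",
    "z_from_distance_samples",
    "ks_normality_check",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioTestReport:
    """Result of a resampling test on the ratio statistic phi = l_B / l_W."""

    phi_observed: float
    null_values: np.ndarray
    p_value: float
    n_resamples: int
    method: str  # "permutation" or "transposition"
    seed: int | None
    full_perm_interval: int | None = None

    def summary(self) -> dict:
        nv = np.asarray(self.null_values)
        return {
            "statistic": "phi",
            "method": self.method,
            "phi_observed": self.phi_observed,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "full_perm_interval": self.full_perm_interval,
            "seed": self.seed,
            "null": {
                "count": int(nv.size),
                "mean": float(nv.mean()),
                "sd": float(nv.std(ddof=1)) if nv.size > 1 else 0.0,
                "quantiles": {
                    str(p): float(np.quantile(nv, p)) for p in (0.025, 0.25, 0.5, 0.75, 0.975)
                },
            },
        }


@dataclass(frozen=True)
class ZTestReport:
    """Result of the parametric Z-test on between- vs within-group distances."""

    mean_within: float
    mean_between: float
    var_within: float
    var_between: float
    z: float
    p_value: float

    def summary(self) -> dict:
        return {
            "statistic": "z",
            "mean_within": self.mean_within,
            "mean_between": self.mean_between,
            "var_within": self.var_within,
            "var_between": self.var_between,
            "z": self.z,
            "p_value": self.p_value,
        }


# ---------------------------------------------------------------------------
# sums and the ratio statistic
# ---------------------------------------------------------------------------

def _as_matrix_labels(D, labels=None):
    if isinstance(D, GroupedDistanceMatrix):
        if labels is None:
            labels = D.labels
        D = D.D01
    if labels is None:
        raise InvalidParameterError("labels are required for a plain distance matrix")
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidParameterError(f"distance matrix must be square, got {D.shape}")
    if len(labels) != D.shape[0]:
        raise InvalidParameterError("labels length must match distance matrix size")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise InvalidParameterError(f"exactly two groups required, got {len(uniq)}")
    lab01 = (labels == uniq[1]).astype(np.int8)
    return D, lab01


def within_between_sums(D, labels=None) -> tuple[float, float]:
    """Within-group and between-group distance sums ``(l_W, l_B)``.

    ``l_W`` sums each unordered within-group pair once (both groups);
    ``l_B`` sums all ``m*n`` cross-group pairs.
    """
    D, lab = _as_matrix_labels(D, labels)
    g1 = lab == 0
    g2 = ~g1
    l_w = float(D[np.ix_(g1, g1)].sum() / 2.0 + D[np.ix_(g2, g2)].sum() / 2.0)
    l_b = float(D[np.ix_(g1, g2)].sum())
    return l_w, l_b


def ratio_statistic(D, labels=None) -> float:
    """phi = l_B / l_W; large values indicate topological group difference."""
    D, lab = _as_matrix_labels(D, labels)
    m = int(np.sum(lab == 0))
    n = int(np.sum(lab == 1))
    if m < 2 or n < 2:
        raise DegenerateGroupingError(
            f"phi needs >= 2 members per group for within-pairs, got m={m}, n={n}"
        )
    l_w, l_b = within_between_sums(D, lab)
    if l_w == 0:
        raise DegenerateDistanceError("within-group distance sum is zero; phi undefined")
    return l_b / l_w


def _phi_for_memberships(D: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Vectorized phi for a batch of 0/1 group-1 membership rows.

    ``member`` is (P, N); returns phi per row.  Uses
    ``l_W = (g D g' + h D h')/2`` with h = 1-g, and l_B = total - l_W.
    """
    total = D.sum() / 2.0
    g = member.astype(float)
    h = 1.0 - g
    lw = (np.einsum("pi,ij,pj->p", g, D, g) + np.einsum("pi,ij,pj->p", h, D, h)) / 2.0
    lb = total - lw
    return lb / lw


def _tail_p(null: np.ndarray, observed: float) -> float:
    """One-sided add-one p-value: P(null >= observed)."""
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + len(null))


def permutation_test(D, labels=None, n_perms: int = 2000, seed=None) -> RatioTestReport:
    """Full-permutation null for phi by shuffling group labels.

    The distance matrix stays fixed; each resample permutes the labelling
    (equivalently, rows/columns) and re-evaluates phi.  One-sided p-value
    with the add-one rule: ``p = (1 + #{null >= observed}) / (1 + n_perms)``.
    """
    if n_perms < 1:
        raise InvalidParameterError("n_perms must be >= 1")
    D, lab = _as_matrix_labels(D, labels)
    phi_obs = ratio_statistic(D, lab)
    rng = np.random.default_rng(seed)
    N = len(lab)
    m = int(np.sum(lab == 0))
    # batch permutations: argsort of uniforms gives uniform random permutations
    null = np.empty(n_perms)
    batch = 2000
    done = 0
    while done < n_perms:
        b = min(batch, n_perms - done)
        order = np.argsort(rng.random((b, N)), axis=1)
        member = np.zeros((b, N))
        np.put_along_axis(member, order[:, :m], 1.0, axis=1)
        null[done : done + b] = _phi_for_memberships(D, member)
        done += b
    p = _tail_p(null, phi_obs)
    return RatioTestReport(
        phi_observed=phi_obs,
        null_values=null,
        p_value=p,
        n_resamples=n_perms,
        method="permutation",
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def transposition_test(
    D,
    labels=None,
    n_transpositions: int = 10_000,
    full_perm_interval: int = 1000,
    seed=None,
) -> RatioTestReport:
    """Online permutation null for phi via single-pair transpositions.

    Each step swaps one member of each group and updates ``l_W`` and ``l_B``
    through the delta of the two touched rows (O(m+n) work; the matrix is
    never rescanned).  Every ``full_perm_interval`` steps the labelling is
    replaced by a fresh uniform permutation to mitigate the chain's serial
    correlation.  The null trace collects phi after every step.
    """
    if n_transpositions < 1:
        raise InvalidParameterError("n_transpositions must be >= 1")
    if full_perm_interval < 1:
        raise InvalidParameterError("full_perm_interval must be >= 1")
    D, lab0 = _as_matrix_labels(D, labels)
    phi_obs = ratio_statistic(D, lab0)
    rng = np.random.default_rng(seed)

    lab = lab0.copy()
    l_w, l_b = within_between_sums(D, lab)
    null = np.empty(n_transpositions)
    for step in range(n_transpositions):
        if (step + 1) % full_perm_interval == 0:
            # full refresh: new uniform labelling, state recomputed once
            lab = rng.permutation(lab)
            l_w, l_b = within_between_sums(D, lab)
        else:
            g1_idx = np.flatnonzero(lab == 0)
            g2_idx = np.flatnonzero(lab == 1)
            a = g1_idx[rng.integers(len(g1_idx))]
            b = g2_idx[rng.integers(len(g2_idx))]
            l_w, l_b = transposition_update(D, lab, l_w, l_b, a, b)
            lab[a], lab[b] = lab[b], lab[a]
        null[step] = l_b / l_w
    p = _tail_p(null, phi_obs)
    return RatioTestReport(
        phi_observed=phi_obs,
        null_values=null,
        p_value=p,
        n_resamples=n_transpositions,
        method="transposition",
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        full_perm_interval=full_perm_interval,
    )


def transposition_update(D, lab, l_w, l_b, a, b):
    """Delta update of (l_W, l_B) for swapping index ``a`` (group 1) with ``b`` (group 2).

    Only the rows of ``a`` and ``b`` are touched.  Pairs of ``a`` with
    current group-1 members leave the within sum and enter the between sum
    (and conversely for its group-2 pairs); ``b`` mirrors this.  The pair
    ``(a, b)`` itself stays between-group.
    """
    g1 = lab == 0
    g2 = ~g1
    row_a = D[a]
    row_b = D[b]
    s1a = row_a[g1].sum() - row_a[a]          # a's within-group-1 pairs (excl. itself)
    s2a = row_a[g2].sum() - row_a[b]          # a's group-2 pairs excl. (a, b)
    s1b = row_b[g1].sum() - row_b[a]          # b's group-1 pairs excl. (a, b)
    s2b = row_b[g2].sum() - row_b[b]
    delta_w = (s2a - s1a) + (s1b - s2b)
    delta_b = (s1a - s2a) + (s2b - s1b)
    return l_w + delta_w, l_b + delta_b


# ---------------------------------------------------------------------------
# parametric Z-test
# ---------------------------------------------------------------------------

def z_test(D, labels=None) -> ZTestReport:
    """Z-test on the difference of average between- and within-group distances.

    Moments are taken over ordered pairs: the within mean divides the ordered
    within-pair sum by ``m(m-1) + n(n-1)`` and the between mean divides by
    ``m*n``.  The statistic is

        Z = (mean_B - mean_W) / sqrt(V_B/(m n) + V_W/(m(m-1) + n(n-1)))

    with the one-sided upper-tail normal p-value (alternative: between-group
    distances exceed within-group distances).
    """
    D, lab = _as_matrix_labels(D, labels)
    m = int(np.sum(lab == 0))
    n = int(np.sum(lab == 1))
    if m < 2 or n < 2:
        raise DegenerateGroupingError(f"z-test needs m, n >= 2, got m={m}, n={n}")
    g1 = lab == 0
    g2 = ~g1
    W = np.concatenate(
        [D[np.ix_(g1, g1)][np.triu_indices(m, k=1)], D[np.ix_(g2, g2)][np.triu_indices(n, k=1)]]
    )
    B = D[np.ix_(g1, g2)].ravel()
    if not (np.any(W) or np.any(B)):
        raise DegenerateDistanceError("all pairwise distances are zero")
    # the ordered within-pair sample duplicates each unordered distance;
    # sums and moments below then carry the ordered-pair denominators
    return z_from_distance_samples(np.concatenate([W, W]), B, m, n)


def z_from_distance_samples(within, between, m: int, n: int) -> ZTestReport:
    """Z-test from raw distance samples with the ordered-pair denominators.

    ``within`` must hold the ordered within-pair sample (length
    ``m(m-1) + n(n-1)``; on a symmetric distance matrix each unordered
    distance appears twice) and ``between`` the ``m*n`` cross distances.
    Separated from :func:`z_test` so calibration studies can feed simulated
    distance samples through the identical moment/Z computation.
    """
    W = np.asarray(within, dtype=float)
    B = np.asarray(between, dtype=float)
    n_w = m * (m - 1) + n * (n - 1)
    n_b = m * n
    if len(W) != n_w or len(B) != n_b:
        raise InvalidParameterError(
            f"expected {n_w} ordered within and {n_b} between distances, "
            f"got {len(W)} and {len(B)}"
        )
    mean_w = W.sum() / n_w
    mom2_w = (W**2).sum() / n_w
    mean_b = B.sum() / n_b
    mom2_b = (B**2).sum() / n_b
    var_w = mom2_w - mean_w**2
    var_b = mom2_b - mean_b**2
    if var_w < 0 or var_b < 0:
        warnings.warn("negative variance from floating-point cancellation; clipped to 0")
        log.warning("variance clipped: var_w=%g var_b=%g", var_w, var_b)
        var_w = max(var_w, 0.0)
        var_b = max(var_b, 0.0)
    se = np.sqrt(var_b / n_b + var_w / n_w)
    if se == 0:
        raise DegenerateDistanceError("pooled variance is zero; Z undefined")
    z = (mean_b - mean_w) / se
    p = float(stats.norm.sf(z))
    return ZTestReport(
        mean_within=float(mean_w),
        mean_between=float(mean_b),
        var_within=float(var_w),
        var_between=float(var_b),
        z=float(z),
        p_value=p,
    )


def ks_normality_check(z_samples) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov check of ``z_samples`` against N(0, 1)."""
    z = np.asarray(z_samples, dtype=float)
    if z.size < 10:
        raise InvalidParameterError(f"need >= 10 samples for the KS check, got {z.size}")
    res = stats.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue)
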