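"""Ordination and permutation inference for shape data.

PCA with shape-space back-projection, one-way PERMANOVA (Anderson's
distance-based pseudo-F with whole-label permutation), pairwise comparisons
with multiplicity adjustment, Welch tests on centroid sizes, and the
shape-on-size (allometry) regression.

All permutation routines take an explicit seed; the permutation p-value
includes the observed statistic in numerator and denominator, so it is never
zero and is bounded below by 1/(n_permutations + 1). When the number of
distinct label arrangements is small (<= 10 000) the exact permutation
distribution is enumerated instead of sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "PCAModel",
    "PermanovaResult",
    "RegressionResult",
    "pca_fit",
    "pc_shape_vectors",
    "permanova",
    "pairwise_permanova",
    "size_group_tests",
    "shape_size_regression",
    "significance_stars",
]

EXHAUSTIVE_LIMIT = 10_000


# --------------------------------------------------------------------------- PCA

@dataclass(frozen=True)
class PCAModel:
    """Principal component decomposition of a shapes x features matrix."""

    mean: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)  # rows, orthonormal
    eigenvalues: np.ndarray = field(repr=False)   # non-increasing
    scores: np.ndarray = field(repr=False)

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, float) - self.mean) @ self.eigenvectors.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self.mean + np.asarray(scores, float) @ self.eigenvectors

    def summary(self) -> str:
        lines = ["Principal component analysis",
                 f"  shapes x features: {self.scores.shape[0]} x {len(self.mean)}"]
        for i, (ev, vf) in enumerate(zip(self.eigenvalues[:5], self.variance_fractions[:5])):
            lines.append(f"  PC{i + 1}: eigenvalue {ev:.4g}  ({100 * vf:.1f}% variance)")
        return "\n".join(lines)


def pca_fit(data: np.ndarray) -> PCAModel:
    """PCA of the feature covariance (divisor n-1) via SVD of centered data.

    Components are ordered by decreasing eigenvalue with a deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (x.shape[0] - 1)
    if eigenvalues.sum() <= 0:
        raise ValueError("constant data: all eigenvalues zero")
    # sign convention
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = xc @ vt.T
    return PCAModel(mean=mean, eigenvectors=vt, eigenvalues=eigenvalues, scores=scores)


def pc_shape_vectors(model: PCAModel, pc: int, magnitude: float,
                     context: str = "procrustes_coords", n_points: int = 360):
    """Back-project a principal axis into shape space.

    Returns the pair of shapes at mean -/+ ``magnitude * sqrt(eigenvalue)``
    along component ``pc`` (0-based). In the ``procrustes_coords`` context the
    feature vector is reshaped to (k, 2) coordinates; in the ``eft_coefs``
    context it is interpreted as a harmonic coefficient row and reconstructed
    as an outline sampled at ``n_points``.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if not 0 <= pc < model.n_components:
        raise ValueError(f"pc {pc} out of range (0..{model.n_components - 1})")
    if context not in ("procrustes_coords", "eft_coefs"):
        raise ValueError(f"unknown context {context!r}")
    excursion = magnitude * math.sqrt(model.eigenvalues[pc]) * model.eigenvectors[pc]
    lo = model.mean - excursion
    hi = model.mean + excursion
    if context == "procrustes_coords":
        return lo.reshape(-1, 2), hi.reshape(-1, 2)
    from .eft import EFTCoefficients, eft_inverse

    shapes = []
    for row in (lo, hi):
        coef = EFTCoefficients(dc=(0.0, 0.0), harmonics=row.reshape(-1, 4))
        shapes.append(eft_inverse(coef, n_points))
    return tuple(shapes)


# ------------------------------------------------------------------- PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA outcome: pseudo-F, R^2 and permutation p-values."""

    pseudo_F: float
    R2: float
    p_raw: float
    n_permutations: int
    seed: int | None
    group_sizes: tuple
    ss_between: float
    ss_within: float
    ss_total: float
    exhaustive: bool = False
    p_adjusted: float | None = None

    def summary(self) -> str:
        adj = f", adj. p = {self.p_adjusted:.4g}" if self.p_adjusted is not None else ""
        mode = "exact" if self.exhaustive else f"{self.n_permutations} permutations"
        return (f"PERMANOVA: F = {self.pseudo_F:.4g}, R^2 = {self.R2:.4g}, "
                f"p = {self.p_raw:.4g}{adj} ({mode}; "
                f"groups n = {list(self.group_sizes)})")


def _encode_groups(groups) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    return labels, codes


def _ss_decomposition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Anderson's sums of squares from squared distances and integer labels."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def _pseudo_f_batch(d2: np.ndarray, code_matrix: np.ndarray, n_groups: int,
                    counts: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of label codes in ``code_matrix`` (B x N)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(code_matrix.shape[0])
    for g in range(n_groups):
        m = (code_matrix == g).astype(float)
        ss_within += np.einsum("bi,ij,bj->b", m, d2, m) / (2.0 * counts[g])
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    return (ss_between / df_b) / (ss_within / df_w)


def _n_arrangements(counts: np.ndarray) -> float:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(data, groups, n_permutations: int = 999, seed: int | None = None,
              distance: bool = False, method: str = "auto") -> PermanovaResult:
    """One-way PERMANOVA on a feature matrix (Euclidean) or a distance matrix.

    The test statistic is Anderson's pseudo-F from the distance-based sum of
    squares decomposition; significance comes from whole-label permutation.
    With ``method="auto"`` the exact permutation distribution is enumerated
    whenever the distinct label arrangements number at most 10 000 (``seed``
    unused there); otherwise ``n_permutations`` random relabelings are drawn
    from ``seed``. ``method="exact"`` / ``"monte_carlo"`` force one route.
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    labels, codes = _encode_groups(groups)
    n_groups = len(labels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[np.argmin(counts)]
        raise ValueError(f"group {small!r} has fewer than 2 members")

    if distance:
        d = np.asarray(data, dtype=float)
        if d.shape[0] != d.shape[1]:
            raise ValueError("distance=True requires a square matrix")
        d2 = d**2
    else:
        x = np.asarray(data, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        d2 = squareform(pdist(x, "sqeuclidean"))
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite distances")
    n = d2.shape[0]
    if len(codes) != n:
        raise ValueError("groups length does not match data")

    ss_total, ss_within = _ss_decomposition(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total

    n_arr = _n_arrangements(counts)
    if method == "exact" and n_arr > EXHAUSTIVE_LIMIT:
        raise ValueError(f"{n_arr} arrangements is too many to enumerate")
    if method != "monte_carlo" and n_arr <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(multiset_permutations(codes.tolist())))
        f_perm = _pseudo_f_batch(d2, perms, n_groups, counts)
        p = float(np.count_nonzero(f_perm >= f_obs - 1e-12) / len(f_perm))
        return PermanovaResult(
            pseudo_F=float(f_obs), R2=float(r2), p_raw=p,
            n_permutations=len(f_perm), seed=seed, group_sizes=tuple(counts),
            ss_between=float(ss_between), ss_within=float(ss_within),
            ss_total=float(ss_total), exhaustive=True)

    if seed is None:
        raise ValueError("seed is required for Monte-Carlo permutation")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
    f_perm = _pseudo_f_batch(d2, perms, n_groups, counts)
    p = float((1 + np.count_nonzero(f_perm >= f_obs - 1e-12)) / (1 + n_permutations))
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2), p_raw=p,
        n_permutations=n_permutations, seed=seed, group_sizes=tuple(counts),
        ss_between=float(ss_between), ss_within=float(ss_within),
        ss_total=float(ss_total), exhaustive=False)


def _adjust(p_values: np.ndarray, method: str) -> np.ndarray:
    m = len(p_values)
    if method == "none":
        return p_values.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p_values)
    if method == "holm":
        order = np.argsort(p_values)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_values[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def pairwise_permanova(data, groups, n_permutations: int = 999,
                       seed: int | None = None, adjust: str = "bonferroni",
                       distance: bool = False) -> list:
    """PERMANOVA on every group pair's subset, with multiplicity adjustment.

    Returns ``[(label_a, label_b, PermanovaResult), ...]`` where each result
    carries ``p_adjusted`` over the number of pairs tested (Bonferroni by
    default: min(1, m * p_raw))."""
    labels, codes = _encode_groups(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    groups_arr = np.asarray(groups)
    data = np.asarray(data, dtype=float)
    results = []
    pairs = list(combinations(labels, 2))
    for j, (ga, gb) in enumerate(pairs):
        sel = (groups_arr == ga) | (groups_arr == gb)
        sub = data[np.ix_(sel, sel)] if distance else data[sel]
        sub_seed = None if seed is None else int((seed + 7919 * j) % (2**31))
        res = permanova(sub, groups_arr[sel], n_permutations=n_permutations,
                        seed=sub_seed, distance=distance)
        results.append((ga, gb, res))
    p_adj = _adjust(np.array([r.p_raw for _, _, r in results]), adjust)
    out = []
    for (ga, gb, r), pa in zip(results, p_adj):
        out.append((ga, gb, PermanovaResult(
            pseudo_F=r.pseudo_F, R2=r.R2, p_raw=r.p_raw,
            n_permutations=r.n_permutations, seed=r.seed,
            group_sizes=r.group_sizes, ss_between=r.ss_between,
            ss_within=r.ss_within, ss_total=r.ss_total,
            exhaustive=r.exhaustive, p_adjusted=float(pa))))
    return out


# --------------------------------------------------------- size and allometry

def size_group_tests(sizes, groups) -> list:
    """Pairwise two-sided Welch tests on centroid sizes.

    Returns ``[(label_a, label_b, p_value, mean_a, mean_b), ...]`` with raw
    (unadjusted) p-values; the sign of ``mean_a - mean_b`` gives the effect
    direction."""
    sizes = np.asarray(sizes, dtype=float)
    groups_arr = np.asarray(groups)
    labels = np.unique(groups_arr)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for ga, gb in combinations(labels, 2):
        a = sizes[groups_arr == ga]
        b = sizes[groups_arr == gb]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"groups {ga!r}/{gb!r} need at least 2 sizes each")
        if a.std() == 0 and b.std() == 0:
            raise ValueError(f"zero variance in both groups {ga!r} and {gb!r}")
        stat = sps.ttest_ind(a, b, equal_var=False)
        out.append((ga, gb, float(stat.pvalue), float(a.mean()), float(b.mean())))
    return out


@dataclass(frozen=True)
class RegressionResult:
    """Shape-on-size regression: allometry strength and significance."""

    R2: float
    p_perm: float
    coefficient_vector: np.ndarray = field(repr=False)
    n_permutations: int = 0
    seed: int | None = None

    def summary(self) -> str:
        return (f"Shape-on-size regression: R^2 = {self.R2:.4g}, "
                f"permutation p = {self.p_perm:.4g} "
                f"({self.n_permutations} permutations)")


def shape_size_regression(aligned, sizes, n_permutations: int = 999,
                          seed: int | None = 0) -> RegressionResult:
    """Multivariate regression of aligned coordinates on log centroid size.

    R^2 is the fraction of total coordinate variance explained by the single
    log-size predictor (SS_model / SS_total over the whole coordinate
    matrix); significance comes from permuting the sizes across specimens.
    """
    y = aligned.coordinate_matrix if hasattr(aligned, "coordinate_matrix") \
        else np.asarray(aligned, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(sizes) != y.shape[0]:
        raise ValueError("one size per shape required")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    x = np.log(sizes)
    if np.ptp(x) == 0:
        raise ValueError("constant sizes: regression undefined")

    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    ss_total = (yc**2).sum()
    if ss_total == 0:
        return RegressionResult(R2=0.0, p_perm=1.0,
                                coefficient_vector=np.zeros(y.shape[1]),
                                n_permutations=n_permutations, seed=seed)

    def model_ss(xv):
        beta = (xv @ yc) / (xv @ xv)
        return (np.outer(xv, beta) ** 2).sum(), beta

    ss_model, beta = model_ss(xc)
    r2 = ss_model / ss_total

    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_permutations):
        ssm, _ = model_ss(rng.permutation(xc))
        if ssm >= ss_model - 1e-12:
            count += 1
    p = count / (n_permutations + 1)
    return RegressionResult(R2=float(r2), p_perm=float(p), coefficient_vector=beta,
                            n_permutations=n_permutations, seed=seed)


def significance_stars(p: float) -> str:
    """Three-tier star convention: * <0.05, ** <0.01, *** <0.005."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
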