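"""Neural-manifold geometry: mean-field capacity and an empirical oracle.

A *manifold* here is the set of feature vectors a layer produces for all
exemplars of one word class.  Two families of measures are implemented:

* **Mean-field analysis** (:func:`mft_analysis`): the replica mean-field
  procedure for manifold classification capacity.  For each class manifold,
  centered points are expressed in their D-dimensional affine subspace,
  scaled by the norm of the class center, and augmented with a constant
  center coordinate.  Gaussian vectors ``t`` are drawn in that (D+1)-space
  and projected onto the feasible set {v : v.s <= -kappa for all manifold
  points s} (a convex QP solved in its dual, which for kappa = 0 is exactly
  non-negative least squares).  The KKT multipliers identify the *anchor
  point* s~(t), the convex combination of manifold points that realizes the
  constraint, and the capacity, effective dimension and radius are moments
  of the anchor statistics:

      1 / alpha_c = < [t.s~ + kappa]_+^2 / ||s~||^2 >
      D_c         = (D + 1) < (t_hat . s~_hat)^2 >
      R_c         = sqrt( < ||s~_(1:D)||^2 > )      (in center-norm units)

  For singleton manifolds (points) this reduces analytically to the classic
  capacity alpha = 2 of homogeneous linear separation.

* **Empirical separability** (:func:`separable_fraction`,
  :func:`empirical_capacity`): draw random balanced dichotomies of the class
  manifolds, decide strict homogeneous linear separability *exactly* by
  linear-program feasibility, and locate the dimension at which half the
  dichotomies are separable.  On point manifolds in general position the
  fraction has a closed form, Cover's function count
  (:func:`cover_fraction`), used as the independent oracle in tests.

Capacity is a per-dimension load (classes per feature dimension), which is
what makes layers of different widths comparable after the random-projection
standardization in :func:`prepare_manifolds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize, nnls

from .errors import (
    DegenerateDataError,
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
)

__all__ = [
    "ActivationSet",
    "ManifoldSet",
    "ManifoldGeometryResult",
    "CapacityEstimate",
    "prepare_manifolds",
    "mft_analysis",
    "is_linearly_separable",
    "separable_fraction",
    "empirical_capacity",
    "cover_fraction",
    "participation_ratio",
]


@dataclass
class ActivationSet:
    """Per-layer, per-class feature vectors extracted from a network.

    ``layers`` maps a layer id to a list of (m_c, N) arrays, one per class in
    ``class_ids`` order.
    """

    layers: dict[str, list[np.ndarray]]
    class_ids: list[int]

    def layer(self, layer_id: str) -> "ActivationSet":
        """Single-layer view."""
        if layer_id not in self.layers:
            raise InvalidInputError(f"unknown layer id {layer_id!r}")
        return ActivationSet(layers={layer_id: self.layers[layer_id]}, class_ids=self.class_ids)

    @property
    def layer_ids(self) -> list[str]:
        return list(self.layers.keys())


@dataclass
class ManifoldSet:
    """P class manifolds of M points each, globally centered, ready for analysis."""

    manifolds: np.ndarray  # (P, M, N)
    class_ids: list[int] = field(default_factory=list)
    layer_id: str = ""
    projection_seed: int | None = None

    @property
    def P(self) -> int:
        return self.manifolds.shape[0]

    @property
    def M(self) -> int:
        return self.manifolds.shape[1]

    @property
    def N(self) -> int:
        return self.manifolds.shape[2]


@dataclass
class ManifoldGeometryResult:
    layer_id: str
    alpha: float  # aggregate capacity: 1 / mean(1/alpha_c)
    dimension: float  # mean of D_c
    radius: float  # mean of R_c
    alpha_per_class: np.ndarray
    dimension_per_class: np.ndarray
    radius_per_class: np.ndarray
    alpha_se: float  # Monte-Carlo standard error of the aggregate capacity
    n_gaussian_samples: int = 0
    kappa: float = 0.0


@dataclass
class CapacityEstimate:
    alpha: float  # P / n_star
    n_star: int
    curve: list[tuple[int, float]]  # probed (n_dims, separable fraction) pairs


def prepare_manifolds(
    acts: ActivationSet,
    M: int = 30,
    N_proj: int = 2000,
    seed: int = 0,
    layer_id: str | None = None,
) -> ManifoldSet:
    """Subsample M exemplars per class, center globally, optionally project.

    The projection is random orthonormal, scaled by sqrt(N / N_proj) so that
    pairwise distances are preserved in expectation (Johnson-Lindenstrauss).
    A class with fewer than M exemplars is an error, never silently resampled.
    """
    if layer_id is None:
        if len(acts.layers) != 1:
            raise InvalidInputError("ActivationSet holds several layers; pass layer_id")
        layer_id = next(iter(acts.layers))
    per_class = acts.layer(layer_id).layers[layer_id]
    rng = np.random.default_rng(seed)
    rows = []
    for cid, feats in zip(acts.class_ids, per_class):
        feats = np.asarray(feats, dtype=np.float64)
        if feats.shape[0] < M:
            raise InsufficientDataError(
                f"class {cid} has {feats.shape[0]} exemplars, needs {M}"
            )
        keep = rng.choice(feats.shape[0], size=M, replace=False)
        rows.append(feats[np.sort(keep)])
    X = np.stack(rows)  # (P, M, N)
    X = X - X.reshape(-1, X.shape[-1]).mean(axis=0)
    N = X.shape[-1]
    if N > N_proj:
        G = rng.standard_normal((N, N_proj))
        Q, _ = np.linalg.qr(G)
        X = (X @ Q) * math.sqrt(N / N_proj)
    return ManifoldSet(
        manifolds=X, class_ids=list(acts.class_ids), layer_id=layer_id, projection_seed=seed
    )


# ---------------------------------------------------------------------------
# Mean-field analysis
# ---------------------------------------------------------------------------


def _anchor_project(sD1: np.ndarray, t: np.ndarray, kappa: float) -> np.ndarray:
    """Dual of min ||v - t||^2 s.t. sD1.T v <= -kappa; returns multipliers."""
    if kappa == 0.0:
        alpha, _ = nnls(sD1, t)
        return alpha
    S = sD1
    Q = S.T @ S
    b = S.T @ t + kappa
    m = S.shape[1]

    def fg(a):
        Qa = Q @ a
        return 0.5 * a @ Qa - a @ b, Qa - b

    res = minimize(fg, np.zeros(m), jac=True, method="L-BFGS-B", bounds=[(0, None)] * m)
    return res.x


def _analyze_one_manifold(
    points: np.ndarray, center_norm_floor: float, kappa: float, n_t: int, rng
) -> tuple[float, float, float, np.ndarray]:
    """Anchor-point statistics for one manifold.

    ``points``: (M, N) globally-centered features of one class.  Returns
    (inv_alpha_mean, D_c, R_c, per-sample inverse-capacity contributions).
    """
    center = points.mean(axis=0)
    centered = points - center
    # Basis of the manifold's own subspace: thin SVD of the centered points.
    if points.shape[0] > 1:
        _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
        rank = int(np.sum(sv > 1e-10 * max(sv[0], 1e-300)))
    else:
        rank = 0
    c_norm = float(np.linalg.norm(center))
    c_norm = max(c_norm, center_norm_floor)
    if rank > 0:
        coords = centered @ Vt[:rank].T / c_norm  # (M, D)
    else:
        coords = np.zeros((points.shape[0], 0))
    D = rank
    sD1 = np.concatenate([coords, np.ones((points.shape[0], 1))], axis=1).T  # (D+1, M)

    T = rng.standard_normal((n_t, D + 1))
    s_all = np.empty((n_t, D + 1))
    for i in range(n_t):
        t = T[i]
        g = t @ sD1
        if g.max() + kappa <= 0:
            # t is already a separating field; anchor = maximally aligned point.
            s_all[i] = sD1[:, np.argmax(g)]
            continue
        a = _anchor_project(sD1, t, kappa)
        tot = a.sum()
        if tot <= 1e-12:
            s_all[i] = sD1[:, np.argmax(g)]
        else:
            s_all[i] = (sD1 @ a) / tot

    ts = np.einsum("ij,ij->i", T, s_all)
    s_sq = np.einsum("ij,ij->i", s_all, s_all)
    inv_alpha_samples = np.maximum(ts + kappa, 0.0) ** 2 / s_sq
    t_hat = T / np.linalg.norm(T, axis=1, keepdims=True)
    s_hat = s_all / np.sqrt(s_sq)[:, None]
    D_c = (D + 1) * float(np.mean(np.einsum("ij,ij->i", t_hat, s_hat) ** 2))
    R_c = float(np.sqrt(np.mean(np.sum(s_all[:, :D] ** 2, axis=1))))
    return float(inv_alpha_samples.mean()), D_c, R_c, inv_alpha_samples


def mft_analysis(
    ms: ManifoldSet, n_gaussian_samples: int = 150, kappa: float = 0.0, seed: int = 0
) -> ManifoldGeometryResult:
    """Mean-field capacity, dimension, and radius of a ManifoldSet.

    Aggregate capacity is the inverse of the mean inverse per-class capacity
    (the load at which a mixture of the manifolds reaches its separability
    threshold); aggregate dimension and radius are plain means.
    """
    if n_gaussian_samples < 50:
        raise InvalidInputError("n_gaussian_samples must be >= 50")
    X = np.asarray(ms.manifolds, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("manifold features must be finite")
    P = X.shape[0]
    if P < 2:
        raise InvalidInputError("need at least 2 manifolds")

    centers = X.mean(axis=1)
    spreads = np.linalg.norm(X - centers[:, None, :], axis=2).max(axis=1)
    for i in range(P):
        if spreads[i] < 1e-12:
            d = np.linalg.norm(centers - centers[i], axis=1)
            d[i] = np.inf
            if d.min() < 1e-12:
                raise DegenerateGeometryError(
                    f"manifold {i} is a point coincident with another class"
                )
    center_floor = 1e-12 * max(float(np.linalg.norm(centers, axis=1).max()), 1.0)

    rng = np.random.default_rng(seed)
    inv_alpha = np.empty(P)
    D_cs = np.empty(P)
    R_cs = np.empty(P)
    sample_vars = np.empty(P)
    for i in range(P):
        ia, D_c, R_c, samples = _analyze_one_manifold(
            X[i], center_floor, kappa, n_gaussian_samples, rng
        )
        inv_alpha[i], D_cs[i], R_cs[i] = ia, D_c, R_c
        sample_vars[i] = samples.var(ddof=1) / n_gaussian_samples
    mean_inv = inv_alpha.mean()
    alpha = 1.0 / mean_inv if mean_inv > 0 else np.inf
    # SE of alpha by the delta method on the pooled mean of 1/alpha samples.
    se_mean_inv = math.sqrt(sample_vars.sum()) / P
    alpha_se = alpha**2 * se_mean_inv if np.isfinite(alpha) else np.inf
    with np.errstate(divide="ignore"):
        alpha_per_class = 1.0 / inv_alpha
    return ManifoldGeometryResult(
        layer_id=ms.layer_id,
        alpha=float(alpha),
        dimension=float(D_cs.mean()),
        radius=float(R_cs.mean()),
        alpha_per_class=alpha_per_class,
        dimension_per_class=D_cs,
        radius_per_class=R_cs,
        alpha_se=float(alpha_se),
        n_gaussian_samples=n_gaussian_samples,
        kappa=kappa,
    )


# ---------------------------------------------------------------------------
# Empirical linear-separability oracle
# ---------------------------------------------------------------------------


def is_linearly_separable(pos: np.ndarray, neg: np.ndarray) -> bool:
    """Exact strict homogeneous separability via LP feasibility.

    True iff some hyperplane through the origin has every ``pos`` point
    strictly on one side and every ``neg`` point strictly on the other
    (equivalently, w with Z w >= 1 for Z = [pos; -neg] is feasible).
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
    neg = np.atleast_2d(np.asarray(neg, dtype=np.float64))
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both point sets must be non-empty")
    if pos.shape[1] != neg.shape[1]:
        raise InvalidInputError("point sets differ in dimension")
    Z = np.vstack([pos, -neg])
    n = Z.shape[1]
    res = linprog(
        c=np.zeros(n),
        A_ub=-Z,
        b_ub=-np.ones(Z.shape[0]),
        bounds=[(None, None)] * n,
        method="highs",
    )
    if res.status == 0:
        return True
    if res.status == 2:
        return False
    raise RuntimeError(f"LP solver failed with status {res.status}: {res.message}")


def _dichotomy_separable(X: np.ndarray, labels: np.ndarray) -> bool:
    """Separability of the pooled exemplars under a per-manifold labeling."""
    P, M, _ = X.shape
    pos = X[labels > 0].reshape(-1, X.shape[-1])
    neg = X[labels < 0].reshape(-1, X.shape[-1])
    return is_linearly_separable(pos, neg)


def _sample_dichotomies(P: int, n_dichotomies: int, rng) -> np.ndarray:
    """Random +/-1 labelings with both signs present, canonicalized later."""
    out = np.empty((n_dichotomies, P), dtype=np.int8)
    for i in range(n_dichotomies):
        while True:
            lab = rng.choice([-1, 1], size=P)
            if lab.max() > 0 and lab.min() < 0:
                out[i] = lab
                break
    return out


def separable_fraction(
    ms: ManifoldSet, n_dims: int, n_dichotomies: int, seed: int, _labelings=None
) -> float:
    """Fraction of random manifold dichotomies separable in ``n_dims``.

    All points are first passed through one seeded random orthonormal
    projection to ``n_dims``.  A dichotomy and its negation have identical
    separability, so results are cached on the sign-canonicalized labeling.
    """
    X = np.asarray(ms.manifolds, dtype=np.float64)
    P, _, N = X.shape
    if P < 2:
        raise InvalidInputError("need at least 2 manifolds")
    if not (1 <= n_dims <= N):
        raise InvalidInputError(f"n_dims={n_dims} outside [1, {N}]")
    if n_dichotomies < 1:
        raise InvalidInputError("n_dichotomies must be >= 1")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((N, n_dims)))
    Xp = X @ Q
    labelings = _labelings if _labelings is not None else _sample_dichotomies(P, n_dichotomies, rng)
    cache: dict[bytes, bool] = {}
    hits = 0
    for lab in labelings:
        canon = (lab * lab[0]).tobytes()
        if canon not in cache:
            cache[canon] = _dichotomy_separable(Xp, lab)
        hits += cache[canon]
    return hits / len(labelings)


def empirical_capacity(
    ms: ManifoldSet,
    f_target: float = 0.5,
    n_dichotomies: int = 200,
    seed: int = 0,
) -> CapacityEstimate:
    """Simulated capacity: P / n*, with n* the separability half-point.

    Bisection over projection dimension n locates the smallest n whose
    separable fraction reaches ``f_target``; the same dichotomy sample is
    reused at every probe (common random numbers) so the crossing is stable.
    """
    X = np.asarray(ms.manifolds, dtype=np.float64)
    P, _, N = X.shape
    if P < 2:
        raise InvalidInputError("need at least 2 manifolds")
    rng = np.random.default_rng(seed)
    labelings = _sample_dichotomies(P, n_dichotomies, rng)
    proj_seeds = np.random.SeedSequence(seed).generate_state(N + 1)

    curve: dict[int, float] = {}

    def frac(n: int) -> float:
        if n not in curve:
            curve[n] = separable_fraction(
                ms, n, n_dichotomies, int(proj_seeds[n] % 2**31), _labelings=labelings
            )
        return curve[n]

    lo, hi = 1, N
    if frac(hi) < f_target:
        raise OutOfRangeError(
            f"separable fraction never reaches {f_target} within [1, {N}]",
            curve=sorted(curve.items()),
        )
    if frac(lo) >= f_target:
        n_star = 1
    else:
        # invariant: frac(lo) < f_target <= frac(hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if frac(mid) >= f_target:
                hi = mid
            else:
                lo = mid
        n_star = hi
    return CapacityEstimate(alpha=P / n_star, n_star=n_star, curve=sorted(curve.items()))


def cover_fraction(P: int, n: int) -> float:
    """Cover's function count: the fraction of the 2^P dichotomies of P
    points in general position that are homogeneously linearly separable in
    n dimensions, 2^(1-P) * sum_{k<n} C(P-1, k); saturates at 1 for n >= P."""
    if P < 1 or n < 1:
        raise InvalidInputError("P and n must be >= 1")
    if n >= P:
        return 1.0
    total = sum(math.comb(P - 1, k) for k in range(n))
    return 2.0 ** (1 - P) * total


def participation_ratio(points: np.ndarray) -> float:
    """Covariance-spectrum effective dimension: (sum l_i)^2 / sum l_i^2."""
    X = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if X.shape[0] < 2 or np.allclose(X, X[0]):
        raise DegenerateDataError("participation ratio needs >= 2 distinct points")
    C = np.cov(X, rowvar=False)
    eig = np.linalg.eigvalsh(np.atleast_2d(C))
    eig = np.clip(eig, 0.0, None)
    return float(eig.sum() ** 2 / np.sum(eig**2))
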