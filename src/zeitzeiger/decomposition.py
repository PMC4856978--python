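"""Pattern matrix construction and penalized matrix decomposition (PMD).

The pattern matrix Z (time-points x features) holds each feature's
discretized time-dependent mean, centered over the time-points and scaled by
the feature's standard deviation about its mean curve, so every entry is in
signal-to-noise units. Sparse principal components (SPCs) are the right
singular vectors of Z under an L1 budget ``sumabsv``, obtained by rank-1
alternating maximization with soft-thresholding, extracted sequentially with
the left singular vectors kept mutually orthogonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .periodic import TimeDensity

MAX_ALT_ITER = 100
ALT_TOL = 1e-7
BISECT_ITER = 50
BISECT_TOL = 1e-8
L1_SLACK = 1e-6


@dataclass
class PatternMatrix:
    """Centered, noise-scaled time-dependent means: m time-points x p features."""

    z: np.ndarray
    timepoints: np.ndarray
    feature_ids: list[str]

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.z.shape[0] < 2:
            raise ValueError("pattern matrix needs m >= 2 time-points")


@dataclass
class SparseComponent:
    """One sparse principal component: loadings v (unit L2), left vector u, d = u'Zv."""

    loadings: np.ndarray
    left_vector: np.ndarray
    singular_value: float
    n_nonzero: int


@dataclass
class Decomposition:
    components: list[SparseComponent]
    sumabsv: float
    orthogonal_u: bool = True

    @property
    def loadings_matrix(self) -> np.ndarray:
        """V as a p x k matrix, one component per column."""
        return np.column_stack([c.loadings for c in self.components])


def build_pattern_matrix(densities: list[TimeDensity], m: int) -> PatternMatrix:
    """Discretize mean curves at m evenly spaced times and scale by noise SD.

    z_ij = (f_j(tau_i) - fbar_j) / s_j with tau_i = (i-1)/m and fbar_j the
    mean of f_j over the tau grid, so each column has exactly zero mean.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    tau = np.arange(m) / m
    p = len(densities)
    z = np.empty((m, p))
    for j, dens in enumerate(densities):
        if dens.variance <= 0:
            raise ValueError(f"density {j} has non-positive variance")
        f = dens.mean_curve.evaluate(tau)
        z[:, j] = (f - f.mean()) / np.sqrt(dens.variance)
    return PatternMatrix(z=z, timepoints=tau, feature_ids=[f"feature_{j}" for j in range(p)])


def _soft(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def l1_constrained_unit(a: np.ndarray, c: float | None) -> np.ndarray:
    """Soft-threshold ``a`` so that v = S(a, delta)/||S(a, delta)||_2 has ||v||_1 <= c.

    delta is found by bisection as the smallest threshold meeting the budget;
    delta = 0 when the unthresholded unit vector already satisfies it. With
    ``c`` None (no constraint) this is plain L2 normalization.
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    v = a / norm
    if c is None or np.isinf(c) or np.sum(np.abs(v)) <= c + L1_SLACK:
        return v
    lo, hi = 0.0, float(np.max(np.abs(a)))
    feasible_delta = None
    for _ in range(BISECT_ITER):
        mid = 0.5 * (lo + hi)
        s = _soft(a, mid)
        sn = np.linalg.norm(s)
        l1 = np.sum(np.abs(s)) / sn if sn > 0 else np.inf
        if l1 > c:
            lo = mid
        else:
            hi = mid
            feasible_delta = mid
        if abs(l1 - c) <= BISECT_TOL:
            break
    if feasible_delta is None:
        # Degenerate tie: the largest |a_j| is shared by several entries and
        # soft-thresholding cannot reach the budget. Keep the k = floor(c^2)
        # lowest-index tied entries with equal magnitude (the exact optimum
        # restricted to the tie set; k=1 reduces to a unit coordinate vector).
        amax = np.max(np.abs(a))
        tied = np.flatnonzero(np.abs(a) >= amax * (1 - 1e-12))
        k = max(1, min(int(np.floor(c * c + 1e-9)), tied.size))
        v = np.zeros_like(a)
        v[tied[:k]] = np.sign(a[tied[:k]]) / np.sqrt(k)
        return v
    s = _soft(a, feasible_delta)
    return s / np.linalg.norm(s)


def _check_sumabsv(sumabsv: float, p: int) -> float | None:
    if np.isinf(sumabsv):
        return None  # sentinel: no L1 constraint (standard PCA)
    if not (1.0 <= sumabsv <= np.sqrt(p) + 1e-12):
        raise ValueError(
            f"sumabsv must lie in [1, sqrt(p)] = [1, {np.sqrt(p):.4g}] "
            f"(or be inf for unpenalized components); got {sumabsv}"
        )
    return float(sumabsv)


def pmd_rank1(z: np.ndarray, sumabsv: float) -> SparseComponent:
    """Best rank-1 penalized factor of ``z``: maximize u'Zv, ||u||_2 <= 1,
    ||v||_2 <= 1, ||v||_1 <= sumabsv.

    Alternating updates (u <- Zv/||Zv||; v <- soft-thresholded Z'u), v
    initialized from the leading right singular vector of the dense SVD.
    The sign is fixed so the largest-magnitude loading is positive (ties
    broken to the lowest feature index).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("Z must be finite")
    m, p = z.shape
    c = _check_sumabsv(sumabsv, p)

    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = l1_constrained_unit(vt[0], c)
    d_old = -np.inf
    d = 0.0
    converged = False
    for _ in range(MAX_ALT_ITER):
        zv = z @ v
        nzv = np.linalg.norm(zv)
        if nzv == 0:
            u = np.zeros(m)
            d = 0.0
            converged = True
            break
        u = zv / nzv
        v = l1_constrained_unit(z.T @ u, c)
        d = float(u @ z @ v)
        if abs(d - d_old) < ALT_TOL:
            converged = True
            break
        d_old = d
    if not converged:
        warnings.warn("PMD rank-1 alternation did not converge; returning last iterate")

    # clip numerically negligible loadings to exact zero so the reported
    # support is meaningful
    vmax = np.max(np.abs(v)) if v.size else 0.0
    if vmax > 0:
        v[np.abs(v) < 1e-11 * vmax] = 0.0
        v = v / np.linalg.norm(v)
        d = float(u @ z @ v)

    nz = np.flatnonzero(v != 0)
    if nz.size:
        i_star = np.argmax(np.abs(v))  # argmax takes the lowest index on ties
        if v[i_star] < 0:
            v = -v
            u = -u
    return SparseComponent(
        loadings=v, left_vector=u, singular_value=max(d, 0.0), n_nonzero=int(nz.size)
    )


def pmd(
    z: np.ndarray,
    sumabsv: float,
    n_components: int,
    orthogonal_u: bool = True,
) -> Decomposition:
    """Sequentially extract sparse components of ``z``.

    With ``orthogonal_u`` (the default) the left-side search space for each
    new component is restricted to the orthogonal complement of the u's
    already extracted, which discourages correlated components; otherwise
    classic rank-1 deflation is used.
    """
    z = np.asarray(z, dtype=float)
    m = z.shape[0]
    if n_components > m:
        raise ValueError(f"n_components ({n_components}) cannot exceed m ({m})")
    components = []
    u_basis: list[np.ndarray] = []
    z_work = z.copy()
    z_scale = max(np.linalg.norm(z), 1.0)
    for _ in range(n_components):
        if orthogonal_u and u_basis:
            u_mat = np.column_stack(u_basis)
            z_work = z - u_mat @ (u_mat.T @ z)
        if np.linalg.norm(z_work) < 1e-12 * z_scale:
            # nothing left to explain: emit null components
            components.append(
                SparseComponent(
                    loadings=np.zeros(z.shape[1]),
                    left_vector=np.zeros(m),
                    singular_value=0.0,
                    n_nonzero=0,
                )
            )
            continue
        comp = pmd_rank1(z_work, sumabsv)
        components.append(comp)
        if orthogonal_u:
            # re-orthonormalize against the basis before appending, so
            # numerical junk from a nearly deflated matrix cannot corrupt
            # the projector
            u = comp.left_vector.copy()
            for b in u_basis:
                u -= (b @ u) * b
            nu = np.linalg.norm(u)
            if nu > 1e-8:
                u_basis.append(u / nu)
        else:
            z_work = z_work - comp.singular_value * np.outer(
                comp.left_vector, comp.loadings
            )
    return Decomposition(components=components, sumabsv=sumabsv, orthogonal_u=orthogonal_u)


def variance_explained(decomposition: Decomposition, z: np.ndarray) -> np.ndarray:
    """Fraction of ||Z||_F^2 captured by each component: d_k^2 / ||Z||_F^2.

    d_k is measured on the sequentially deflated matrix, so for unpenalized
    components with orthogonal u's this reproduces sigma_k^2 / sum(sigma^2).
    """
    total = float(np.sum(np.asarray(z, dtype=float) ** 2))
    if total == 0:
        return np.zeros(len(decomposition.components))
    d = np.array([c.singular_value for c in decomposition.components])
    return d**2 / total
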