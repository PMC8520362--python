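"""Local polynomial kernel regression primitives.

The estimator treats scattered ultrasound samples as noisy observations of an
unknown smooth intensity field ``r``:

    Y_i = r(X_i) + eps_i,   i = 1..P,

with ``X_i`` a 3D position (mm) and ``eps_i`` i.i.d. zero-mean noise.  Around
a query point ``X`` the field is approximated by its Taylor polynomial of
order ``N`` and the polynomial coefficients ``beta`` are obtained by weighted
least squares, the weight of each sample being an isotropic Gaussian kernel
of its distance to ``X``.  The fitted intercept ``beta_0`` is the estimate of
``r(X)``.

Monomial basis ordering (columns of the design matrix), fixed and relied upon
throughout the package:

    order 0:  [1]
    order 1:  [1, dx, dy, dz]
    order 2:  [1, dx, dy, dz, dx^2, dy^2, dz^2, dx*dy, dx*dz, dy*dz]

where ``(dx, dy, dz) = X_i - X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EmptyNeighborhoodError

#: number of monomials of degree <= N in three variables
BASIS_SIZE = {0: 1, 1: 4, 2: 10}


def _as_points(a) -> np.ndarray:
    """Coerce to a float (n, 3) array; a single (3,) point becomes (1, 3)."""
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DomainError(f"expected 3D point(s), got shape {np.shape(a)}")
    return arr


@dataclass(frozen=True)
class PointCloud:
    """Scattered observations ``(X_i, Y_i)`` of the intensity field.

    Parameters
    ----------
    positions : (P, 3) array of float
        Sample positions in mm (patient space, right-handed: x = patient
        left, y = anterior, z = cranial).
    values : (P,) array of float
        Observed intensities in arbitrary ultrasound units.
    """

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        pos = _as_points(self.positions)
        val = np.asarray(self.values, dtype=float).ravel()
        if len(pos) != len(val):
            raise DomainError(
                f"positions ({len(pos)}) and values ({len(val)}) differ in length"
            )
        if len(pos) < 1:
            raise DomainError("a point cloud needs at least one sample")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(val))):
            raise DomainError("positions and values must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def count(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return self.count


@dataclass(frozen=True)
class KernelSpec:
    """Kernel-regression configuration.

    Parameters
    ----------
    bandwidth_h : float
        Gaussian bandwidth in mm (> 0); the smoothing length scale.
    order_N : int
        Local polynomial order, one of {0, 1, 2}.  Order 0 is the
        Nadaraya-Watson weighted mean; order 1 (the default elsewhere in the
        package) fits intercept plus gradient.
    support_radius_factor : float
        Neighborhood cutoff in units of ``bandwidth_h`` (the Gaussian has
        unbounded support; samples beyond this radius are ignored).
    min_extra_neighbors : int
        A fit at order N requires at least ``BASIS_SIZE[N] + min_extra_neighbors``
        neighbors; otherwise the order degrades (2 -> 1 -> 0).
    ridge_eps : float
        Dimensionless Tikhonov factor applied (times the trace of the normal
        matrix) only when the plain weighted normal equations cannot be
        solved.
    """

    bandwidth_h: float
    order_N: int = 1
    support_radius_factor: float = 3.0
    min_extra_neighbors: int = 2
    ridge_eps: float = 1e-10

    def __post_init__(self):
        if not (np.isfinite(self.bandwidth_h) and self.bandwidth_h > 0):
            raise DomainError(f"bandwidth_h must be positive, got {self.bandwidth_h}")
        if self.order_N not in BASIS_SIZE:
            raise DomainError(f"order_N must be in {{0,1,2}}, got {self.order_N}")
        if self.support_radius_factor < 1:
            raise DomainError("support_radius_factor must be >= 1")
        if self.ridge_eps < 0:
            raise DomainError("ridge_eps must be >= 0")

    @property
    def support_radius(self) -> float:
        return self.support_radius_factor * self.bandwidth_h

    @property
    def second_moment_c(self) -> float:
        """Second moment of the (1D marginal) Gaussian kernel: h**2."""
        return self.bandwidth_h**2


@dataclass
class LocalFit:
    """Result of one weighted local polynomial fit."""

    design: np.ndarray
    weights: np.ndarray
    beta: np.ndarray
    n_used: int
    ridge_applied: bool = False
    order: int = field(default=1)

    @property
    def estimate(self) -> float:
        """The fitted intercept beta_0 — the field estimate at the center."""
        return float(self.beta[0])


def gaussian_kernel(offset, h: float):
    """Isotropic Gaussian kernel ``exp(-||u||^2 / (2 h^2))`` (unnormalized).

    The normalizing constant cancels in the weighted least-squares fit, so it
    is omitted.  ``offset`` may be a single 3-vector or an (n, 3) array of
    displacements in mm; a matching scalar or (n,) array is returned.
    """
    if not (np.isfinite(h) and h > 0):
        raise DomainError(f"bandwidth h must be positive, got {h}")
    u = np.asarray(offset, dtype=float)
    single = u.ndim == 1
    u = _as_points(u)
    if not np.all(np.isfinite(u)):
        raise DomainError("offsets must be finite")
    sq = np.einsum("ij,ij->i", u, u)
    w = np.exp(-sq / (2.0 * h * h))
    return float(w[0]) if single else w


def local_weights(center, neighbors, h: float) -> np.ndarray:
    """Kernel weight of each neighbor relative to ``center``.

    Weights decrease monotonically with Euclidean distance and are invariant
    to direction (isotropy).
    """
    nb = _as_points(neighbors)
    if len(nb) == 0:
        raise EmptyNeighborhoodError("no neighbors supplied")
    c = _as_points(center)[0]
    return gaussian_kernel(nb - c, h)


def build_design(center, neighbors, order_N: int) -> np.ndarray:
    """Design matrix of centered monomials up to degree ``order_N``.

    Row i holds the basis evaluated at ``X_i - center`` in the fixed column
    order documented in the module docstring; the first column is all ones.
    """
    if order_N not in BASIS_SIZE:
        raise DomainError(f"order_N must be in {{0,1,2}}, got {order_N}")
    nb = _as_points(neighbors)
    c = _as_points(center)[0]
    d = nb - c
    n = len(nb)
    cols = [np.ones(n)]
    if order_N >= 1:
        cols += [d[:, 0], d[:, 1], d[:, 2]]
    if order_N >= 2:
        cols += [
            d[:, 0] ** 2,
            d[:, 1] ** 2,
            d[:, 2] ** 2,
            d[:, 0] * d[:, 1],
            d[:, 0] * d[:, 2],
            d[:, 1] * d[:, 2],
        ]
    return np.column_stack(cols)


def fit_local(
    design: np.ndarray,
    weights: np.ndarray,
    values: np.ndarray,
    ridge_eps: float = 1e-10,
) -> LocalFit:
    """Solve the weighted least-squares problem for one neighborhood.

    Minimizes ``sum_i w_i (y_i - phi_i . beta)^2`` through the weighted normal
    equations ``(Phi' W Phi) beta = Phi' W y``.  If the plain solve fails
    (singular or numerically unusable normal matrix), a Tikhonov term
    ``ridge_eps * trace(A)`` is added to the diagonal; the fallback is
    deterministic and recorded on the returned :class:`LocalFit`.
    """
    phi = np.atleast_2d(np.asarray(design, dtype=float))
    w = np.asarray(weights, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if not (len(phi) == len(w) == len(y)):
        raise DomainError("design, weights and values must have matching rows")
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
        raise DomainError("non-finite input to fit_local")
    if np.any(w < 0):
        raise DomainError("weights must be non-negative")
    if not np.any(w > 0):
        raise EmptyNeighborhoodError("all weights are zero")

    A = phi.T @ (w[:, None] * phi)
    b = phi.T @ (w * y)
    beta, ridged = _solve_normal(A, b, ridge_eps)
    return LocalFit(
        design=phi,
        weights=w,
        beta=beta,
        n_used=int(np.count_nonzero(w > 0)),
        ridge_applied=ridged,
        order={1: 0, 4: 1, 10: 2}.get(phi.shape[1], -1),
    )


def _solve_normal(A: np.ndarray, b: np.ndarray, ridge_eps: float):
    """Solve ``A beta = b``; ridge-regularize only if the plain solve fails."""
    try:
        beta = np.linalg.solve(A, b)
        resid = np.linalg.norm(A @ beta - b)
        if np.all(np.isfinite(beta)) and resid <= 1e-8 * (np.linalg.norm(b) + 1e-300):
            return beta, False
    except np.linalg.LinAlgError:
        pass
    ridge = ridge_eps * np.trace(A)
    if ridge <= 0:
        ridge = ridge_eps if ridge_eps > 0 else 1e-300
    beta = np.linalg.solve(A + ridge * np.eye(len(A)), b)
    return beta, True
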