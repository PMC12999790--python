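"""Chromatin contact matrices and their spectral reduction quantities.

The contact matrix ``W`` (symmetric, non-negative) plays the role of a
Hi-C-like map: ``w_ij`` is the frequency with which regions ``i`` and ``j``
touch, and thereby the strength with which marks at ``j`` feed back on
modification rates at ``i``.  Three generator classes are provided —
all-to-all, first-neighbors (strong band plus weak long-range background)
and heterogeneous (TAD-like blocks) — plus an ablated first-neighbors
variant whose strictly tridiagonal structure makes the spectral reduction
inapplicable (the contact graph is still connected, but the variant is
tagged so downstream coarse-graining refuses it, and serves as the
long-range-ablation control).

The reduction is built on the Perron–Frobenius eigenpair of ``W^T``: the
dominant eigenvector ``u > 0`` defines collective observables
``X_i = sum_j u_j x_ij`` and a handful of scalars (``|u|_1``, ``||u||^2``,
``alpha_w``, ``Phi_1*``, ``Gamma_1*``) that close the coarse-grained drift
and noise.  The single structural summary ``phi_hat = alpha_w*Phi_1*/|u|_1``
multiplies the landscape feedback in the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csgraph, csr_matrix

__all__ = [
    "ConnectivityError",
    "NotIrreducibleError",
    "NonPositiveEigenvectorError",
    "ConnectivityMatrix",
    "SpectralQuantities",
    "make_all_to_all",
    "make_first_neighbors",
    "make_ablated_first_neighbors",
    "make_heterogeneous",
    "spectral_quantities",
    "phi_hat",
]

#: patterns for which the coarse-graining is refused outright
_CG_FORBIDDEN = {"ablated_first_neighbors"}


class ConnectivityError(ValueError):
    """Invalid contact matrix or generator arguments."""


class NotIrreducibleError(ConnectivityError):
    """The contact graph is not strongly connected (or the pattern is ablated)."""


class NonPositiveEigenvectorError(ConnectivityError):
    """The dominant eigenvector has a non-positive component."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A symmetric non-negative contact-frequency matrix with provenance tag."""

    W: np.ndarray
    pattern: str = "user"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ConnectivityError(f"contact matrix must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ConnectivityError("contact matrix has non-finite entries")
        if np.any(W < 0):
            raise ConnectivityError("contact matrix has negative entries")
        if not np.allclose(W, W.T, rtol=0.0, atol=1e-12 * max(1.0, W.max(initial=1.0))):
            raise ConnectivityError("contact matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class SpectralQuantities:
    """Perron eigenpair of ``W^T`` and the derived coarse-graining scalars.

    ``u`` is normalised to unit Euclidean norm, so ``norm_sq = 1`` and
    ``norm_l1`` lies in ``[1, sqrt(N_C)]``.
    """

    u: np.ndarray
    lambda_dom: float
    norm_l1: float
    norm_sq: float
    alpha_w: float
    phi1_star: float
    gamma1_star: float
    phi_hat: float
    n_regions: int = field(default=0)

    def rescaled(self, norm: str = "l1") -> "SpectralQuantities":
        """Recompute all scalars with a differently-normalised ``u``.

        ``phi_hat`` itself is normalisation-dependent; the physically
        meaningful combinations (e.g. ``phi_hat * X`` with
        ``X = sum u_j x_j``) are invariant under rescaling of ``u``.  This
        helper exists to verify that property.
        """
        if norm == "l1":
            c = 1.0 / self.norm_l1
        elif norm == "l2":
            c = 1.0 / np.sqrt(self.norm_sq)
        else:
            raise ValueError(f"unknown normalisation {norm!r}")
        u = self.u * c
        return SpectralQuantities(
            u=u,
            lambda_dom=self.lambda_dom,
            norm_l1=self.norm_l1 * c,
            norm_sq=self.norm_sq * c * c,
            alpha_w=self.alpha_w * c,
            phi1_star=self.phi1_star / c,
            gamma1_star=self.gamma1_star / c,
            phi_hat=self.phi_hat / c,
            n_regions=self.n_regions,
        )


def make_all_to_all(
    n_regions: int, weight: float, include_diagonal: bool = False
) -> ConnectivityMatrix:
    """Uniform contact matrix: every pair of regions touches equally often.

    The diagonal (self-contact) is zero by default; ``include_diagonal=True``
    fills it with ``weight`` as well, in which case the structural summary
    takes the exact closed form ``phi_hat = weight * sqrt(n_regions)``.
    """
    if n_regions < 1:
        raise ConnectivityError("n_regions must be >= 1")
    if not weight > 0:
        raise ConnectivityError("weight must be > 0")
    W = np.full((n_regions, n_regions), float(weight))
    if not include_diagonal:
        np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(W=W, pattern="all_to_all")


def make_first_neighbors(
    n_regions: int, weight_strong: float, weight_background: float
) -> ConnectivityMatrix:
    """Strong chain contacts with a weak all-to-all background.

    Adjacent regions (``|i-j| = 1``) interact with ``weight_strong``; all
    other pairs with ``weight_background``.  A strictly positive background
    keeps the contact graph strongly connected, so the coarse-graining
    applies; with zero background the result degenerates to the ablated
    variant.
    """
    if n_regions < 2:
        raise ConnectivityError("n_regions must be >= 2")
    if weight_background < 0 or not weight_strong > weight_background:
        raise ConnectivityError(
            "require weight_strong > weight_background >= 0 "
            f"(got {weight_strong}, {weight_background})"
        )
    if weight_background == 0.0:
        return ConnectivityMatrix(
            W=_tridiagonal(n_regions, weight_strong), pattern="ablated_first_neighbors"
        )
    W = np.full((n_regions, n_regions), float(weight_background))
    np.fill_diagonal(W, 0.0)
    idx = np.arange(n_regions - 1)
    W[idx, idx + 1] = weight_strong
    W[idx + 1, idx] = weight_strong
    return ConnectivityMatrix(W=W, pattern="first_neighbors")


def _tridiagonal(n_regions: int, weight: float) -> np.ndarray:
    W = np.zeros((n_regions, n_regions))
    idx = np.arange(n_regions - 1)
    W[idx, idx + 1] = weight
    W[idx + 1, idx] = weight
    return W


def make_ablated_first_neighbors(n_regions: int, weight: float) -> ConnectivityMatrix:
    """Strictly tridiagonal contacts: chain neighbours only, no background.

    Downstream spectral reduction refuses this pattern (no guaranteed
    strictly positive dominant eigenvector for the reducible perturbation
    theory); the microscopic simulator accepts it, which is what makes the
    long-range-ablation study possible.
    """
    if n_regions < 2:
        raise ConnectivityError("n_regions must be >= 2")
    if not weight > 0:
        raise ConnectivityError("weight must be > 0")
    return ConnectivityMatrix(
        W=_tridiagonal(n_regions, weight), pattern="ablated_first_neighbors"
    )


def make_heterogeneous(
    n_regions: int,
    block_sizes: list[int],
    weight_intra: float,
    weight_inter: float,
    seed: int,
    jitter: float = 0.0,
) -> ConnectivityMatrix:
    """TAD-like block matrix: tight blocks, weak inter-block background.

    Emulates the heterogeneous structure of Hi-C maps at the scale of
    topologically associating domains.  ``jitter > 0`` applies symmetric
    multiplicative noise ``(1 + jitter*eta)`` with ``eta ~ U(-1, 1)`` drawn
    reproducibly from ``seed``.
    """
    if sum(block_sizes) != n_regions:
        raise ConnectivityError(
            f"block sizes {block_sizes} do not sum to n_regions = {n_regions}"
        )
    if not (weight_intra > weight_inter > 0):
        raise ConnectivityError("require weight_intra > weight_inter > 0")
    if not 0.0 <= jitter < 1.0:
        raise ConnectivityError("jitter must lie in [0, 1)")
    W = np.full((n_regions, n_regions), float(weight_inter))
    start = 0
    for size in block_sizes:
        W[start : start + size, start : start + size] = weight_intra
        start += size
    np.fill_diagonal(W, 0.0)
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        eta = rng.uniform(-1.0, 1.0, size=W.shape)
        eta = np.triu(eta, 1)
        eta = eta + eta.T
        W = W * (1.0 + jitter * eta)
    return ConnectivityMatrix(W=W, pattern="heterogeneous", seed=seed)


def _check_irreducible(W: np.ndarray) -> None:
    graph = csr_matrix((W > 0).astype(np.int8))
    n_comp, _ = csgraph.connected_components(graph, directed=True, connection="strong")
    if n_comp != 1:
        raise NotIrreducibleError(
            f"contact graph has {n_comp} strongly connected components; "
            "CG not applicable"
        )


def _power_iteration(
    A: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000
) -> tuple[np.ndarray, float]:
    """Perron eigenpair by power iteration with a deterministic positive start."""
    n = A.shape[0]
    u = np.ones(n) / np.sqrt(n)
    lam = 0.0
    for _ in range(max_iter):
        v = A @ u
        lam_new = float(np.linalg.norm(v))
        if lam_new == 0.0:
            raise NonPositiveEigenvectorError("matrix maps start vector to zero")
        v /= lam_new
        if np.linalg.norm(v - u) < tol and abs(lam_new - lam) < tol * max(1.0, lam):
            return v, lam_new
        u, lam = v, lam_new
    raise ConnectivityError(
        f"power iteration did not converge to tol={tol} in {max_iter} iterations"
    )


def spectral_quantities(
    conn: ConnectivityMatrix,
    K: Optional[np.ndarray] = None,
    v: Optional[np.ndarray] = None,
    tol: float = 1e-12,
) -> SpectralQuantities:
    """Compute the Perron eigenpair of ``W^T`` and all reduction scalars.

    ``u`` is the dominant eigenvector of ``W^T`` (strictly positive by
    Perron–Frobenius for an irreducible non-negative matrix), normalised to
    unit Euclidean norm.  Derived scalars::

        norm_l1   = sum_j u_j
        alpha_w   = sum_{i,j} w_ij u_j
        phi1_star = u^T K u / (alpha_w u^T u)
        gamma1_star = u^T K v / (alpha_w u^T u)
        phi_hat   = alpha_w * phi1_star / norm_l1

    ``K`` defaults to ``W`` and ``v`` to ``u`` (self-consistent closure;
    both overridable).

    Raises
    ------
    NotIrreducibleError
        If the contact graph is not strongly connected, or the matrix is
        tagged ``ablated_first_neighbors``.
    NonPositiveEigenvectorError
        If any eigenvector component is ``<= tol``.
    """
    if conn.pattern in _CG_FORBIDDEN:
        raise NotIrreducibleError(
            f"CG not applicable to pattern {conn.pattern!r}: long-range "
            "ablation voids the positivity guarantee for the dominant eigenvector"
        )
    W = conn.W
    n = conn.n_regions
    if n == 1 and W[0, 0] == 0.0:
        raise NotIrreducibleError("1x1 zero matrix has no positive Perron pair")
    _check_irreducible(W)
    u, lam = _power_iteration(W.T, tol=tol)
    if np.any(u <= tol):
        raise NonPositiveEigenvectorError(
            "dominant eigenvector has a non-positive component"
        )
    # residual guard: ||W^T u - lam u|| / lam
    resid = np.linalg.norm(W.T @ u - lam * u) / lam
    if resid > 1e-10:
        raise ConnectivityError(f"Perron pair residual {resid:.2e} exceeds 1e-10")
    K_mat = W if K is None else np.asarray(K, dtype=float)
    v_vec = u if v is None else np.asarray(v, dtype=float)
    norm_l1 = float(np.sum(u))
    norm_sq = float(u @ u)  # = 1 under unit-Euclidean normalisation
    alpha_w = float(np.sum(W @ u))
    phi1 = float(u @ K_mat @ u) / (alpha_w * norm_sq)
    gamma1 = float(u @ K_mat @ v_vec) / (alpha_w * norm_sq)
    return SpectralQuantities(
        u=u,
        lambda_dom=lam,
        norm_l1=norm_l1,
        norm_sq=norm_sq,
        alpha_w=alpha_w,
        phi1_star=phi1,
        gamma1_star=gamma1,
        phi_hat=alpha_w * phi1 / norm_l1,
        n_regions=n,
    )


def phi_hat(spec: SpectralQuantities) -> float:
    """The structural feedback summary ``alpha_w * Phi_1* / |u|_1``."""
    return spec.alpha_w * spec.phi1_star / spec.norm_l1
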