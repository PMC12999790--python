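"""Fixed points, stability, continuation and saddle-node (fold) detection.

Works on the coarse-grained mean-field system or on any user-supplied model
exposing ``drift``/``dim``/``domain`` (see :class:`epitip.cg.CustomModel`).
The continuation scheme is deliberately simple — natural-parameter stepping
with a root-count bisection at branch terminations — which is robust and
auditable for planar systems with at most a handful of equilibria.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import root

__all__ = [
    "FixedPoint",
    "Fold",
    "BifurcationDiagram",
    "NoEquilibriumInRangeError",
    "find_fixed_points",
    "find_fixed_points_model",
    "continuation",
    "detect_folds",
]

_MERGE_TOL = 1e-6
_RESID_TOL = 1e-9
_NONHYP_TOL = 1e-6


class NoEquilibriumInRangeError(RuntimeError):
    """Continuation found no equilibrium anywhere in the parameter range."""


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium with its Jacobian spectrum and stability class."""

    X: np.ndarray
    jacobian_eigenvalues: np.ndarray
    stability: str  # stable_node | saddle | unstable | non_hyperbolic
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable_node"


@dataclass(frozen=True)
class Fold:
    """A saddle-node point: critical parameter value and merging state."""

    parameter: float
    X: np.ndarray
    bracket: tuple[float, float]


@dataclass
class BifurcationDiagram:
    """Equilibria tracked over a parameter grid, plus detected folds."""

    parameter_name: str
    values: np.ndarray
    points: list[list[FixedPoint]]  # per grid value
    folds: list[Fold] = field(default_factory=list)

    def stable_count(self) -> np.ndarray:
        return np.array([sum(fp.is_stable for fp in fps) for fps in self.points])

    def root_count(self) -> np.ndarray:
        return np.array([len(fps) for fps in self.points])


def _numerical_jacobian(drift: Callable, X: np.ndarray, scale: float) -> np.ndarray:
    n = len(X)
    J = np.zeros((n, n))
    h = 1e-6 * max(scale, 1.0)
    for i in range(n):
        Xp, Xm = X.copy(), X.copy()
        Xp[i] += h
        Xm[i] -= h
        J[:, i] = (np.atleast_1d(drift(Xp)) - np.atleast_1d(drift(Xm))) / (2 * h)
    return J


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) < _NONHYP_TOL):
        return "non_hyperbolic"
    if np.all(re < 0):
        return "stable_node"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(
    drift: Callable,
    domain: Sequence[tuple[float, float]],
    grid_density: int = 24,
    mask: Optional[Callable] = None,
    merge_tol: float = _MERGE_TOL,
    seeds: Optional[Sequence[np.ndarray]] = None,
) -> list[FixedPoint]:
    """All roots of ``drift`` in a box, by grid-seeded Newton polishing.

    A uniform grid (density per axis) seeds damped-Newton iterations; roots
    are kept if the drift's infinity norm falls below 1e-9, deduplicated
    within ``merge_tol`` (keeping the smaller residual), and classified by
    the eigenvalues of a central-difference Jacobian.  ``mask(X) -> bool``
    restricts the admissible region (e.g. a simplex inside the box).
    An empty list is a valid result.
    """
    domain = [tuple(map(float, d)) for d in domain]
    dim = len(domain)
    scale = max(hi - lo for lo, hi in domain)

    def f(X):
        return np.atleast_1d(np.asarray(drift(np.asarray(X, float)), float))

    axes = [np.linspace(lo, hi, grid_density + 2)[1:-1] for lo, hi in domain]
    candidates = [np.array(p) for p in itertools.product(*axes)]
    if seeds is not None:
        candidates = [np.asarray(s, float) for s in seeds] + candidates
    if mask is not None:
        candidates = [p for p in candidates if mask(p)]

    roots: list[np.ndarray] = []
    resids: list[float] = []
    for X0 in candidates:
        sol = root(f, X0, method="hybr", tol=1e-13)
        X = sol.x
        if not sol.success:
            continue
        if any(X[i] < domain[i][0] - 1e-9 * scale or X[i] > domain[i][1] + 1e-9 * scale
               for i in range(dim)):
            continue
        if mask is not None and not mask(X):
            continue
        r = float(np.max(np.abs(f(X))))
        if r > _RESID_TOL:
            continue
        matched = False
        for k, R in enumerate(roots):
            if np.linalg.norm(X - R) < merge_tol * max(1.0, scale):
                matched = True
                if r < resids[k]:  # tie-break: keep the smaller residual
                    roots[k], resids[k] = X, r
                break
        if not matched:
            roots.append(X)
            resids.append(r)

    out = []
    for X, r in zip(roots, resids):
        J = _numerical_jacobian(f, X, scale)
        eigs = np.linalg.eigvals(J)
        out.append(
            FixedPoint(X=X, jacobian_eigenvalues=eigs, stability=_classify(eigs),
                       residual=r)
        )
    out.sort(key=lambda fp: tuple(fp.X))
    return out


def find_fixed_points_model(model, grid_density: int = 24, **kw) -> list[FixedPoint]:
    """Fixed points of a model object (uses its domain and simplex mask)."""
    mask = getattr(model, "in_domain", None)
    return find_fixed_points(
        model.drift, model.domain, grid_density=grid_density, mask=mask, **kw
    )


def _fixed_points_at(model, name: str, value: float, grid_density: int,
                     seeds=None) -> list[FixedPoint]:
    m = model.with_params(**{name: value})
    return find_fixed_points_model(m, grid_density=grid_density, seeds=seeds)


def continuation(
    model,
    parameter_name: str,
    parameter_range: tuple[float, float],
    n_steps: int = 41,
    grid_density: int = 18,
    fold_tol: float = 1e-4,
) -> BifurcationDiagram:
    """Natural-parameter continuation over a uniform grid with fold refinement.

    The model must implement ``with_params(<parameter_name>=value)``; the
    competition level ``B``, any kinetic constant, the structural summary
    ``phi_hat`` or the effective cofactors ``a_hat``/``s_hat`` all qualify
    for the coarse-grained model.  Equilibria from the previous grid value
    seed the next solve (plus a global rescan), and every change of root
    count is bisected down to a parameter bracket ``<= fold_tol`` (relative
    to the range width).
    """
    lo, hi = map(float, parameter_range)
    values = np.linspace(lo, hi, n_steps)
    points: list[list[FixedPoint]] = []
    seeds = None
    for v in values:
        fps = _fixed_points_at(model, parameter_name, v, grid_density, seeds=seeds)
        points.append(fps)
        seeds = [fp.X for fp in fps] or None
    diagram = BifurcationDiagram(
        parameter_name=parameter_name, values=values, points=points
    )
    if all(len(fps) == 0 for fps in points):
        raise NoEquilibriumInRangeError(
            f"no equilibria found for {parameter_name} in [{lo}, {hi}]"
        )
    diagram.folds = detect_folds(
        diagram, model, tolerance=fold_tol * (hi - lo), grid_density=grid_density
    )
    return diagram


def detect_folds(
    diagram: BifurcationDiagram,
    model,
    tolerance: float = 1e-4,
    grid_density: int = 18,
) -> list[Fold]:
    """Bisection refinement of every root-count change in the diagram.

    Returns the critical parameter values together with the state at which
    branches merge (the root that disappears across the fold), each
    bracketed to ``tolerance``.
    """
    name = diagram.parameter_name
    counts = diagram.root_count()
    folds: list[Fold] = []
    for k in range(len(counts) - 1):
        if counts[k] == counts[k + 1]:
            continue
        a, b = float(diagram.values[k]), float(diagram.values[k + 1])
        fps_a, fps_b = diagram.points[k], diagram.points[k + 1]
        na, nb = len(fps_a), len(fps_b)
        while b - a > tolerance:
            mid = 0.5 * (a + b)
            seeds = [fp.X for fp in (fps_a if na > nb else fps_b)]
            fps_mid = _fixed_points_at(model, name, mid, grid_density, seeds=seeds)
            if len(fps_mid) == na:
                a, fps_a = mid, fps_mid
            else:
                b, fps_b = mid, fps_mid
        # the merging state: root(s) on the richer side without a partner
        rich, poor = (fps_a, fps_b) if na > nb else (fps_b, fps_a)
        X_merge = _unmatched_root(rich, poor)
        folds.append(Fold(parameter=0.5 * (a + b), X=X_merge, bracket=(a, b)))
    return folds


def _unmatched_root(rich: list[FixedPoint], poor: list[FixedPoint]) -> np.ndarray:
    if not poor:
        return rich[0].X
    best, best_d = None, -1.0
    for fp in rich:
        d = min(np.linalg.norm(fp.X - q.X) for q in poor)
        if d > best_d:
            best, best_d = fp.X, d
    return best
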