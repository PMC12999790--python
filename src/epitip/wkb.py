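"""Quasi-potential robustness of metastable landscapes via WKB asymptotics.

In the small-noise (large ``Omega27``) limit the stationary distribution of
the slow system behaves as ``psi ~ exp(Omega27 * S0(X))``; the exponent
solves a Hamilton–Jacobi equation with Hamiltonian

    <H>(X, P) = sum_i ( -<D_i> P_i + 1/2 <N_i> P_i^2 )

Characteristics obey  dX/ds = -dH/dP,  dP/ds = +dH/dX  (in this convention
the P = 0 flow reproduces the forward deterministic dynamics).  The
heteroclinic of this flow connecting a stable node (at P = 0) to the saddle
(at P = 0) on the H = 0 level set is the *instanton*: the most probable
fluctuational escape path.  Its line integral

    dS = | \\int_path P . dX |

is the quasi-potential barrier between the node and the saddle — the
robustness proxy of the corresponding epigenetic landscape.  Sensitivity of
the barrier to kinetic parameters is the gradient of dS in parameter space,
computed either by re-solving the instanton at perturbed parameters or by
integrating the parameter-derivative of the Hamiltonian along the
unperturbed path.

The machinery accepts any model exposing ``drift``/``noise``/``domain``
(dimension 1 or 2); one-dimensional models reduce to the analytic
fluctuational branch ``P = 2 D / N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .bifurcation import FixedPoint, find_fixed_points_model

__all__ = [
    "InstantonPath",
    "RobustnessResult",
    "SensitivityResult",
    "NotBistableError",
    "InstantonNotConvergedError",
    "hamiltonian",
    "hamilton_flow",
    "compute_instanton",
    "action",
    "robustness",
    "action_gradient",
]

_H_TOL = 1e-6
_ENDPOINT_TOL = 1e-5
_S_MAX = 1e3


class NotBistableError(RuntimeError):
    """The model lacks the two-nodes-plus-saddle structure."""


class InstantonNotConvergedError(RuntimeError):
    """Shooting failed to land on the saddle within tolerance."""

    def __init__(self, msg: str, best_miss: float = math.nan):
        super().__init__(msg)
        self.best_miss = best_miss


@dataclass
class InstantonPath:
    """Heteroclinic (X(s), P(s)) from a node to the saddle on <H> = 0."""

    s: np.ndarray
    X: np.ndarray  # (n, dim)
    P: np.ndarray  # (n, dim)
    hamiltonian_residuals: np.ndarray
    endpoints: tuple[np.ndarray, np.ndarray]
    miss: float = 0.0


@dataclass
class RobustnessResult:
    """Barrier heights of the two basins and the equilibria used."""

    dS_minus: float  # hypoacetylated node (smaller X2)
    dS_plus: float  # hyperacetylated node (larger X2)
    X_minus: np.ndarray
    X_plus: np.ndarray
    X_saddle: np.ndarray
    path_minus: InstantonPath
    path_plus: InstantonPath
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SensitivityResult:
    """Parameter gradient of the barrier heights."""

    theta: list[str]
    grad_minus: dict
    grad_plus: dict
    method: str
    failures: dict = field(default_factory=dict)


def hamiltonian(X, P, model) -> float:
    """<H>(X, P) = sum_i(-D_i P_i + N_i P_i^2 / 2)."""
    X = np.atleast_1d(np.asarray(X, float))
    P = np.atleast_1d(np.asarray(P, float))
    D = model.drift(X)
    N = model.noise(X)
    return float(np.sum(-D * P + 0.5 * N * P * P))


def _grad_X(f: Callable, X: np.ndarray, scale: float) -> np.ndarray:
    h = 1e-6 * max(scale, 1.0)
    g = np.zeros_like(X)
    for i in range(len(X)):
        Xp, Xm = X.copy(), X.copy()
        Xp[i] += h
        Xm[i] -= h
        g[i] = (f(Xp) - f(Xm)) / (2 * h)
    return g


def hamilton_flow(X, P, model) -> tuple[np.ndarray, np.ndarray]:
    """Characteristic equations: dX/ds = -dH/dP, dP/ds = +dH/dX.

    The P-derivative is analytic (H is quadratic in P); the X-derivative
    differentiates drift and noise by central differences.  At P = 0 the
    X-equation reduces to the mean-field drift.
    """
    X = np.atleast_1d(np.asarray(X, float))
    P = np.atleast_1d(np.asarray(P, float))
    D = model.drift(X)
    N = model.noise(X)
    dX = D - N * P
    scale = max(hi - lo for lo, hi in model.domain)
    dP = _grad_X(lambda Y: hamiltonian(Y, P, model), X, scale)
    return dX, dP


def _flow_rhs(model, dim):
    def rhs(s, y):
        dX, dP = hamilton_flow(y[:dim], y[dim:], model)
        return np.concatenate([dX, dP])

    return rhs


# --------------------------------------------------------------------------
# 1-D reduction: analytic fluctuational branch
# --------------------------------------------------------------------------


def _instanton_1d(model, x_node: float, x_saddle: float, n_points: int) -> InstantonPath:
    x = np.linspace(x_node, x_saddle, n_points)
    D = np.array([model.drift([xi])[0] for xi in x])
    N = np.array([model.noise([xi])[0] for xi in x])
    if np.any(N <= 0):
        raise InstantonNotConvergedError("noise vanishes on the 1-D path")
    P = 2.0 * D / N
    # pseudo-time from dx/ds = -D (singular at endpoints; cumulative inside)
    s = np.zeros_like(x)
    with np.errstate(divide="ignore"):
        inv = np.where(np.abs(D) > 1e-300, -1.0 / D, 0.0)
    s[1:] = np.cumsum(0.5 * (inv[1:] + inv[:-1]) * np.diff(x))
    H = np.array(
        [hamiltonian([xi], [pi], model) for xi, pi in zip(x, P)]
    )
    return InstantonPath(
        s=s,
        X=x[:, None],
        P=P[:, None],
        hamiltonian_residuals=np.abs(H),
        endpoints=(np.array([x_node]), np.array([x_saddle])),
        miss=0.0,
    )


# --------------------------------------------------------------------------
# 2-D path-space minimisation (geometric minimum-action)
# --------------------------------------------------------------------------

_NOISE_FLOOR = 1e-12


def _drift_many(model, Xs: np.ndarray) -> np.ndarray:
    f = getattr(model, "drift_many", None)
    if f is not None:
        return f(Xs)
    return np.array([model.drift(x) for x in Xs])


def _noise_many(model, Xs: np.ndarray) -> np.ndarray:
    f = getattr(model, "noise_many", None)
    if f is not None:
        return f(Xs)
    return np.array([model.noise(x) for x in Xs])


def _geometric_action(model, pts: np.ndarray) -> float:
    """Discrete Freidlin–Wentzell geometric action of a polygonal path.

    ``sum_seg ( ||b||_a ||dX||_a - <b, dX>_a )`` with the inverse-noise
    metric ``<u, v>_a = sum u_i v_i / N_i``, drift and noise evaluated at
    segment midpoints.  Parametrisation-invariant and non-negative; zero
    exactly on deterministic orbits.
    """
    mids = 0.5 * (pts[1:] + pts[:-1])
    d = np.diff(pts, axis=0)
    b = _drift_many(model, mids)
    a = np.maximum(_noise_many(model, mids), _NOISE_FLOOR)
    B = np.sqrt(np.sum(b * b / a, axis=1))
    Phi = np.sqrt(np.sum(d * d / a, axis=1))
    c = np.sum(d * b / a, axis=1)
    return float(np.sum(B * Phi - c))


def _gmam_fun_grad(model, z, x0, x1, M, total):
    """Geometric action and its analytic gradient wrt interior points."""
    pts = np.empty((M, 2))
    pts[0], pts[-1] = x0, x1
    pts[1:-1] = z.reshape(M - 2, 2)
    mids = 0.5 * (pts[1:] + pts[:-1])
    d = np.diff(pts, axis=0)
    b = _drift_many(model, mids)
    a = np.maximum(_noise_many(model, mids), _NOISE_FLOOR)
    B = np.sqrt(np.maximum(np.sum(b * b / a, axis=1), 1e-300))
    Phi = np.sqrt(np.maximum(np.sum(d * d / a, axis=1), 1e-300))
    c = np.sum(d * b / a, axis=1)
    S = float(np.sum(B * Phi - c))
    lam = B / Phi
    P = (lam[:, None] * d - b) / a  # FW momentum at midpoints
    # midpoint Jacobians of drift and noise by central differences
    scale = max(hi - lo for lo, hi in model.domain)
    h = 1e-6 * max(scale, 1.0)
    dl_dm = np.zeros_like(mids)
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        bp = _drift_many(model, mids + e)
        bm = _drift_many(model, mids - e)
        ap = np.maximum(_noise_many(model, mids + e), _NOISE_FLOOR)
        am = np.maximum(_noise_many(model, mids - e), _NOISE_FLOOR)
        Jb = (bp - bm) / (2 * h)
        Ja = (ap - am) / (2 * h)
        dB = (np.sum(b * Jb / a, axis=1)
              - 0.5 * np.sum(b * b * Ja / (a * a), axis=1)) / B
        dPhi = -0.5 * np.sum(d * d * Ja / (a * a), axis=1) / Phi
        dc = np.sum(d * Jb / a, axis=1) - np.sum(d * b * Ja / (a * a), axis=1)
        dl_dm[:, j] = Phi * dB + B * dPhi - dc
    grad = np.zeros((M, 2))
    grad[:-1] += -P + 0.5 * dl_dm
    grad[1:] += P + 0.5 * dl_dm
    if total is not None:  # soft wall at the physical simplex boundary
        viol = np.maximum(pts[:, 0] + pts[:, 1] - total, 0.0)
        w = 1e3 / max(total, 1.0)
        S += float(w * np.sum(viol**2))
        grad += (2 * w * viol)[:, None]
    return S, grad[1:-1].ravel()


def _resample(pts: np.ndarray, M: int) -> np.ndarray:
    """Resample a polygonal path to M points by arclength interpolation."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(pts[:1], M, axis=0)
    tt = np.linspace(0.0, s[-1], M)
    return np.stack([np.interp(tt, s, pts[:, j]) for j in range(pts.shape[1])],
                    axis=1)


def _reparametrize(pts: np.ndarray) -> np.ndarray:
    """Redistribute the path points to uniform Euclidean arclength."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return pts
    t = np.linspace(0.0, s[-1], len(pts))
    out = np.empty_like(pts)
    for j in range(pts.shape[1]):
        out[:, j] = np.interp(t, s, pts[:, j])
    return out


def _instanton_geometric(
    model, X_node: np.ndarray, X_sad: np.ndarray, n_points: int,
    rounds: int = 6, maxiter: int = 400, init: "InstantonPath" = None,
) -> InstantonPath:
    from scipy.optimize import minimize

    M = n_points
    total = getattr(model, "total", None)
    t = np.linspace(0.0, 1.0, M)[:, None]
    if init is None:
        pts = t * (X_sad - X_node) + X_node
    else:
        pts = _reparametrize(_resample(init.X, M))
        # carry the warm-start path over to the (slightly moved) endpoints
        pts = pts + (1.0 - t) * (X_node - pts[0]) + t * (X_sad - pts[-1])
    (lo1, hi1), (lo2, hi2) = model.domain
    m1, m2 = 0.05 * (hi1 - lo1), 0.05 * (hi2 - lo2)
    bounds = [(lo1 - m1, hi1 + m1), (lo2 - m2, hi2 + m2)] * (M - 2)
    S_prev = np.inf
    for r in range(rounds):
        res = minimize(
            lambda z: _gmam_fun_grad(model, z, X_node, X_sad, M, total),
            pts[1:-1].ravel(), jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-13},
        )
        pts[1:-1] = res.x.reshape(M - 2, 2)
        if abs(S_prev - res.fun) < 1e-12 * max(1.0, abs(res.fun)):
            break
        S_prev = res.fun
        if r < rounds - 1:  # keep the returned path at the minimiser
            pts = _reparametrize(pts)
    # momenta at segment midpoints (P = 0 exactly at the two equilibria)
    mids = 0.5 * (pts[1:] + pts[:-1])
    d = np.diff(pts, axis=0)
    b = _drift_many(model, mids)
    a = np.maximum(_noise_many(model, mids), _NOISE_FLOOR)
    B = np.sqrt(np.maximum(np.sum(b * b / a, axis=1), 1e-300))
    Phi = np.sqrt(np.maximum(np.sum(d * d / a, axis=1), 1e-300))
    lam = B / Phi
    P_fw = (lam[:, None] * d - b) / a
    # the quasi-potential convention here has momenta of the opposite sign
    P_mid = -P_fw
    X_path = np.vstack([X_node, mids, X_sad])
    P_path = np.vstack([np.zeros(2), P_mid, np.zeros(2)])
    # pseudo-time: ds = |dX| / |dX/ds|, dX/ds = D - N P (zero at endpoints)
    v = b - a * P_mid
    speed = np.maximum(np.linalg.norm(v, axis=1), 1e-300)
    ds = np.linalg.norm(d, axis=1) / speed
    s = np.concatenate([[0.0], np.cumsum(ds)])
    s = np.concatenate([[s[0]], 0.5 * (s[1:] + s[:-1]), [s[-1]]])
    Hres = np.abs(
        [hamiltonian(X_path[i], P_path[i], model) for i in range(len(s))]
    )
    drift_scale = max(float(np.max(np.abs(b))), 1.0)
    if Hres.max() > _H_TOL * drift_scale:
        raise InstantonNotConvergedError(
            f"Hamiltonian residual {Hres.max():.2e} on geometric path",
            best_miss=float(Hres.max()),
        )
    return InstantonPath(
        s=s, X=X_path, P=P_path, hamiltonian_residuals=Hres,
        endpoints=(X_node, X_sad), miss=0.0,
    )


# --------------------------------------------------------------------------
# 2-D shooting
# --------------------------------------------------------------------------


def _unstable_frame(model, X_node: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Basis of the unstable subspace of the linearised flow at (node, 0).

    The 4-D Jacobian is block-triangular: [[A, -N], [0, -A^T]] with
    A = dD/dX.  Unstable eigenvalues are -lambda(A) > 0; for eigenvector p
    of A^T with eigenvalue lambda, the lifted direction is
    [(A - mu)^-1 N p, p] with mu = -lambda.
    """
    scale = max(hi - lo for lo, hi in model.domain)
    h = 1e-6 * max(scale, 1.0)
    dim = 2
    A = np.zeros((dim, dim))
    for i in range(dim):
        Xp, Xm = X_node.copy(), X_node.copy()
        Xp[i] += h
        Xm[i] -= h
        A[:, i] = (model.drift(Xp) - model.drift(Xm)) / (2 * h)
    N = np.diag(model.noise(X_node))
    lam, V = np.linalg.eig(A.T)
    if np.any(lam.real >= 0):
        raise NotBistableError("start point is not a stable node")
    basis = []
    for k in range(dim):
        mu = -lam[k]
        p = V[:, k]
        dx = np.linalg.solve(A - mu * np.eye(dim), N @ p)
        v = np.concatenate([dx, p]).real
        basis.append(v / np.linalg.norm(v))
    return basis[0], basis[1]


def _shoot(model, y0: np.ndarray, target: np.ndarray, s_max: float,
           box: tuple, rtol: float) -> tuple:
    """Integrate until escape; return (sol, side, closest-approach info)."""
    (lo1, hi1), (lo2, hi2) = box
    pmax = 1e3
    total = getattr(model, "total", None)
    margin1 = 0.2 * (hi1 - lo1)
    margin2 = 0.2 * (hi2 - lo2)

    def escape(s, y):
        d = min(
            y[0] - (lo1 - margin1), (hi1 + margin1) - y[0],
            y[1] - (lo2 - margin2), (hi2 + margin2) - y[1],
            pmax - abs(y[2]), pmax - abs(y[3]),
        )
        if total is not None:  # keep inside the physical simplex margin
            d = min(d, (1.2 * total) - (y[0] + y[1]))
        return d

    escape.terminal = True
    escape.direction = -1
    sol = solve_ivp(
        _flow_rhs(model, 2), (0.0, s_max), y0, method="DOP853",
        rtol=rtol, atol=rtol * 1e-2, events=escape, dense_output=True,
        max_step=s_max / 50.0,
    )
    ys = sol.y
    d = np.sqrt(np.sum((ys - target[:, None]) ** 2, axis=0))
    k = int(np.argmin(d))
    return sol, k, float(d[k])


def compute_instanton(
    model,
    from_node: FixedPoint,
    to_saddle: FixedPoint,
    n_points: int = 150,
    method: str = "geometric",
    init_path: "InstantonPath" = None,
    rounds: int = 6,
    maxiter: int = 400,
    delta: float = 1e-6,
    rtol: float = 1e-10,
    n_scan: int = 180,
    max_bisect: int = 60,
) -> InstantonPath:
    """Heteroclinic instanton from a stable node to the saddle.

    One-dimensional models use the analytic fluctuational branch
    ``P = 2D/N``.  In two dimensions the default route minimises the
    discrete Freidlin–Wentzell geometric action over polygonal paths with
    fixed endpoints (L-BFGS with analytic gradient, arclength
    reparametrisation between rounds); the momenta are recovered segmentwise
    and satisfy ``<H> = 0`` along the path.  ``method="shooting"`` instead
    launches trajectories from the unstable subspace of the linearised
    characteristic flow at (node, 0) and bisects the launch angle — kept for
    cross-checks, but ill-conditioned when the traversal time is long.

    Raises
    ------
    InstantonNotConvergedError
        If the endpoint miss / Hamiltonian residual exceeds tolerance.
    NotBistableError
        If the endpoints do not have node/saddle character.
    """
    if from_node.stability != "stable_node":
        raise NotBistableError("from_node must be a stable node")
    dim = len(np.atleast_1d(from_node.X))
    if dim == 1:
        if to_saddle.stability not in ("saddle", "unstable"):
            raise NotBistableError("to_saddle must be unstable in 1-D")
        return _instanton_1d(
            model, float(from_node.X[0]), float(to_saddle.X[0]), n_points
        )
    if to_saddle.stability != "saddle":
        raise NotBistableError("to_saddle must be a saddle")
    if method == "geometric":
        return _instanton_geometric(
            model, np.asarray(from_node.X, float),
            np.asarray(to_saddle.X, float), n_points, init=init_path,
            rounds=rounds, maxiter=maxiter,
        )

    X_node = np.asarray(from_node.X, float)
    X_sad = np.asarray(to_saddle.X, float)
    scale = max(hi - lo for lo, hi in model.domain)
    v1, v2 = _unstable_frame(model, X_node)
    target = np.concatenate([X_sad, np.zeros(2)])

    # saddle's deterministic unstable direction: side classifier
    h = 1e-6 * max(scale, 1.0)
    A = np.zeros((2, 2))
    for i in range(2):
        Xp, Xm = X_sad.copy(), X_sad.copy()
        Xp[i] += h
        Xm[i] -= h
        A[:, i] = (model.drift(Xp) - model.drift(Xm)) / (2 * h)
    lam, V = np.linalg.eig(A)
    e_u = V[:, int(np.argmax(lam.real))].real
    e_u /= np.linalg.norm(e_u)

    def launch(theta):
        d4 = math.cos(theta) * v1 + math.sin(theta) * v2
        return np.concatenate([X_node, np.zeros(2)]) + delta * scale * d4

    def trial(theta):
        sol, k, miss = _shoot(model, launch(theta), target, _S_MAX,
                              model.domain, rtol)
        side = float(np.dot(sol.y[:2, -1] - X_sad, e_u))
        return sol, k, miss, side

    # coarse scan for sign changes of the side classifier
    thetas = np.linspace(0.0, 2.0 * math.pi, n_scan, endpoint=False)
    results = {}
    best = None
    for th in thetas:
        res = trial(th)
        results[th] = res
        if best is None or res[2] < best[1][2]:
            best = (th, res)
    brackets = []
    for i in range(n_scan):
        th_a, th_b = thetas[i], thetas[(i + 1) % n_scan]
        sa, sb = results[th_a][3], results[th_b][3]
        if sa * sb < 0:
            brackets.append((th_a, th_b if th_b > th_a else th_b + 2 * math.pi))

    for th_a, th_b in brackets:
        ra = results.get(th_a % (2 * math.pi)) or trial(th_a)
        sa = ra[3]
        a, b = th_a, th_b
        for _ in range(max_bisect):
            mid = 0.5 * (a + b)
            rm = trial(mid)
            if rm[2] < best[1][2]:
                best = (mid, rm)
            if rm[3] * sa > 0:
                a = mid
            else:
                b = mid
            if b - a < 1e-15:
                break

    theta_best, (sol, k, miss, _) = best
    miss_rel = miss / max(scale, 1.0)
    if miss_rel > _ENDPOINT_TOL:
        raise InstantonNotConvergedError(
            f"instanton endpoint miss {miss_rel:.2e} (relative) exceeds "
            f"{_ENDPOINT_TOL}", best_miss=miss_rel,
        )
    s = sol.t[: k + 1]
    Y = sol.y[:, : k + 1]
    # prepend the exact node and append the exact saddle (both with P = 0)
    X_path = np.vstack([X_node, Y[:2].T, X_sad])
    P_path = np.vstack([np.zeros(2), Y[2:].T, np.zeros(2)])
    s = np.concatenate([[s[0] - 1.0], s, [s[-1] + 1.0]])
    Hres = np.abs(
        [hamiltonian(X_path[i], P_path[i], model) for i in range(len(s))]
    )
    path = InstantonPath(
        s=s, X=X_path, P=P_path, hamiltonian_residuals=Hres,
        endpoints=(X_node, X_sad), miss=miss_rel,
    )
    if Hres.max() > _H_TOL * max(1.0, np.abs(model.drift(X_node)).max()):
        raise InstantonNotConvergedError(
            f"Hamiltonian residual {Hres.max():.2e} exceeds {_H_TOL}",
            best_miss=miss_rel,
        )
    return path


def action(path: InstantonPath) -> float:
    """Barrier height |int P . dX| by trapezoidal quadrature (clamped >= 0)."""
    dX = np.diff(path.X, axis=0)
    Pm = 0.5 * (path.P[1:] + path.P[:-1])
    val = abs(float(np.sum(Pm * dX)))
    return 0.0 if val < 1e-10 else val


def _bistable_triple(model, grid_density: int = 24, seeds=None):
    fps = find_fixed_points_model(model, grid_density=grid_density, seeds=seeds)
    stables = [fp for fp in fps if fp.is_stable]
    saddles = [fp for fp in fps if fp.stability in ("saddle", "unstable")]
    if len(stables) != 2 or not saddles:
        raise NotBistableError(
            f"need 2 stable nodes and a saddle, found {len(stables)} stable "
            f"and {len(saddles)} unstable"
        )
    if len(saddles) > 1:  # keep the saddle between the nodes
        mid = 0.5 * (stables[0].X + stables[1].X)
        saddles.sort(key=lambda fp: np.linalg.norm(fp.X - mid))
    axis = -1 if len(np.atleast_1d(stables[0].X)) == 1 else 1
    stables.sort(key=lambda fp: np.atleast_1d(fp.X)[axis])
    return stables[0], stables[1], saddles[0]


def robustness(model, grid_density: int = 24, warm_from: RobustnessResult = None,
               **instanton_kw) -> RobustnessResult:
    """Barrier heights of both basins of a bistable model.

    ``dS_minus`` belongs to the node with the smaller acetylation observable
    (hypoacetylated landscape), ``dS_plus`` to the larger one.
    ``warm_from`` seeds equilibria and instanton paths from a previous
    result at nearby parameters (used by the finite-difference sensitivity
    route so that discretisation errors cancel in differences).
    """
    seeds = None
    init_minus = init_plus = None
    if warm_from is not None:
        seeds = [warm_from.X_minus, warm_from.X_plus, warm_from.X_saddle]
        init_minus, init_plus = warm_from.path_minus, warm_from.path_plus
    lo_fp, hi_fp, sad = _bistable_triple(model, grid_density, seeds=seeds)
    path_minus = compute_instanton(model, lo_fp, sad, init_path=init_minus,
                                   **instanton_kw)
    path_plus = compute_instanton(model, hi_fp, sad, init_path=init_plus,
                                  **instanton_kw)
    return RobustnessResult(
        dS_minus=action(path_minus),
        dS_plus=action(path_plus),
        X_minus=np.atleast_1d(lo_fp.X),
        X_plus=np.atleast_1d(hi_fp.X),
        X_saddle=np.atleast_1d(sad.X),
        path_minus=path_minus,
        path_plus=path_plus,
        diagnostics={
            "miss_minus": path_minus.miss,
            "miss_plus": path_plus.miss,
            "H_max_minus": float(path_minus.hamiltonian_residuals.max()),
            "H_max_plus": float(path_plus.hamiltonian_residuals.max()),
        },
    )


def _path_gradient(model, path: InstantonPath, name: str, h_rel: float) -> float:
    """-int dH/dtheta ds along the frozen path (central difference in theta).

    One-dimensional paths use the equivalent x-space quadrature
    ``d(dS)/dtheta = 2 int (dD/dtheta / N - D dN/dtheta / N^2) dx`` (in
    magnitude), which avoids the singular time parametrisation at the
    endpoints.
    """
    theta0 = _get_param(model, name)
    h = h_rel * (1.0 + abs(theta0))
    mp = model.with_params(**{name: theta0 + h})
    mm = model.with_params(**{name: theta0 - h})
    if path.X.shape[1] == 1:
        x = path.X[:, 0]
        D = np.array([model.drift([xi])[0] for xi in x])
        N = np.array([model.noise([xi])[0] for xi in x])
        dD = np.array(
            [(mp.drift([xi])[0] - mm.drift([xi])[0]) / (2 * h) for xi in x]
        )
        dN = np.array(
            [(mp.noise([xi])[0] - mm.noise([xi])[0]) / (2 * h) for xi in x]
        )
        g = 2.0 * (dD / N - D * dN / (N * N))
        # dS is oriented saddle -> node; the path runs node -> saddle
        return -float(np.trapezoid(g, x))
    # 2-D: envelope theorem on the frozen path — differentiate the geometric
    # action functional in theta (equivalent to -int dH/dtheta ds at the
    # minimiser, without the singular time parametrisation)
    Sp = _geometric_action(mp, path.X)
    Sm = _geometric_action(mm, path.X)
    return (Sp - Sm) / (2 * h)


def _get_param(model, name: str) -> float:
    if name == "phi_hat" and hasattr(model, "phi_hat"):
        return float(model.phi_hat)
    params = getattr(model, "params", None)
    if params is not None and hasattr(params, name):
        value = getattr(params, name)
        return 0.0 if value is None else float(value)
    return float(getattr(model, name))


def action_gradient(
    model,
    theta_names: Sequence[str],
    method: str = "both",
    h_rel: float = 3e-3,
    grid_density: int = 24,
    base: Optional[RobustnessResult] = None,
    **instanton_kw,
) -> SensitivityResult:
    """Gradient of the barrier heights with respect to named parameters.

    Two routes:

    - ``"fd"``: central finite differences with relative step ``h_rel``,
      re-solving equilibria and instantons at each perturbed parameter,
      warm-started from the base solution (endpoint motion contributes
      nothing at first order because P = 0 at both endpoints).  The step
      ``h_rel * (1 + |theta|)`` balances truncation against the
      path-solver's termination jitter even for small-valued parameters;
    - ``"path"``: the along-path formula ``-int dH/dtheta ds`` on the
      unperturbed instanton.

    ``"both"`` evaluates the two and reports ``fd`` values with the path
    values alongside in ``grad_*['<name>:path']``.  Per-parameter failures
    are collected, not raised.
    """
    if method not in ("fd", "path", "both"):
        raise ValueError(f"unknown method {method!r}")
    if base is None:
        base = robustness(model, grid_density=grid_density, **instanton_kw)
    grad_minus: dict = {}
    grad_plus: dict = {}
    failures: dict = {}
    for name in theta_names:
        try:
            if method in ("path", "both"):
                gm = _path_gradient(model, base.path_minus, name, h_rel)
                gp = _path_gradient(model, base.path_plus, name, h_rel)
                key = f"{name}:path" if method == "both" else name
                grad_minus[key] = gm
                grad_plus[key] = gp
            if method in ("fd", "both"):
                theta0 = _get_param(model, name)
                h = h_rel * (1.0 + abs(theta0))
                rp = robustness(model.with_params(**{name: theta0 + h}),
                                grid_density=grid_density, warm_from=base,
                                **instanton_kw)
                rm = robustness(model.with_params(**{name: theta0 - h}),
                                grid_density=grid_density, warm_from=base,
                                **instanton_kw)
                grad_minus[name] = (rp.dS_minus - rm.dS_minus) / (2 * h)
                grad_plus[name] = (rp.dS_plus - rm.dS_plus) / (2 * h)
        except (NotBistableError, InstantonNotConvergedError) as exc:
            failures[name] = str(exc)
    return SensitivityResult(
        theta=list(theta_names),
        grad_minus=grad_minus,
        grad_plus=grad_plus,
        method=method,
        failures=failures,
    )
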