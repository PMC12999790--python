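"""The coarse-grained 2-D stochastic model of collective chromatin marks.

Spectral reduction followed by adiabatic elimination of the fast enzyme
variables collapses the full ``12 x N_C``-dimensional network onto two slow
collective observables: weighted methylation ``X1 = sum_j u_j m_j`` and
weighted acetylation ``X2 = sum_j u_j a_j``, with the unmodified pool
``X3 = |u|_1 s_sites - X1 - X2`` fixed by site conservation.  Their dynamics
follow the Ito SDEs

    dX_i = <D_i> dt + Omega27^{-1/2} sqrt(<N_i>) dB_t,   i = 1, 2

whose drift terms are differences of two Michaelis–Menten-like fluxes
(addition minus removal) and whose noise terms are sums of the underlying
jump intensities.  The competition level ``B`` enters only the deacetylation
denominator, as ``|u|_1 B / sqrt(N_C)``.

The fast enzyme/complex observables are evaluated on their quasi-stationary
("fast") manifold, i.e. at the roots of the fast drift — the Laplace-method
evaluation point of the averaged Fokker–Planck operator.  The per-pool
stationary densities themselves are available through
:func:`fast_stationary_density`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .connectivity import SpectralQuantities


__all__ = [
    "CGState",
    "FastManifoldState",
    "CGModel",
    "CustomModel",
    "euler_maruyama_simulate",
    "fast_stationary_density",
    "StepTooLargeError",
    "NoRootInDomainError",
]

_FAST_POOLS = ("ezh2", "utx", "hat", "sirt")


class StepTooLargeError(RuntimeError):
    """An Euler–Maruyama step produced a non-finite drift or noise."""


class NoRootInDomainError(RuntimeError):
    """No fast-manifold root inside the physical domain box."""


@dataclass(frozen=True)
class CGState:
    """Slow collective state ``(X1, X2)`` with conserved total ``|u|_1 s_sites``."""

    X1: float
    X2: float
    total: float

    @property
    def X3(self) -> float:
        return self.total - self.X1 - self.X2

    def as_array(self) -> np.ndarray:
        return np.array([self.X1, self.X2])


@dataclass(frozen=True)
class FastManifoldState:
    """Quasi-stationary fast observables: free enzymes and complexes per pool."""

    c_E: float
    c_U: float
    c_H: float
    c_S: float
    c_SD: float
    e2: float
    eU: float
    eH: float
    eS: float


class CGModel:
    """Drift/noise evaluator for the two slow collective observables.

    Parameters
    ----------
    params, scaling:
        Kinetic parameters and system sizes (validated).
    spec:
        Spectral quantities of the contact matrix used in the microscopic
        model.  ``phi_hat`` may be overridden (see ``with_params``) to treat
        the structural summary as a differentiable input for sensitivity
        analysis; the noise closure scalar ``gamma_hat = alpha_w*Gamma_1*/|u|_1``
        is scaled proportionally in that case.
    noise_enzymes:
        ``"fast_manifold"`` (default) evaluates the free-enzyme factors of
        the noise at the fast-manifold root; ``"total_pools"`` substitutes
        the cruder total-pool levels ``e0/sqrt(N_C)`` etc.
    """

    dim = 2

    def __init__(
        self,
        params: KineticParameters,
        spec: SpectralQuantities,
        scaling: ScalingSettings,
        noise_enzymes: str = "fast_manifold",
        _phi_hat_override: Optional[float] = None,
    ):
        if noise_enzymes not in ("fast_manifold", "total_pools"):
            raise ValueError(f"unknown noise_enzymes mode {noise_enzymes!r}")
        self.params = params
        self.spec = spec
        self.scaling = scaling
        self.noise_enzymes = noise_enzymes
        self._phi_override = _phi_hat_override
        self.n_regions = spec.n_regions
        self.l1 = spec.norm_l1
        self.sqrtN = math.sqrt(spec.n_regions)
        base_phi = spec.phi_hat
        self.phi_hat = base_phi if _phi_hat_override is None else _phi_hat_override
        # noise closure scalar; scales with the phi_hat override
        gamma_base = spec.alpha_w * spec.gamma1_star / spec.norm_l1
        ratio = 1.0 if _phi_hat_override is None else self.phi_hat / base_phi
        self.gamma_hat = gamma_base * ratio
        self.total = self.l1 * params.s_sites
        self.B_tilde = self.l1 * params.B / self.sqrtN
        #: rectangular hull of the physical simplex {X1,X2>=0, X1+X2<=total}
        self.domain = ((0.0, self.total), (0.0, self.total))

    # -- construction helpers -------------------------------------------------

    def with_params(self, **changes) -> "CGModel":
        """New model with kinetic parameters (or ``B``, ``phi_hat``, ``a_hat``,
        ``s_hat``) replaced.

        ``a_hat``/``s_hat`` apply the metabolic-cofactor substitutions
        ``k7 -> k7*a_hat`` / ``k1 -> k1*s_hat`` relative to the *current*
        parameters.
        """
        phi = changes.pop("phi_hat", self._phi_override)
        params = self.params
        a_hat = changes.pop("a_hat", None)
        s_hat = changes.pop("s_hat", None)
        if changes:
            params = params.replace(**changes)
        if a_hat is not None:
            params = params.replace(k7=params.k7 * a_hat)
        if s_hat is not None:
            params = params.replace(k1=params.k1 * s_hat)
        return CGModel(
            params,
            self.spec,
            self.scaling,
            noise_enzymes=self.noise_enzymes,
            _phi_hat_override=phi,
        )

    def state(self, X1: float, X2: float) -> CGState:
        return CGState(X1=X1, X2=X2, total=self.total)

    def in_domain(self, X) -> bool:
        X1, X2 = float(X[0]), float(X[1])
        tol = 1e-9 * max(1.0, self.total)
        return (
            X1 >= -tol and X2 >= -tol and X1 + X2 <= self.total + tol
        )

    # -- kinetic building blocks ----------------------------------------------

    def _kappas(self, X1: float, X2: float) -> tuple[float, float, float, float]:
        """Landscape-modulated binding intensities for the four enzyme cycles."""
        p = self.params
        k = self.l1
        return (
            p.k1 * k * (p.alpha1 + self.phi_hat * X1),
            p.k4 * k * (p.alpha4 + self.phi_hat * X2),
            p.k7 * k * (p.alpha7 + self.phi_hat * X2),
            p.k10 * k * (p.alpha10 + self.phi_hat * X1),
        )

    def fast_manifold(self, X) -> FastManifoldState:
        """Quasi-stationary enzyme observables at frozen slow state.

        Each pool's fast drift is affine in its complex observable, so the
        root is unique and available in closed form; residuals are checked
        against 1e-12.  Complexes live in the box ``[0, pool/sqrt(N_C)]``.
        """
        X1, X2 = float(X[0]), float(X[1])
        # soft margin: the Hamiltonian characteristics may graze the simplex
        # boundary; the closed forms continue analytically a short way out
        margin = 0.25 * self.total
        if (
            X1 < -margin
            or X2 < -margin
            or X1 + X2 > self.total + margin
        ):
            raise NoRootInDomainError(f"slow state ({X1}, {X2}) outside domain")
        p = self.params
        X3 = self.total - X1 - X2
        kap1, kap4, kap7, kap10 = self._kappas(X1, X2)
        e_tot = p.e0 / self.sqrtN
        u_tot = p.u0 / self.sqrtN
        h_tot = p.h0 / self.sqrtN
        s_tot = p.s0_enz / self.sqrtN

        c_E = e_tot * kap1 * X3 / (p.k2 + p.k3 + kap1 * X3)
        c_U = u_tot * kap4 * X1 / (p.k5 + p.k6 + kap4 * X1)
        c_H = h_tot * kap7 * X3 / (p.k8 + p.k9 + kap7 * X3)
        den_S = p.k11 + p.k12 + self.B_tilde + kap10 * X2
        c_S = s_tot * kap10 * X2 / den_S
        e_S = (s_tot - c_S) * (p.k11 + p.k12) / (p.k11 + p.k12 + self.B_tilde)
        c_SD = s_tot - c_S - e_S
        state = FastManifoldState(
            c_E=c_E,
            c_U=c_U,
            c_H=c_H,
            c_S=c_S,
            c_SD=c_SD,
            e2=e_tot - c_E,
            eU=u_tot - c_U,
            eH=h_tot - c_H,
            eS=e_S,
        )
        self._check_fast_residual(state, X1, X2, X3)
        return state

    def _check_fast_residual(
        self, f: FastManifoldState, X1: float, X2: float, X3: float
    ) -> None:
        p = self.params
        kap1, kap4, kap7, kap10 = self._kappas(X1, X2)
        scale = max(1.0, p.k2 + p.k3, p.k5 + p.k6, p.k8 + p.k9, p.k11 + p.k12)
        resid = (
            abs(kap1 * X3 * f.e2 - (p.k2 + p.k3) * f.c_E),
            abs(kap4 * X1 * f.eU - (p.k5 + p.k6) * f.c_U),
            abs(kap7 * X3 * f.eH - (p.k8 + p.k9) * f.c_H),
            abs(kap10 * X2 * f.eS - (p.k11 + p.k12) * f.c_S),
            abs(self.B_tilde * f.eS - (p.k11 + p.k12) * f.c_SD),
        )
        if max(resid) > 1e-12 * scale * max(1.0, self.total):
            raise NoRootInDomainError(
                f"fast-manifold residual {max(resid):.2e} at ({X1}, {X2})"
            )

    # -- drift / noise ---------------------------------------------------------

    def drift(self, X) -> np.ndarray:
        """Averaged slow drift ``(<D1>, <D2>)``.

        Each component is the difference of two saturating fluxes, e.g. for
        methylation: EZH2 catalysis minus UTX-mediated removal, with
        landscape feedback entering the binding intensity and the
        competition term ``|u|_1 B/sqrt(N_C)`` padding the deacetylation
        denominator.
        """
        X1, X2 = float(X[0]), float(X[1])
        p = self.params
        X3 = self.total - X1 - X2
        kap1, kap4, kap7, kap10 = self._kappas(X1, X2)
        sn = self.sqrtN
        D1 = (
            p.k3 * (p.e0 / sn) * kap1 * X3 / (p.k2 + p.k3 + kap1 * X3)
            - p.k6 * (p.u0 / sn) * kap4 * X1 / (p.k5 + p.k6 + kap4 * X1)
        )
        D2 = (
            p.k9 * (p.h0 / sn) * kap7 * X3 / (p.k8 + p.k9 + kap7 * X3)
            - p.k12
            * (p.s0_enz / sn)
            * kap10
            * X2
            / (p.k11 + p.k12 + self.B_tilde + kap10 * X2)
        )
        return np.array([D1, D2])

    def noise(self, X) -> np.ndarray:
        """Averaged slow noise intensities ``(<N1>, <N2>)`` (always >= 0).

        Sums of binding/unbinding/catalysis jump intensities; the
        free-enzyme factors are taken from the fast manifold (or the total
        pools, per ``noise_enzymes``).
        """
        X1, X2 = float(X[0]), float(X[1])
        p = self.params
        X3 = self.total - X1 - X2
        if self.noise_enzymes == "fast_manifold":
            f = self.fast_manifold((X1, X2))
            e2, eU, eH, eS = f.e2, f.eU, f.eH, f.eS
        else:
            sn = self.sqrtN
            e2, eU, eH, eS = p.e0 / sn, p.u0 / sn, p.h0 / sn, p.s0_enz / sn

        def leg(kb, ku, kc, alpha, Xfb, enz, sub):
            # one Michaelis--Menten leg's contribution to the jump intensity
            coeff = (2.0 * ku + kc) / (ku + kc) * alpha + (
                self.gamma_hat + ku / (ku + kc) * self.phi_hat
            ) * Xfb
            return kb * coeff * enz * sub

        N1 = leg(p.k1, p.k2, p.k3, p.alpha1, X1, e2, X3) + leg(
            p.k4, p.k5, p.k6, p.alpha4, X2, eU, X1
        )
        N2 = leg(p.k7, p.k8, p.k9, p.alpha7, X2, eH, X3) + leg(
            p.k10, p.k11, p.k12, p.alpha10, X1, eS, X2
        )
        return np.array([N1, N2])

    def meanfield_rhs(self, X) -> np.ndarray:
        """Deterministic (Omega27 -> infinity) limit: identical to the drift."""
        return self.drift(X)

    # -- vectorised evaluation (used by the path-space instanton solver) ------

    def drift_many(self, Xs: np.ndarray) -> np.ndarray:
        """Drift at an (M, 2) array of slow states."""
        Xs = np.asarray(Xs, dtype=float)
        X1, X2 = Xs[:, 0], Xs[:, 1]
        p = self.params
        X3 = self.total - X1 - X2
        k = self.l1
        kap1 = p.k1 * k * (p.alpha1 + self.phi_hat * X1)
        kap4 = p.k4 * k * (p.alpha4 + self.phi_hat * X2)
        kap7 = p.k7 * k * (p.alpha7 + self.phi_hat * X2)
        kap10 = p.k10 * k * (p.alpha10 + self.phi_hat * X1)
        sn = self.sqrtN
        D1 = (
            p.k3 * (p.e0 / sn) * kap1 * X3 / (p.k2 + p.k3 + kap1 * X3)
            - p.k6 * (p.u0 / sn) * kap4 * X1 / (p.k5 + p.k6 + kap4 * X1)
        )
        D2 = (
            p.k9 * (p.h0 / sn) * kap7 * X3 / (p.k8 + p.k9 + kap7 * X3)
            - p.k12 * (p.s0_enz / sn) * kap10 * X2
            / (p.k11 + p.k12 + self.B_tilde + kap10 * X2)
        )
        return np.stack([D1, D2], axis=1)

    def noise_many(self, Xs: np.ndarray) -> np.ndarray:
        """Noise intensities at an (M, 2) array of slow states."""
        Xs = np.asarray(Xs, dtype=float)
        X1, X2 = Xs[:, 0], Xs[:, 1]
        p = self.params
        X3 = self.total - X1 - X2
        k = self.l1
        kap1 = p.k1 * k * (p.alpha1 + self.phi_hat * X1)
        kap4 = p.k4 * k * (p.alpha4 + self.phi_hat * X2)
        kap7 = p.k7 * k * (p.alpha7 + self.phi_hat * X2)
        kap10 = p.k10 * k * (p.alpha10 + self.phi_hat * X1)
        sn = self.sqrtN
        e_tot, u_tot = p.e0 / sn, p.u0 / sn
        h_tot, s_tot = p.h0 / sn, p.s0_enz / sn
        if self.noise_enzymes == "fast_manifold":
            e2 = e_tot * (p.k2 + p.k3) / (p.k2 + p.k3 + kap1 * X3)
            eU = u_tot * (p.k5 + p.k6) / (p.k5 + p.k6 + kap4 * X1)
            eH = h_tot * (p.k8 + p.k9) / (p.k8 + p.k9 + kap7 * X3)
            den_S = p.k11 + p.k12 + self.B_tilde + kap10 * X2
            eS = (
                s_tot
                * (1.0 - kap10 * X2 / den_S)
                * (p.k11 + p.k12)
                / (p.k11 + p.k12 + self.B_tilde)
            )
        else:
            e2 = np.full_like(X1, e_tot)
            eU = np.full_like(X1, u_tot)
            eH = np.full_like(X1, h_tot)
            eS = np.full_like(X1, s_tot)

        def leg(kb, ku, kc, alpha, Xfb, enz, sub):
            coeff = (2.0 * ku + kc) / (ku + kc) * alpha + (
                self.gamma_hat + ku / (ku + kc) * self.phi_hat
            ) * Xfb
            return kb * coeff * enz * sub

        N1 = leg(p.k1, p.k2, p.k3, p.alpha1, X1, e2, X3) + leg(
            p.k4, p.k5, p.k6, p.alpha4, X2, eU, X1
        )
        N2 = leg(p.k7, p.k8, p.k9, p.alpha7, X2, eH, X3) + leg(
            p.k10, p.k11, p.k12, p.alpha10, X1, eS, X2
        )
        return np.stack([N1, N2], axis=1)


class CustomModel:
    """A user-supplied drift/noise model (any dimension) for the generic
    bifurcation and quasi-potential machinery.

    ``drift_fn``/``noise_fn`` map a state array to an array of the same
    length; ``domain`` is a sequence of ``(lo, hi)`` pairs.
    """

    def __init__(self, drift_fn, noise_fn, domain, dim=None):
        self._drift = drift_fn
        self._noise = noise_fn
        self.domain = tuple(tuple(map(float, d)) for d in domain)
        self.dim = dim if dim is not None else len(self.domain)

    def drift(self, X) -> np.ndarray:
        return np.atleast_1d(np.asarray(self._drift(np.asarray(X, float)), float))

    def noise(self, X) -> np.ndarray:
        return np.atleast_1d(np.asarray(self._noise(np.asarray(X, float)), float))

    def meanfield_rhs(self, X) -> np.ndarray:
        return self.drift(X)

    def in_domain(self, X) -> bool:
        X = np.atleast_1d(np.asarray(X, float))
        return all(
            lo - 1e-9 <= x <= hi + 1e-9 for x, (lo, hi) in zip(X, self.domain)
        )


def _reflect_simplex(X: np.ndarray, total: float) -> np.ndarray:
    """Reflect a proposed step back into {X1 >= 0, X2 >= 0, X1+X2 <= total}."""
    X = X.copy()
    for _ in range(10):
        moved = False
        for i in range(2):
            if X[i] < 0.0:
                X[i] = -X[i]
                moved = True
        s = X[0] + X[1]
        if s > total:
            # reflect across the hyperplane X1 + X2 = total
            excess = s - total
            X -= excess
            moved = True
        if not moved:
            return X
    return np.clip(X, 0.0, total)


def euler_maruyama_simulate(
    model: CGModel,
    X0,
    dt: float,
    t_end: float,
    seed: int,
    record_every: int = 1,
    omega27: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama integration of the slow SDEs with reflecting boundary.

    Noise amplitude is ``omega27**-0.5`` (defaults to the model's scaling);
    the state is reflected at the physical simplex boundary, a
    regularisation that keeps ``X3 >= 0``.  Returns ``(times, states)`` with
    states of shape ``(n_rec, 2)``.  Reproducible for a fixed ``seed``.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    X = np.atleast_1d(np.asarray(X0, dtype=float)).copy()
    if not model.in_domain(X):
        raise ValueError(f"initial state {X} outside domain")
    if omega27 is not None:
        omega = float(omega27)
    else:
        scaling = getattr(model, "scaling", None)
        omega = float(scaling.omega27) if scaling is not None else math.inf
    amp = omega**-0.5 if np.isfinite(omega) else 0.0
    total = getattr(model, "total", None)
    dim = len(X)
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    times = [0.0]
    states = [X.copy()]
    sqdt = math.sqrt(dt)
    for step in range(1, n_steps + 1):
        D = model.drift(X)
        if amp > 0.0:
            N = model.noise(X)
            if not (np.all(np.isfinite(D)) and np.all(np.isfinite(N)) and np.all(N >= -1e-12)):
                raise StepTooLargeError(
                    f"non-finite drift/noise at t={step * dt:.6g}, X={X}"
                )
            X = X + D * dt + amp * np.sqrt(np.maximum(N, 0.0)) * rng.normal(size=dim) * sqdt
        else:
            if not np.all(np.isfinite(D)):
                raise StepTooLargeError(f"non-finite drift at t={step * dt:.6g}, X={X}")
            X = X + D * dt
        if total is not None:
            X = _reflect_simplex(X, total)
        if step % record_every == 0:
            times.append(step * dt)
            states.append(X.copy())
    return np.asarray(times), np.asarray(states)


def _fast_pool_rates(model: CGModel, which: str, Xs) -> tuple[float, float, float]:
    """(binding intensity kappa*substrate, total pool, unbind+cat rate) for a pool."""
    p = model.params
    X1, X2 = float(Xs[0]), float(Xs[1])
    X3 = model.total - X1 - X2
    kap1, kap4, kap7, kap10 = model._kappas(X1, X2)
    sn = model.sqrtN
    table = {
        "ezh2": (kap1 * X3, p.e0 / sn, p.k2 + p.k3),
        "utx": (kap4 * X1, p.u0 / sn, p.k5 + p.k6),
        "hat": (kap7 * X3, p.h0 / sn, p.k8 + p.k9),
        "sirt": (kap10 * X2, p.s0_enz / sn, p.k11 + p.k12 + model.B_tilde),
    }
    if which not in table:
        raise ValueError(f"unknown fast pool {which!r}; choose from {_FAST_POOLS}")
    return table[which]


def fast_stationary_density(
    which: str,
    Xs,
    model: CGModel,
    grid: np.ndarray,
    omega_e: Optional[float] = None,
) -> np.ndarray:
    """Quasi-stationary density of one fast complex observable at frozen slow state.

    For a single pool the fast dynamics is a birth–death diffusion with
    drift ``D(c) = kS*(e_tot - c) - K*c`` and intensity
    ``N(c) = kS*(e_tot - c) + K*c``; the zero-flux stationary solution is

        ``psi(c) ∝ N(c)^{-1} exp( 2 Omega_E \\int_0^c D/N ds )``,

    normalised by trapezoidal quadrature on ``grid`` (which must cover
    ``[0, e_tot]`` or a sub-segment).  As ``Omega_E`` grows the density
    sharpens around the fast-manifold root (Laplace's method).
    """
    kS, e_tot, K = _fast_pool_rates(model, which, Xs)
    omega = float(omega_e if omega_e is not None else model.scaling.omega_e)
    c = np.asarray(grid, dtype=float)
    if c.ndim != 1 or len(c) < 8:
        raise ValueError("grid must be a 1-D array with at least 8 points")
    D = kS * (e_tot - c) - K * c
    N = kS * (e_tot - c) + K * c
    if np.any(N <= 0):
        raise ValueError("noise intensity vanishes on the grid; density not integrable")
    # cumulative exponent 2*Omega_E int D/N, stabilised by subtracting the max
    integrand = D / N
    expo = 2.0 * omega * _cumtrapz(integrand, c)
    log_psi = expo - np.log(N)
    log_psi -= log_psi.max()
    psi = np.exp(log_psi)
    Z = np.trapezoid(psi, c)
    if not (np.isfinite(Z) and Z > 0):
        raise ValueError("density not integrable on the supplied grid")
    return psi / Z


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out
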