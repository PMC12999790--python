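"""Early-warning scans, micro-vs-CG validation and bistability calibration.

Three jobs live here: (i) the variance early-warning signal — the ensemble
variance of the collective acetylation observable peaks as a control
parameter approaches a saddle-node tipping point; (ii) the agreement
harness that pits coarse-grained fixed points against microscopic
mean-field steady states across a control-parameter grid, including the
fold (tipping-point) locations both layers predict; and (iii) calibration
of the bistable window of the coarse-grained model in any control
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .bifurcation import find_fixed_points_model
from .cg import CGModel, euler_maruyama_simulate
from .connectivity import ConnectivityMatrix, NotIrreducibleError, spectral_quantities
from .micro import (
    build_reaction_network,
    collective_observables,
    gillespie_simulate,
    initial_condition,
    meanfield_initial,
    micro_steady_state,
    NotConvergedError,
)
from .params import KineticParameters, ScalingSettings

__all__ = [
    "VarianceScan",
    "AgreementReport",
    "variance_scan",
    "cg_ews_simulator",
    "micro_ews_simulator",
    "compare_micro_cg",
    "calibrate_bistability",
]


@dataclass
class VarianceScan:
    """Ensemble variance of the acetylation observable along a control grid."""

    control_name: str
    grid: np.ndarray
    variances: np.ndarray
    means: np.ndarray
    n_reps: int
    burn_in: float
    seed: int
    failures: dict = field(default_factory=dict)

    def peak(self) -> tuple[float, float]:
        """(control value, variance) at the scan maximum (NaNs ignored)."""
        k = int(np.nanargmax(self.variances))
        return float(self.grid[k]), float(self.variances[k])


@dataclass
class AgreementReport:
    """Micro vs CG steady observables and fold locations on a control grid."""

    control_name: str
    table: pd.DataFrame
    micro_window: Optional[tuple[float, float]]
    cg_window: Optional[tuple[float, float]]
    cg_applicable: bool

    def max_relative_error(self) -> float:
        cols = [c for c in self.table.columns if c.startswith("rel_err")]
        if not cols or not self.cg_applicable:
            return float("nan")
        return float(np.nanmax(self.table[cols].to_numpy()))


def variance_scan(
    simulator: Callable,
    control_name: str,
    grid: Sequence[float],
    n_reps: int,
    t_end: float,
    burn_in: Optional[float] = None,
    seed: int = 0,
) -> VarianceScan:
    """Unbiased sample variance of the acetylation observable per grid point.

    ``simulator(control_value, seed, t_end, burn_in)`` must return a 1-D
    array of post-burn-in acetylation samples from one replicate; samples
    from ``n_reps`` independently seeded replicates are pooled at each grid
    value.  Burn-in defaults to half of ``t_end`` (heuristic).  Individual
    replicate failures are recorded and the scan continues.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    burn = 0.5 * t_end if burn_in is None else burn_in
    grid = np.asarray(grid, dtype=float)
    variances = np.full(len(grid), np.nan)
    means = np.full(len(grid), np.nan)
    failures: dict = {}
    rng = np.random.default_rng(seed)
    for k, value in enumerate(grid):
        samples = []
        for _ in range(n_reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            try:
                samples.append(np.asarray(simulator(value, rep_seed, t_end, burn)))
            except Exception as exc:  # noqa: BLE001 - scan must continue
                failures.setdefault(float(value), []).append(str(exc))
        if len(samples) >= 2:
            pooled = np.concatenate(samples)
            variances[k] = float(np.var(pooled, ddof=1))
            means[k] = float(np.mean(pooled))
    return VarianceScan(
        control_name=control_name,
        grid=grid,
        variances=variances,
        means=means,
        n_reps=n_reps,
        burn_in=burn,
        seed=seed,
        failures=failures,
    )


def cg_ews_simulator(
    model: CGModel,
    control_name: str,
    branch: str = "hyperacetylated",
    dt: float = 0.01,
    omega27: Optional[float] = None,
) -> Callable:
    """Euler–Maruyama replicate generator for :func:`variance_scan`.

    Each replicate starts from the requested stable branch (tracked across
    the grid via the deterministic fixed points; if the branch has vanished
    the start falls back to the surviving state) and returns the
    post-burn-in X2 samples.
    """

    def simulate(value, seed, t_end, burn_in):
        m = model.with_params(**{control_name: value})
        fps = [fp for fp in find_fixed_points_model(m, grid_density=14) if fp.is_stable]
        if not fps:
            raise NotConvergedError(f"no stable state at {control_name}={value}")
        key = (lambda fp: fp.X[1]) if branch == "hyperacetylated" else (
            lambda fp: -fp.X[1]
        )
        X0 = max(fps, key=key).X
        times, states = euler_maruyama_simulate(
            m, X0, dt=dt, t_end=t_end, seed=seed, omega27=omega27
        )
        return states[times > burn_in, 1]

    return simulate


def micro_ews_simulator(
    params: KineticParameters,
    conn: ConnectivityMatrix,
    scaling: ScalingSettings,
    control_name: str,
    branch: str = "hyperacetylated",
    n_records: int = 101,
) -> Callable:
    """Exact-SSA replicate generator for :func:`variance_scan`.

    The control parameter is applied through ``KineticParameters.replace``
    (``a_hat``/``s_hat`` multiply k7/k1).  The observable is the collective
    acetylation ``X2 = sum_j u_j a_j``.
    """
    spec = spectral_quantities(conn)

    def simulate(value, seed, t_end, burn_in):
        if control_name == "a_hat":
            p = params.replace(k7=params.k7 * value)
        elif control_name == "s_hat":
            p = params.replace(k1=params.k1 * value)
        else:
            p = params.replace(**{control_name: value})
        network = build_reaction_network(p, conn, scaling)
        x0 = initial_condition(network, kind=branch)
        traj = gillespie_simulate(network, x0, t_end=t_end, seed=seed,
                                  n_records=n_records)
        keep = traj.times - traj.times[0] > burn_in
        out = []
        for k in np.nonzero(keep)[0]:
            out.append(
                collective_observables(
                    traj.state_at(int(k)), spec, scaling, s_sites=p.s_sites
                ).X2
            )
        return np.asarray(out)

    return simulate


# --------------------------------------------------------------------------
# Micro vs CG agreement
# --------------------------------------------------------------------------


def _micro_branch_states(params, conn, scaling, control_name, value):
    """Micro mean-field steady states from hypo- and hyper-acetylated starts."""
    if control_name == "a_hat":
        p = params.replace(k7=params.k7 * value)
    elif control_name == "s_hat":
        p = params.replace(k1=params.k1 * value)
    else:
        p = params.replace(**{control_name: value})
    network = build_reaction_network(p, conn, scaling)
    out = {}
    for kind in ("hypoacetylated", "hyperacetylated"):
        try:
            x, _ = micro_steady_state(network, meanfield_initial(network, kind))
            out[kind] = x
        except NotConvergedError:
            out[kind] = None
    return out, network


def compare_micro_cg(
    params: KineticParameters,
    conn: ConnectivityMatrix,
    scaling: ScalingSettings,
    control_name: str = "B",
    grid: Sequence[float] = (),
    window_refine: bool = True,
) -> AgreementReport:
    """Steady-state and fold-location agreement between the two layers.

    For each control value the microscopic mean-field system is relaxed
    from hypo- and hyper-acetylated starts and projected onto the
    collective observables; the coarse-grained fixed points are computed at
    the same control value.  Relative errors pair each micro branch with
    its nearest CG stable state.  For an ablated (reducible) contact matrix
    the CG columns are absent and only the microscopic bistability window
    is reported.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty control grid")
    try:
        spec = spectral_quantities(conn)
        cg_ok = True
    except NotIrreducibleError:
        spec, cg_ok = None, False

    rows = []
    micro_bistable = []
    for value in grid:
        states, network = _micro_branch_states(params, conn, scaling,
                                               control_name, value)
        row: dict = {control_name: value}
        obs = {}
        for kind, x in states.items():
            tag = "hypo" if kind.startswith("hypo") else "hyper"
            if x is None:
                row[f"micro_X1_{tag}"] = np.nan
                row[f"micro_X2_{tag}"] = np.nan
                continue
            if cg_ok:
                c = collective_observables(x, spec, scaling, s_sites=params.s_sites)
                X1, X2 = c.X1, c.X2
            else:
                X1 = float(np.mean(x[0]))
                X2 = float(np.mean(x[1]))
            obs[tag] = (X1, X2)
            row[f"micro_X1_{tag}"] = X1
            row[f"micro_X2_{tag}"] = X2
        distinct = (
            len(obs) == 2
            and np.hypot(obs["hypo"][0] - obs["hyper"][0],
                         obs["hypo"][1] - obs["hyper"][1])
            > 1e-3 * max(1.0, params.s_sites)
        )
        micro_bistable.append(distinct)
        row["micro_bistable"] = distinct
        if cg_ok:
            model = CGModel(network.params, spec, scaling)
            stables = [fp for fp in find_fixed_points_model(model, grid_density=18)
                       if fp.is_stable]
            row["cg_n_stable"] = len(stables)
            for tag in ("hypo", "hyper"):
                if tag not in obs or not stables:
                    continue
                X = np.array(obs[tag])
                fp = min(stables, key=lambda f: np.linalg.norm(f.X - X))
                scale = max(np.linalg.norm(X), 1e-12 * max(1.0, model.total))
                row[f"cg_X1_{tag}"] = fp.X[0]
                row[f"cg_X2_{tag}"] = fp.X[1]
                row[f"rel_err_{tag}"] = float(np.linalg.norm(fp.X - X) / scale)
        rows.append(row)

    micro_window = _window_from_flags(grid, micro_bistable)
    cg_window = None
    if cg_ok:
        model = CGModel(params, spec, scaling)
        cg_window = calibrate_bistability(
            model, control_name, (float(grid[0]), float(grid[-1])),
            n_scan=len(grid), refine=window_refine,
        )
    return AgreementReport(
        control_name=control_name,
        table=pd.DataFrame(rows),
        micro_window=micro_window,
        cg_window=cg_window,
        cg_applicable=cg_ok,
    )


def micro_is_bistable(
    params: KineticParameters,
    conn: ConnectivityMatrix,
    scaling: ScalingSettings,
    control_name: str = "B",
    value: float = None,
    t_relax: float = 300.0,
    tol: float = 1e-3,
) -> bool:
    """Whether the microscopic mean-field system holds two distinct basins.

    Relaxes the system from hypo- and hyper-acetylated starts and compares
    the per-region mark averages of the resulting steady states.
    """
    v = params.B if value is None else value
    states, _ = _micro_branch_states(params, conn, scaling, control_name, v)
    obs = []
    for x in states.values():
        if x is None:
            return False
        obs.append((float(np.mean(x[0])), float(np.mean(x[1]))))
    (m1, a1), (m2, a2) = obs
    return bool(np.hypot(m1 - m2, a1 - a2) > tol * max(1.0, params.s_sites))


def micro_fold_bisect(
    params: KineticParameters,
    conn: ConnectivityMatrix,
    scaling: ScalingSettings,
    bracket: tuple[float, float],
    control_name: str = "B",
    tol: float = 0.02,
    t_relax: float = 300.0,
) -> float:
    """Bisect the control value at which microscopic bistability is lost.

    The bracket endpoints must differ in their bistability flag; the
    returned value is the bracket midpoint once its width falls below
    ``tol``.
    """
    a, b = map(float, bracket)
    fa = micro_is_bistable(params, conn, scaling, control_name, a, t_relax)
    fb = micro_is_bistable(params, conn, scaling, control_name, b, t_relax)
    if fa == fb:
        raise ValueError(
            f"bracket ({a}, {b}) does not straddle a bistability change"
        )
    while b - a > tol:
        mid = 0.5 * (a + b)
        if micro_is_bistable(params, conn, scaling, control_name, mid, t_relax) == fa:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def _window_from_flags(grid, flags) -> Optional[tuple[float, float]]:
    idx = np.nonzero(np.asarray(flags))[0]
    if idx.size == 0:
        return None
    return float(grid[idx[0]]), float(grid[idx[-1]])


def calibrate_bistability(
    model: CGModel,
    control_name: str,
    search_range: tuple[float, float],
    n_scan: int = 41,
    refine: bool = True,
    rel_tol: float = 1e-3,
    grid_density: int = 18,
) -> Optional[tuple[float, float]]:
    """The control-parameter window in which the CG model is bistable.

    Scans the range, then bisects each window edge until its bracket is
    below ``rel_tol`` of the range width.  Returns ``(lo, hi)`` or ``None``
    when no bistable point exists in range.
    """
    lo, hi = map(float, search_range)
    grid = np.linspace(lo, hi, n_scan)

    def n_stable(value) -> int:
        m = model.with_params(**{control_name: value})
        return sum(
            fp.is_stable
            for fp in find_fixed_points_model(m, grid_density=grid_density)
        )

    flags = [n_stable(v) >= 2 for v in grid]
    idx = np.nonzero(flags)[0]
    if idx.size == 0:
        return None
    w_lo, w_hi = float(grid[idx[0]]), float(grid[idx[-1]])
    if refine:
        tol = rel_tol * (hi - lo)
        if idx[0] > 0:
            a, b = float(grid[idx[0] - 1]), w_lo
            while b - a > tol:
                mid = 0.5 * (a + b)
                if n_stable(mid) >= 2:
                    b = mid
                else:
                    a = mid
            w_lo = b
        if idx[-1] < len(grid) - 1:
            a, b = w_hi, float(grid[idx[-1] + 1])
            while b - a > tol:
                mid = 0.5 * (a + b)
                if n_stable(mid) >= 2:
                    a = mid
                else:
                    b = mid
            w_hi = a
    return w_lo, w_hi
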