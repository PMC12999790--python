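"""Kinetic parameters, system-size scalings and metabolic-cofactor modulation.

The chromatin-modification model tracks four Michaelis--Menten enzyme cycles
acting on H3K27 sites: methylation by EZH2 (rates ``k1``--``k3``),
demethylation by UTX (``k4``--``k6``), acetylation by a HAT (``k7``--``k9``)
and deacetylation by SIRT-class HDACs (``k10``--``k12``).  Binding rates are
modulated by the surrounding epigenetic landscape through dimensionless basal
offsets ``alpha1/alpha4/alpha7/alpha10`` plus contact-weighted feedback sums
(see :mod:`epitip.micro`).

Two system sizes govern the multiscale structure: ``omega27`` rescales
substrate (H3K27 site) abundances and ``omega_e`` rescales enzyme abundances.
Their ratio ``epsilon = omega_e/omega27 < 1`` is the singular-perturbation
parameter that separates fast (enzyme/complex) from slow (mark) dynamics.

Metabolic cofactors SAM and acetyl-CoA donate the methyl and acetyl groups;
their effective availabilities multiply ``k1`` and ``k7`` respectively.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "NUCLEOSOMES_PER_REGION",
    "BASES_PER_NUCLEOSOME",
    "region_span_bases",
    "ParameterError",
    "KineticParameters",
    "ScalingSettings",
    "CofactorSettings",
    "validate_parameters",
    "effective_cofactors",
    "apply_cofactors",
    "default_bistable",
]


class ParameterError(ValueError):
    """A kinetic parameter or scaling invariant is violated."""


#: geometry of one model region: ~5 nucleosomes of ~150 wrapped bases each,
#: i.e. one region spans about 750 bases of chromatin (the resolution at
#: which contact maps are read)
NUCLEOSOMES_PER_REGION = 5
BASES_PER_NUCLEOSOME = 150


def region_span_bases(n_nucleosomes: int = NUCLEOSOMES_PER_REGION) -> int:
    """Genomic span of one region in bases."""
    return n_nucleosomes * BASES_PER_NUCLEOSOME


_RATE_FIELDS = tuple(f"k{i}" for i in range(1, 13))
_ALPHA_FIELDS = ("alpha1", "alpha4", "alpha7", "alpha10")
_POOL_FIELDS = ("e0", "u0", "h0", "s0_enz")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and abundances of the chromatin-modification network.

    All quantities are expressed in rescaled (dimensionless) units: rates in
    the rescaled time convention, abundances divided by their system size
    (substrate totals by ``omega27``, enzyme totals by ``omega_e``).

    Attributes
    ----------
    k1..k12:
        Binding / unbinding / catalysis rate constants for the four enzyme
        cycles (EZH2, UTX, HAT, SIRT in groups of three).
    alpha1, alpha4, alpha7, alpha10:
        Basal (landscape-independent) binding activities.
    e0, u0, h0, s0_enz:
        Total rescaled abundances of EZH2, UTX, HAT and SIRT.  Pools are
        shared between all regions.
    s_sites:
        Rescaled total of modifiable H3K27 sites per region.
    B:
        Competition level: additive rate term representing SIRT sequestered
        away from chromatin (e.g. at DNA double-strand breaks).
    D_dsb, b_on, b_off:
        Microscopic realisation of the sequestration as a reversible
        capture/release reaction; only used by the exact stochastic
        simulator.  ``None`` means "derive from B" (see
        :func:`epitip.micro.build_reaction_network`).
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 1.0
    k5: float = 1.0
    k6: float = 1.0
    k7: float = 1.0
    k8: float = 1.0
    k9: float = 1.0
    k10: float = 1.0
    k11: float = 1.0
    k12: float = 1.0
    alpha1: float = 0.05
    alpha4: float = 0.05
    alpha7: float = 0.05
    alpha10: float = 0.05
    e0: float = 15.0
    u0: float = 15.0
    h0: float = 15.0
    s0_enz: float = 45.0
    s_sites: float = 1.0
    B: float = 0.0
    D_dsb: Optional[float] = None
    b_on: Optional[float] = None
    b_off: Optional[float] = None

    def replace(self, **changes: float) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ScalingSettings:
    """System sizes for substrate (``omega27``) and enzyme (``omega_e``) pools."""

    omega27: float = 1000.0
    omega_e: float = 50.0

    @property
    def epsilon(self) -> float:
        """Time-scale separation ratio ``omega_e / omega27``."""
        return self.omega_e / self.omega27


@dataclass
class CofactorSettings:
    """Metabolic cofactor abundances and affinities.

    ``A_T``/``S_T`` are the acetyl-CoA and SAM levels, ``K_A``/``K_S`` the
    corresponding affinity constants.  Infinite abundance recovers the base
    (cofactor-saturated) model.  ``a_hat``/``s_hat`` are the resolved
    effective cofactors in [0, 1]; they stay ``None`` until
    :func:`effective_cofactors` is called (or may be set directly to use the
    effective level itself as a control parameter).
    """

    K_A: float = 1.0
    K_S: float = 1.0
    A_T: float = math.inf
    S_T: float = math.inf
    a_hat: Optional[float] = None
    s_hat: Optional[float] = None


def validate_parameters(
    params: KineticParameters, scaling: ScalingSettings
) -> tuple[KineticParameters, ScalingSettings]:
    """Check all parameter invariants; return the bundle unchanged if valid.

    Raises
    ------
    ParameterError
        On the first violated invariant: a negative or non-finite rate,
        non-positive substrate total, or ``epsilon >= 1``.
    """
    for name in _RATE_FIELDS + _ALPHA_FIELDS + _POOL_FIELDS:
        value = getattr(params, name)
        if not math.isfinite(value):
            raise ParameterError(f"non-finite rate: {name} = {value}")
        if value < 0:
            raise ParameterError(f"negative rate: {name} = {value}")
    if not params.s_sites > 0:
        raise ParameterError(f"zero substrate: s_sites = {params.s_sites} must be > 0")
    if params.B < 0 or not math.isfinite(params.B):
        raise ParameterError(f"negative rate: B = {params.B}")
    for name in ("D_dsb", "b_on", "b_off"):
        value = getattr(params, name)
        if value is not None and (value < 0 or not math.isfinite(value)):
            raise ParameterError(f"negative rate: {name} = {value}")
    if not (scaling.omega27 > 0 and scaling.omega_e > 0):
        raise ParameterError("system sizes omega27 and omega_e must be > 0")
    if not scaling.epsilon < 1:
        raise ParameterError(
            f"epsilon must be < 1 (got omega_e/omega27 = {scaling.epsilon})"
        )
    return params, scaling


def effective_cofactors(
    cofactors: CofactorSettings, norm_l1: float, n_regions: int
) -> tuple[float, float]:
    """Resolve the effective cofactor levels ``(a_hat, s_hat)``.

    The effective acetyl-CoA level is the saturation fraction

        ``a_hat = K_A * A_T / (|u|_1/sqrt(N_C) + K_A * A_T)``

    and analogously for SAM.  Both lie in [0, 1], are monotone in the
    abundances, tend to 1 as the abundance grows without bound (recovering
    the base model) and vanish with the abundance.

    Parameters
    ----------
    norm_l1:
        The l1 norm of the dominant contact eigenvector, ``|u|_1 > 0``.
    n_regions:
        Number of chromatin regions ``N_C >= 1``.
    """
    if not norm_l1 > 0:
        raise ParameterError(f"norm_l1 must be > 0 (got {norm_l1})")
    if n_regions < 1:
        raise ParameterError(f"n_regions must be >= 1 (got {n_regions})")
    for name in ("K_A", "K_S", "A_T", "S_T"):
        if getattr(cofactors, name) < 0:
            raise ParameterError(f"negative cofactor setting: {name}")
    scale = norm_l1 / math.sqrt(n_regions)

    def _sat(k: float, tot: float) -> float:
        if math.isinf(tot):
            return 1.0
        ka = k * tot
        if ka == 0.0:
            return 0.0
        return ka / (scale + ka)

    a_hat = _sat(cofactors.K_A, cofactors.A_T)
    s_hat = _sat(cofactors.K_S, cofactors.S_T)
    cofactors.a_hat = a_hat
    cofactors.s_hat = s_hat
    return a_hat, s_hat


def apply_cofactors(
    params: KineticParameters, cofactors: CofactorSettings
) -> KineticParameters:
    """Return parameters with ``k1 -> k1*s_hat`` and ``k7 -> k7*a_hat``.

    SAM limitation throttles methyl addition (``k1``), acetyl-CoA limitation
    throttles acetyl addition (``k7``).  The input object is not modified.
    Requires resolved effective cofactors (call :func:`effective_cofactors`
    first, or set ``a_hat``/``s_hat`` explicitly).
    """
    if cofactors.a_hat is None or cofactors.s_hat is None:
        raise ParameterError(
            "unresolved effective cofactors: call effective_cofactors() first"
        )
    if not (0.0 <= cofactors.a_hat <= 1.0 and 0.0 <= cofactors.s_hat <= 1.0):
        raise ParameterError("effective cofactors must lie in [0, 1]")
    return params.replace(
        k1=params.k1 * cofactors.s_hat, k7=params.k7 * cofactors.a_hat
    )


def default_bistable(n_regions: int = 50) -> tuple[KineticParameters, ScalingSettings]:
    """The shipped reference kinetic regime (repository-calibrated).

    A symmetric enzyme-kinetics toggle with per-region pools of 0.3 for
    EZH2/UTX/HAT and 0.9 for SIRT, unit rate constants, basal activities
    0.05 and one modifiable-site unit per region.  With a uniform all-to-all
    contact matrix of total row weight 1 this regime is monostable
    (hypoacetylated) at B = 0 and develops a bistable window bounded by two
    saddle-node folds as the competition level B increases, losing the
    hypoacetylated state again at large B.  The default B = 10 sits inside
    the window.

    Abundances scale linearly with ``n_regions`` so that per-region enzyme
    densities stay fixed.  Note that the dynamics is not size-invariant:
    enzyme pools are shared, so the Michaelis–Menten saturation level — and
    with it the exact location of the bistable window — shifts with the
    number of competing regions (at 10 regions the window in B is roughly
    (0.7, 27.8); at 50 regions roughly (5.0, 31.3)).
    """
    per_region = {"e0": 0.3, "u0": 0.3, "h0": 0.3, "s0_enz": 0.9}
    params = KineticParameters(
        B=10.0, **{k: v * n_regions for k, v in per_region.items()}
    )
    return params, ScalingSettings(omega27=1000.0, omega_e=50.0)
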