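"""Ligand-binding thermodynamics for a two-site homodimeric sensor.

Two complementary parameterizations of dimer binding are provided:

* the independent "two sets of sites" model used to fit calorimetric
  titrations (:class:`TwoSetsParams`, with per-class stoichiometries,
  association constants and enthalpies), and
* the macroscopic sequential (binding-polynomial) model
  (:class:`SequentialParams`), which resolves the dimer into species with
  0, 1 or 2 ligands bound and is the natural frame for occupancy-linked
  activation questions.

Mapping fitted two-sets constants onto stepwise constants (β1 = 1/Kd of the
first binding event, β2 = β1 / Kd of the second) treats the fitted classes
as ordered binding events; this is an interpretive assumption, not a
property of the fit, and downstream reports flag it as such.

All energies are in calories to match the conventional calorimetry units
(R = 1.987 cal mol⁻¹ K⁻¹); concentrations are molar and association
constants M⁻¹ throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermoConstants",
    "TwoSetsParams",
    "ThermoDerived",
    "SequentialParams",
    "OccupancyState",
    "delta_S_from_K_dH",
    "kd_from_kass",
    "occupancy_two_sets",
    "occupancy_sequential",
    "free_ligand",
    "free_ligand_many",
    "cooperativity_index",
]


class DomainError(ValueError):
    """An argument is outside the physically meaningful domain."""


class ConvergenceError(RuntimeError):
    """A bounded iterative solve failed to reach tolerance."""


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant (cal mol⁻¹ K⁻¹) and absolute temperature (K).

    The default temperature corresponds to the 25 °C at which the
    titrations are equilibrated.
    """

    R: float = 1.987
    T: float = 298.15

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise DomainError(f"temperature must be positive, got {self.T}")


@dataclass(frozen=True)
class TwoSetsParams:
    """Parameters of the independent two-sets-of-sites binding model.

    ``n1``/``n2`` are sites per monomer of each class (≈0.5 each for one
    site of each class per dimer), ``K1``/``K2`` association constants in
    M⁻¹ and ``dH1``/``dH2`` molar binding enthalpies in cal mol⁻¹.
    """

    n1: float
    n2: float
    K1: float
    K2: float
    dH1: float
    dH2: float

    def __post_init__(self) -> None:
        if not (self.K1 > 0 and self.K2 > 0):
            raise DomainError("association constants must be positive")
        if self.n1 < 0 or self.n2 < 0:
            raise DomainError("site stoichiometries must be non-negative")

    def as_sequential(self) -> "SequentialParams":
        """Map fitted class constants to macroscopic stepwise constants.

        Class 1 is read as the first binding event and class 2 as the
        second: β1 = K1, β2 = K1·K2. Interpretive, see module docstring.
        """
        return SequentialParams(beta1=self.K1, beta2=self.K1 * self.K2)


@dataclass(frozen=True)
class ThermoDerived:
    """ΔG (cal/mol), ΔS (cal K⁻¹ mol⁻¹) and Kd (M) derived from K and ΔH."""

    dG: float
    dS: float
    Kd: float


@dataclass(frozen=True)
class SequentialParams:
    """Macroscopic stepwise constants of the dimer binding polynomial.

    ``beta1`` (M⁻¹) is the first stepwise association constant, ``beta2``
    (M⁻²) the product of the first and second. The binding polynomial is
    Q(L) = 1 + β1·L + β2·L².
    """

    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise DomainError("stepwise constants must be positive")

    @classmethod
    def from_stepwise_kds(cls, kd_first: float, kd_second: float) -> "SequentialParams":
        """Build from the dissociation constants of the two binding events (M)."""
        if not (kd_first > 0 and kd_second > 0):
            raise DomainError("dissociation constants must be positive")
        beta1 = 1.0 / kd_first
        return cls(beta1=beta1, beta2=beta1 / kd_second)

    @property
    def kd_first(self) -> float:
        return 1.0 / self.beta1

    @property
    def kd_second(self) -> float:
        return self.beta1 / self.beta2

    @property
    def kd_low_affinity(self) -> float:
        """The weaker (larger) of the two stepwise dissociation constants."""
        return max(self.kd_first, self.kd_second)


@dataclass(frozen=True)
class OccupancyState:
    """Fractions of dimers with 0/1/2 ligands bound and mean occupancy ν."""

    f0: float
    f1: float
    f2: float
    nu: float

    def __post_init__(self) -> None:
        if abs(self.f0 + self.f1 + self.f2 - 1.0) > 1e-10:
            raise DomainError("species fractions must sum to 1")
        for f in (self.f0, self.f1, self.f2):
            if not -1e-12 <= f <= 1.0 + 1e-12:
                raise DomainError("species fractions must lie in [0, 1]")


def delta_S_from_K_dH(K: float, dH: float, tc: ThermoConstants = ThermoConstants()) -> ThermoDerived:
    """ΔG = −RT ln K, ΔS = (ΔH − ΔG)/T and Kd = 1/K for one binding class."""
    if not K > 0:
        raise DomainError(f"association constant must be positive, got {K}")
    dG = -tc.R * tc.T * math.log(K)
    dS = (dH - dG) / tc.T
    return ThermoDerived(dG=dG, dS=dS, Kd=1.0 / K)


def kd_from_kass(K: float) -> float:
    """Dissociation constant (M) from an association constant (M⁻¹)."""
    if not K > 0:
        raise DomainError(f"association constant must be positive, got {K}")
    return 1.0 / K


def occupancy_two_sets(p: TwoSetsParams, L: float) -> tuple[float, float]:
    """Fractional saturation of each independent site class at free ligand L.

    θi = Ki·L / (1 + Ki·L).
    """
    if L < 0:
        raise DomainError(f"free ligand concentration must be non-negative, got {L}")
    theta1 = p.K1 * L / (1.0 + p.K1 * L)
    theta2 = p.K2 * L / (1.0 + p.K2 * L)
    return theta1, theta2


def occupancy_sequential(p: SequentialParams, L: float) -> OccupancyState:
    """Dimer species fractions from the binding polynomial at free ligand L.

    Q = 1 + β1·L + β2·L²; f1 = β1·L/Q, f2 = β2·L²/Q, ν = f1 + 2·f2.
    """
    if L < 0:
        raise DomainError(f"free ligand concentration must be non-negative, got {L}")
    q1 = p.beta1 * L
    q2 = p.beta2 * L * L
    Q = 1.0 + q1 + q2
    f1 = q1 / Q
    f2 = q2 / Q
    return OccupancyState(f0=1.0 / Q, f1=f1, f2=f2, nu=f1 + 2.0 * f2)


def _bound_per_monomer(p: TwoSetsParams, L: np.ndarray) -> np.ndarray:
    # moles ligand bound per mole monomer at free ligand L
    return p.n1 * p.K1 * L / (1.0 + p.K1 * L) + p.n2 * p.K2 * L / (1.0 + p.K2 * L)


def free_ligand_many(
    p: TwoSetsParams,
    Ptot: np.ndarray,
    Ltot: np.ndarray,
    max_iter: int = 200,
) -> np.ndarray:
    """Vectorized free-ligand solve; see :func:`free_ligand`."""
    Ptot = np.asarray(Ptot, dtype=float)
    Ltot = np.asarray(Ltot, dtype=float)
    if np.any(Ptot < 0) or np.any(Ltot < 0):
        raise DomainError("total concentrations must be non-negative")
    lo = np.zeros_like(Ltot)
    hi = Ltot.copy()
    # mass balance residual g(L) = L + Ptot·b(L) − Ltot is strictly increasing
    # in L, with g(0) ≤ 0 and g(Ltot) ≥ 0: plain bisection is safe.
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = mid + Ptot * _bound_per_monomer(p, mid) - Ltot
        hi = np.where(g >= 0.0, mid, hi)
        lo = np.where(g < 0.0, mid, lo)
        if np.all(hi - lo <= 1e-12 * np.maximum(hi, 1e-300)):
            break
    L = 0.5 * (lo + hi)
    resid = np.abs(L + Ptot * _bound_per_monomer(p, L) - Ltot)
    tol = 1e-10 * np.maximum(Ltot, 1e-12)
    if np.any(resid > tol):
        worst = int(np.argmax(resid - tol))
        raise ConvergenceError(
            "free-ligand mass balance did not converge: "
            f"residual {resid.flat[worst]:.3e} > tol {tol.flat[worst]:.3e} "
            f"at Ptot={Ptot.flat[worst]:.3e} M, Ltot={Ltot.flat[worst]:.3e} M"
        )
    return L


def free_ligand(p: TwoSetsParams, Ptot: float, Ltot: float) -> float:
    """Free ligand concentration solving Ltot = L + Ptot·(n1θ1(L) + n2θ2(L)).

    Bracketed bisection on [0, Ltot] (the mass-balance residual is strictly
    monotone, so the root is unique). Raises :class:`ConvergenceError` with
    diagnostics if the residual tolerance is not met.
    """
    if Ltot == 0.0:
        return 0.0
    return float(free_ligand_many(p, np.asarray([Ptot]), np.asarray([Ltot]))[0])


def cooperativity_index(kd_high: float, kd_low: float, band: float = 0.1) -> tuple[float, str]:
    """Cooperativity index c = 4·K2a/K1a for two sequential binding events.

    ``kd_high`` is the dissociation constant of the first event in titration
    order and ``kd_low`` that of the second (names reflect the affinity of
    the archetypal negatively cooperative case; either ordering is valid).
    For two identical independent sites the statistical factors alone give
    c = 1; c < 1 indicates negative and c > 1 positive cooperativity. Values
    within ``band`` (default ±10%) of 1 are labelled non-cooperative,
    reflecting fitted-constant uncertainty.
    """
    if not (kd_high > 0 and kd_low > 0):
        raise DomainError("dissociation constants must be positive")
    c = 4.0 * (1.0 / kd_low) / (1.0 / kd_high)
    if c < 1.0 - band:
        label = "negative"
    elif c > 1.0 + band:
        label = "positive"
    else:
        label = "non-cooperative"
    return c, label
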