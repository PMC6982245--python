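"""Ogden hyperelastic material model for ocular tissue.

Corneal and scleral stroma behave as nearly incompressible, strongly
strain-stiffening solids: the stress-strain path is S-shaped, with very low
stiffness near the unloaded state and a steep rise within a few percent
strain.  A first-order Ogden strain-energy function with a large exponent
(alpha ~ 100) captures this behaviour and is the standard choice for ocular
tissue in the inflation/tonometry literature.

The strain energy density (per unit reference volume) is

    W = sum_i 2 mu_i / alpha_i^2 * (l1^a_i + l2^a_i + l3^a_i - 3)
      + sum_i 1 / D_i * (J_el - 1)^(2 i)

with deviatoric principal stretches l1 l2 l3 = 1, elastic volume ratio
J_el, shear-like moduli mu_i (MPa), exponents alpha_i, and compressibility
coefficients D_i (MPa^-1); D_i = 0 means fully incompressible and the
volumetric term is omitted.  The initial shear modulus is sum(mu_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OgdenMaterial",
    "KinematicState",
    "RegionalMaterialMap",
    "REGIONS",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "membrane_stress_and_tangent",
    "default_regional_map",
]

#: The five material regions of the eye model, ordered from anterior pole.
REGIONS = (
    "cornea",
    "limbus",
    "anterior_sclera",
    "equatorial_sclera",
    "posterior_sclera",
)

# Default regional stiffness multipliers relative to the corneal mu.  The
# limbus is slightly softer than the cornea; the sclera stiffens toward the
# posterior pole.
REGION_MU_FACTORS = {
    "cornea": 1.0,
    "limbus": 0.8,
    "anterior_sclera": 3.0,
    "equatorial_sclera": 3.5,
    "posterior_sclera": 4.0,
}

#: Default Ogden exponent: produces the steep S-shaped stiffening of
#: corneal stroma within the strain range of the air-puff test.
DEFAULT_ALPHA = 110.0

#: Soft-tissue density, kg/m^3.
DEFAULT_RHO_TISSUE = 1062.0


@dataclass(frozen=True)
class OgdenMaterial:
    """First-to-sixth order Ogden material.

    Parameters
    ----------
    mu : tuple of float
        Moduli mu_i in MPa.  ``sum(mu)`` is the initial shear modulus.
    alpha : tuple of float
        Dimensionless exponents alpha_i (non-zero).
    D : tuple of float
        Compressibility coefficients in MPa^-1; 0 = incompressible.
    rho_tissue : float
        Density in kg/m^3 (used for inertia in dynamic analyses).
    """

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    D: tuple[float, ...] = ()
    rho_tissue: float = DEFAULT_RHO_TISSUE

    def __post_init__(self) -> None:
        mu = tuple(float(m) for m in self.mu)
        alpha = tuple(float(a) for a in self.alpha)
        D = tuple(float(d) for d in self.D) if self.D else (0.0,) * len(mu)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "D", D)
        n = len(mu)
        if not 1 <= n <= 6:
            raise ValueError(f"Ogden order must be 1..6, got N={n}")
        if len(alpha) != n or len(D) != n:
            raise ValueError("mu, alpha and D must have equal length")
        if any(a == 0.0 for a in alpha):
            raise ValueError("Ogden exponents alpha_i must be non-zero")
        if any(d < 0.0 for d in D):
            raise ValueError("compressibility coefficients D_i must be >= 0")
        if sum(mu) <= 0.0:
            raise ValueError("initial shear modulus sum(mu_i) must be > 0")

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def shear_modulus(self) -> float:
        """Initial (small-strain) shear modulus, MPa."""
        return float(sum(self.mu))

    def scaled(self, factor: float) -> "OgdenMaterial":
        """Same material with all mu_i multiplied by ``factor``."""
        return OgdenMaterial(
            mu=tuple(factor * m for m in self.mu),
            alpha=self.alpha,
            D=self.D,
            rho_tissue=self.rho_tissue,
        )


@dataclass(frozen=True)
class KinematicState:
    """Deviatoric principal stretches plus elastic volume ratio."""

    lam_bar: tuple[float, float, float]
    J_el: float = 1.0

    def __post_init__(self) -> None:
        l1, l2, l3 = self.lam_bar
        if min(l1, l2, l3) <= 0.0 or self.J_el <= 0.0:
            raise ValueError("stretches and J_el must be positive")
        if abs(l1 * l2 * l3 - 1.0) > 1e-10:
            raise ValueError("deviatoric stretches must satisfy l1*l2*l3 = 1")


def strain_energy(mat: OgdenMaterial, kin: KinematicState) -> float:
    """Strain energy density W (MPa) at the given kinematic state."""
    l1, l2, l3 = kin.lam_bar
    w = 0.0
    for i, (m, a, d) in enumerate(zip(mat.mu, mat.alpha, mat.D), start=1):
        w += 2.0 * m / a**2 * (l1**a + l2**a + l3**a - 3.0)
        if d > 0.0:
            w += (kin.J_el - 1.0) ** (2 * i) / d
    return float(w)


def uniaxial_cauchy_stress(mat: OgdenMaterial, lam) -> float | np.ndarray:
    """Uniaxial Cauchy stress (MPa) for the incompressible Ogden solid.

    sigma = sum_i 2 mu_i / alpha_i * (lam^a_i - lam^(-a_i/2)),
    the closed-form derivative of the Ogden energy along a uniaxial,
    volume-preserving stretch lam with the hydrostatic term eliminated by
    the traction-free lateral faces.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    s = np.zeros_like(lam)
    for m, a in zip(mat.mu, mat.alpha):
        s = s + 2.0 * m / a * (lam**a - lam ** (-a / 2.0))
    return float(s) if s.ndim == 0 else s


def _plane_stress_sigma(mat: OgdenMaterial, l1, l2):
    """Principal Cauchy stresses for an incompressible membrane.

    Plane stress with l3 = 1/(l1 l2):  sigma_k = sum 2 mu/a (lk^a - (l1 l2)^-a).
    """
    s1 = np.zeros_like(l1)
    s2 = np.zeros_like(l2)
    for m, a in zip(mat.mu, mat.alpha):
        l3a = (l1 * l2) ** (-a)
        s1 = s1 + 2.0 * m / a * (l1**a - l3a)
        s2 = s2 + 2.0 * m / a * (l2**a - l3a)
    return s1, s2


def membrane_stress_and_tangent(
    mat: OgdenMaterial, lam1: float, lam2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Principal membrane Cauchy stresses (MPa) and 2x2 tangent d(sigma)/d(lam).

    Incompressible plane-stress specialisation: the through-thickness stretch
    is 1/(lam1*lam2) and the normal stress vanishes.
    """
    if lam1 <= 0.0 or lam2 <= 0.0:
        raise ValueError("in-plane stretches must be positive")
    l1 = np.asarray(lam1, dtype=float)
    l2 = np.asarray(lam2, dtype=float)
    s1, s2 = _plane_stress_sigma(mat, l1, l2)
    # analytic tangent
    d11 = d12 = d21 = d22 = 0.0
    for m, a in zip(mat.mu, mat.alpha):
        c = 2.0 * m / a
        l3a = (l1 * l2) ** (-a)
        d11 += c * (a * l1 ** (a - 1.0) + a * l3a / l1)
        d12 += c * (a * l3a / l2)
        d21 += c * (a * l3a / l1)
        d22 += c * (a * l2 ** (a - 1.0) + a * l3a / l2)
    sig = np.array([float(s1), float(s2)])
    tan = np.array([[float(d11), float(d12)], [float(d21), float(d22)]])
    return sig, tan


@dataclass(frozen=True)
class RegionalMaterialMap:
    """Ogden material per anatomical region; all five regions required."""

    materials: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.materials]
        if missing:
            raise ValueError(f"missing material regions: {missing}")

    def __getitem__(self, region: str) -> OgdenMaterial:
        return self.materials[region]


def default_regional_map(
    mu_cornea: float = 0.0712,
    alpha: float = DEFAULT_ALPHA,
    factors: dict | None = None,
) -> RegionalMaterialMap:
    """Regional material map from a single corneal stiffness coefficient.

    ``mu_cornea`` is the first-order Ogden modulus of the cornea (MPa); the
    other regions are scaled copies using fixed multipliers (limbus softer,
    sclera progressively stiffer toward the posterior pole).
    """
    f = dict(REGION_MU_FACTORS)
    if factors:
        f.update(factors)
    mats = {
        r: OgdenMaterial(mu=(mu_cornea * f[r],), alpha=(alpha,), D=(0.0,))
        for r in REGIONS
    }
    return RegionalMaterialMap(materials=mats)
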