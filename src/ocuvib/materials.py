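"""Material models: linear-elastic solids with Prony-series viscoelasticity, acoustic fluids.

The solid tissue is isotropic and nearly incompressible (Poisson ratio 0.499).
Time dependence is carried by a Prony relaxation series; in the frequency
domain this turns the Young's modulus into a complex, frequency-dependent
quantity whose imaginary part encodes viscoelastic damping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaterialSpec", "FluidSpec", "complex_modulus"]


class ConfigurationError(ValueError):
    """Raised when a material or model specification violates its invariants."""


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic viscoelastic solid.

    Parameters
    ----------
    E : float
        Instantaneous (high-frequency) Young's modulus in Pa.  The relaxed
        long-term modulus is ``E * (1 - sum(p_i))``.
    nu : float
        Poisson ratio, in (0, 0.5).  Ocular tissue is close to incompressible.
    rho : float
        Mass density in kg/m^3.
    prony : tuple of (p_i, T_i)
        Prony terms: relative modulus p_i (dimensionless) and relaxation time
        T_i in seconds.  An empty tuple gives a purely elastic material.
    """

    E: float
    nu: float
    rho: float
    prony: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ConfigurationError(f"Young's modulus must be positive, got {self.E}")
        if not 0.0 < self.nu < 0.5:
            raise ConfigurationError(f"Poisson ratio must lie in (0, 0.5), got {self.nu}")
        if not self.rho > 0:
            raise ConfigurationError(f"density must be positive, got {self.rho}")
        psum = sum(p for p, _ in self.prony)
        if psum >= 1.0:
            raise ConfigurationError(f"sum of Prony relative moduli must be < 1, got {psum}")
        if any(p < 0 for p, _ in self.prony):
            raise ConfigurationError("Prony relative moduli must be non-negative")
        if any(T <= 0 for _, T in self.prony):
            raise ConfigurationError("Prony relaxation times must be positive")

    @property
    def relaxed_fraction(self) -> float:
        """Long-term modulus as a fraction of the instantaneous one."""
        return 1.0 - sum(p for p, _ in self.prony)

    def lame(self, E: complex | float | None = None) -> tuple[complex, complex]:
        """Lame parameters (lambda, mu) for a given (possibly complex) modulus."""
        e = self.E if E is None else E
        lam = e * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = e / (2.0 * (1.0 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class FluidSpec:
    """Acoustic fluid (aqueous/vitreous humour, modelled as water).

    ``mu`` (dynamic viscosity) is carried as metadata only: the acoustic
    element model is lossless.  ``fsi_range`` is the distance from solid
    tissue within which fluid-structure coupling is active.
    """

    rho: float = 1000.0
    c: float = 1480.0
    mu: float = 8.94e-4
    fsi_range: float = 2.8e-3

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ConfigurationError(f"fluid density must be positive, got {self.rho}")
        if not self.c > 0:
            raise ConfigurationError(f"sonic velocity must be positive, got {self.c}")
        if self.fsi_range < 0:
            raise ConfigurationError("fsi_range must be non-negative")


def complex_modulus(mat: MaterialSpec, f: float) -> complex:
    """Complex Young's modulus E*(f) of a Prony-series viscoelastic solid.

    E*(f) = E * (1 - sum_i p_i / (1 + i * Omega * T_i)),  Omega = 2*pi*f.

    Limits: E*(0) = E * (1 - sum p_i) (relaxed, purely real) and
    E*(inf) -> E (instantaneous, loss part -> 0).  The imaginary part is
    non-negative (dissipative) and |E*| is non-decreasing in f.
    """
    if f < 0:
        raise ValueError(f"frequency must be non-negative, got {f}")
    omega = 2.0 * np.pi * f
    acc = 0.0 + 0.0j
    for p, T in mat.prony:
        acc += p / (1.0 + 1j * omega * T)
    return mat.E * (1.0 - acc)
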