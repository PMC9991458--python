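"""Coarse-grained tropomyosin chain mechanics.

Each half tropomyosin molecule is modeled as a flexible cable of torsional
springs in series, one per residue, whose stiffnesses come from the MD
per-residue angular fluctuations by equipartition (kappa_i = RT / <delta_i^2>).
Holding one end fixed and displacing the other azimuthally by theta, the chain
relaxes its internal node angles to the minimum-energy configuration; the
resulting energy-vs-theta curve over the 0-35 degree sweep is quadratic and a
least-squares fit of E = (1/2) gamma theta^2 through the origin defines the
global effective chain stiffness gamma.

For springs in series the exact minimum is the series-compliance form
E = (1/2) (sum_i 1/kappa_i)^(-1) theta^2; the implementation nevertheless
solves the full linear system so that the closed form can serve as an
independent oracle.

Units: kappa and gamma in kJ/mol/rad^2; theta grids in degrees (the sweep
convention of the azimuthal scan); energies in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .synthetic_md import FlexibilityProfile

__all__ = [
    "R_GAS",
    "TorsionalChain",
    "ChainEnergyCurve",
    "ChainStiffnessFit",
    "stiffness_from_flexibility",
    "chain_energy_curve",
    "fit_effective_stiffness",
    "series_stiffness",
    "series_stiffness_from_profile",
]

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314462618e-3

#: Azimuthal sweep limits, degrees.
THETA_MIN, THETA_MAX = 0.0, 35.0

DEG2_PER_RAD2 = np.degrees(1.0) ** 2


@dataclass(frozen=True)
class TorsionalChain:
    """Series of torsional springs (kappa in kJ/mol/rad^2, one per residue)."""

    kappa: np.ndarray
    temperature: float = 300.0

    def __post_init__(self):
        kappa = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "kappa", kappa)
        if kappa.ndim != 1 or len(kappa) < 2:
            raise ValueError("chain needs at least 2 springs")
        if not np.all(np.isfinite(kappa)) or np.any(kappa <= 0):
            raise ValueError("all kappa must be positive and finite")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    def __len__(self) -> int:
        return len(self.kappa)


@dataclass(frozen=True)
class ChainEnergyCurve:
    """Minimized chain energy (kJ/mol) over an azimuthal displacement grid (deg)."""

    theta_deg: np.ndarray
    energy: np.ndarray

    def __post_init__(self):
        theta = np.asarray(self.theta_deg, dtype=float)
        energy = np.asarray(self.energy, dtype=float)
        object.__setattr__(self, "theta_deg", theta)
        object.__setattr__(self, "energy", energy)
        if theta.shape != energy.shape or theta.ndim != 1:
            raise ValueError("theta and energy must be matching 1-D arrays")
        if not np.all(np.isfinite(energy)):
            raise ValueError("energies must be finite")


@dataclass(frozen=True)
class ChainStiffnessFit:
    """Effective stiffness gamma (kJ/mol/rad^2) and fit residual (sum of squares)."""

    gamma: float
    residual: float

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    @property
    def gamma_per_deg2(self) -> float:
        """Same stiffness expressed in kJ/mol/deg^2."""
        return self.gamma / DEG2_PER_RAD2


def stiffness_from_flexibility(
    profile: FlexibilityProfile, temperature: float = 300.0
) -> TorsionalChain:
    """Equipartition map: kappa_i = R*T / <delta_i^2> with delta in radians.

    A larger local fluctuation means a softer local spring; the map is
    monotone decreasing in delta and preserves the relative MD profile.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    delta_rad = np.radians(profile.delta)
    if np.any(delta_rad == 0):
        raise ValueError("delta contains zeros (infinite stiffness)")
    kappa = R_GAS * temperature / delta_rad**2
    return TorsionalChain(kappa=kappa, temperature=temperature)


def chain_energy_curve(chain: TorsionalChain, theta_grid_deg) -> ChainEnergyCurve:
    """Minimum chain energy at each end displacement on a [0, 35] degree grid.

    Minimizes sum_i (1/2) kappa_i (phi_i - phi_{i-1})^2 over the internal node
    angles with phi_0 = 0 and phi_N = theta, via the (tridiagonal,
    positive-definite) stationarity system.
    """
    theta = np.asarray(theta_grid_deg, dtype=float)
    if theta.ndim != 1 or len(theta) < 1:
        raise ValueError("theta grid must be a non-empty 1-D array")
    if theta[0] != 0.0:
        raise ValueError("theta grid must start at 0")
    if np.any(np.diff(theta) <= 0):
        raise ValueError("theta grid must be strictly ascending")
    if theta[-1] > THETA_MAX or theta[0] < THETA_MIN:
        raise ValueError(f"theta grid must lie within [{THETA_MIN}, {THETA_MAX}] degrees")

    kappa = chain.kappa
    n = len(kappa)  # number of springs; internal nodes 1..n-1
    energies = np.empty_like(theta)
    theta_rad = np.radians(theta)

    if n == 1:  # pragma: no cover - excluded by the >=2 invariant
        energies = 0.5 * kappa[0] * theta_rad**2
        return ChainEnergyCurve(theta_deg=theta, energy=energies)

    # Stationarity: kappa_i (phi_i - phi_{i-1}) = kappa_{i+1} (phi_{i+1} - phi_i)
    # -> symmetric tridiagonal system A phi_int = b(theta); b is linear in theta
    # so solve once for a unit end displacement.
    diag = kappa[:-1] + kappa[1:]
    b = np.zeros(n - 1)
    b[-1] = kappa[-1]  # times theta
    if n == 2:
        phi_unit = b / diag  # single internal node
    else:
        ab = np.zeros((2, n - 1))
        ab[0, 1:] = -kappa[1:-1]
        ab[1, :] = diag
        phi_unit = solveh_banded(ab, b)  # internal angles for theta = 1 rad

    for j, th in enumerate(theta_rad):
        phi = np.concatenate(([0.0], phi_unit * th, [th]))
        energies[j] = 0.5 * np.sum(kappa * np.diff(phi) ** 2)
    return ChainEnergyCurve(theta_deg=theta, energy=energies)


def fit_effective_stiffness(curve: ChainEnergyCurve) -> ChainStiffnessFit:
    """Least-squares fit of E = (1/2) gamma theta^2 through the origin."""
    if len(curve.theta_deg) < 3:
        raise ValueError("curve needs at least 3 points")
    if np.allclose(curve.energy, 0.0):
        raise ValueError("all energies are zero; gamma is undefined")
    x = 0.5 * np.radians(curve.theta_deg) ** 2
    y = curve.energy
    gamma = float(np.dot(x, y) / np.dot(x, x))
    residual = float(np.sum((y - gamma * x) ** 2))
    return ChainStiffnessFit(gamma=gamma, residual=residual)


def series_stiffness(kappa) -> float:
    """Series-compliance closed form (sum_i 1/kappa_i)^-1, kJ/mol/rad^2."""
    kappa = np.asarray(kappa, dtype=float)
    return float(1.0 / np.sum(1.0 / kappa))


def series_stiffness_from_profile(
    profile: FlexibilityProfile, temperature: float = 300.0
) -> float:
    """Closed-form effective stiffness of a flexibility profile's chain."""
    return series_stiffness(stiffness_from_flexibility(profile, temperature).kappa)
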