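"""Synthetic stand-ins for molecular-dynamics outputs.

The downstream pipeline consumes two kinds of MD-derived data: per-residue
angular flexibility profiles of the tropomyosin superhelical backbone (the
delta angle, in degrees) and ensembles of actin-tropomyosin interaction-energy
frames for the blocked (B) and closed (C) regulatory states.  This module
generates both synthetically so that every later stage is testable without an
MD engine: a flexibility profile is a positive baseline plus an optional
localized Gaussian-shaped bump (emulating a point mutation's local
destabilization of the coiled coil) plus i.i.d. Gaussian noise, and an energy
ensemble is Gaussian frames with a prescribed mean and standard deviation.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FlexibilityProfile",
    "EnergyFrameEnsemble",
    "Perturbation",
    "generate_flexibility_profile",
    "sample_energy_frames",
    "baseline_delta_for_stiffness",
    "calibrate_bump_amplitude",
    "write_flexibility_profile",
    "read_flexibility_profile",
    "write_energy_frames",
    "read_energy_frames",
]

#: Default number of residues in one modeled half tropomyosin molecule
#: (284 residues in the full molecule, halved).
DEFAULT_SPAN = 142

#: Residue index (within the half-molecule span) at which the mutant
#: perturbation is centered: the C-terminal half spans residues 143-284 of
#: the full molecule, so S215 sits 215 - 142 = 73 residues into that half.
DEFAULT_BUMP_CENTER = 73

#: Width (Gaussian sigma, residues) of the localized mutant perturbation.
DEFAULT_BUMP_WIDTH = 5.0


@dataclass(frozen=True)
class Perturbation:
    """Localized Gaussian bump in a flexibility profile.

    center : residue index (in profile coordinates) of the bump peak
    width : Gaussian sigma in residues
    amplitude : peak height added to the baseline, degrees (may be negative
        but must exceed ``-baseline``)
    """

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-residue angular fluctuation (delta, degrees) of one half-molecule."""

    genotype: str
    residues: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        residues = np.asarray(self.residues, dtype=int)
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "residues", residues)
        object.__setattr__(self, "delta", delta)
        if residues.ndim != 1 or delta.shape != residues.shape:
            raise ValueError("residues and delta must be matching 1-D arrays")
        if len(residues) < 2:
            raise ValueError("a profile needs at least 2 residues")
        if not np.all(np.diff(residues) == 1):
            raise ValueError("residue indices must be strictly increasing and contiguous")
        if not np.all(np.isfinite(delta)) or np.any(delta <= 0):
            raise ValueError("all delta values must be positive and finite")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EnergyFrameEnsemble:
    """Per-frame interaction energies (kcal/mol) for one genotype/state."""

    genotype: str
    state: str
    values: np.ndarray
    n_frames: int = field(default=0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_frames", len(values))
        if self.state not in ("B", "C"):
            raise ValueError(f"state must be 'B' or 'C', got {self.state!r}")
        if len(values) < 2:
            raise ValueError("n_frames must be >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("all frame energies must be finite")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator)."""
        return float(np.std(self.values, ddof=1))


def generate_flexibility_profile(
    baseline_delta: float,
    span: int = DEFAULT_SPAN,
    perturbation: Perturbation | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    genotype: str = "synthetic",
    start_residue: int = 1,
) -> FlexibilityProfile:
    """Baseline + localized Gaussian bump + i.i.d. noise, truncated positive.

    Parameters
    ----------
    baseline_delta : flat flexibility level, degrees (> 0)
    span : number of residues in the half-molecule (>= 2)
    perturbation : optional localized bump; its amplitude must exceed
        ``-baseline_delta``
    noise_sd : per-residue i.i.d. Gaussian noise SD, degrees
    seed : RNG seed; identical seeds give bit-identical profiles
    """
    if not np.isfinite(baseline_delta) or baseline_delta <= 0:
        raise ValueError(f"baseline_delta must be positive, got {baseline_delta}")
    if span < 2:
        raise ValueError(f"span must be >= 2, got {span}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if perturbation is not None and perturbation.amplitude <= -baseline_delta:
        raise ValueError(
            f"perturbation amplitude must exceed -baseline_delta "
            f"({perturbation.amplitude} <= {-baseline_delta})"
        )

    residues = np.arange(start_residue, start_residue + span)
    delta = np.full(span, float(baseline_delta))
    if perturbation is not None and perturbation.amplitude != 0.0:
        x = residues - (start_residue - 1 + perturbation.center)
        delta += perturbation.amplitude * np.exp(-0.5 * (x / perturbation.width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        delta += rng.normal(0.0, noise_sd, size=span)
    # keep strictly positive (infinite stiffness is rejected downstream)
    delta = np.maximum(delta, 1e-3 * baseline_delta)
    return FlexibilityProfile(genotype=genotype, residues=residues, delta=delta)


def sample_energy_frames(
    mean: float,
    sd: float,
    n_frames: int = 500,
    seed: int | None = None,
    genotype: str = "synthetic",
    state: str = "C",
) -> EnergyFrameEnsemble:
    """Gaussian i.i.d. interaction-energy frames with given mean/SD (kcal/mol)."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    rng = np.random.default_rng(seed)
    values = mean + sd * rng.standard_normal(n_frames)
    return EnergyFrameEnsemble(genotype=genotype, state=state, values=values)


# ---------------------------------------------------------------------------
# Calibration helpers linking the generator to the chain-stiffness target
# ---------------------------------------------------------------------------

def baseline_delta_for_stiffness(
    gamma: float, span: int = DEFAULT_SPAN, temperature: float = 300.0
) -> float:
    """Uniform delta (degrees) whose chain fits exactly to stiffness ``gamma``.

    For a uniform profile the effective series stiffness is RT/(span * <d^2>)
    with delta in radians, so the baseline follows in closed form.  ``gamma``
    is in kJ/mol/rad^2.
    """
    from .chain_mechanics import R_GAS

    if gamma <= 0 or span < 2 or temperature <= 0:
        raise ValueError("gamma, span and temperature must be positive (span >= 2)")
    delta_rad = np.sqrt(R_GAS * temperature / (span * gamma))
    return float(np.degrees(delta_rad))


def calibrate_bump_amplitude(
    target_gamma: float,
    baseline_delta: float,
    span: int = DEFAULT_SPAN,
    center: float = DEFAULT_BUMP_CENTER,
    width: float = DEFAULT_BUMP_WIDTH,
    temperature: float = 300.0,
) -> float:
    """Bump amplitude (degrees) so the perturbed profile fits ``target_gamma``.

    The mutant flexibility increase is not printed in any source; only its
    downstream effect on the effective chain stiffness is constrained.  This
    solves (by bisection on the noise-free profile) for the Gaussian bump
    amplitude whose series-compliance stiffness equals the target.
    """
    from scipy.optimize import brentq

    from .chain_mechanics import series_stiffness_from_profile

    def f(amplitude: float) -> float:
        prof = generate_flexibility_profile(
            baseline_delta,
            span=span,
            perturbation=Perturbation(center, width, amplitude),
        )
        return series_stiffness_from_profile(prof, temperature) - target_gamma

    base = series_stiffness_from_profile(
        generate_flexibility_profile(baseline_delta, span=span), temperature
    )
    if target_gamma >= base:
        if abs(target_gamma - base) / base < 1e-12:
            return 0.0
        raise ValueError(
            "target_gamma must be below the unperturbed stiffness "
            f"({target_gamma} >= {base:.4g}); a positive bump only softens the chain"
        )
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("calibration bracket not found")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def write_flexibility_profile(profile: FlexibilityProfile, path: str | Path) -> None:
    """Two-column text (residue, delta_degrees) with a metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# genotype={profile.genotype} units=degrees\n")
        fh.write("# residue\tdelta_degrees\n")
        for r, d in zip(profile.residues, profile.delta):
            fh.write(f"{r}\t{d:.10g}\n")


def read_flexibility_profile(path: str | Path) -> FlexibilityProfile:
    path = Path(path)
    genotype = "unknown"
    residues, delta = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("genotype="):
                    genotype = tok.split("=", 1)[1]
            continue
        r, d = line.split()
        residues.append(int(r))
        delta.append(float(d))
    return FlexibilityProfile(genotype=genotype, residues=np.array(residues), delta=np.array(delta))


def write_energy_frames(ensemble: EnergyFrameEnsemble, path: str | Path) -> None:
    """One energy per line, plus a JSON sidecar ``<path>.json`` with metadata."""
    path = Path(path)
    np.savetxt(path, ensemble.values, fmt="%.10g")
    sidecar = {
        "genotype": ensemble.genotype,
        "state": ensemble.state,
        "n_frames": int(ensemble.n_frames),
        "units": "kcal/mol",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_energy_frames(path: str | Path) -> EnergyFrameEnsemble:
    path = Path(path)
    values = np.loadtxt(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EnergyFrameEnsemble(genotype=meta["genotype"], state=meta["state"], values=values)
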