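"""Blocked/closed-state interaction energetics and the K_BC mapping.

The MD stage yields actin-tropomyosin(+troponin I) interaction energies for
the blocked (B) and closed (C) tropomyosin positions.  The B-to-C energy
difference is reported as mean_C - mean_B, i.e. the energetic cost of leaving
the blocked state, which is positive when B is the more favorable state (the
raw Table-style means are large negative numbers, so sign conventions matter
and are fixed here once).

The mutant blocked-closed equilibrium constant follows from the Gibbs
relation: K_BC,WT = exp(-dG_WT/RT) defines dG_WT from the calibrated WT
constant; the mutant free energy is scaled proportionally by the ratio of the
mutant to WT interaction-energy differences, and inverting the relation gives
K_BC,mutant = K_BC,WT ** (dE_mut/dE_wt).  The temperature cancels
algebraically in that power form, which the EquilibriumMapping invariant
asserts numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_md import EnergyFrameEnsemble

__all__ = [
    "R_KCAL",
    "KBC_WT",
    "MD_REFERENCE_ENERGIES",
    "InteractionEnergySummary",
    "EquilibriumMapping",
    "summarize_frames",
    "bc_energy_difference",
    "map_kbc",
    "read_energy_table",
    "write_energy_table",
]

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987204259e-3

#: Calibrated WT blocked-closed equilibrium constant (model input, not computed).
KBC_WT = 0.76

#: Published MD interaction-energy summaries, kcal/mol over 500 frames:
#: (genotype, state) -> (mean, sd).  B-state entries include the
#: tropomyosin-troponin I contribution; C-state entries are tropomyosin-actin.
MD_REFERENCE_ENERGIES = {
    ("WT", "B"): (-5108.7, 280.9),
    ("WT", "C"): (-3895.4, 236.9),
    ("S215L", "B"): (-4581.3, 232.9),
    ("S215L", "C"): (-4426.2, 206.2),
}

MD_REFERENCE_N_FRAMES = 500


@dataclass(frozen=True)
class InteractionEnergySummary:
    genotype: str
    state: str
    mean: float
    sd: float
    n_frames: int

    def __post_init__(self):
        if self.state not in ("B", "C"):
            raise ValueError(f"state must be 'B' or 'C', got {self.state!r}")
        if not np.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class EquilibriumMapping:
    """Gibbs-relation mapping from energy differences to a mutant K_BC."""

    kbc_ref: float
    delta_e_wt: float
    delta_e_mut: float
    scale: float
    delta_g_wt: float
    delta_g_mut: float
    temperature: float
    kbc_mut: float

    def __post_init__(self):
        if self.kbc_mut <= 0:
            raise ValueError("kbc_mut must be positive")
        # temperature cancels: kbc_mut must equal kbc_ref ** scale
        if not np.isclose(self.kbc_mut, self.kbc_ref**self.scale, rtol=1e-10):
            raise ValueError("inconsistent mapping: kbc_mut != kbc_ref ** scale")

    @property
    def percent_change(self) -> float:
        """Percent decrease in the magnitude of the B-C energy difference."""
        return 100.0 * (1.0 - self.scale)


def summarize_frames(ensemble: EnergyFrameEnsemble) -> InteractionEnergySummary:
    """Arithmetic mean and sample SD (n-1 denominator) of the frame energies."""
    return InteractionEnergySummary(
        genotype=ensemble.genotype,
        state=ensemble.state,
        mean=ensemble.mean,
        sd=ensemble.sd,
        n_frames=ensemble.n_frames,
    )


def bc_energy_difference(
    summary_b: InteractionEnergySummary, summary_c: InteractionEnergySummary
) -> float:
    """mean_C - mean_B (kcal/mol): the energetic cost of leaving the B state."""
    if summary_b.genotype != summary_c.genotype:
        raise ValueError(
            f"genotype mismatch: {summary_b.genotype!r} vs {summary_c.genotype!r}"
        )
    if summary_b.state != "B" or summary_c.state != "C":
        raise ValueError("arguments must be the B-state and C-state summaries, in order")
    return summary_c.mean - summary_b.mean


def map_kbc(
    kbc_ref: float,
    delta_e_wt: float,
    delta_e_mut: float,
    temperature: float = 300.0,
) -> EquilibriumMapping:
    """Scale the WT Gibbs free energy by the energy-difference ratio.

    dG_WT = -RT ln(K_BC,WT); dG_mut = (dE_mut/dE_wt) dG_WT;
    K_BC,mut = exp(-dG_mut/RT) = K_BC,WT ** (dE_mut/dE_wt).
    """
    if kbc_ref <= 0:
        raise ValueError(f"kbc_ref must be positive, got {kbc_ref}")
    if delta_e_wt == 0:
        raise ValueError("delta_e_wt is zero; the proportional scale is undefined")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    rt = R_KCAL * temperature
    delta_g_wt = -rt * np.log(kbc_ref)
    scale = delta_e_mut / delta_e_wt
    delta_g_mut = scale * delta_g_wt
    kbc_mut = float(np.exp(-delta_g_mut / rt))
    return EquilibriumMapping(
        kbc_ref=kbc_ref,
        delta_e_wt=delta_e_wt,
        delta_e_mut=delta_e_mut,
        scale=scale,
        delta_g_wt=float(delta_g_wt),
        delta_g_mut=float(delta_g_mut),
        temperature=temperature,
        kbc_mut=kbc_mut,
    )


# ---------------------------------------------------------------------------
# Tabular I/O (genotype, state, mean, sd, n_frames)
# ---------------------------------------------------------------------------

def write_energy_table(summaries, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "genotype": s.genotype,
                "state": s.state,
                "mean_kcal_mol": s.mean,
                "sd_kcal_mol": s.sd,
                "n_frames": s.n_frames,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_energy_table(path: str | Path) -> list[InteractionEnergySummary]:
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionEnergySummary(
            genotype=str(row.genotype),
            state=str(row.state),
            mean=float(row.mean_kcal_mol),
            sd=float(row.sd_kcal_mol),
            n_frames=int(row.n_frames),
        )
        for row in df.itertuples()
    ]
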