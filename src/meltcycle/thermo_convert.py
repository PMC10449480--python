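"""Conversion between melting-temperature shifts and folding free energies.

For a perturbation of a reversible two-state equilibrium, the relative
melting-temperature shift is proportional to the incremental free-energy
change (Calvin relation):

    dTm / Tm0 = dG / dH   =>   dG = (dTm / Tm0) * dH,

where Tm0 is the reference (wild-type) melting temperature and dH the
overall enthalpy change of the transition.  The calorimetric enthalpies
use the convention that unfolding releases heat to the baseline
integration (negative dH): dH_tot = -46 kcal/mole for complete
unfolding, partitioned as dH_phi = -27 (molten-globule formation) and
dH_theta = -11 (helix melting).  Those signs are preserved here; a
stabilizing wild-type residue (positive dTm on mutation removal read the
other way) therefore maps to a negative dG with these constants.

The denominator scale is selectable: KELVIN (physically motivated;
``Tm0`` in deg C is converted to K) or CELSIUS (``Tm0`` used as given in
deg C).  Round trips are exact in either mode provided the same mode is
used both ways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .factorial_design import N_TERMS, TERM_NAMES, RegressionFit
from .melt_fit import T0_K

#: calorimetric enthalpy of complete unfolding, kcal/mole
DH_TOTAL_KCAL = -46.0
#: molten-globule formation enthalpy, kcal/mole
DH_PHI_KCAL = -27.0
#: helix-melting enthalpy, kcal/mole
DH_THETA_KCAL = -11.0

SCALES = ("KELVIN", "CELSIUS")


class ThermoError(ValueError):
    """Invalid thermodynamic conversion input."""


@dataclass
class EnthalpyPartition:
    """Per-transition enthalpy changes, kcal/mole (unfolding negative)."""

    dH_total: float = DH_TOTAL_KCAL
    dH_phi: float = DH_PHI_KCAL
    dH_theta: float = DH_THETA_KCAL
    fractions: Optional[dict[str, float]] = None


def partition_enthalpy(fractions: Mapping[str, float],
                       dH_total: float = DH_TOTAL_KCAL) -> EnthalpyPartition:
    """Split the total unfolding enthalpy by per-transition fractions.

    Fractions (e.g. from peak integration of a calorimetric thermogram)
    must each lie in (0, 1] and sum to at most 1; the remainder belongs
    to transitions not modelled here.
    """
    fr = dict(fractions)
    for name, f in fr.items():
        if not 0.0 < f <= 1.0:
            raise ThermoError(f"fraction {name}={f} outside (0, 1]")
    if sum(fr.values()) > 1.0 + 1e-12:
        raise ThermoError(f"fractions sum to {sum(fr.values()):.3f} > 1")
    return EnthalpyPartition(
        dH_total=dH_total,
        dH_phi=fr.get("phi", np.nan) * dH_total,
        dH_theta=fr.get("theta", np.nan) * dH_total,
        fractions=fr,
    )


def _tm0_on_scale(Tm0_C: float, scale: str) -> float:
    if scale == "KELVIN":
        t = Tm0_C + T0_K
    elif scale == "CELSIUS":
        t = Tm0_C
    else:
        raise ThermoError(f"scale must be one of {SCALES}, got {scale!r}")
    if t <= 0:
        raise ThermoError(f"Tm0 = {t} not positive on the {scale} scale")
    return t


def tm_shift_to_ddG(dTm, Tm0: float, dH: float, scale: str = "KELVIN"):
    """Incremental free energy (kcal/mole) from a Tm shift (deg C).

    ``Tm0`` is the reference melting temperature in deg C; ``scale``
    selects the denominator scale.  Exactly linear in both ``dTm`` and
    ``dH``.
    """
    if dH == 0:
        raise ThermoError("dH must be nonzero")
    return np.asarray(dTm, dtype=float) / _tm0_on_scale(Tm0, scale) * dH


def ddG_to_tm_shift(ddG, Tm0: float, dH: float, scale: str = "KELVIN"):
    """Inverse conversion: free-energy increment (kcal/mole) to dTm (deg C)."""
    if dH == 0:
        raise ThermoError("dH must be nonzero")
    return np.asarray(ddG, dtype=float) * _tm0_on_scale(Tm0, scale) / dH


@dataclass
class EnergyTable:
    """Per-term free-energy increments for the two transitions."""

    terms: tuple[str, ...]
    dG_phi: np.ndarray  # kcal/mole; NaN for terms not retained
    dG_theta: np.ndarray
    provenance: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "dG_phi_kcal": self.dG_phi,
                "dG_theta_kcal": self.dG_theta,
            }
        )


def coefficients_to_energy_table(fit_phi: RegressionFit,
                                 fit_theta: RegressionFit,
                                 Tm0_phi: float, Tm0_theta: float,
                                 partition: EnthalpyPartition = EnthalpyPartition(),
                                 scale: str = "KELVIN") -> EnergyTable:
    """Convert regression coefficients (deg C) to per-term free energies.

    Each transition's retained coefficients are scaled with its own
    reference temperature and enthalpy; terms dropped from a model get
    NaN in that column.
    """
    if fit_phi.term_names != fit_theta.term_names:
        raise ThermoError("phi and theta fits have mismatched term sets")
    dg_phi = np.full(N_TERMS, np.nan)
    dg_theta = np.full(N_TERMS, np.nan)
    for j in range(N_TERMS):
        if fit_phi.retained[j]:
            dg_phi[j] = tm_shift_to_ddG(
                fit_phi.beta[j], Tm0_phi, partition.dH_phi, scale
            )
        if fit_theta.retained[j]:
            dg_theta[j] = tm_shift_to_ddG(
                fit_theta.beta[j], Tm0_theta, partition.dH_theta, scale
            )
    return EnergyTable(
        terms=fit_phi.term_names,
        dG_phi=dg_phi,
        dG_theta=dg_theta,
        provenance={
            "Tm0_phi_C": Tm0_phi,
            "Tm0_theta_C": Tm0_theta,
            "dH_phi_kcal": partition.dH_phi,
            "dH_theta_kcal": partition.dH_theta,
            "scale": scale,
        },
    )


def energy_table_to_betas(table: EnergyTable, Tm0_phi: float, Tm0_theta: float,
                          partition: EnthalpyPartition = EnthalpyPartition(),
                          scale: str = "KELVIN") -> tuple[np.ndarray, np.ndarray]:
    """Invert an energy table to per-term Tm effects (deg C).

    NaN entries (terms absent from a model) map to zero effect.  Used by
    the synthetic generator to inject published free energies as ground
    truth.
    """
    beta_phi = np.where(
        np.isfinite(table.dG_phi),
        ddG_to_tm_shift(np.nan_to_num(table.dG_phi), Tm0_phi,
                        partition.dH_phi, scale),
        0.0,
    )
    beta_theta = np.where(
        np.isfinite(table.dG_theta),
        ddG_to_tm_shift(np.nan_to_num(table.dG_theta), Tm0_theta,
                        partition.dH_theta, scale),
        0.0,
    )
    return beta_phi, beta_theta
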