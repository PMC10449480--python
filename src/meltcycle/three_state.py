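"""Three-state population model: native -> molten globule -> unfolded.

The two fitted transitions (phi: loss of native core packing seen by the
dye; theta: helix melting seen by far-UV CD) are combined as sequential
two-state equilibria

    S1 <-> S2 <-> S3,   K1(T), K2(T)

with van't Hoff free energies dG_i(T) = dH_i * (1 - T/Tm_i) (Kelvin,
dCp = 0; dS is implied by the two-state condition dS = dH/Tm rather than
being a free parameter).  The Boltzmann-weighted populations are

    P1 = 1 / (1 + K1 + K1*K2)
    P2 = K1 / (1 + K1 + K1*K2)
    P3 = K1*K2 / (1 + K1 + K1*K2).

When the two melting temperatures are well separated, P2 rises close to
1 between them with P1 and P3 near 0 — the quantitative signature that a
three-state description with a populated intermediate is valid.  The
peak of P2 and the P1 = P3 crossing are unconstrained by the fits, which
makes them useful validity metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .melt_fit import R_KCAL, T0_K, TwoStateFit

logger = logging.getLogger(__name__)


@dataclass
class StateProfile:
    """Populations of the three states on a temperature grid."""

    temperatures: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("temperatures", "P1", "P2", "P3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        total = self.P1 + self.P2 + self.P3
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state populations do not sum to 1")


@dataclass
class ProfileMetrics:
    """Validity metrics of the three-state approximation."""

    P2max: float
    T_P2max: float
    P1_at_P2max: float
    P3_at_P2max: float
    T_cross: Optional[float]  # temperature where P1 = P3; None if absent


def _equilibrium_constant(T_C: np.ndarray, Tm_C: float, dH: float) -> np.ndarray:
    T_K = T_C + T0_K
    Tm_K = Tm_C + T0_K
    dG = dH * (1.0 - T_K / Tm_K)
    return np.exp(np.clip(-dG / (R_KCAL * T_K), -700.0, 700.0))


def state_probabilities(fit_phi: TwoStateFit, fit_theta: TwoStateFit,
                        grid) -> StateProfile:
    """Populations of native, molten globule and unfolded states.

    ``fit_phi`` and ``fit_theta`` supply (Tm, dH_vH) for the first and
    second transition.  A phi midpoint above the theta midpoint is
    physically suspicious (the intermediate would never accumulate) and
    triggers a warning, not an error.
    """
    T = np.asarray(grid, dtype=float)
    if fit_phi.Tm > fit_theta.Tm:
        warnings.warn(
            f"Tm_phi ({fit_phi.Tm:.2f}) exceeds Tm_theta ({fit_theta.Tm:.2f}); "
            "transitions out of order", stacklevel=2,
        )
    K1 = _equilibrium_constant(T, fit_phi.Tm, fit_phi.dH_vH)
    K2 = _equilibrium_constant(T, fit_theta.Tm, fit_theta.dH_vH)
    Z = 1.0 + K1 + K1 * K2
    return StateProfile(temperatures=T, P1=1.0 / Z, P2=K1 / Z, P3=K1 * K2 / Z)


def profile_metrics(profile: StateProfile) -> ProfileMetrics:
    """Locate the P2 maximum (with local quadratic refinement) and the
    P1 = P3 crossing."""
    T, P1, P2, P3 = (profile.temperatures, profile.P1, profile.P2, profile.P3)
    i = int(np.argmax(P2))
    if i == 0 or i == T.size - 1:
        warnings.warn(
            "P2 extremum at grid edge (degenerate overlapping transitions); "
            "metrics taken from the grid extremum", stacklevel=2,
        )
        t_star, p2_star = float(T[i]), float(P2[i])
    else:
        # parabola through the three points around the grid maximum
        t3, p3v = T[i - 1:i + 2], P2[i - 1:i + 2]
        denom = (t3[0] - t3[1]) * (t3[0] - t3[2]) * (t3[1] - t3[2])
        a = (t3[2] * (p3v[1] - p3v[0]) + t3[1] * (p3v[0] - p3v[2])
             + t3[0] * (p3v[2] - p3v[1])) / denom
        b = (t3[2]**2 * (p3v[0] - p3v[1]) + t3[1]**2 * (p3v[2] - p3v[0])
             + t3[0]**2 * (p3v[1] - p3v[2])) / denom
        if a < 0:
            t_star = float(np.clip(-b / (2 * a), t3[0], t3[2]))
            c = p3v[1] - a * t3[1]**2 - b * t3[1]
            p2_star = float(a * t_star**2 + b * t_star + c)
        else:  # numerically flat top
            t_star, p2_star = float(T[i]), float(P2[i])

    p1_at = float(np.interp(t_star, T, P1))
    p3_at = float(np.interp(t_star, T, P3))

    g = P1 - P3
    t_cross: Optional[float] = None
    sign_change = np.nonzero(g[:-1] * g[1:] < 0)[0]
    exact = np.nonzero(g == 0)[0]
    if exact.size:
        t_cross = float(T[exact[0]])
    elif sign_change.size:
        j = int(sign_change[0])
        w = g[j] / (g[j] - g[j + 1])
        t_cross = float(T[j] + w * (T[j + 1] - T[j]))
    else:
        logger.info("P1 - P3 has no sign change in range; T_cross undefined")

    return ProfileMetrics(P2max=p2_star, T_P2max=t_star,
                          P1_at_P2max=p1_at, P3_at_P2max=p3_at,
                          T_cross=t_cross)
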