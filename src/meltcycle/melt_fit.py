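"""Two-state fitting of individual melting curves.

Each melt (the DSF-detected molten-globule transition or the CD-detected
helix-melting transition) is modelled as a van't Hoff two-state sigmoid
between linear native and unfolded baselines,

    y(T) = (1 - f(T)) * B_N(T) + f(T) * B_U(T),
    f(T) = 1 / (1 + exp[(dH_vH / R) * (1/T_K - 1/Tm_K)]),

with temperatures in Kelvin inside the exponential and dH_vH > 0 the
van't Hoff enthalpy of unfolding.  Tm is estimated two ways:

* **Model** — nonlinear least squares over all six parameters
  (Tm, dH_vH, two baseline intercept/slope pairs);
* **Ratio** — linear baselines fitted in the pre- and post-transition
  windows and extrapolated; Tm is the temperature at which the fraction
  converted f = (y - B_N) / (B_U - B_N) crosses 0.5.

On clean two-state data the two agree to within a temperature grid step.

DSF traces are truncated at the global fluorescence maximum before any
fitting: Sypro-Orange fluorescence decays above the transition as the
unfolded protein aggregates, and the two-state model cannot represent
that decay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .plate_io import MeltCurve, MIN_FIT_POINTS

logger = logging.getLogger(__name__)

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3
#: Celsius -> Kelvin offset
T0_K = 273.15

#: Savitzky-Golay smoothing defaults for derivative estimation
SMOOTH_WINDOW = 11
SMOOTH_ORDER = 2

#: initial van't Hoff enthalpy guess, kcal/mole
DH_INIT = 50.0
DH_BOUNDS = (1.0, 500.0)


class MeltFitError(RuntimeError):
    """Base class for fitting failures."""


class NoTransitionError(MeltFitError):
    """No sigmoidal transition detectable; manual bounds required."""


class BaselineCrossError(MeltFitError):
    """Extrapolated baselines cross inside the transition region."""


@dataclass
class TransitionBounds:
    """Temperatures bracketing the sigmoidal segment.

    ``T_low`` ends the native-baseline window, ``T_high`` starts the
    unfolded-baseline window.
    """

    T_low: float
    T_high: float
    source: str = "AUTO"  # AUTO | MANUAL

    def __post_init__(self) -> None:
        if not self.T_low < self.T_high:
            raise ValueError("T_low must be below T_high")
        if self.source not in ("AUTO", "MANUAL"):
            raise ValueError("source must be AUTO or MANUAL")


@dataclass
class TwoStateFit:
    """Fitted two-state transition parameters for one curve."""

    Tm: float
    dH_vH: float
    baseline_native: tuple[float, float] = (0.0, 0.0)
    baseline_unfolded: tuple[float, float] = (1.0, 0.0)
    method: str = "MODEL"  # MODEL | RATIO
    rmse: float = np.nan
    converged: bool = True
    bounds: Optional[TransitionBounds] = None
    # provenance labels carried over from the curve
    well_id: str = ""
    variant_index: int = -1
    replicate_id: int = 0
    batch_id: str = ""
    probe: str = "DSF"


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def fraction_unfolded(T, Tm: float, dH_vH: float):
    """van't Hoff fraction converted at temperature ``T`` (all in deg C)."""
    T_K = np.asarray(T, dtype=float) + T0_K
    Tm_K = Tm + T0_K
    x = (dH_vH / R_KCAL) * (1.0 / T_K - 1.0 / Tm_K)
    # clip to avoid overflow in exp for extreme arguments
    return 1.0 / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


def two_state_signal(T, Tm: float, dH_vH: float,
                     baseline_native: Sequence[float],
                     baseline_unfolded: Sequence[float]):
    """Predicted signal of a two-state melt with linear baselines."""
    T = np.asarray(T, dtype=float)
    f = fraction_unfolded(T, Tm, dH_vH)
    bn = baseline_native[0] + baseline_native[1] * T
    bu = baseline_unfolded[0] + baseline_unfolded[1] * T
    return (1.0 - f) * bn + f * bu


def _model6(T, Tm, dH, bn0, bn1, bu0, bu1):
    return two_state_signal(T, Tm, dH, (bn0, bn1), (bu0, bu1))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def truncate_dsf_peak(curve: MeltCurve) -> MeltCurve:
    """Truncate a DSF trace at its global fluorescence maximum.

    Non-DSF curves are returned unchanged.  If the maximum sits at the
    last point (no post-transition quench) the curve is also unchanged.
    """
    if curve.probe != "DSF":
        return curve
    imax = int(np.argmax(curve.signals))
    if imax >= len(curve) - 1:
        return curve
    if imax + 1 < MIN_FIT_POINTS:
        raise MeltFitError(
            f"well {curve.well_id}: fewer than {MIN_FIT_POINTS} points "
            "before the fluorescence maximum"
        )
    return curve.sorted_copy(
        temperatures=curve.temperatures[: imax + 1],
        signals=curve.signals[: imax + 1],
    )


def smoothed_derivative(curve: MeltCurve, window: int = SMOOTH_WINDOW,
                        order: int = SMOOTH_ORDER) -> np.ndarray:
    """Centered local-polynomial estimate of dy/dT on the curve's grid."""
    n = len(curve)
    win = min(window, n if n % 2 == 1 else n - 1)
    if win <= order:
        return np.gradient(curve.signals, curve.temperatures)
    steps = np.diff(curve.temperatures)
    if np.allclose(steps, steps[0], rtol=1e-6):
        return savgol_filter(curve.signals, win, order, deriv=1,
                             delta=float(steps[0]))
    ysm = savgol_filter(curve.signals, win, order)
    return np.gradient(ysm, curve.temperatures)


# ---------------------------------------------------------------------------
# bounds detection
# ---------------------------------------------------------------------------

def detect_transition_bounds(curve: MeltCurve,
                             manual: Optional[tuple[float, float]] = None,
                             window: int = SMOOTH_WINDOW,
                             rel_threshold: float = 0.10,
                             ) -> TransitionBounds:
    """Locate the native/unfolded baseline windows around the sigmoid.

    The smoothed first derivative is centred on its median (so a uniform
    baseline slope does not register as signal); the baseline windows are
    the maximal leading and trailing runs where the centred derivative
    magnitude stays below ``rel_threshold`` of its peak.  A derivative
    peak that does not rise above 3x the derivative noise (scaled median
    absolute deviation) means no detectable transition.

    ``manual`` bounds, when given, are returned unchanged with
    ``source='MANUAL'``.
    """
    if manual is not None:
        return TransitionBounds(float(manual[0]), float(manual[1]), "MANUAL")
    if len(curve) < MIN_FIT_POINTS:
        raise MeltFitError(
            f"well {curve.well_id}: need >= {MIN_FIT_POINTS} points, "
            f"got {len(curve)}"
        )
    curve = truncate_dsf_peak(curve)
    T = curve.temperatures
    d = smoothed_derivative(curve, window=window)
    dc = d - np.median(d)
    mag = np.abs(dc)
    peak = float(mag.max())
    noise = 1.4826 * float(np.median(np.abs(dc - np.median(dc))))
    if peak <= 3.0 * noise:
        raise NoTransitionError(
            f"well {curve.well_id}: derivative peak {peak:.3g} within noise "
            f"(MAD {noise:.3g}); supply MANUAL bounds"
        )
    thresh = rel_threshold * peak
    ipk = int(np.argmax(mag))
    # walk outward from the derivative peak to the 10% crossings; the
    # leading/trailing quiet regions beyond them are the baseline windows
    lo = ipk
    while lo > 0 and mag[lo] >= thresh:
        lo -= 1
    hi = ipk
    while hi < mag.size - 1 and mag[hi] >= thresh:
        hi += 1
    if mag[lo] >= thresh or mag[hi] >= thresh:
        raise NoTransitionError(
            f"well {curve.well_id}: no flat baseline run found; "
            "supply MANUAL bounds"
        )
    return TransitionBounds(float(T[lo]), float(T[hi]), "AUTO")


def _baseline_windows(curve: MeltCurve, bounds: TransitionBounds):
    T = curve.temperatures
    native = T <= bounds.T_low
    unfolded = T >= bounds.T_high
    return native, unfolded


def _linfit(T: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) least-squares line; constant line if 1 point."""
    if T.size == 1:
        return float(y[0]), 0.0
    slope, intercept = np.polyfit(T, y, 1)
    return float(intercept), float(slope)


# ---------------------------------------------------------------------------
# "Model" method
# ---------------------------------------------------------------------------

def fit_two_state(curve: MeltCurve,
                  bounds: Optional[TransitionBounds] = None,
                  seed: int = 0,
                  max_restarts: int = 2) -> TwoStateFit:
    """Fit the six-parameter two-state model to one curve.

    Initial values come from linear fits inside the baseline windows, the
    derivative-peak temperature and a generic 50 kcal/mole enthalpy.
    Non-convergence triggers up to ``max_restarts`` seeded restarts with
    the initial Tm perturbed by +-2 deg C; a still-unconverged or
    bound-pinned fit is returned flagged (``converged=False``).
    """
    curve = truncate_dsf_peak(curve)
    if bounds is None:
        bounds = detect_transition_bounds(curve)
    T, y = curve.temperatures, curve.signals
    native, unfolded = _baseline_windows(curve, bounds)
    if native.sum() < 2 or unfolded.sum() < 2:
        raise MeltFitError(
            f"well {curve.well_id}: baseline windows too small for bounds "
            f"({bounds.T_low}, {bounds.T_high})"
        )
    bn = _linfit(T[native], y[native])
    bu = _linfit(T[unfolded], y[unfolded])
    d = smoothed_derivative(curve)
    dc = d - np.median(d)
    tm0 = float(T[int(np.argmax(np.abs(dc)))])
    tm0 = float(np.clip(tm0, bounds.T_low, bounds.T_high))

    lo = [T[0], DH_BOUNDS[0], -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [T[-1], DH_BOUNDS[1], np.inf, np.inf, np.inf, np.inf]
    rng = np.random.default_rng(seed)

    tm_starts = [tm0]
    for _ in range(max_restarts):
        tm_starts.append(tm0 + rng.uniform(-2.0, 2.0))

    best = None
    for tm_start in tm_starts:
        p0 = [np.clip(tm_start, T[0], T[-1]), DH_INIT, bn[0], bn[1], bu[0], bu[1]]
        try:
            popt, _ = curve_fit(
                _model6, T, y, p0=p0, bounds=(lo, hi), maxfev=5000
            )
        except RuntimeError:
            continue
        resid = y - _model6(T, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
        if rmse <= 1e-6 * max(1.0, float(np.ptp(y))):
            break

    labels = dict(
        well_id=curve.well_id, variant_index=curve.variant_index,
        replicate_id=curve.replicate_id, batch_id=curve.batch_id,
        probe=curve.probe,
    )
    if best is None:
        logger.warning("well %s: two-state fit did not converge", curve.well_id)
        return TwoStateFit(Tm=np.nan, dH_vH=np.nan, method="MODEL",
                           converged=False, bounds=bounds, **labels)
    popt, rmse = best
    tm, dh = float(popt[0]), float(popt[1])
    pinned = (
        np.isclose(dh, DH_BOUNDS[0]) or np.isclose(dh, DH_BOUNDS[1])
        or np.isclose(tm, T[0]) or np.isclose(tm, T[-1])
    )
    if pinned:
        logger.warning(
            "well %s: fit pinned at parameter bound (Tm=%.2f, dH=%.1f)",
            curve.well_id, tm, dh,
        )
    return TwoStateFit(
        Tm=tm, dH_vH=dh,
        baseline_native=(float(popt[2]), float(popt[3])),
        baseline_unfolded=(float(popt[4]), float(popt[5])),
        method="MODEL", rmse=rmse, converged=not pinned, bounds=bounds,
        **labels,
    )


# ---------------------------------------------------------------------------
# "Ratio" method
# ---------------------------------------------------------------------------

def tm_by_ratio(curve: MeltCurve,
                bounds: Optional[TransitionBounds] = None) -> float:
    """Tm from extrapolated baselines: the f = 0.5 crossing.

    With several 0.5-crossings (noise), the one nearest the derivative
    peak inside the transition window is chosen.
    """
    curve = truncate_dsf_peak(curve)
    if bounds is None:
        bounds = detect_transition_bounds(curve)
    T, y = curve.temperatures, curve.signals
    native, unfolded = _baseline_windows(curve, bounds)
    if native.sum() < 5 or unfolded.sum() < 5:
        raise MeltFitError(
            f"well {curve.well_id}: ratio method needs >= 5 points per "
            "baseline window"
        )
    # note: the 10%-derivative windows still admit a few percent of
    # sigmoid tail; for transitions whose plateaus are sampled within the
    # scan the induced bias is well under half a grid step, but a broad
    # transition running off the scan edge has no observable baseline and
    # the extrapolation is biased low — flag such wells for manual bounds
    bn = _linfit(T[native], y[native])
    bu = _linfit(T[unfolded], y[unfolded])
    denom = (bu[0] + bu[1] * T) - (bn[0] + bn[1] * T)
    inside = (T > bounds.T_low) & (T < bounds.T_high)
    if np.any(denom[inside] > 0) and np.any(denom[inside] < 0):
        raise BaselineCrossError(
            f"well {curve.well_id}: extrapolated baselines cross inside "
            "the transition region"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (y - (bn[0] + bn[1] * T)) / denom

    g = f - 0.5
    crossings = []
    for i in range(T.size - 1):
        if not (bounds.T_low <= T[i] and T[i + 1] <= bounds.T_high):
            continue
        if g[i] == 0.0:
            crossings.append(float(T[i]))
        elif g[i] * g[i + 1] < 0:
            w = g[i] / (g[i] - g[i + 1])
            crossings.append(float(T[i] + w * (T[i + 1] - T[i])))
    if g[-1] == 0.0 and bounds.T_low <= T[-1] <= bounds.T_high:
        crossings.append(float(T[-1]))
    if not crossings:
        raise MeltFitError(
            f"well {curve.well_id}: fraction converted never crosses 0.5 "
            "inside the transition bounds"
        )
    d = smoothed_derivative(curve)
    dc = np.abs(d - np.median(d))
    dc[(T <= bounds.T_low) | (T >= bounds.T_high)] = -np.inf
    t_peak = float(T[int(np.argmax(dc))])
    return min(crossings, key=lambda t: abs(t - t_peak))


# ---------------------------------------------------------------------------
# ensemble derivative shape statistics
# ---------------------------------------------------------------------------

@dataclass
class ShapeStats:
    """Ensemble-mean +- SD of derivative-distribution shape moments."""

    skewness_mean: float
    skewness_sd: float
    kurtosis_mean: float
    kurtosis_sd: float
    n_curves: int
    per_curve: list[tuple[float, float]] = field(default_factory=list)


def _weighted_shape(T: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    w = w / w.sum()
    mu = float(np.sum(w * T))
    var = float(np.sum(w * (T - mu) ** 2))
    sd = np.sqrt(var)
    skew = float(np.sum(w * (T - mu) ** 3) / sd**3)
    kurt = float(np.sum(w * (T - mu) ** 4) / sd**4 - 3.0)
    return skew, kurt


def derivative_shape_stats(curves: Iterable[MeltCurve],
                           window: int = SMOOTH_WINDOW) -> ShapeStats:
    """Skewness and excess kurtosis of per-curve melting-rate distributions.

    Each curve's smoothed dy/dT (negative parts clipped to zero) is
    treated as a weight distribution over temperature; heat-capacity-like
    traces (probe ``DSC``) are already rate-shaped and are used directly.
    Moment-based skewness and excess kurtosis are computed per curve and
    summarised as ensemble mean +- SD.
    """
    per_curve = []
    for curve in curves:
        if curve.probe == "DSC":
            w = np.clip(curve.signals, 0.0, None)
        else:
            w = np.clip(smoothed_derivative(curve, window=window), 0.0, None)
        if w.sum() <= 0:
            warnings.warn(
                f"well {curve.well_id}: derivative non-positive everywhere; "
                "skipped", stacklevel=2,
            )
            continue
        per_curve.append(_weighted_shape(curve.temperatures, w))
    if len(per_curve) < 1:
        raise MeltFitError("no usable curves for shape statistics")
    arr = np.array(per_curve)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(2)
    return ShapeStats(
        skewness_mean=float(arr[:, 0].mean()), skewness_sd=float(sd[0]),
        kurtosis_mean=float(arr[:, 1].mean()), kurtosis_sd=float(sd[1]),
        n_curves=arr.shape[0], per_curve=per_curve,
    )


# ---------------------------------------------------------------------------
# convenience: fit a whole dataset
# ---------------------------------------------------------------------------

def fit_dataset(dataset, method: str = "MODEL", seed: int = 0,
                manual_bounds: Optional[dict] = None) -> list[TwoStateFit]:
    """Fit every curve of a dataset with the requested method.

    ``manual_bounds`` maps well ids to (T_low, T_high) overrides.  Wells
    whose fit fails outright are flagged (returned with
    ``converged=False``) rather than dropped, so downstream stages can
    report exclusions.
    """
    fits = []
    for curve in dataset.curves:
        mb = (manual_bounds or {}).get(curve.well_id)
        labels = dict(
            well_id=curve.well_id, variant_index=curve.variant_index,
            replicate_id=curve.replicate_id, batch_id=curve.batch_id,
            probe=curve.probe,
        )
        try:
            bounds = detect_transition_bounds(curve, manual=mb)
            if method == "RATIO":
                tm = tm_by_ratio(curve, bounds)
                fits.append(TwoStateFit(Tm=tm, dH_vH=np.nan, method="RATIO",
                                        bounds=bounds, **labels))
            else:
                fits.append(fit_two_state(curve, bounds, seed=seed))
        except MeltFitError as exc:
            logger.warning("well %s flagged: %s", curve.well_id, exc)
            fits.append(TwoStateFit(Tm=np.nan, dH_vH=np.nan, method=method,
                                    converged=False, **labels))
    return fits
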