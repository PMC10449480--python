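"""Seeded synthetic plate ensembles with known factorial truth.

The generator emulates the study conditions of the thermal-melting
screen: 16 combinatorial variants, six replicates each on a 384-well
plate heated 25 -> 95 deg C in 0.4-degree steps, observed by two probes
(DSF dye fluorescence for the molten-globule transition, ellipticity at
221 nm for helix melting), optionally in two measurement batches with an
additive between-batch temperature offset.

Per-variant true melting temperatures follow the factorial effect model:
Tm_phi,i = wt_Tm_phi + x_i . beta_phi and Tm_theta,i = wt_Tm_phi +
gap_i + x_i . beta_theta, where x_i is variant i's design row and gap_i
is drawn from a fixed 16-entry table with mean exactly 8.5 deg C (the
ensemble-mean separation between the two transitions) and spread
0.8 deg C.  Curves are the two-state forward model plus seeded Gaussian
noise proportional to the transition amplitude; an optional
post-transition quench envelope mimics fluorescence loss from
aggregation of the unfolded protein.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import skewnorm

from .factorial_design import ALL_VARIANTS, N_TERMS, build_design_matrix
from .melt_fit import two_state_signal
from .plate_io import MeltCurve, PlateDataset, write_plate, write_variant_map

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20230823

#: fixed per-variant theta-phi gap table: mean exactly 8.5, SD 0.8 deg C
_pattern = np.linspace(-1.0, 1.0, 16)
DEFAULT_GAP_TABLE = 8.5 + 0.8 * _pattern / _pattern.std()

#: default probe baselines (intercept, slope per deg C)
DEFAULT_BASELINES = {
    "DSF": ((1000.0, 5.0), (20000.0, 20.0)),      # fluorescence, a.u.
    "CD221": ((-21.0, 0.01), (-3.0, 0.01)),       # ellipticity, mdeg
    "CD270": ((-2.5, 0.002), (-0.2, 0.001)),
}

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well format: 16 rows x 24 columns


class GeneratorError(ValueError):
    """Configuration produces unusable (unfittable) data."""


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic ensemble."""

    beta_phi: np.ndarray = field(
        default_factory=lambda: np.zeros(N_TERMS)
    )
    beta_theta: np.ndarray = field(
        default_factory=lambda: np.zeros(N_TERMS)
    )
    wt_Tm_phi: float = 64.0
    gap_theta_minus_phi: np.ndarray = field(
        default_factory=lambda: DEFAULT_GAP_TABLE.copy()
    )
    dH_vH_phi: float = 80.0
    dH_vH_theta: float = 60.0
    baselines: dict = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_BASELINES.items()}
    )
    noise_sd: float = 0.02           # fraction of transition amplitude
    n_replicates: int = 6
    batch_offsets: dict = field(default_factory=lambda: {"b1": 0.0})
    condition_offset: float = 0.0    # e.g. ~-2.5 deg C with 20 mM Mg2+
    grid_min: float = 25.0
    grid_max: float = 95.0
    grid_step: float = 0.4
    dsf_quench: Optional[float] = None  # fractional decay per deg C past Tm
    coding: str = "ZERO_ONE"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.beta_phi = np.asarray(self.beta_phi, dtype=float)
        self.beta_theta = np.asarray(self.beta_theta, dtype=float)
        self.gap_theta_minus_phi = np.asarray(
            self.gap_theta_minus_phi, dtype=float
        )
        if self.beta_phi.shape != (N_TERMS,) or self.beta_theta.shape != (N_TERMS,):
            raise GeneratorError(f"effect vectors must have length {N_TERMS}")
        if np.isscalar(self.gap_theta_minus_phi) or self.gap_theta_minus_phi.ndim == 0:
            self.gap_theta_minus_phi = np.full(16, float(self.gap_theta_minus_phi))
        if self.gap_theta_minus_phi.shape != (16,):
            raise GeneratorError("gap table must have 16 entries")
        if self.grid_step <= 0:
            raise GeneratorError("grid step must be positive")
        if self.n_replicates < 1:
            raise GeneratorError("need at least one replicate")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass
class TruthRecord:
    """Ground-truth ledger for recovery tests."""

    tm_phi: np.ndarray        # per variant index 0..15, deg C
    tm_theta: np.ndarray
    beta_phi: np.ndarray      # per factorial term, deg C
    beta_theta: np.ndarray
    gap: np.ndarray
    batch_offsets: dict
    condition_offset: float
    coding: str
    seed: int

    def to_json(self, path) -> Path:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        for k in ("tm_phi", "tm_theta", "beta_phi", "beta_theta", "gap"):
            payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


def make_truth(config: GeneratorConfig) -> TruthRecord:
    """Per-variant true melting temperatures from the factorial effects.

    Truth outside the fittable interior of the grid (5 deg C margins)
    is fatal: such curves lack a baseline window and cannot be fitted.
    """
    X = build_design_matrix(ALL_VARIANTS, coding=config.coding).X
    tm_phi = config.wt_Tm_phi + X @ config.beta_phi
    tm_theta = config.wt_Tm_phi + config.gap_theta_minus_phi + X @ config.beta_theta
    lo, hi = config.grid_min + 5.0, config.grid_max - 5.0
    worst = np.concatenate([tm_phi, tm_theta])
    shifts = [config.condition_offset + off for off in
              config.batch_offsets.values()]
    extremes = worst[:, None] + np.asarray(shifts)[None, :]
    if extremes.min() <= lo or extremes.max() >= hi:
        raise GeneratorError(
            f"true Tm range [{extremes.min():.1f}, {extremes.max():.1f}] "
            f"leaves the fittable interior ({lo:.1f}, {hi:.1f})"
        )
    return TruthRecord(
        tm_phi=tm_phi, tm_theta=tm_theta,
        beta_phi=config.beta_phi.copy(), beta_theta=config.beta_theta.copy(),
        gap=config.gap_theta_minus_phi.copy(),
        batch_offsets=dict(config.batch_offsets),
        condition_offset=config.condition_offset,
        coding=config.coding, seed=config.seed,
    )


def _well_label(i: int) -> str:
    return f"{PLATE_ROWS[i // 24]}{i % 24 + 1}"


def _quench_envelope(T: np.ndarray, tm: float, rate: float) -> np.ndarray:
    """Linear post-transition decay, starting ~3 deg past the midpoint."""
    past = np.clip(T - (tm + 3.0), 0.0, None)
    return np.clip(1.0 - rate * past, 0.05, 1.0)


def generate_plate(truth: TruthRecord, config: GeneratorConfig,
                   probe: str = "DSF") -> PlateDataset:
    """Simulate one probe's full ensemble of melt curves.

    Wells are assigned deterministically in (batch, variant, replicate)
    order; the noise stream is keyed by (seed, probe) so the same seed
    reproduces bit-identical datasets.
    """
    if probe not in config.baselines:
        raise GeneratorError(f"no baselines configured for probe {probe!r}")
    T = config.grid
    bn, bu = config.baselines[probe]
    tm_true = truth.tm_phi if probe == "DSF" else truth.tm_theta
    dh = config.dH_vH_phi if probe == "DSF" else config.dH_vH_theta
    amplitude = abs(
        (bu[0] + bu[1] * np.mean(T)) - (bn[0] + bn[1] * np.mean(T))
    )
    probe_code = {"DSF": 0, "CD221": 1, "CD270": 2}.get(probe, 3)
    rng = np.random.default_rng([config.seed, probe_code])

    n_wells = len(config.batch_offsets) * 16 * config.n_replicates
    if n_wells > 384:
        raise GeneratorError(
            f"{n_wells} wells exceed the 384-well plate format"
        )

    curves = []
    w = 0
    for batch, offset in config.batch_offsets.items():
        for variant in range(16):
            tm = float(tm_true[variant] + offset + config.condition_offset)
            for rep in range(1, config.n_replicates + 1):
                y = two_state_signal(T, tm, dh, bn, bu)
                if probe == "DSF" and config.dsf_quench:
                    y = y * _quench_envelope(T, tm, config.dsf_quench)
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd * amplitude,
                                       size=T.size)
                curves.append(
                    MeltCurve(
                        well_id=_well_label(w), variant_index=variant,
                        replicate_id=rep, batch_id=str(batch), probe=probe,
                        temperatures=T.copy(), signals=y,
                    )
                )
                w += 1
    meta = {
        "probe": probe, "step_C": config.grid_step,
        "dwell_s": 8.7, "seed": config.seed,
    }
    return PlateDataset(curves=curves, metadata=meta)


def generate_dsc_like(peaks: Sequence[tuple[float, float, float, float]],
                      grid) -> MeltCurve:
    """Heat-capacity-like trace as a sum of skew-normal peaks.

    ``peaks`` lists (Tm, width, skew, area) tuples.  Used to exercise the
    ensemble derivative-shape statistics on traces with known asymmetry.
    """
    if not peaks:
        raise GeneratorError("need at least one peak")
    T = np.asarray(grid, dtype=float)
    y = np.zeros_like(T)
    for tm, width, skew, area in peaks:
        y += area * skewnorm.pdf(T, a=skew, loc=tm, scale=width)
    return MeltCurve(
        well_id="dsc", variant_index=0, replicate_id=1, batch_id="dsc",
        probe="DSC", temperatures=T, signals=y,
    )


def simulate(config: GeneratorConfig, outdir,
             probes: Sequence[str] = ("DSF", "CD221")) -> dict:
    """Generate an ensemble and write plate CSVs, variant map, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_truth(config)
    paths = {"truth": truth.to_json(outdir / "truth.json")}
    for probe in probes:
        ds = generate_plate(truth, config, probe=probe)
        paths[f"plate_{probe}"] = write_plate(ds, outdir / f"plate_{probe}.csv")
        paths[f"map_{probe}"] = write_variant_map(
            ds, outdir / f"variant_map_{probe}.csv"
        )
    logger.info("simulated ensemble written to %s", outdir)
    return paths
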