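"""End-to-end orchestration: parse -> fit -> populations -> regression -> energies.

A :class:`RunConfig` (built directly or loaded from YAML) either points
at plate exports plus a variant map, or carries a ``simulate`` block (a
:class:`~meltcycle.synthetic_data.GeneratorConfig`).  ``run_pipeline``
executes the stages in order, writes every tabular output as CSV into
the output directory, and returns a :class:`RunReport` whose manifest
records the seed, configuration hash and per-stage outputs.  Fatal
errors abort with a stage-tagged :class:`PipelineError`; flagged wells
propagate as recorded exclusions, never silent drops.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .factorial_design import (
    ALL_VARIANTS,
    build_design_matrix,
    batch_align,
    fit_factorial,
    reduce_model,
    RegressionFit,
)
from .melt_fit import TwoStateFit, fit_dataset, tm_by_ratio
from .plate_io import (
    PlateDataset,
    PlateIOError,
    average_replicates,
    parse_plate_export,
    write_summary,
    _FLOAT_FMT,
)
from .synthetic_data import GeneratorConfig, generate_plate, make_truth
from .three_state import profile_metrics, state_probabilities
from .thermo_convert import (
    EnthalpyPartition,
    coefficients_to_energy_table,
)

logger = logging.getLogger(__name__)

PROBE_PHI = "DSF"
PROBE_THETA = "CD221"


class PipelineError(RuntimeError):
    """Fatal stage failure; the message is prefixed with the stage tag."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    outdir: str = "meltcycle_out"
    seed: int = 0
    method: str = "MODEL"             # MODEL | RATIO | BOTH
    coding: str = "ZERO_ONE"
    reduce: bool = False
    p_remove: float = 0.5
    p_sig: float = 0.05
    Tm0_phi: float = 64.0
    Tm0_theta: float = 72.5
    scale: str = "KELVIN"
    partition: EnthalpyPartition = field(default_factory=EnthalpyPartition)
    simulate: Optional[GeneratorConfig] = None
    plate_phi: Optional[str] = None   # long/wide CSV for the DSF melt
    plate_theta: Optional[str] = None  # CSV for the CD221 melt
    variant_map: Optional[str] = None
    manual_bounds: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        partition = raw.pop("partition", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = GeneratorConfig(**sim)
        if partition is not None:
            cfg.partition = EnthalpyPartition(**partition)
        return cfg

    def digest(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        blob = json.dumps(self.__dict__, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Stage outputs of one run (in-memory hooks plus written files)."""

    fits: pd.DataFrame
    summary: pd.DataFrame
    coefficients_phi: RegressionFit
    coefficients_theta: Optional[RegressionFit]
    energy_table: Optional[pd.DataFrame]
    metrics: Optional[pd.DataFrame]
    manifest: dict
    truth: Optional[object] = None


def fits_to_frame(fits: Sequence[TwoStateFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        b = f.bounds
        rows.append(
            {
                "well": f.well_id, "variant": f.variant_index,
                "replicate": f.replicate_id, "batch": f.batch_id,
                "probe": f.probe, "method": f.method,
                "Tm_C": f.Tm, "dHvH_kcal": f.dH_vH, "rmse": f.rmse,
                "converged": f.converged,
                "T_low": b.T_low if b else np.nan,
                "T_high": b.T_high if b else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _load_or_simulate(config: RunConfig):
    if config.simulate is not None:
        truth = make_truth(config.simulate)
        ds_phi = generate_plate(truth, config.simulate, probe=PROBE_PHI)
        ds_theta = generate_plate(truth, config.simulate, probe=PROBE_THETA)
        return ds_phi, ds_theta, truth
    if config.plate_phi is None or config.variant_map is None:
        raise PipelineError(
            "parse", "need either a simulate block or plate_phi + variant_map"
        )
    try:
        ds_phi = parse_plate_export(
            config.plate_phi, config.variant_map, probe=PROBE_PHI
        )
        ds_theta = None
        if config.plate_theta is not None:
            ds_theta = parse_plate_export(
                config.plate_theta, config.variant_map, probe=PROBE_THETA
            )
    except (PlateIOError, OSError) as exc:
        raise PipelineError("parse", str(exc)) from exc
    return ds_phi, ds_theta, None


def _fit_stage(ds: PlateDataset, config: RunConfig) -> list[TwoStateFit]:
    method = "MODEL" if config.method == "BOTH" else config.method
    return fit_dataset(ds, method=method, seed=config.seed,
                       manual_bounds=config.manual_bounds)


def _regress(summ_fits: pd.DataFrame, probe: str,
             config: RunConfig) -> tuple[RegressionFit, pd.Series]:
    """Per-replicate OLS for one probe; returns fit + per-variant means."""
    sub = summ_fits[
        (summ_fits["probe"] == probe) & summ_fits["converged"]
    ].copy()
    if sub.empty:
        raise PipelineError("regress", f"no converged fits for probe {probe}")

    batches = sorted(sub["batch"].unique())
    if len(batches) > 1:
        means = sub.groupby(["batch", "variant"])["Tm_C"].mean()
        ref = batches[0]
        for other in batches[1:]:
            offset, _ = batch_align(means.loc[ref], means.loc[other])
            sub.loc[sub["batch"] == other, "Tm_C"] += offset
            logger.info("probe %s: batch %s aligned to %s by %+.3f deg",
                        probe, other, ref, offset)

    sub = sub.sort_values(["variant", "batch", "replicate"])
    counts = sub.groupby("variant").size()
    if set(counts.index) != set(range(16)):
        missing = sorted(set(range(16)) - set(counts.index))
        raise PipelineError(
            "regress", f"probe {probe}: variants missing after fitting: {missing}"
        )
    design = build_design_matrix(ALL_VARIANTS, coding=config.coding)
    # per-replicate rows (replicate scatter supplies the residual df)
    rows = np.repeat(design.X, counts.loc[range(16)].to_numpy(), axis=0)
    from .factorial_design import DesignMatrix  # local: keep row multiplicity

    X = DesignMatrix(X=rows, variants=tuple(
        v for v, c in zip(ALL_VARIANTS, counts.loc[range(16)]) for _ in range(c)
    ), coding=config.coding)
    y = sub["Tm_C"].to_numpy()
    fit = fit_factorial(X, y)
    if config.reduce:
        fit = reduce_model(fit, X, y, p_remove=config.p_remove,
                           p_sig=config.p_sig)
    means = sub.groupby("variant")["Tm_C"].mean()
    return fit, means


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write CSV outputs plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "outputs": {},
        "exclusions": {},
    }

    # --- parse / simulate -------------------------------------------------
    ds_phi, ds_theta, truth = _load_or_simulate(config)
    manifest["exclusions"]["parse"] = dict(ds_phi.flags)
    if ds_theta is not None:
        manifest["exclusions"]["parse_theta"] = dict(ds_theta.flags)

    # --- per-curve fitting ------------------------------------------------
    fits: list[TwoStateFit] = _fit_stage(ds_phi, config)
    if ds_theta is not None:
        fits += _fit_stage(ds_theta, config)
    fit_frame = fits_to_frame(fits)
    flagged = fit_frame[~fit_frame["converged"]]
    if not flagged.empty:
        manifest["exclusions"]["fit"] = flagged["well"].tolist()
    fit_path = outdir / "fits.csv"
    fit_frame.to_csv(fit_path, index=False, float_format=_FLOAT_FMT)
    manifest["outputs"]["fits"] = fit_path.name

    # optional model-vs-ratio comparison
    if config.method == "BOTH":
        comp = _model_vs_ratio(ds_phi, ds_theta, fit_frame, config)
        comp_path = outdir / "model_vs_ratio.csv"
        comp.to_csv(comp_path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"]["model_vs_ratio"] = comp_path.name
        manifest["max_abs_model_ratio_delta_C"] = float(
            comp["delta_C"].abs().max()
        )

    # --- replicate averaging ----------------------------------------------
    ok = [f for f in fits if f.converged]
    summary = average_replicates(ok)
    sum_path = outdir / "summary.csv"
    write_summary(summary, sum_path)
    manifest["outputs"]["summary"] = sum_path.name

    # --- three-state profiles ----------------------------------------------
    metrics_df = None
    if ds_theta is not None:
        metrics_df = _states_stage(fit_frame, config, outdir, manifest)

    # --- factorial regression + energies ------------------------------------
    try:
        fit_phi, means_phi = _regress(fit_frame, PROBE_PHI, config)
    except PipelineError:
        raise
    fit_theta = None
    energy_frame = None
    if ds_theta is not None:
        fit_theta, _ = _regress(fit_frame, PROBE_THETA, config)

    for tag, rfit in (("phi", fit_phi), ("theta", fit_theta)):
        if rfit is None:
            continue
        path = outdir / f"coefficients_{tag}.csv"
        rfit.table().to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"][f"coefficients_{tag}"] = path.name

    if fit_theta is not None:
        table = coefficients_to_energy_table(
            fit_phi, fit_theta, config.Tm0_phi, config.Tm0_theta,
            config.partition, config.scale,
        )
        energy_frame = table.frame()
        for key, val in table.provenance.items():
            energy_frame[key] = val
        e_path = outdir / "energy_table.csv"
        energy_frame.to_csv(e_path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"]["energy_table"] = e_path.name

    manifest["R2_phi"] = fit_phi.R2
    if fit_theta is not None:
        manifest["R2_theta"] = fit_theta.R2
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return RunReport(
        fits=fit_frame, summary=summary,
        coefficients_phi=fit_phi, coefficients_theta=fit_theta,
        energy_table=energy_frame, metrics=metrics_df,
        manifest=manifest, truth=truth,
    )


def _model_vs_ratio(ds_phi, ds_theta, fit_frame: pd.DataFrame,
                    config: RunConfig) -> pd.DataFrame:
    rows = []
    datasets = [ds_phi] + ([ds_theta] if ds_theta is not None else [])
    model_tm = fit_frame.set_index(["well", "probe"])["Tm_C"]
    for ds in datasets:
        for curve in ds.curves:
            key = (curve.well_id, curve.probe)
            if key not in model_tm.index or not np.isfinite(model_tm[key]):
                continue
            try:
                ratio = tm_by_ratio(curve)
            except Exception as exc:  # flagged, not fatal
                logger.info("ratio method failed for %s: %s", key, exc)
                continue
            rows.append(
                {
                    "well": curve.well_id, "probe": curve.probe,
                    "Tm_model_C": float(model_tm[key]),
                    "Tm_ratio_C": ratio,
                    "delta_C": float(model_tm[key]) - ratio,
                }
            )
    return pd.DataFrame(rows)


def _states_stage(fit_frame: pd.DataFrame, config: RunConfig, outdir: Path,
                  manifest: dict) -> pd.DataFrame:
    """Per-variant three-state profiles from replicate-mean fits."""
    ok = fit_frame[fit_frame["converged"]]
    mean_params = ok.groupby(["probe", "variant"])[["Tm_C", "dHvH_kcal"]].mean()
    grid = np.arange(25.0, 95.0 + 0.2, 0.4)
    profile_rows, metric_rows = [], []
    for variant in sorted(ok["variant"].unique()):
        try:
            phi = mean_params.loc[(PROBE_PHI, variant)]
            theta = mean_params.loc[(PROBE_THETA, variant)]
        except KeyError:
            continue
        prof = state_probabilities(
            TwoStateFit(Tm=phi["Tm_C"], dH_vH=phi["dHvH_kcal"]),
            TwoStateFit(Tm=theta["Tm_C"], dH_vH=theta["dHvH_kcal"]),
            grid,
        )
        m = profile_metrics(prof)
        metric_rows.append(
            {
                "variant": variant, "P2max": m.P2max, "T_P2max_C": m.T_P2max,
                "P1_at_P2max": m.P1_at_P2max, "P3_at_P2max": m.P3_at_P2max,
                "T_cross_C": m.T_cross if m.T_cross is not None else np.nan,
            }
        )
        profile_rows.append(
            pd.DataFrame(
                {
                    "variant": variant, "temperature_C": prof.temperatures,
                    "P1": prof.P1, "P2": prof.P2, "P3": prof.P3,
                }
            )
        )
    profiles = pd.concat(profile_rows, ignore_index=True)
    metrics = pd.DataFrame(metric_rows)
    p_path = outdir / "profiles.csv"
    m_path = outdir / "state_metrics.csv"
    profiles.to_csv(p_path, index=False, float_format=_FLOAT_FMT)
    metrics.to_csv(m_path, index=False, float_format=_FLOAT_FMT)
    manifest["outputs"]["profiles"] = p_path.name
    manifest["outputs"]["state_metrics"] = m_path.name
    return metrics
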