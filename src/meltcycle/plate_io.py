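"""Reading and writing plate-reader and CD melting exports.

The canonical in-memory form of one well's melt is a :class:`MeltCurve`:
an ordered temperature grid plus the probe signal (dye fluorescence for
DSF/Thermofluor, ellipticity for CD), tagged with the variant barcode
index, replicate number and measurement batch.  A :class:`PlateDataset`
collects the curves of one export together with acquisition metadata.

Two text dialects are accepted:

* **long** — one row per (well, temperature):
  ``well,variant,temperature_C,signal`` (the variant column is optional
  when a variant map is supplied);
* **wide** — a temperature column followed by one signal column per well,
  the usual shape of RT-PCR melt exports.

The dialect is auto-detected from the header.  Missing or non-numeric
cells cause the affected well to be flagged and excluded — values are
never interpolated, because midpoint fitting is sensitive to fabricated
points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBES = ("DSF", "CD221", "CD270", "DSC")

#: Minimum number of points for a curve to be fittable.
MIN_FIT_POINTS = 20


class PlateIOError(ValueError):
    """Fatal problem with an input table."""


@dataclass
class MeltCurve:
    """One well's temperature/signal trace.

    ``temperatures`` must be strictly increasing with no missing values in
    ``signals``; construction fails otherwise.  Short curves (< 20 points)
    are representable — the fitting layer enforces its own minimum.
    """

    well_id: str
    variant_index: int
    replicate_id: int
    batch_id: str
    probe: str
    temperatures: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.temperatures.shape != self.signals.shape:
            raise PlateIOError(
                f"well {self.well_id}: temperature/signal length mismatch"
            )
        if self.temperatures.size < 2:
            raise PlateIOError(f"well {self.well_id}: fewer than 2 points")
        if np.any(~np.isfinite(self.temperatures)) or np.any(
            ~np.isfinite(self.signals)
        ):
            raise PlateIOError(f"well {self.well_id}: non-finite values")
        if np.any(np.diff(self.temperatures) <= 0):
            raise PlateIOError(
                f"well {self.well_id}: temperatures not strictly increasing"
            )
        if self.probe not in PROBES:
            raise PlateIOError(f"unknown probe {self.probe!r}")

    def __len__(self) -> int:
        return int(self.temperatures.size)

    def sorted_copy(self, **overrides) -> "MeltCurve":
        """Return a copy re-sorted by ascending temperature."""
        order = np.argsort(self.temperatures, kind="stable")
        kw = dict(
            well_id=self.well_id,
            variant_index=self.variant_index,
            replicate_id=self.replicate_id,
            batch_id=self.batch_id,
            probe=self.probe,
            temperatures=self.temperatures[order],
            signals=self.signals[order],
        )
        kw.update(overrides)
        return MeltCurve(**kw)


@dataclass
class PlateDataset:
    """A collection of melt curves from one export.

    ``flags`` records wells excluded during ingestion, keyed by well id,
    with a human-readable reason.
    """

    curves: list[MeltCurve]
    metadata: dict = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.curves:
            key = (c.well_id, c.probe)
            if key in seen:
                raise PlateIOError(f"duplicate (well, probe) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.curves)

    def by_variant(self) -> dict[int, list[MeltCurve]]:
        out: dict[int, list[MeltCurve]] = {}
        for c in self.curves:
            out.setdefault(c.variant_index, []).append(c)
        return out


# ---------------------------------------------------------------------------
# variant maps
# ---------------------------------------------------------------------------

def read_variant_map(source) -> pd.DataFrame:
    """Load a well → (variant_index, replicate, batch) assignment table.

    Accepts a CSV path or an equivalent DataFrame with columns
    ``well,variant_index,replicate,batch``.
    """
    if isinstance(source, pd.DataFrame):
        vm = source.copy()
    else:
        vm = pd.read_csv(source)
    required = {"well", "variant_index", "replicate", "batch"}
    missing = required - set(vm.columns)
    if missing:
        raise PlateIOError(f"variant map missing columns: {sorted(missing)}")
    vm["well"] = vm["well"].astype(str)
    if vm["well"].duplicated().any():
        raise PlateIOError("variant map contains duplicate wells")
    return vm.set_index("well")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _detect_dialect(columns: Sequence[str]) -> str:
    cols = {str(c).strip().lower() for c in columns}
    if "signal" in cols and ("temperature_c" in cols or "temperature" in cols):
        return "long"
    return "wide"


def _temperature_column(df: pd.DataFrame) -> str:
    for cand in df.columns:
        if str(cand).strip().lower() in ("temperature_c", "temperature", "temp_c"):
            return cand
    raise PlateIOError("no temperature column found")


def parse_plate_export(file, variant_map, probe: str = "DSF") -> PlateDataset:
    """Read a plate melt export (long or wide dialect) into a dataset.

    Wells absent from the variant map are reported and excluded; wells with
    missing or non-numeric cells are flagged and excluded.  Duplicate
    (well, temperature) records are fatal.
    """
    path = Path(file)
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PlateIOError(f"unreadable plate export {path}: {exc}") from exc
    vm = read_variant_map(variant_map)
    dialect = _detect_dialect(raw.columns)
    logger.debug("parsed %s as %s dialect", path, dialect)

    flags: dict[str, str] = {}
    curves: list[MeltCurve] = []

    if dialect == "long":
        tcol = _temperature_column(raw)
        groups = raw.groupby(raw["well"].astype(str), sort=True)
        per_well = {w: (g[tcol], g["signal"]) for w, g in groups}
    else:
        tcol = _temperature_column(raw)
        per_well = {
            str(col): (raw[tcol], raw[col]) for col in raw.columns if col != tcol
        }

    for well, (traw, sraw) in sorted(per_well.items()):
        t = pd.to_numeric(traw, errors="coerce").to_numpy()
        s = pd.to_numeric(sraw, errors="coerce").to_numpy()
        if np.any(~np.isfinite(t)):
            raise PlateIOError(f"well {well}: non-numeric temperature cell")
        if np.any(~np.isfinite(s)):
            flags[well] = "missing or non-numeric signal cell"
            logger.info("flagged well %s: %s", well, flags[well])
            continue
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        if np.any(np.diff(t) == 0):
            raise PlateIOError(f"well {well}: duplicate (well, temperature) record")
        if well not in vm.index:
            flags[well] = "well not present in variant map"
            logger.info("excluded unmapped well %s", well)
            continue
        row = vm.loc[well]
        curves.append(
            MeltCurve(
                well_id=well,
                variant_index=int(row["variant_index"]),
                replicate_id=int(row["replicate"]),
                batch_id=str(row["batch"]),
                probe=probe,
                temperatures=t,
                signals=s,
            )
        )

    meta = {"source": str(path), "probe": probe, "dialect": dialect}
    if curves:
        steps = np.diff(curves[0].temperatures)
        meta["step_C"] = float(np.median(steps))
    return PlateDataset(curves=curves, metadata=meta, flags=flags)


def parse_cd_scan(file, probe: str, variant_index: int,
                  replicate_id: int = 1, batch_id: str = "cd") -> MeltCurve:
    """Read a two-column temperature/ellipticity thermal scan.

    Descending scans are re-sorted ascending with a warning; duplicated
    temperatures and scans shorter than 20 points are fatal.
    """
    if probe not in ("CD221", "CD270"):
        raise PlateIOError(f"CD probe must be CD221 or CD270, got {probe!r}")
    path = Path(file)
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PlateIOError(f"unreadable CD scan {path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise PlateIOError(f"{path}: expected two columns")
    t = pd.to_numeric(raw.iloc[:, 0], errors="coerce").to_numpy()
    s = pd.to_numeric(raw.iloc[:, 1], errors="coerce").to_numpy()
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(s)):
        raise PlateIOError(f"{path}: non-numeric cells in CD scan")
    if t.size < MIN_FIT_POINTS:
        raise PlateIOError(
            f"{path}: only {t.size} points; at least {MIN_FIT_POINTS} required"
        )
    if np.all(np.diff(t) < 0):
        logger.warning("%s: descending temperature scan re-sorted ascending", path)
        t, s = t[::-1], s[::-1]
    if np.any(np.diff(t) <= 0):
        raise PlateIOError(f"{path}: non-monotone or duplicated temperatures")
    return MeltCurve(
        well_id=path.stem,
        variant_index=int(variant_index),
        replicate_id=replicate_id,
        batch_id=batch_id,
        probe=probe,
        temperatures=t,
        signals=s,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # >= 10 significant digits so round trips are lossless


def write_plate(dataset: PlateDataset, path) -> Path:
    """Write a dataset as a long-format plate CSV (lossless round trip)."""
    rows = []
    for c in dataset.curves:
        rows.append(
            pd.DataFrame(
                {
                    "well": c.well_id,
                    "variant": c.variant_index,
                    "temperature_C": c.temperatures,
                    "signal": c.signals,
                }
            )
        )
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def write_variant_map(dataset: PlateDataset, path) -> Path:
    rows = [
        {
            "well": c.well_id,
            "variant_index": c.variant_index,
            "replicate": c.replicate_id,
            "batch": c.batch_id,
        }
        for c in dataset.curves
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# replicate summaries
# ---------------------------------------------------------------------------

def average_replicates(fits: Iterable) -> pd.DataFrame:
    """Average replicate melting temperatures per (variant, probe).

    ``fits`` is a collection of :class:`~meltcycle.melt_fit.TwoStateFit`
    carrying variant/probe labels (or any objects with ``variant_index``,
    ``probe``, ``Tm`` and ``converged`` attributes).  Non-converged fits
    are excluded.  Groups of size 1 report SD/SE as NaN; empty groups are
    dropped with a warning.

    Returns a DataFrame with columns
    ``variant,probe,n,Tm_mean_C,Tm_sd_C,Tm_se_C``.
    """
    records = []
    for f in fits:
        if not getattr(f, "converged", True):
            logger.warning(
                "excluding non-converged fit for variant %s", f.variant_index
            )
            continue
        records.append(
            {"variant": f.variant_index, "probe": f.probe, "Tm": float(f.Tm)}
        )
    if not records:
        raise PlateIOError("no converged fits to average")
    df = pd.DataFrame(records)
    out = (
        df.groupby(["variant", "probe"])["Tm"]
        .agg(n="size", Tm_mean_C="mean", Tm_sd_C=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out["Tm_se_C"] = out["Tm_sd_C"] / np.sqrt(out["n"])
    return out


def write_summary(summary: pd.DataFrame, path) -> Path:
    path = Path(path)
    summary.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
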