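"""File formats: sensor CSV dialects, motion/Ct tables, TIFF stacks, JSON.

Canonical on-disk formats:

* flow trace CSV, header ``time_s,flow_ul_min`` (seconds, µL/min);
* motion trace CSV, header ``frame,magnitude_px``;
* Ct table CSV, header ``group,gene,replicate,ct``;
* per-beat CSV and fold-change CSV as written by the CLI;
* metrics / drug-response JSON;
* multi-page TIFF (8-bit grayscale) for videos.

Vendor flow-sensor exports vary, so parsing goes through an explicit
`SensorCsvDialect`: delimiter, decimal mark, column names or indices, time
and flow units, and header rows are configuration, converted to the
canonical units (s, µL/min) at the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError, FormatError, ParameterError
from .flowmetrics import RecordingMetrics
from .synth import VentricleSimParams
from .traces import FlowTrace, MotionTrace

logger = logging.getLogger("ventriflow")

__all__ = [
    "SensorCsvDialect",
    "read_flow_csv",
    "write_flow_csv",
    "read_motion_csv",
    "write_motion_csv",
    "read_ct_csv",
    "write_ct_csv",
    "read_tiff_stack",
    "write_tiff_stack",
    "write_metrics_json",
    "read_metrics_json",
    "load_sim_params",
]

_TIME_ALIASES = ("time_s", "time", "t", "timestamp")
_FLOW_ALIASES = ("flow_ul_min", "flow", "q", "flow_rate")

_TIME_SCALE = {"s": 1.0, "ms": 1e-3}
_FLOW_SCALE = {"uL/min": 1.0, "µL/min": 1.0, "ul/min": 1.0, "mL/min": 1e3,
               "ml/min": 1e3}

#: Timestamp jitter (relative to the median interval) above which the trace
#: is resampled onto a uniform grid.
_JITTER_TOL = 0.01


@dataclass(frozen=True)
class SensorCsvDialect:
    """How to read a flow-sensor CSV export.

    ``time_column``/``flow_column`` may be header names, integer positions,
    or None to auto-resolve among common aliases (``time_s``/``time``,
    ``flow_ul_min``/``flow``). Declared units are converted to the canonical
    seconds and µL/min on read.
    """

    delimiter: str = ","
    decimal: str = "."
    time_column: str | int | None = None
    flow_column: str | int | None = None
    time_units: str = "s"
    flow_units: str = "uL/min"
    header_rows: int = 1

    def __post_init__(self) -> None:
        if self.time_units not in _TIME_SCALE:
            raise ParameterError(
                f"time_units must be one of {sorted(_TIME_SCALE)}"
            )
        if self.flow_units not in _FLOW_SCALE:
            raise ParameterError(
                f"flow_units must be one of {sorted(set(_FLOW_SCALE))}"
            )
        if self.header_rows < 0:
            raise ParameterError("header_rows must be >= 0")


def _resolve_column(
    df: pd.DataFrame, spec: str | int | None, aliases: tuple[str, ...],
    what: str,
) -> pd.Series:
    if isinstance(spec, int):
        if spec >= df.shape[1]:
            raise FormatError(
                f"{what} column index {spec} out of range; file has "
                f"{df.shape[1]} columns"
            )
        return df.iloc[:, spec]
    if isinstance(spec, str):
        if spec not in df.columns:
            raise FormatError(
                f"{what} column {spec!r} not found; available headers: "
                f"{list(df.columns)}"
            )
        return df[spec]
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for alias in aliases:
        if alias in lowered:
            return df[lowered[alias]]
    raise FormatError(
        f"could not auto-resolve the {what} column; available headers: "
        f"{list(df.columns)}"
    )


def read_flow_csv(
    path: str | Path, dialect: SensorCsvDialect | None = None
) -> FlowTrace:
    """Parse a sensor CSV export into a canonical FlowTrace.

    Non-finite rows are dropped (count logged); if timestamp jitter exceeds
    1% of the median sampling interval the trace is resampled onto a uniform
    grid by linear interpolation, recorded in ``metadata['resampled']``.
    """
    dialect = dialect or SensorCsvDialect()
    path = Path(path)
    header = 0 if dialect.header_rows > 0 else None
    skip = dialect.header_rows - 1 if dialect.header_rows > 1 else 0
    try:
        df = pd.read_csv(
            path, sep=dialect.delimiter, decimal=dialect.decimal,
            header=header, skiprows=skip,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    t_raw = pd.to_numeric(
        _resolve_column(df, dialect.time_column, _TIME_ALIASES, "time"),
        errors="coerce",
    ).to_numpy()
    q_raw = pd.to_numeric(
        _resolve_column(df, dialect.flow_column, _FLOW_ALIASES, "flow"),
        errors="coerce",
    ).to_numpy()
    finite = np.isfinite(t_raw) & np.isfinite(q_raw)
    n_dropped = int(np.sum(~finite))
    if n_dropped:
        logger.warning("dropped %d non-finite row(s) from %s", n_dropped, path)
    t = t_raw[finite] * _TIME_SCALE[dialect.time_units]
    q = q_raw[finite] * _FLOW_SCALE[dialect.flow_units]
    if len(t) < 2:
        raise DataError(f"{path} holds fewer than 2 valid samples")
    order = np.argsort(t, kind="stable")
    t, q = t[order], q[order]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path} has duplicate timestamps")
    med_dt = float(np.median(dt))
    meta: dict[str, Any] = {"source": str(path), "dropped_rows": n_dropped}
    if np.max(np.abs(dt - med_dt)) > _JITTER_TOL * med_dt:
        n_uniform = int(np.floor((t[-1] - t[0]) / med_dt)) + 1
        t_new = t[0] + np.arange(n_uniform) * med_dt
        q = np.interp(t_new, t, q)
        t = t_new
        meta["resampled"] = True
        logger.info("resampled %s onto a uniform %.6g s grid", path, med_dt)
    else:
        # snap to an exactly uniform grid so FlowTrace's 1 ns check holds
        t = t[0] + np.arange(len(t)) * med_dt
    return FlowTrace(t=t, q=q, sample_rate=1.0 / med_dt, metadata=meta)


def write_flow_csv(trace: FlowTrace, path: str | Path) -> None:
    """Write the canonical two-column flow CSV (``time_s,flow_ul_min``)."""
    pd.DataFrame({"time_s": trace.t, "flow_ul_min": trace.q}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_motion_csv(motion: MotionTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": motion.frame_index, "magnitude_px": motion.magnitude}
    ).to_csv(path, index=False, float_format="%.12g")


def read_motion_csv(
    path: str | Path, fps: float, frame_offset: int = 1
) -> MotionTrace:
    """Read a ``frame,magnitude_px`` CSV; fps is not stored in the file."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("frame", "magnitude_px"):
        if col not in df.columns:
            raise FormatError(
                f"{path} lacks column {col!r}; headers: {list(df.columns)}"
            )
    return MotionTrace(
        frame_index=df["frame"].to_numpy(),
        magnitude=df["magnitude_px"].to_numpy(),
        fps=fps,
        frame_offset=frame_offset,
        metadata={"source": str(path)},
    )


def read_ct_csv(
    path: str | Path, housekeeping_gene: str | None = None
) -> pd.DataFrame:
    """Read a tidy ``group,gene,replicate,ct`` table."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ("group", "gene", "replicate", "ct")
               if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path} lacks columns {missing}; headers: {list(df.columns)}"
        )
    if housekeeping_gene:
        df.attrs["housekeeping_gene"] = housekeeping_gene
    return df


def write_ct_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_tiff_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a (n, h, w) array."""
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3:
        raise DataError(f"{path} is not a grayscale stack (ndim={frames.ndim})")
    return frames


def write_tiff_stack(frames: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(frames), photometric="minisblack")


def write_metrics_json(
    metrics: RecordingMetrics, path: str | Path, **extra: Any
) -> None:
    payload = {**metrics.to_dict(), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metrics_json(path: str | Path) -> RecordingMetrics:
    payload = json.loads(Path(path).read_text())
    try:
        return RecordingMetrics(
            frequency=payload["frequency"],
            mean_stroke_volume=payload["mean_stroke_volume"],
            theoretical_cardiac_output=payload["theoretical_cardiac_output"],
            max_volume_flow=payload["max_volume_flow"],
            n_beats=payload["n_beats"],
        )
    except KeyError as exc:
        raise FormatError(f"{path} lacks metrics key {exc}") from exc


def load_sim_params(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON simulation config.

    The ``flow`` block mirrors `VentricleSimParams` field names one-to-one;
    optional ``motion`` and ``ct`` blocks mirror the corresponding generator
    signatures. A flat file of VentricleSimParams fields is treated as a
    bare ``flow`` block.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path} does not hold a mapping")
    known = set(VentricleSimParams.__dataclass_fields__)
    if "flow" not in cfg and set(cfg) <= known:
        cfg = {"flow": cfg}
    return cfg
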