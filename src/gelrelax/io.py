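"""Instrument-trace and configuration I/O.

A low-load compression tester records three channels while a plunger is
lowered onto a gel: time (s), plunger position (μm, increasing toward the
glass slide) and force. Exported files are delimited text with a header row;
the force unit varies by instrument dialect (mg-load, mN or N) and is
declared in the experiment configuration. All forces are converted to
newtons on load; everything downstream works in SI and converts to the
reporting units (kPa, μm, mg) only at the edges.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError, FormatError, TraceValidationError

STANDARD_GRAVITY = 9.80665  # m/s^2, for mg-load <-> newton conversion

ForceUnit = Literal["mg", "mN", "N"]

# Case-insensitive column aliases; instrument export dialects vary.
TIME_ALIASES = ("time_s", "time", "t_s", "t")
POSITION_ALIASES = ("position_um", "position", "pos_um", "pos", "z_um", "z")
FORCE_ALIASES = ("force", "force_mg", "force_mn", "force_n", "load", "f")


class ExperimentConfig(BaseModel):
    """Protocol and instrument parameters of a stress-relaxation run.

    Defaults reproduce the low-load compression protocol used for
    adipose-ECM hydrogels: a 0.25-cm stainless-steel plunger approaches at
    5 μm/s, contact is declared at a 10 mg touch load, the gel (cast in an
    0.8-mm ring) is compressed by 20% and the strain is held for 100 s.
    """

    plunger_diameter_cm: float = Field(default=0.25, gt=0)
    approach_speed_um_s: float = Field(default=5.0, gt=0)
    ramp_speed_um_s: float | None = Field(default=None, gt=0)  # None -> approach speed
    touch_load_mg: float = Field(default=10.0, gt=0)
    deformation_fraction: float = Field(default=0.20, gt=0, lt=1)
    hold_duration_s: float = Field(default=100.0, gt=0)
    force_unit: ForceUnit = "mg"
    gravity_m_s2: float = Field(default=STANDARD_GRAVITY, gt=0)
    ring_height_um: float = Field(default=800.0, gt=0)
    sampling_rate_hz: float = Field(default=10.0, gt=0)
    contact_debounce_n: int = Field(default=5, ge=1)
    # Slack when deciding that plunger travel has reached the ramp target;
    # absorbs float round-off only — traces whose position channel plateaus
    # short of the target are handled by the plateau fallback in preprocess.
    ramp_end_tol_um: float = Field(default=1e-6, ge=0)

    @model_validator(mode="after")
    def _default_ramp_speed(self) -> "ExperimentConfig":
        if self.ramp_speed_um_s is None:
            object.__setattr__(self, "ramp_speed_um_s", self.approach_speed_um_s)
        return self

    @property
    def plunger_area_m2(self) -> float:
        d_m = self.plunger_diameter_cm * 1e-2
        return math.pi * (d_m / 2.0) ** 2

    @property
    def touch_load_n(self) -> float:
        return self.force_to_newtons(self.touch_load_mg, unit="mg")

    def force_to_newtons(self, value, unit: ForceUnit | None = None):
        """Convert force values in the declared (or given) unit to newtons."""
        unit = unit or self.force_unit
        if unit == "mg":
            return np.asarray(value, dtype=float) * (1e-6 * self.gravity_m_s2)
        if unit == "mN":
            return np.asarray(value, dtype=float) * 1e-3
        if unit == "N":
            return np.asarray(value, dtype=float) * 1.0
        raise ConfigError(f"unknown force unit {unit!r}")

    def newtons_to(self, value, unit: ForceUnit | None = None):
        """Inverse of :meth:`force_to_newtons`; involutive to round-off."""
        unit = unit or self.force_unit
        if unit == "mg":
            return np.asarray(value, dtype=float) / (1e-6 * self.gravity_m_s2)
        if unit == "mN":
            return np.asarray(value, dtype=float) * 1e3
        if unit == "N":
            return np.asarray(value, dtype=float) * 1.0
        raise ConfigError(f"unknown force unit {unit!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
        try:
            return cls(**payload)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigError(f"invalid experiment config {path}: {exc}") from exc


@dataclasses.dataclass
class RawTrace:
    """A sampled instrument record with force already converted to newtons."""

    time_s: np.ndarray
    position_um: np.ndarray
    force_n: np.ndarray
    sample_id: str = ""
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        n = self.time_s.size
        if not (self.position_um.size == n and self.force_n.size == n):
            raise TraceValidationError("time/position/force lengths differ")
        if n < 2:
            raise TraceValidationError("trace needs at least 2 samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise TraceValidationError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force_n)):
            raise TraceValidationError("force contains non-finite values")
        if not np.all(np.isfinite(self.position_um)):
            raise TraceValidationError("position contains non-finite values")

    def __len__(self) -> int:
        return int(self.time_s.size)


def _resolve_column(columns: list[str], aliases: tuple[str, ...], what: str) -> str:
    lower = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    raise FormatError(f"no {what} column found (accepted names: {', '.join(aliases)})")


def read_trace(path: str | Path, config: ExperimentConfig) -> RawTrace:
    """Read a delimited trace file, converting force to newtons.

    The delimiter (comma or tab) is auto-detected from the header line.
    Column matching is case-insensitive against a short alias list.
    """
    path = Path(path)
    header = path.open().readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    tcol = _resolve_column(list(df.columns), TIME_ALIASES, "time")
    pcol = _resolve_column(list(df.columns), POSITION_ALIASES, "position")
    fcol = _resolve_column(list(df.columns), FORCE_ALIASES, "force")
    return RawTrace(
        time_s=df[tcol].to_numpy(dtype=float),
        position_um=df[pcol].to_numpy(dtype=float),
        force_n=config.force_to_newtons(df[fcol].to_numpy(dtype=float)),
        sample_id=path.stem,
    )


def write_trace(trace: RawTrace, path: str | Path, config: ExperimentConfig) -> None:
    """Write a trace as CSV in the config's declared force unit."""
    unit_suffix = {"mg": "force_mg", "mN": "force_mn", "N": "force_n"}[config.force_unit]
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "position_um": trace.position_um,
            unit_suffix: config.newtons_to(trace.force_n),
        }
    )
    df.to_csv(path, index=False)


def to_jsonable(obj: Any) -> Any:
    """Recursively convert pipeline objects to JSON-serialisable structures."""
    if isinstance(obj, BaseModel):
        return to_jsonable(obj.model_dump())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def write_results(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialise pipeline output to JSON or CSV.

    JSON accepts any dataclass/dict/list tree; CSV requires tabular input
    (a DataFrame or a list of flat records). Round-trip safe: integers and
    strings exactly, reals to better than 1e-12 relative (repr precision).
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(to_jsonable(results), indent=2) + "\n")
    elif format == "csv":
        if isinstance(results, pd.DataFrame):
            df = results
        else:
            records = to_jsonable(results)
            if records == [] or records is None:
                df = pd.DataFrame()
            elif isinstance(records, list) and all(isinstance(r, dict) for r in records):
                df = pd.DataFrame.from_records(records)
            else:
                raise FormatError("CSV output requires tabular results")
        df.to_csv(path, index=False)
    else:
        raise ConfigError(f"unknown result format {format!r}")


def read_results(path: str | Path) -> Any:
    """Read back a JSON or CSV result file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    return json.loads(path.read_text())
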