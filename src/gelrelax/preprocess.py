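"""Contact detection, phase segmentation and stress/strain conversion.

The plunger approaches the gel until the force exceeds the touch load
(10 mg by default), which defines the touch position; gel thickness is the
difference between the top-of-slide position (a calibration input measured
from a blank run) and the touch position. The trace is then segmented into
approach / ramp / hold (and trailing post) phases; force divided by the
plunger cross-section gives stress and plunger travel divided by thickness
gives engineering compression strain.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import (
    ContactNotFoundError,
    GeometryError,
    GelRelaxError,
    TruncatedTraceError,
)
from .io import ExperimentConfig, RawTrace

PHASES = ("approach", "ramp", "hold", "post")


@dataclasses.dataclass
class ContactEvent:
    """First sustained touch-load crossing and the geometry it implies."""

    index: int
    touch_time_s: float
    touch_position_um: float
    slide_position_um: float
    thickness_um: float


@dataclasses.dataclass
class StressStrainTrace:
    """Phase-labelled trace in stress (Pa) / strain (dimensionless) space."""

    time_s: np.ndarray
    stress_pa: np.ndarray
    strain: np.ndarray
    phase: np.ndarray  # str array, values in PHASES
    truncated: bool = False

    def select(self, phase: str) -> "StressStrainTrace":
        m = self.phase == phase
        return StressStrainTrace(
            self.time_s[m], self.stress_pa[m], self.strain[m], self.phase[m], self.truncated
        )

    def __len__(self) -> int:
        return int(self.time_s.size)


def to_stress(force_n, config: ExperimentConfig):
    """Force (N) -> stress (Pa): divide by the plunger cross-section area."""
    return np.asarray(force_n, dtype=float) / config.plunger_area_m2


def to_strain(deformation_percent) -> float:
    """Deformation in percent -> engineering strain (deformation/100)."""
    d = float(deformation_percent)
    if not 0.0 <= d <= 100.0:
        raise GelRelaxError(f"deformation percent {d} outside [0, 100]")
    return d / 100.0


def detect_contact(
    trace: RawTrace, config: ExperimentConfig, slide_position_um: float
) -> ContactEvent:
    """Find the first index where force stays >= touch load for debounce_n samples.

    The debounce requirement rejects isolated noise spikes in the force
    channel; with the default of 5 consecutive samples, Gaussian noise well
    below the threshold essentially never fires.
    """
    thr = config.touch_load_n
    above = trace.force_n >= thr
    n = config.contact_debounce_n
    if above.size >= n:
        # window[k] == n  <=>  samples k .. k+n-1 all above threshold
        window = np.convolve(above.astype(int), np.ones(n, dtype=int), mode="valid")
        hits = np.nonzero(window == n)[0]
    else:
        hits = np.array([], dtype=int)
    if hits.size == 0:
        raise ContactNotFoundError(
            f"no sustained crossing of touch load {config.touch_load_mg} mg "
            f"({thr:.3e} N) over {n} samples"
        )
    idx = int(hits[0])
    touch_pos = float(trace.position_um[idx])
    thickness = float(slide_position_um) - touch_pos
    if thickness < 0:
        raise GeometryError(
            f"touch position {touch_pos:.1f} um lies beyond the slide at "
            f"{slide_position_um:.1f} um"
        )
    return ContactEvent(
        index=idx,
        touch_time_s=float(trace.time_s[idx]),
        touch_position_um=touch_pos,
        slide_position_um=float(slide_position_um),
        thickness_um=thickness,
    )


def segment_phases(
    trace: RawTrace, contact: ContactEvent, config: ExperimentConfig
) -> StressStrainTrace:
    """Label every sample approach/ramp/hold/post and convert to stress-strain.

    The ramp runs from contact until plunger travel past the touch position
    reaches deformation_fraction x thickness (within ``ramp_end_tol_um`` to
    absorb position-channel discretisation). The hold is the following
    ``hold_duration_s`` seconds at constant strain; per the protocol the
    hold strain is taken as exactly the target deformation fraction.

    Raises :class:`TruncatedTraceError` (carrying the partial result) when
    the record ends before the hold completes.
    """
    t = trace.time_s
    stress = to_stress(trace.force_n, config)
    travel = trace.position_um - contact.touch_position_um
    target = config.deformation_fraction * contact.thickness_um

    phase = np.full(t.size, "approach", dtype=object)
    strain = np.zeros(t.size)

    after = np.arange(t.size) >= contact.index
    reached = after & (travel >= target - config.ramp_end_tol_um)
    if reached.any():
        hold_start = int(np.nonzero(reached)[0][0])
    else:
        # position channel plateaued short of the target (servo/quantisation):
        # hold starts where the plunger first parks at its deepest position
        deepest = after & (trace.position_um >= trace.position_um[after].max() - 1e-9)
        hold_start = int(np.nonzero(deepest)[0][0])
        if hold_start >= t.size - 1:
            raise TruncatedTraceError("trace ends before the ramp reaches target deformation")

    ramp = after & (np.arange(t.size) < hold_start)
    phase[ramp] = "ramp"
    strain[ramp] = np.clip(travel[ramp] / contact.thickness_um, 0.0, config.deformation_fraction)

    hold_end_t = t[hold_start] + config.hold_duration_s
    dt = float(np.median(np.diff(t)))
    in_hold = (np.arange(t.size) >= hold_start) & (t <= hold_end_t + dt / 2)
    phase[in_hold] = "hold"
    strain[in_hold] = config.deformation_fraction
    post = np.arange(t.size) >= np.nonzero(in_hold)[0][-1] + 1
    phase[post] = "post"
    strain[post] = config.deformation_fraction

    out = StressStrainTrace(t, stress, strain, np.asarray(phase, dtype=object))
    if t[-1] < hold_end_t - dt / 2:
        out.truncated = True
        held = t[-1] - t[hold_start]
        raise TruncatedTraceError(
            f"trace ends {config.hold_duration_s - held:.1f} s before the hold completes "
            f"({held:.1f} s of hold recorded)",
            partial=out,
        )
    return out
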