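"""Stiffness and relaxation extraction.

Instantaneous stiffness E is the ordinary least-squares slope of the
stress-strain line over the compression ramp. During the constant-strain
hold the stress relaxes; dividing relaxing stress by the (constant) hold
strain gives the relaxing stiffness E(t), and the percentage drop of E(t)
over the hold is the total relaxation. Stiffness is reported in kPa, the
unit used for soft ECM hydrogels; stress stays in Pa internally.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .errors import DegenerateRampError, GelRelaxError, UndefinedRelaxationError
from .preprocess import StressStrainTrace


@dataclasses.dataclass
class StiffnessResult:
    E_kpa: float
    intercept_kpa: float
    r2: float
    n_points: int


@dataclasses.dataclass
class RelaxationCurve:
    """Relaxing stiffness over the hold, time zeroed at hold start."""

    t_s: np.ndarray
    Et_kpa: np.ndarray
    strain0: float

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.Et_kpa = np.asarray(self.Et_kpa, dtype=float)
        if self.t_s.size != self.Et_kpa.size:
            raise GelRelaxError("t and Et lengths differ")
        if self.strain0 <= 0:
            raise GelRelaxError("hold strain must be positive")

    def __len__(self) -> int:
        return int(self.t_s.size)


def fit_stiffness(sst: StressStrainTrace, include_intercept: bool = True) -> StiffnessResult:
    """OLS slope of stress vs strain over the ramp, in kPa.

    The intercept is fitted by default so a touch-load offset in the force
    channel does not bias the slope; a through-origin fit is available.
    """
    ramp = sst.select("ramp") if not np.all(sst.phase == "ramp") else sst
    x = ramp.strain
    y = ramp.stress_pa / 1000.0  # kPa
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateRampError("ramp has fewer than 2 distinct strain values")
    if include_intercept:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        ss_res = float(np.sum((y - slope * x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StiffnessResult(E_kpa=slope, intercept_kpa=intercept, r2=r2, n_points=int(x.size))


def relaxing_stiffness(sst: StressStrainTrace) -> RelaxationCurve:
    """E(t) = relaxing stress / constant hold strain, time rebased to hold start."""
    hold = sst.select("hold") if not np.all(sst.phase == "hold") else sst
    if len(hold) == 0:
        raise GelRelaxError("no hold samples")
    strain0 = float(hold.strain[0])
    if strain0 <= 0:
        raise UndefinedRelaxationError("hold strain is zero; E(t) undefined")
    return RelaxationCurve(
        t_s=hold.time_s - hold.time_s[0],
        Et_kpa=hold.stress_pa / strain0 / 1000.0,
        strain0=strain0,
    )


def total_relaxation(curve: RelaxationCurve) -> float:
    """Percent drop of E(t) from hold start to hold end: 100*(E0 - Eend)/E0."""
    e0 = float(curve.Et_kpa[0])
    if e0 <= 0:
        raise UndefinedRelaxationError("initial relaxing stiffness is non-positive")
    return 100.0 * (e0 - float(curve.Et_kpa[-1])) / e0
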