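"""Forward simulation of the low-load compression experiment.

Generates instrument traces with known ground truth so that every pipeline
stage — contact detection, segmentation, stiffness, Prony fitting, QC,
aggregation — can be tested by parameter recovery. The simulated plunger
approaches at the configured speed, touches the gel (the force channel
registers at least the touch load from the moment of geometric contact,
then grows elastically with the instantaneous modulus during the ramp),
and the hold-phase force follows the gel's Prony series at constant strain:

    F(t) = A * strain0 * (E_inf + sum_i E_i exp(-t/tau_i))

with additive Gaussian stress noise. The ramp material response is
idealised as elastic loading at E(0); the relaxation clock starts at hold
start. An optional collapse mode forces the hold force to decay to baseline
with a 0.2-s time constant after ``collapse_time_s`` — a minimal stand-in
for gel failure that exercises QC flagging, not a physical failure model.
"""

from __future__ import annotations

import string

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import GelRelaxError
from .io import ExperimentConfig, RawTrace
from .maxwell import MaxwellElement

APPROACH_CLEARANCE_UM = 50.0  # plunger starts this far above the gel surface
COLLAPSE_TAU_S = 0.2


class SyntheticGelSpec(BaseModel):
    """Ground-truth material, geometry and noise parameters of one gel."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    elements: list[MaxwellElement]
    E_inf_kpa: float = Field(default=0.0, ge=0)
    thickness_um: float = Field(default=800.0, gt=0)
    noise_sigma: float = Field(default=0.01, ge=0)  # fraction of E(0)
    collapse_time_s: float | None = Field(default=None, gt=0)
    seed: int = 0
    sample_id: str = "SIM"

    @property
    def e0_kpa(self) -> float:
        """Instantaneous stiffness E(0) = E_inf + sum E_i."""
        return self.E_inf_kpa + sum(el.E_kpa for el in self.elements)

    def et_kpa(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.E_inf_kpa)
        for el in self.elements:
            out = out + el.E_kpa * np.exp(-t / el.tau_s)
        return out


class CohortSpec(BaseModel):
    """Hierarchical cohort layout mirroring the donor/pregel/replicate design.

    Per the study design, each donor contributes three pregel solutions
    measured in duplicate. Element stiffnesses vary normally (truncated at
    zero) and time constants log-normally around the group template; donors
    carry the largest share of the variation, pregels less, replicates the
    least — emulating the large intradonor (pregel-to-pregel) spread seen
    in these gels.
    """

    group: str = "NAM"  # "NAM"-like (stable) or "DAM"-like (collapsing)
    n_donors: int = Field(default=3, ge=1)
    n_pregels_per_donor: int = Field(default=3, ge=1)
    replicates: int = Field(default=2, ge=1)
    # template elements: (mean E [kPa], median tau [s]) per element
    template: list[tuple[float, float]] = [(1.2, 0.4), (0.5, 4.0)]
    third_element: tuple[float, float] | None = (0.25, 30.0)
    third_element_prob: float = Field(default=0.3, ge=0, le=1)
    e_cv: float = Field(default=0.25, ge=0)  # donor-level coefficient of variation on E
    tau_sigma_log: float = Field(default=0.3, ge=0)  # donor-level log-sd on tau
    pregel_scale: float = Field(default=0.6, ge=0)  # pregel variation vs donor variation
    replicate_scale: float = Field(default=0.2, ge=0)
    noise_sigma: float = Field(default=0.01, ge=0)
    collapse: bool | None = None  # None -> True iff group starts with "DAM"
    collapse_window_s: tuple[float, float] = (1.0, 6.0)
    thickness_um: float = Field(default=800.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _default_collapse(self) -> "CohortSpec":
        if self.collapse is None:
            object.__setattr__(self, "collapse", self.group.upper().startswith("DAM"))
        return self


def simulate_trace(
    gel: SyntheticGelSpec, config: ExperimentConfig, seed: int | None = None
) -> RawTrace:
    """Simulate one full instrument trace (approach + ramp + hold).

    Deterministic for a given gel seed. The approach clearance and speeds
    are chosen so that geometric contact falls exactly on a sample, keeping
    noiseless thickness recovery exact to the position step.
    """
    rng = np.random.default_rng(gel.seed if seed is None else seed)
    dt = 1.0 / config.sampling_rate_hz
    v_app = config.approach_speed_um_s
    v_ramp = config.ramp_speed_um_s or v_app

    # phase boundaries on the sampling grid (geometric contact snaps onto a
    # sample so noiseless thickness recovery is exact)
    i_contact = int(round(APPROACH_CLEARANCE_UM / v_app / dt))
    ramp_dist = config.deformation_fraction * gel.thickness_um
    i_hold = i_contact + int(np.ceil(ramp_dist / v_ramp / dt - 1e-9))
    n = i_hold + int(round(config.hold_duration_s / dt)) + 21
    t = np.arange(n) * dt
    idx = np.arange(n)
    t_contact = t[i_contact]
    contact_pos = v_app * t_contact
    slide_pos = contact_pos + gel.thickness_um

    # position: approach then ramp at constant speed, then parked
    pos = np.where(idx < i_contact, v_app * t, contact_pos + v_ramp * (t - t_contact))
    pos = np.minimum(pos, contact_pos + ramp_dist)

    area = config.plunger_area_m2
    e0_pa = gel.e0_kpa * 1000.0
    strain0 = config.deformation_fraction

    force = np.zeros(n)
    in_ramp = (idx >= i_contact) & (idx < i_hold)
    strain_ramp = (pos[in_ramp] - contact_pos) / gel.thickness_um
    # the force channel registers the touch load from geometric contact
    # onward (snap-on), riding on the elastic response during the ramp
    force[in_ramp] = config.touch_load_n + area * e0_pa * strain_ramp

    in_hold = idx >= i_hold
    th = (idx[in_hold] - i_hold) * dt
    f_hold = area * strain0 * 1000.0 * gel.et_kpa(th)
    if gel.collapse_time_s is not None:
        if gel.collapse_time_s >= config.hold_duration_s:
            raise GelRelaxError("collapse_time_s must fall within the hold")
        after = th >= gel.collapse_time_s
        f_at = area * strain0 * 1000.0 * float(gel.et_kpa(gel.collapse_time_s))
        f_hold = np.where(
            after, f_at * np.exp(-(th - gel.collapse_time_s) / COLLAPSE_TAU_S), f_hold
        )
    force[in_hold] = f_hold

    if gel.noise_sigma > 0:
        sigma_f = gel.noise_sigma * e0_pa * strain0 * area
        force = force + rng.normal(0.0, sigma_f, n)

    return RawTrace(
        time_s=t,
        position_um=pos,
        force_n=force,
        sample_id=gel.sample_id,
        meta={
            "slide_position_um": slide_pos,
            "thickness_um": gel.thickness_um,
            "collapse_time_s": gel.collapse_time_s,
        },
    )


def _sample_elements(cohort: CohortSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Donor-level element parameters drawn around the group template."""
    base = list(cohort.template)
    if cohort.third_element is not None and rng.random() < cohort.third_element_prob:
        base.append(cohort.third_element)
    out = []
    for e_mean, tau_med in base:
        e = max(rng.normal(e_mean, cohort.e_cv * e_mean), 1e-3)
        tau = tau_med * np.exp(rng.normal(0.0, cohort.tau_sigma_log))
        out.append((e, tau))
    return out


def simulate_cohort(
    cohort: CohortSpec, config: ExperimentConfig
) -> list[tuple[RawTrace, SyntheticGelSpec]]:
    """Simulate a donor x pregel x replicate cohort with ground truth.

    Sample ids follow the replicate nomenclature (group + donor number +
    pregel letter, e.g. NAM2B, with a -1/-2 suffix for duplicates). In a
    DAM-like cohort every trace is assigned a collapse time inside the
    early hold, reproducing the universal collapse of diabetic-derived
    gels.
    """
    rng = np.random.default_rng(cohort.seed)
    letters = string.ascii_uppercase
    out: list[tuple[RawTrace, SyntheticGelSpec]] = []
    for d in range(cohort.n_donors):
        donor_elements = _sample_elements(cohort, rng)
        for p in range(cohort.n_pregels_per_donor):
            pregel_elements = [
                (
                    max(e * np.exp(rng.normal(0, cohort.pregel_scale * cohort.e_cv)), 1e-3),
                    tau * np.exp(rng.normal(0, cohort.pregel_scale * cohort.tau_sigma_log)),
                )
                for e, tau in donor_elements
            ]
            for r in range(cohort.replicates):
                rep_elements = [
                    MaxwellElement(
                        max(e * np.exp(rng.normal(0, cohort.replicate_scale * cohort.e_cv)), 1e-3),
                        tau * np.exp(rng.normal(0, cohort.replicate_scale * cohort.tau_sigma_log)),
                    )
                    for e, tau in pregel_elements
                ]
                base_id = f"{cohort.group}{d + 1}{letters[p]}"
                sample_id = base_id if cohort.replicates == 1 else f"{base_id}-{r + 1}"
                collapse_t = (
                    float(rng.uniform(*cohort.collapse_window_s)) if cohort.collapse else None
                )
                gel = SyntheticGelSpec(
                    elements=rep_elements,
                    E_inf_kpa=0.0,
                    thickness_um=cohort.thickness_um,
                    noise_sigma=cohort.noise_sigma,
                    collapse_time_s=collapse_t,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    sample_id=sample_id,
                )
                trace = simulate_trace(gel, config)
                trace.meta.update({"group": cohort.group, "donor": d + 1, "pregel": letters[p],
                                   "replicate": r + 1})
                out.append((trace, gel))
    return out


def simulate_relaxation_curve(
    gel: SyntheticGelSpec, config: ExperimentConfig, n_samples: int = 1001
):
    """Directly simulate the hold-phase relaxing stiffness E(t) in kPa.

    Shortcut past approach/ramp for fitting studies: returns a
    :class:`~gelrelax.mechanics.RelaxationCurve` sampled uniformly over the
    hold with additive Gaussian noise of sigma = noise_sigma * E(0).
    """
    from .mechanics import RelaxationCurve

    rng = np.random.default_rng(gel.seed)
    t = np.linspace(0.0, config.hold_duration_s, n_samples)
    et = gel.et_kpa(t)
    if gel.noise_sigma > 0:
        et = et + rng.normal(0.0, gel.noise_sigma * gel.e0_kpa, t.size)
    return RelaxationCurve(t_s=t, Et_kpa=et, strain0=config.deformation_fraction)
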