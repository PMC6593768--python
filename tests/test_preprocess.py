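"""Contact detection, phase segmentation and stress/strain conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelrelax import (
    ExperimentConfig,
    RawTrace,
    detect_contact,
    segment_phases,
    simulate_trace,
    to_strain,
    to_stress,
)
from gelrelax.errors import ContactNotFoundError, GelRelaxError, GeometryError, TruncatedTraceError

PLUNGER_AREA = 4.908739e-6  # m^2, pi*(0.00125)^2 by independent arithmetic


def _step_trace(n=200, step_at=57, level=2e-4):
    t = np.arange(n) * 0.1
    force = np.where(np.arange(n) >= step_at, level, 0.0)
    return RawTrace(t, t * 5.0, force)


def test_contact_at_constructed_step(cfg):
    tr = _step_trace()
    ev = detect_contact(tr, cfg, slide_position_um=1000.0)
    assert ev.index == 57
    assert ev.touch_position_um == pytest.approx(tr.position_um[57])


def test_thickness_from_simulated_ring(cfg, two_element_gel):
    """A gel cast in an 800-um ring yields thickness 800 um +/- one position step."""
    tr = simulate_trace(two_element_gel, cfg)
    ev = detect_contact(tr, cfg, slide_position_um=tr.meta["slide_position_um"])
    step = cfg.approach_speed_um_s / cfg.sampling_rate_hz
    assert abs(ev.thickness_um - 800.0) <= step


def test_no_gel_noise_rarely_triggers_contact(cfg, rng):
    """Force noise at 0.2x threshold: false-positive rate < 1% over 1,000 traces."""
    thr = cfg.touch_load_n
    t = np.arange(400) * 0.1
    false_pos = 0
    for _ in range(1000):
        tr = RawTrace(t, t * 5.0, rng.normal(0, 0.2 * thr, t.size))
        try:
            detect_contact(tr, cfg, slide_position_um=1e6)
            false_pos += 1
        except ContactNotFoundError:
            pass
    assert false_pos / 1000 < 0.01


def test_negative_thickness_is_geometry_error(cfg):
    tr = _step_trace()
    with pytest.raises(GeometryError):
        detect_contact(tr, cfg, slide_position_um=0.0)


def test_segmentation_of_simulated_trace(cfg, two_element_gel):
    tr = simulate_trace(two_element_gel, cfg)
    ev = detect_contact(tr, cfg, tr.meta["slide_position_um"])
    sst = segment_phases(tr, ev, cfg)
    # ramp ends once travel past contact reaches 0.2 x 800 = 160 um
    ramp = sst.select("ramp")
    assert ramp.strain.max() < 0.2
    hold = sst.select("hold")
    assert np.all(hold.strain == 0.2)
    assert len(hold) == pytest.approx(cfg.hold_duration_s * cfg.sampling_rate_hz + 1)
    # phases appear in order and conserve samples
    order = {"approach": 0, "ramp": 1, "hold": 2, "post": 3}
    codes = [order[p] for p in sst.phase]
    assert codes == sorted(codes)
    assert sum(len(sst.select(p)) for p in order) == len(tr)


def test_truncated_hold_raises_with_partial(cfg, two_element_gel):
    tr = simulate_trace(two_element_gel, cfg)
    ev = detect_contact(tr, cfg, tr.meta["slide_position_um"])
    # cut the record 40 s into the hold
    hold_start_t = tr.time_s[ev.index] + 160.0 / cfg.ramp_speed_um_s
    keep = tr.time_s <= hold_start_t + 40.0
    cut = RawTrace(tr.time_s[keep], tr.position_um[keep], tr.force_n[keep])
    with pytest.raises(TruncatedTraceError) as exc:
        segment_phases(cut, ev, cfg)
    partial = exc.value.partial
    assert partial is not None and partial.truncated
    hold = partial.select("hold")
    assert hold.time_s[-1] - hold.time_s[0] == pytest.approx(40.0, abs=0.2)


@pytest.mark.parametrize(
    "force_n,expected_pa",
    [(4.908739e-6, 1.0), (0.0, 0.0), (9.80665e-5, 19.977)],
)
def test_to_stress_arithmetic(cfg, force_n, expected_pa):
    assert to_stress(force_n, cfg) == pytest.approx(expected_pa, rel=1e-3)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=-1e3, max_value=1e3), st.floats(min_value=-10, max_value=10))
def test_to_stress_linear(force, scale):
    cfg = ExperimentConfig()
    assert to_stress(scale * force, cfg) == pytest.approx(
        scale * to_stress(force, cfg), rel=1e-12, abs=1e-15
    )


@pytest.mark.parametrize("pct,expected", [(20, 0.2), (0, 0.0), (100, 1.0)])
def test_to_strain(pct, expected):
    assert to_strain(pct) == expected


def test_to_strain_out_of_range():
    with pytest.raises(GelRelaxError):
        to_strain(120)
    with pytest.raises(GelRelaxError):
        to_strain(-1)
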