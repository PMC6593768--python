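# gelrelax

Stress-relaxation analysis for soft extracellular-matrix (ECM) hydrogels
measured on a low-load compression tester.

Decellularized adipose-tissue ECM can be digested and re-gelled into soft
hydrogels (~1–2 kPa) for wound-healing applications, and their mechanical
quality control rests on a stress-relaxation test: a small plunger
compresses the gel by 20% and the force decay is monitored over a 100-s
hold. `gelrelax` turns the raw instrument traces (time, plunger position,
force) into the quantities that characterise such gels — thickness,
instantaneous stiffness, relaxing stiffness E(t), total relaxation — and
decomposes the relaxation into a generalized Maxwell (Prony) series

    E(t) = E_inf + sum_i E_i * exp(-t / tau_i)

fitted by bounded multi-start least squares, with the number of elements
chosen by adding elements until the chi-squared improvement becomes
insignificant. Each element's relative importance RI_i = 100·E_i / Σ E_j
and its time-constant class (sub-second fluid expulsion, 1–10 s ECM
network, 10–100 s slow modes) summarise what carries the gel's stiffness.
Gels that collapse during the hold — a failure mode that affects entire
cohorts of structurally compromised (e.g. diabetic-derived) matrices — are
flagged and excluded from cohort statistics (mean, SD, SEM, one-tailed
t tests).

Because raw donor traces for such gels are typically not shareable, the
package includes a forward simulator of the whole experiment
(approach/ramp/hold, touch-load contact, hierarchical donor–pregel–replicate
cohorts, additive noise, collapse mode) so every stage is validated by
parameter recovery against known ground truth.

## Worked example

Simulate one gel with a known two-element Prony law (E₁ = 1.2 kPa,
τ₁ = 0.5 s; E₂ = 0.6 kPa, τ₂ = 20 s; 1% stress noise) and analyse it:

```python
from gelrelax import (ExperimentConfig, MaxwellElement, SyntheticGelSpec,
                      simulate_trace, analyze_trace, classify_elements)

cfg = ExperimentConfig()          # 0.25-cm plunger, 10-mg touch load,
                                  # 20% strain held 100 s, 800-um ring
gel = SyntheticGelSpec(
    elements=[MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)],
    noise_sigma=0.01, seed=42, sample_id="NAM1A",
)
trace = simulate_trace(gel, cfg)
res = analyze_trace(trace, cfg, seed=1)

print(f"thickness      : {res.thickness_um:.1f} um")
print(f"stiffness E    : {res.stiffness.E_kpa:.3f} kPa (r2 = {res.stiffness.r2:.4f})")
print(f"total relaxation: {res.total_relaxation_pct:.1f} %")
for el, ri, lab in zip(res.fit.elements, res.fit.relative_importance,
                       classify_elements(res.fit)):
    print(f"  E = {el.E_kpa:.3f} kPa  tau = {el.tau_s:6.2f} s  RI = {ri:4.1f} %  [{lab}]")
```

prints

```
thickness      : 799.5 um
stiffness E    : 1.800 kPa (r2 = 0.9988)
total relaxation: 100.0 %
  E = 1.190 kPa  tau =   0.49 s  RI = 66.4 %  [sub_second_fluid]
  E = 0.602 kPa  tau =  19.73 s  RI = 33.6 %  [slow_10_100s]
```

The detected thickness is within one position step of the 800-μm casting
ring; the stiffness slope recovers E(0) = E₁ + E₂ = 1.8 kPa; the fit
selects n = 2 elements and recovers both (E, τ) pairs to ~1–2%, with the
sub-second element carrying two thirds of the stiffness — the signature of
a mostly-viscous gel that relaxes essentially completely within the hold.

The same pipeline is scriptable from the shell:

```sh
gelrelax simulate --out traces/          # 18-trace synthetic cohort + ground truth
gelrelax analyze traces/ --out report    # report.json + report.csv
gelrelax fit curve.csv --max-n 4 --epsilon 0.05 --seed 1
```

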