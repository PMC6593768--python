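"""End-to-end analysis of traces and report assembly.

``analyze_trace`` runs one raw trace through contact detection,
segmentation, stiffness extraction, relaxation, QC and Prony fitting;
``analyze_cohort`` maps it over a cohort and ``build_report`` assembles the
per-sample table, group summaries and exclusion list into a JSON/CSV-ready
bundle.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import pandas as pd

from .errors import GelRelaxError, TruncatedTraceError
from .io import ExperimentConfig, RawTrace
from .maxwell import (
    FitOptions,
    MaxwellFit,
    QCResult,
    classify_elements,
    qc_flag_collapse,
    select_order,
)
from .mechanics import (
    RelaxationCurve,
    StiffnessResult,
    fit_stiffness,
    relaxing_stiffness,
    total_relaxation,
)
from .preprocess import detect_contact, segment_phases
from .stats import CohortSummary, summarize


@dataclasses.dataclass
class SampleResult:
    """Everything the pipeline extracted from one measurement."""

    sample_id: str
    meta: dict[str, Any]
    thickness_um: float | None
    stiffness: StiffnessResult | None
    total_relaxation_pct: float | None
    fit: MaxwellFit | None
    qc: QCResult
    curve: RelaxationCurve | None = None


def analyze_trace(
    trace: RawTrace,
    config: ExperimentConfig,
    slide_position_um: float | None = None,
    max_n: int = 4,
    epsilon: float = 0.05,
    options: FitOptions | None = None,
    seed: int = 0,
) -> SampleResult:
    """Run the full per-sample pipeline on one raw trace.

    ``slide_position_um`` defaults to the trace's calibration metadata.
    Samples that fail QC (collapse) skip the Maxwell fit and carry the flag.
    """
    if slide_position_um is None:
        slide_position_um = trace.meta.get("slide_position_um")
    if slide_position_um is None:
        raise GelRelaxError("slide position calibration required")
    contact = detect_contact(trace, config, slide_position_um)
    try:
        sst = segment_phases(trace, contact, config)
    except TruncatedTraceError as exc:
        if exc.partial is None:
            raise
        sst = exc.partial
    stiffness = fit_stiffness(sst)
    curve = relaxing_stiffness(sst)
    qc = qc_flag_collapse(curve)
    if qc.collapsed:
        return SampleResult(trace.sample_id, dict(trace.meta), contact.thickness_um,
                            stiffness, None, None, qc, curve)
    fit = select_order(curve, max_n=max_n, epsilon=epsilon, options=options, seed=seed)
    qc = qc_flag_collapse(curve, fit)
    tr = total_relaxation(curve) if not qc.collapsed else None
    return SampleResult(trace.sample_id, dict(trace.meta), contact.thickness_um,
                        stiffness, tr, None if qc.collapsed else fit, qc, curve)


def analyze_cohort(
    traces: Sequence[RawTrace],
    config: ExperimentConfig,
    seed: int = 0,
    **kwargs,
) -> list[SampleResult]:
    return [
        analyze_trace(tr, config, seed=seed + i, **kwargs) for i, tr in enumerate(traces)
    ]


def build_report(results: Sequence[SampleResult]) -> dict:
    """Assemble per-sample rows, group summaries and the exclusion list.

    Collapse-flagged samples appear only in ``excluded`` (with reasons) and
    contribute nothing to the viscoelastic summaries, mirroring the handling
    of gels that yield no relaxation data.
    """
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "group": r.meta.get("group", "all"),
            "donor": r.meta.get("donor"),
            "thickness_um": r.thickness_um,
            "stiffness_kpa": r.stiffness.E_kpa if r.stiffness else None,
            "stiffness_r2": r.stiffness.r2 if r.stiffness else None,
            "total_relaxation_pct": r.total_relaxation_pct,
            "collapsed": r.qc.collapsed,
            "qc_reasons": "; ".join(r.qc.reasons),
        }
        if r.fit is not None:
            labels = classify_elements(r.fit)
            row.update(
                n_elements=r.fit.n_elements,
                chi2=r.fit.chi2,
                E_inf_kpa=r.fit.E_inf_kpa,
                elements=[
                    {"E_kpa": el.E_kpa, "tau_s": el.tau_s, "RI_pct": ri, "class": lab}
                    for el, ri, lab in zip(
                        r.fit.elements, r.fit.relative_importance, labels
                    )
                ],
            )
        rows.append(row)

    included = [r for r in results if not r.qc.collapsed]
    excluded = [
        {"sample_id": r.sample_id, "reasons": r.qc.reasons}
        for r in results
        if r.qc.collapsed
    ]
    summaries: dict[str, list[CohortSummary]] = {}
    if included:
        groups = [r.meta.get("group", "all") for r in included]
        excl_ids = [e["sample_id"] for e in excluded]
        summaries["stiffness_kpa"] = summarize(
            [r.stiffness.E_kpa for r in included], groups, excluded=excl_ids
        )
        summaries["total_relaxation_pct"] = summarize(
            [r.total_relaxation_pct for r in included], groups, excluded=excl_ids
        )
    return {
        "samples": rows,
        "summary": {
            metric: [dataclasses.asdict(s) for s in ss] for metric, ss in summaries.items()
        },
        "excluded": excluded,
        "n_included": len(included),
        "n_excluded": len(excluded),
    }


def report_table(report: dict) -> pd.DataFrame:
    """Flatten the per-sample rows of a report into a DataFrame for CSV."""
    rows = []
    for r in report["samples"]:
        flat = {k: v for k, v in r.items() if k != "elements"}
        for i, el in enumerate(r.get("elements", []) or [], start=1):
            flat[f"E{i}_kpa"] = el["E_kpa"]
            flat[f"tau{i}_s"] = el["tau_s"]
            flat[f"RI{i}_pct"] = el["RI_pct"]
            flat[f"class{i}"] = el["class"]
        rows.append(flat)
    return pd.DataFrame(rows)
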