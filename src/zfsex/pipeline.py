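"""Full sexing pipeline: plate data in, specimen sex calls out.

Stages: read (trace or endpoint dialect) -> per-dye threshold + Cq (trace
runs only) -> standard-curve fit per dye -> per-well genotype calls ->
absolute copy numbers -> per-specimen summaries -> dropout risk ->
consensus sex calls -> cohort report.  Deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import quantify
from .consensus import ConsensusParams, SexCall, SpecimenSummary, cohort_report, infer_sex
from .genotype import CallParams, ControlReport, WellGenotype, call_well, qc_controls
from .io import RunBundle, WellRecord, render_risk
from .quantify import StandardCurveFit

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_sexing"]


@dataclass
class PipelineResult:
    thresholds: dict[str, float]
    fits: dict[str, StandardCurveFit]
    well_genotypes: dict[str, WellGenotype]
    summaries: list[SpecimenSummary]
    sex_calls: list[SexCall]
    controls: ControlReport
    report: dict
    warnings: list[str] = field(default_factory=list)
    _sheet: list = field(default_factory=list, repr=False)

    def well_rows(self) -> list[dict]:
        rows = []
        sheet_by_well = {}
        for srow in self._sheet:
            sheet_by_well[srow.well] = srow
        for well in sorted(self.well_genotypes,
                           key=lambda w: (w[0], int(w[1:]))):
            g = self.well_genotypes[well]
            srow = sheet_by_well.get(well)
            rows.append({
                "well": well,
                "specimen_id": srow.specimen_id if srow else "",
                "replicate_index": srow.replicate_index if srow else "",
                "call": g.call,
                "cq_x": g.cq_x, "cq_y": g.cq_y,
                "end_rfu_x": g.end_rfu_x, "end_rfu_y": g.end_rfu_y,
                "copies_x": g.copies_x, "copies_y": g.copies_y,
            })
        return rows

    def specimen_rows(self) -> list[dict]:
        rows = []
        calls_by_id = {c.specimen_id: c for c in self.sex_calls}
        for s in self.summaries:
            call = calls_by_id[s.specimen_id]
            rows.append({
                "specimen_id": s.specimen_id,
                "pcr_positive": s.n_positive,
                "n_xx": s.count("XX"), "n_xy": s.count("XY"),
                "n_yy": s.count("YY"),
                "n_inconclusive": s.count("inconclusive"),
                "mean_rfu_y": s.mean_rfu_y, "mean_rfu_x": s.mean_rfu_x,
                "mean_cn_y": s.mean_cn_y, "mean_cn_x": s.mean_cn_x,
                "mean_cn_total": s.mean_cn_total,
                "sex": call.sex, "status": call.status,
                "risk": call.risk.rendered if call.risk else "na",
                "flags": list(call.flags),
            })
        return rows


def _mean(values: list[float]) -> Optional[float]:
    return float(np.mean(values)) if values else None


def run_sexing(
    bundle: RunBundle,
    call_params: CallParams = CallParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
) -> PipelineResult:
    """Run the complete sexing analysis on one plate."""
    warnings: list[str] = []
    bundle.validate(dyes=(call_params.dye_x, call_params.dye_y))
    dyes = (call_params.dye_x, call_params.dye_y)

    records = {(r.well, r.dye): r for r in bundle.records}
    has_traces = any(r.trace is not None for r in bundle.records)

    # per-dye threshold + Cq from traces, unless Cq came from the instrument
    thresholds: dict[str, float] = {}
    if has_traces:
        for dye in dyes:
            thresholds[dye] = quantify.run_threshold(bundle, dye)
        for rec in bundle.records:
            if rec.trace is not None and rec.cq is None:
                rec.cq = quantify.cq_from_trace(rec.fluorescence(), thresholds[rec.dye])

    # standard-curve fit per dye from role=standard wells with a Cq
    fits: dict[str, StandardCurveFit] = {}
    std_rows = [row for row in bundle.sheet if row.role == "standard"]
    for dye in dyes:
        points = []
        for row in std_rows:
            rec = records.get((row.well, dye))
            if rec is not None and rec.cq is not None:
                points.append((row.standard_copies, rec.cq))
        if len(points) >= 2 and len({c for c, _ in points}) >= 2:
            fits[dye] = quantify.fit_standard_curve(points, dye)
        else:
            warnings.append(
                f"no usable standard series for dye {dye}: copy numbers and "
                "dropout risks unavailable"
            )
    if std_rows and not fits:
        logger.warning("standards present but no curve could be fitted")
    if not std_rows:
        warnings.append("run has no standards: copy numbers unavailable, risk=na")

    # per-well genotype calls + copy numbers
    genotypes: dict[str, WellGenotype] = {}
    for row in bundle.sheet:
        x_rec = records[(row.well, call_params.dye_x)]
        y_rec = records[(row.well, call_params.dye_y)]
        g = call_well(x_rec, y_rec, call_params)
        fit_x = fits.get(call_params.dye_x)
        fit_y = fits.get(call_params.dye_y)
        copies_x = (
            quantify.copies_from_cq(fit_x, g.cq_x)
            if fit_x is not None and g.cq_x is not None else None
        )
        copies_y = (
            quantify.copies_from_cq(fit_y, g.cq_y)
            if fit_y is not None and g.cq_y is not None else None
        )
        genotypes[row.well] = replace(g, copies_x=copies_x, copies_y=copies_y)

    controls = qc_controls(bundle, genotypes)
    warnings.extend(controls.warnings)

    # per-specimen summaries over unknowns
    summaries: list[SpecimenSummary] = []
    unknown_rows = [row for row in bundle.sheet if row.role == "unknown"]
    by_specimen: dict[str, list] = {}
    for row in unknown_rows:
        by_specimen.setdefault(row.specimen_id, []).append(row)
    for specimen_id, rows in by_specimen.items():
        rows.sort(key=lambda r: r.replicate_index)
        calls, cns_x, cns_y, rfus_x, rfus_y = [], [], [], [], []
        for row in rows:
            g = genotypes[row.well]
            calls.append(g.call)
            if g.positive:
                # average CN and RFU over positive reactions; an absent
                # channel contributes zero copies, as in the cohort table
                cns_x.append(g.copies_x if g.copies_x is not None else 0.0)
                cns_y.append(g.copies_y if g.copies_y is not None else 0.0)
                rfus_x.append(g.end_rfu_x)
                rfus_y.append(g.end_rfu_y)
        has_cn = bool(fits) and bool(cns_x)
        summaries.append(SpecimenSummary(
            specimen_id=specimen_id,
            replicate_calls=tuple(calls),
            mean_cn_x=_mean(cns_x) if has_cn else None,
            mean_cn_y=_mean(cns_y) if has_cn else None,
            mean_rfu_x=_mean(rfus_x),
            mean_rfu_y=_mean(rfus_y),
            known_sex=rows[0].known_sex,
        ))

    sex_calls = [infer_sex(s, consensus_params) for s in summaries]
    report = cohort_report(summaries, sex_calls)
    report["contamination_suspect"] = controls.contamination_suspect

    return PipelineResult(
        thresholds=thresholds, fits=fits, well_genotypes=genotypes,
        summaries=summaries, sex_calls=sex_calls, controls=controls,
        report=report, warnings=warnings, _sheet=list(bundle.sheet),
    )
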