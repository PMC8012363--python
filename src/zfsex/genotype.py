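"""Per-well allelic-discrimination genotype calling.

A well carries two channels (X allele on VIC, Y allele on FAM by default).
An allele is *detected* when its channel has a Cq AND its final-cycle RFU
reaches the detection level (default 100 RFU).  The five-way call:

* both detected -> XY (heterozygote, male pattern)
* X only -> XX, Y only -> YY
* no Cq on either channel -> negative (like NTCs and extraction blanks)
* a Cq somewhere but no channel fully detected -> inconclusive
  (non-discriminant endpoint fluorescence, typical of late-Cq wells that
  never reach plateau within 40 cycles)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .io import RunBundle, WellRecord

logger = logging.getLogger(__name__)

__all__ = ["CallParams", "WellGenotype", "call_well", "qc_controls", "ControlReport"]

CALLS = ("XX", "XY", "YY", "negative", "inconclusive")
DISCRIMINANT = ("XX", "XY", "YY")


@dataclass(frozen=True)
class CallParams:
    """Endpoint calling thresholds.

    detect_rfu: minimum final RFU for a Cq-positive channel to count as a
    detected allele.  noise_rfu: level below which a Cq-free channel is
    plain background.  Both default to the published 100 RFU rule.
    """

    detect_rfu: float = 100.0
    noise_rfu: float = 100.0
    cycles: int = 40
    dye_x: str = "VIC"
    dye_y: str = "FAM"

    def __post_init__(self) -> None:
        if self.detect_rfu <= 0 or self.noise_rfu <= 0:
            raise ValueError("detection/noise RFU thresholds must be > 0")


@dataclass(frozen=True)
class WellGenotype:
    well: str
    call: str
    x_detected: bool
    y_detected: bool
    cq_x: Optional[float]
    cq_y: Optional[float]
    end_rfu_x: float
    end_rfu_y: float
    copies_x: Optional[float] = None
    copies_y: Optional[float] = None

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def discriminant(self) -> bool:
        return self.call in DISCRIMINANT

    @property
    def positive(self) -> bool:
        """Any amplification signal (a Cq on either channel)."""
        return self.cq_x is not None or self.cq_y is not None


def _detected(cq: Optional[float], end_rfu: Optional[float], detect_rfu: float) -> bool:
    return cq is not None and end_rfu is not None and end_rfu >= detect_rfu


def call_well(
    x_channel: WellRecord,
    y_channel: WellRecord,
    params: CallParams = CallParams(),
) -> WellGenotype:
    """Combine the two dye channels of one well into a genotype call."""
    if x_channel.well != y_channel.well:
        raise ValueError(
            f"channels from different wells: {x_channel.well} vs {y_channel.well}"
        )
    end_x = x_channel.final_rfu
    end_y = y_channel.final_rfu
    x_det = _detected(x_channel.cq, end_x, params.detect_rfu)
    y_det = _detected(y_channel.cq, end_y, params.detect_rfu)
    if x_det and y_det:
        call = "XY"
    elif x_det:
        call = "XX"
    elif y_det:
        call = "YY"
    elif x_channel.cq is None and y_channel.cq is None:
        call = "negative"
    else:
        call = "inconclusive"
    return WellGenotype(
        well=x_channel.well,
        call=call,
        x_detected=x_det,
        y_detected=y_det,
        cq_x=x_channel.cq,
        cq_y=y_channel.cq,
        end_rfu_x=end_x if end_x is not None else 0.0,
        end_rfu_y=end_y if end_y is not None else 0.0,
    )


@dataclass
class ControlReport:
    """Outcome of the run's negative controls (NTCs, extraction blanks)."""

    n_controls: int = 0
    failures: list[tuple[str, str, str]] = field(default_factory=list)  # (well, role, call)
    warnings: list[str] = field(default_factory=list)

    @property
    def contamination_suspect(self) -> bool:
        return bool(self.failures)

    @property
    def clean(self) -> bool:
        return not self.failures


def qc_controls(bundle: RunBundle, calls: dict[str, WellGenotype]) -> ControlReport:
    """Check that every NTC and extraction blank stayed negative.

    Any non-negative control marks the run contamination-suspect; a sheet
    without controls yields a warning, not an error.
    """
    report = ControlReport()
    for row in bundle.sheet:
        if row.role not in ("ntc", "extraction_blank"):
            continue
        report.n_controls += 1
        geno = calls.get(row.well)
        if geno is None:
            report.warnings.append(f"control well {row.well} has no call")
            continue
        if geno.call != "negative":
            report.failures.append((row.well, row.role, geno.call))
    if report.n_controls == 0:
        report.warnings.append("no NTC or extraction blank on the sample sheet")
        logger.warning("run has no negative controls")
    return report
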