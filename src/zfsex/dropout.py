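"""Allelic-dropout probability and the false-homozygote risk (P_XX)^n.

For a true heterozygote (male) amplified from U total Zinc-Finger copies
per reaction, P_XX(U) is the per-reaction probability that only one allele
is detected.  Across n discriminant replicates the probability that a male
masquerades as a female is (P_XX)^n — the confidence column of the
specimen table.

Two functional forms are provided:

* ``calibrated`` (default): P_XX(U) = 2^-(U/2 + 1).  An empirical closed
  form calibrated against the published mammoth cohort: it reproduces
  every printed (P_XX)^n value at one-decimal-percent precision.
* ``poisson``: a mechanistic molecule-sampling model.  Each allele enters
  the reaction as a Poisson(U/2) draw; conditional on the reaction being
  positive at all, the chance that exactly one allele is present is
  2 e^{-U/2}(1 - e^{-U/2}) / (1 - e^{-U}) = 2 / (e^{U/2} + 1).

Both are strictly decreasing in U; they disagree at low U, which is why
the simulator exposes matching outcome modes for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .io import render_risk

__all__ = [
    "MODELS", "DropoutInput", "RiskResult",
    "p_dropout", "false_homozygote_risk", "replicates_needed",
]

MODELS = ("calibrated", "poisson")


def p_dropout(U: float, model: str = "calibrated") -> float:
    """Per-reaction probability of allelic dropout for a heterozygote
    amplified from U total template copies."""
    if U < 0:
        raise ValueError(f"copy number U must be >= 0, got {U}")
    if not math.isfinite(U):
        raise ValueError("copy number U must be finite")
    if model == "calibrated":
        return 2.0 ** (-(U / 2.0 + 1.0))
    if model == "poisson":
        # algebraic simplification of 2e^{-U/2}(1-e^{-U/2})/(1-e^{-U});
        # the U -> 0 limit of 1 falls out automatically
        return 2.0 / (math.exp(U / 2.0) + 1.0)
    raise ValueError(f"unknown dropout model {model!r}; choose from {MODELS}")


@dataclass(frozen=True)
class DropoutInput:
    """U: mean total copies per reaction (X + Y channel CN, the copy-number
    proxy); n: number of PCR attempts that yielded a discriminant
    genotype."""

    U: float
    n: int
    model: str = "calibrated"

    def __post_init__(self) -> None:
        if self.U < 0 or not math.isfinite(self.U):
            raise ValueError("U must be finite and >= 0")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.model not in MODELS:
            raise ValueError(f"unknown dropout model {self.model!r}")


@dataclass(frozen=True)
class RiskResult:
    p_per_reaction: float
    risk: Optional[float]  # None when n = 0 (undefined)
    n: int
    rendered: str


def false_homozygote_risk(inp: DropoutInput) -> RiskResult:
    """(P_XX)^n: probability that all n discriminant replicates of a true
    heterozygote dropped the same allele.  n = 0 leaves the risk undefined
    ("na")."""
    p = p_dropout(inp.U, inp.model)
    if inp.n == 0:
        return RiskResult(p_per_reaction=p, risk=None, n=0, rendered="na")
    risk = p ** inp.n
    return RiskResult(
        p_per_reaction=p, risk=risk, n=inp.n, rendered=render_risk(risk, inp.n)
    )


def replicates_needed(U: float, target_risk: float, model: str = "calibrated") -> int:
    """Smallest number of concordant homozygous replicates n such that
    p_dropout(U)^n <= target_risk.

    With ~3 copies per reaction, 3 replicates reach the 1% level; at lower
    copy numbers several more are required (up to 7 for 99% confidence in
    the classical multi-tube regime).
    """
    if not 0 < target_risk < 1:
        raise ValueError("target_risk must be in (0, 1)")
    p = p_dropout(U, model)
    if p >= 1.0:
        raise ValueError("per-reaction dropout probability is 1: unreachable target")
    n = max(1, math.ceil(math.log(target_risk) / math.log(p)))
    # guard against floating-point edge cases on the ceiling
    while p ** n > target_risk:
        n += 1
    while n > 1 and p ** (n - 1) <= target_risk:
        n -= 1
    return n
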