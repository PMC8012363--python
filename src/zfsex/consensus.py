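"""Multi-tube consensus: reconcile replicate genotypes into a sex call.

Decision logic for a specimen typed in several independent PCR replicates:

1. No discriminant replicate (all negative/inconclusive) -> undetermined.
2. >= 2 Y-bearing replicates (XY or YY) -> confirmed male.  YY is read as
   X-allele dropout from a male, so [XY,XY,YY] and even [XX,XY,YY] confirm
   a male: dropout of either allele in different tubes.
3. Exactly 1 Y-bearing replicate -> putative male; a lone Y observation
   cannot exclude random contamination.
4. All discriminant replicates XX -> female; confirmed only when the
   false-homozygote risk (P_XX)^n computed from the specimen's mean total
   copy number falls below the risk threshold (default 1%), otherwise
   putative.

Known-sex specimens are validation material: a mismatch raises a flag but
never overrides the molecular call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .dropout import DropoutInput, RiskResult, false_homozygote_risk
from .genotype import CALLS, DISCRIMINANT

__all__ = ["SpecimenSummary", "SexCall", "ConsensusParams", "infer_sex", "cohort_report"]


@dataclass(frozen=True)
class SpecimenSummary:
    """Replicate-level evidence for one specimen."""

    specimen_id: str
    replicate_calls: tuple[str, ...]
    mean_cn_x: Optional[float] = None
    mean_cn_y: Optional[float] = None
    mean_rfu_x: Optional[float] = None
    mean_rfu_y: Optional[float] = None
    known_sex: Optional[str] = None

    def __post_init__(self) -> None:
        for call in self.replicate_calls:
            if call not in CALLS:
                raise ValueError(f"unknown replicate call {call!r}")

    @property
    def n_genotyped(self) -> int:
        """Discriminant replicates (XX + XY + YY)."""
        return sum(c in DISCRIMINANT for c in self.replicate_calls)

    @property
    def n_positive(self) -> int:
        """Replicates with any amplification (discriminant or inconclusive)."""
        return sum(c != "negative" for c in self.replicate_calls)

    def count(self, call: str) -> int:
        return sum(c == call for c in self.replicate_calls)

    @property
    def mean_cn_total(self) -> Optional[float]:
        if self.mean_cn_x is None and self.mean_cn_y is None:
            return None
        return (self.mean_cn_x or 0.0) + (self.mean_cn_y or 0.0)


@dataclass(frozen=True)
class ConsensusParams:
    female_risk_threshold: float = 0.01
    male_min_y_reactions: int = 2
    dropout_model: str = "calibrated"


@dataclass(frozen=True)
class SexCall:
    specimen_id: str
    sex: str      # female / male / undetermined
    status: str   # confirmed / putative / none
    risk: Optional[RiskResult] = None
    rationale: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status == "confirmed" and self.sex == "undetermined":
            raise ValueError("confirmed calls cannot be undetermined")


def _risk_for(summary: SpecimenSummary, params: ConsensusParams) -> Optional[RiskResult]:
    U = summary.mean_cn_total
    if U is None:
        return None
    return false_homozygote_risk(
        DropoutInput(U=U, n=summary.n_genotyped, model=params.dropout_model)
    )


def infer_sex(summary: SpecimenSummary, params: ConsensusParams = ConsensusParams()) -> SexCall:
    """Consensus sex call for one specimen (see module docstring)."""
    flags: list[str] = []
    n_y = summary.count("XY") + summary.count("YY")
    n_xx = summary.count("XX")
    risk = _risk_for(summary, params)

    if summary.n_genotyped == 0:
        sex, status, rationale = "undetermined", "none", ("no-discriminant-replicate",)
    elif n_y >= params.male_min_y_reactions:
        rationale = ["replicated-y-evidence"]
        if summary.count("YY"):
            rationale.append("yy-read-as-x-dropout")
        if n_xx:
            rationale.append("xx-read-as-y-dropout")
        sex, status = "male", "confirmed"
        rationale = tuple(rationale)
    elif n_y == 1:
        sex, status = "male", "putative"
        rationale = (
            ("possible-contamination-vs-dropout",)
            if n_xx
            else ("single-y-observation",)
        )
    else:
        # all discriminant replicates XX
        sex = "female"
        rationale = ["all-xx"]
        if risk is not None and risk.risk is not None and risk.risk < params.female_risk_threshold:
            status = "confirmed"
            rationale.append("dropout-risk-below-threshold")
        else:
            status = "putative"
            rationale.append(
                "dropout-risk-above-threshold" if risk is not None and risk.risk is not None
                else "no-copy-number-estimate"
            )
        rationale = tuple(rationale)

    if summary.known_sex is not None and sex != "undetermined" and sex != summary.known_sex:
        flags.append(f"known-sex-mismatch:{summary.known_sex}")
    return SexCall(
        specimen_id=summary.specimen_id,
        sex=sex, status=status, risk=risk,
        rationale=rationale, flags=tuple(flags),
    )


def cohort_report(
    summaries: Sequence[SpecimenSummary],
    calls: Sequence[SexCall],
) -> dict:
    """Aggregate statistics over a cohort of specimens.

    Includes per-reaction genotype counts, per-specimen replicate
    consistency among specimens with >= 2 discriminant calls, the
    confirmed/putative/undetermined tallies, and the reaction-level call
    rate (discriminant / attempted)."""
    geno_counts = {c: 0 for c in CALLS}
    attempted = 0
    for s in summaries:
        attempted += len(s.replicate_calls)
        for c in s.replicate_calls:
            geno_counts[c] += 1
    discriminant = sum(geno_counts[c] for c in DISCRIMINANT)

    consistent = {"XX": 0, "XY": 0, "YY": 0}
    inconsistent = 0
    multi = 0
    for s in summaries:
        disc = [c for c in s.replicate_calls if c in DISCRIMINANT]
        if len(disc) < 2:
            continue
        multi += 1
        if len(set(disc)) == 1:
            consistent[disc[0]] += 1
        else:
            inconsistent += 1

    tally: dict[tuple[str, str], int] = {}
    mismatches = []
    for call in calls:
        tally[(call.sex, call.status)] = tally.get((call.sex, call.status), 0) + 1
        if call.flags:
            mismatches.append((call.specimen_id, call.flags))

    return {
        "n_specimens": len(summaries),
        "genotype_counts": geno_counts,
        "reactions_attempted": attempted,
        "reactions_discriminant": discriminant,
        "call_rate": (discriminant / attempted) if attempted else math.nan,
        "specimens_multi_replicate": multi,
        "consistent": consistent,
        "consistent_total": sum(consistent.values()),
        "inconsistent": inconsistent,
        "confirmed_females": tally.get(("female", "confirmed"), 0),
        "putative_females": tally.get(("female", "putative"), 0),
        "confirmed_males": tally.get(("male", "confirmed"), 0),
        "putative_males": tally.get(("male", "putative"), 0),
        "undetermined": tally.get(("undetermined", "none"), 0),
        "known_sex_mismatches": mismatches,
    }
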