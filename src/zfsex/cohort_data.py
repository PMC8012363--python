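"""Published replicate-level summary of the woolly mammoth cohort.

Twenty-six Late Pleistocene mammoth bone extracts (Siberia) that yielded at
least one positive qPCR reaction out of three replicates of the Zinc-Finger
sexing assay.  For each specimen: the replicate genotype breakdown
(XX / XY / YY / inconclusive, negatives padding to three attempts), mean
endpoint fluorescence per dye, mean absolute copy number per reaction for
each allele channel, and the sex and rendered dropout risk as published.

Mean total CN spans three orders of magnitude (~0.6 to ~888 copies per
reaction).  Six specimens carried an a-priori morphological sex
(three males: Lyakhov, Jarkov, Oymiakon; three females: 2000/174, Lyuba,
Khroma) and all were recovered correctly.

This table is input data for validation and worked examples: the dropout
and consensus modules recompute its last two columns from the replicate
breakdown and copy numbers alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .consensus import SpecimenSummary

__all__ = ["CohortRow", "MAMMOTH_COHORT", "cohort_summaries"]


@dataclass(frozen=True)
class CohortRow:
    specimen_id: str
    known_sex: Optional[str]  # a-priori morphological sex, when available
    pcr_positive: int         # replicates with any amplification (of 3)
    n_xx: int
    n_xy: int
    n_yy: int
    n_inconclusive: int
    mean_rfu_y: float         # Y-FAM channel, arbitrary units
    mean_rfu_x: float         # X-VIC channel
    mean_cn_y: float          # mean copies per reaction, Y allele
    mean_cn_x: float          # mean copies per reaction, X allele
    mean_cn_total: float      # published sum (the dropout proxy U)
    published_sex: str        # "Female", "Male", "Female ?", "Male ?", "?"
    published_risk: str       # rendered (P_XX)^n, e.g. "0.4%", "<0.1%", "na"

    @property
    def replicate_calls(self) -> tuple[str, ...]:
        calls = (
            ["XX"] * self.n_xx + ["XY"] * self.n_xy + ["YY"] * self.n_yy
            + ["inconclusive"] * self.n_inconclusive
        )
        calls += ["negative"] * (3 - len(calls))
        return tuple(calls)

    @property
    def n_genotyped(self) -> int:
        return self.n_xx + self.n_xy + self.n_yy


_R = CohortRow

#: Rows ordered by descending mean total copy number, as published.
MAMMOTH_COHORT: tuple[CohortRow, ...] = (
    _R("Khroma",   "female", 3, 3, 0, 0, 0,  23, 966,   0.0, 887.5, 887.5, "Female",   "<0.1%"),
    _R("2005/931", None,     3, 3, 0, 0, 0,  23, 760,   0.0, 678.3, 678.3, "Female",   "<0.1%"),
    _R("2005/918", None,     3, 3, 0, 0, 0,  26, 736,   0.0, 500.3, 500.3, "Female",   "<0.1%"),
    _R("2005/898", None,     3, 0, 3, 0, 0, 826, 565, 237.2, 214.8, 452.0, "Male",     "<0.1%"),
    _R("Oymiakon", "male",   3, 0, 3, 0, 0, 772, 498, 174.5, 229.9, 404.4, "Male",     "<0.1%"),
    _R("2005/897", None,     3, 0, 3, 0, 0, 874, 575, 143.7, 135.4, 279.1, "Male",     "<0.1%"),
    _R("Lyakhov",  "male",   3, 0, 3, 0, 0, 913, 680, 121.0, 151.8, 272.8, "Male",     "<0.1%"),
    _R("2005/915", None,     3, 0, 3, 0, 0, 700, 510,  81.0,  86.3, 167.3, "Male",     "<0.1%"),
    _R("2005/924", None,     3, 0, 3, 0, 0, 877, 647,  50.8,  34.9,  85.7, "Male",     "<0.1%"),
    _R("WR2",      None,     3, 3, 0, 0, 0,  25, 611,   0.0,  53.3,  53.3, "Female",   "<0.1%"),
    _R("2000/174", "female", 3, 3, 0, 0, 0,  27, 387,   0.0,  24.8,  24.8, "Female",   "<0.1%"),
    _R("2005/999", None,     3, 3, 0, 0, 0,  15, 503,   0.0,  22.1,  22.1, "Female",   "<0.1%"),
    _R("2005/913", None,     3, 0, 3, 0, 0, 572, 282,  13.6,   7.1,  20.7, "Male",     "<0.1%"),
    _R("2005/900", None,     3, 3, 0, 0, 0,  16, 415,   0.0,  10.3,  10.3, "Female",   "<0.1%"),
    _R("Jarkov",   "male",   3, 0, 3, 0, 0, 333, 253,   3.0,   3.7,   6.7, "Male",     "<0.1%"),
    _R("Lyuba",    "female", 3, 3, 0, 0, 0,  39, 317,   0.0,   3.3,   3.3, "Female",   "0.4%"),
    _R("2005/945", None,     3, 0, 2, 1, 0, 346,  95,   2.1,   0.7,   2.8, "Male",     "0.7%"),
    _R("2001/451", None,     2, 2, 0, 0, 0,  13, 287,   0.0,   2.3,   2.3, "Female ?", "5.1%"),
    _R("2002/489", None,     3, 0, 3, 0, 0, 189, 126,   0.9,   0.9,   1.8, "Male",     "1.9%"),
    _R("2003/838", None,     2, 0, 0, 1, 1, 167, 101,   0.6,   1.0,   1.6, "Male ?",   "28.7%"),
    _R("2005/927", None,     3, 1, 2, 0, 0,  65, 195,   0.2,   1.4,   1.6, "Male",     "2.4%"),
    _R("2000/165", None,     3, 2, 0, 0, 1,  50, 181,   0.3,   1.2,   1.5, "Female ?", "8.8%"),
    _R("2000/187", None,     3, 1, 1, 1, 0, 209,  85,   0.8,   0.7,   1.5, "Male",     "2.6%"),
    _R("2005/904", None,     3, 0, 3, 0, 0, 118,  91,   0.7,   0.7,   1.4, "Male",     "2.9%"),
    _R("2000/175", None,     2, 2, 0, 0, 0,   8, 280,   0.0,   1.2,   1.2, "Female ?", "10.9%"),
    _R("2000/176", None,     2, 0, 0, 0, 2,  18,   1,   0.0,   0.6,   0.6, "?",        "na"),
)


def cohort_summaries() -> list[SpecimenSummary]:
    """The cohort as consensus-ready SpecimenSummary objects."""
    out = []
    for row in MAMMOTH_COHORT:
        out.append(SpecimenSummary(
            specimen_id=row.specimen_id,
            replicate_calls=row.replicate_calls,
            mean_cn_x=row.mean_cn_x,
            mean_cn_y=row.mean_cn_y,
            mean_rfu_x=row.mean_rfu_x,
            mean_rfu_y=row.mean_rfu_y,
            known_sex=row.known_sex,
        ))
    return out
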