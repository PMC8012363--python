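"""Synthetic qPCR plates with known ground truth.

The generator emulates the study conditions of a degraded-DNA sexing run:

* specimen mean total copy numbers drawn log-normally over roughly three
  orders of magnitude (~0.5 to ~1000 copies per reaction);
* Poisson sampling of template molecules into each reaction (the driver of
  allelic dropout at low copy number): a male's X and Y alleles each enter
  as Poisson(U/2), a female's X as Poisson(U);
* 40-cycle logistic amplification at ~98% efficiency, calibrated so one
  copy crosses the quantification threshold near cycle 38 — late-Cq wells
  never reach plateau and yield low final RFU (inconclusive calls);
* FAM plateaus higher than VIC, per-dye, with multiplicative noise;
* a tenfold standard series per dye (1e5 down to 1 copy, triplicate at the
  lowest level) plus NTC and extraction-blank wells.

Two outcome models: ``molecule`` (mechanistic Poisson sampling, the
default) and ``calibrated`` (detections drawn directly from the calibrated
dropout curve), so the two dropout parameterizations can be compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .dropout import p_dropout
from .io import PlateGeometry, RunBundle, SampleSheetRow, WellRecord

__all__ = ["SimulationConfig", "GroundTruth", "ReactionTruth",
           "sample_reaction", "render_trace", "simulate_run", "expected_cq"]


@dataclass(frozen=True)
class SimulationConfig:
    n_specimens: int = 12
    sex_ratio: float = 0.5            # probability a specimen is male
    cn_log_mean: float = math.log(20.0)   # log of median total copies/reaction
    cn_log_sd: float = 2.0            # ~3 orders of magnitude across specimens
    replicates: int = 3
    cycles: int = 40
    efficiency: float = 0.98
    cq_at_1_copy: float = 38.0
    plateau_fam: float = 1000.0
    plateau_vic: float = 700.0
    plateau_noise_sd: float = 0.10    # lognormal sigma, multiplicative
    baseline_noise_sd: float = 2.0    # additive RFU noise on every cycle
    cq_noise_sd: float = 0.15         # cycles
    outcome_model: str = "molecule"   # or "calibrated"
    poisson_standards: bool = False   # Poisson-degrade nominal standard copies
    dye_x: str = "VIC"
    dye_y: str = "FAM"
    plate: str = "96"                 # "96" or "384"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        for name in ("plateau_noise_sd", "baseline_noise_sd", "cq_noise_sd",
                     "cn_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.outcome_model not in ("molecule", "calibrated"):
            raise ValueError(f"unknown outcome_model {self.outcome_model!r}")
        if self.efficiency <= 0:
            raise ValueError("efficiency must be > 0")
        if self.plate not in ("96", "384"):
            raise ValueError("plate must be '96' or '384'")

    @property
    def cycles_per_decade(self) -> float:
        return 1.0 / math.log10(1.0 + self.efficiency)


@dataclass(frozen=True)
class ReactionTruth:
    specimen_id: str
    replicate_index: int
    well: str
    m_x: float  # template molecules of the X allele in the tube
    m_y: float
    x_detected: bool
    y_detected: bool


@dataclass
class GroundTruth:
    sexes: dict[str, str] = field(default_factory=dict)
    mean_u: dict[str, float] = field(default_factory=dict)
    reactions: list[ReactionTruth] = field(default_factory=list)


def sample_reaction(
    sex: str,
    mean_u: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, float, bool, bool]:
    """Draw one reaction's template molecules and allele detections.

    Returns (m_x, m_y, x_detected, y_detected).  Under the ``molecule``
    model an allele is detected iff at least one of its molecules entered
    the tube.  Under the ``calibrated`` model a male's detections follow
    the calibrated dropout curve directly (each allele independently lost
    with probability P_XX(U)), with a Poisson(U) total occupancy draw
    gating whether the tube holds any template at all.
    """
    if config.outcome_model == "molecule":
        if sex == "female":
            m_x = float(rng.poisson(mean_u))
            m_y = 0.0
        else:
            m_x = float(rng.poisson(mean_u / 2.0))
            m_y = float(rng.poisson(mean_u / 2.0))
        return m_x, m_y, m_x >= 1, m_y >= 1
    # calibrated outcome model
    occupied = rng.poisson(mean_u) >= 1
    if sex == "female":
        m_x = mean_u if occupied else 0.0
        return m_x, 0.0, occupied, False
    p = p_dropout(mean_u, "calibrated")
    drop_x = rng.random() < p
    drop_y = rng.random() < p
    x_det = occupied and not drop_x
    y_det = occupied and not drop_y
    half = mean_u / 2.0
    return (half if x_det else 0.0), (half if y_det else 0.0), x_det, y_det


def expected_cq(copies: float, config: SimulationConfig) -> float:
    """Noise-free quantification cycle for a given per-reaction copy number:
    Cq = cq_at_1_copy - log10(copies)/log10(1 + efficiency)."""
    return config.cq_at_1_copy - math.log10(copies) * config.cycles_per_decade


def _logistic_trace(
    cq_star: float,
    plateau: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Logistic amplification curve crossing 10% of *plateau* at cq_star.

    Growth rate ln(1+e) per cycle; truncation at the run's cycle count
    means late crossings never approach the plateau.
    """
    k = math.log(1.0 + config.efficiency)
    midpoint = cq_star + math.log(9.0) / k  # F(cq_star) = plateau/10
    cycles = np.arange(1, config.cycles + 1, dtype=float)
    f = plateau / (1.0 + np.exp(-k * (cycles - midpoint)))
    f += rng.normal(0.0, config.baseline_noise_sd, size=len(cycles))
    return f


def _noise_trace(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, config.baseline_noise_sd, size=config.cycles)


def render_trace(
    well: str,
    copies_x: float,
    copies_y: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[WellRecord, WellRecord]:
    """Render the two dye channels of one well as amplification traces.

    A detected channel (copies > 0) follows a logistic curve whose 10%-of-
    plateau crossing sits at Cq* = cq_at_1_copy - log10(copies)/log10(1+e)
    plus Gaussian Cq noise; an undetected channel emits baseline noise.
    """
    out = []
    for copies, dye, plateau_mean in (
        (copies_x, config.dye_x, config.plateau_vic),
        (copies_y, config.dye_y, config.plateau_fam),
    ):
        if copies > 0:
            cq_star = expected_cq(copies, config) + rng.normal(0.0, config.cq_noise_sd)
            plateau = plateau_mean * math.exp(rng.normal(0.0, config.plateau_noise_sd))
            f = _logistic_trace(cq_star, plateau, config, rng)
        else:
            f = _noise_trace(config, rng)
        trace = [(c, float(v)) for c, v in enumerate(f, start=1)]
        out.append(WellRecord(well=well, dye=dye, trace=trace))
    return out[0], out[1]


#: Standard series levels, high to low; the lowest level runs in triplicate.
STANDARD_LEVELS = (1e5, 1e4, 1e3, 1e2, 1e1, 1e0)
STANDARD_LOW_REPLICATES = 3


def simulate_run(config: SimulationConfig) -> tuple[RunBundle, GroundTruth]:
    """Compose a full plate: standards, unknowns, NTCs, extraction blanks.

    Deterministic for a fixed config (including seed).  Raises when the
    layout exceeds the 96-well plate.
    """
    rng = np.random.default_rng(config.seed)
    geometry = PlateGeometry() if config.plate == "96" else PlateGeometry.plate384()
    wells = iter(geometry.all_wells())
    records: list[WellRecord] = []
    sheet: list[SampleSheetRow] = []
    truth = GroundTruth()

    def next_well() -> str:
        try:
            return next(wells)
        except StopIteration:
            raise ValueError(
                f"plate capacity ({config.plate} wells) exceeded: reduce "
                "n_specimens or split the run across multiple plates"
            ) from None

    # standard series, one per dye (allele-specific standards)
    for allele, dye in (("X", config.dye_x), ("Y", config.dye_y)):
        for level in STANDARD_LEVELS:
            reps = STANDARD_LOW_REPLICATES if level == STANDARD_LEVELS[-1] else 1
            for rep in range(1, reps + 1):
                well = next_well()
                nominal = float(level)
                realized = (
                    float(rng.poisson(nominal)) if config.poisson_standards else nominal
                )
                cx = realized if allele == "X" else 0.0
                cy = realized if allele == "Y" else 0.0
                rx, ry = render_trace(well, cx, cy, config, rng)
                records += [rx, ry]
                sheet.append(SampleSheetRow(
                    well=well, specimen_id=f"STD_{allele}_{level:g}",
                    replicate_index=rep, role="standard", standard_copies=nominal,
                ))

    # unknowns
    for i in range(1, config.n_specimens + 1):
        specimen = f"SIM{i:03d}"
        sex = "male" if rng.random() < config.sex_ratio else "female"
        mean_u = float(rng.lognormal(config.cn_log_mean, config.cn_log_sd))
        truth.sexes[specimen] = sex
        truth.mean_u[specimen] = mean_u
        for rep in range(1, config.replicates + 1):
            well = next_well()
            m_x, m_y, x_det, y_det = sample_reaction(sex, mean_u, config, rng)
            rx, ry = render_trace(
                well, m_x if x_det else 0.0, m_y if y_det else 0.0, config, rng
            )
            records += [rx, ry]
            sheet.append(SampleSheetRow(
                well=well, specimen_id=specimen, replicate_index=rep, role="unknown",
            ))
            truth.reactions.append(ReactionTruth(
                specimen_id=specimen, replicate_index=rep, well=well,
                m_x=m_x, m_y=m_y, x_detected=x_det, y_detected=y_det,
            ))

    # negative controls
    for role, count in (("ntc", 2), ("extraction_blank", 2)):
        for rep in range(1, count + 1):
            well = next_well()
            rx, ry = render_trace(well, 0.0, 0.0, config, rng)
            records += [rx, ry]
            sheet.append(SampleSheetRow(
                well=well, specimen_id=role.upper(), replicate_index=rep, role=role,
            ))

    bundle = RunBundle(records=records, sheet=sheet, cycles=config.cycles,
                       metadata={"simulated": "true", "seed": str(config.seed),
                                 "outcome_model": config.outcome_model})
    bundle.validate(dyes=(config.dye_x, config.dye_y))
    return bundle, truth
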