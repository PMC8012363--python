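"""Cq extraction and absolute quantification from standard curves.

The quantification cycle (Cq) is determined by the single-threshold method:
per dye, the threshold is 10% of the average plateau fluorescence of the
run's positive wells, and Cq is the (linearly interpolated) first crossing
of the baseline-subtracted curve.  A log-linear standard curve
``Cq = slope * log10(copies) + intercept`` fitted to a tenfold dilution
series then converts Cq to absolute copy number (CN) per reaction; the
amplification efficiency is ``10^(-1/slope) - 1`` (1.0 = perfect doubling,
the published assay runs at ~0.98 with r² > 0.997).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import RunBundle, WellRecord

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurveFit", "QuantResult",
    "subtract_baseline", "plateau", "run_threshold",
    "cq_from_trace", "fit_standard_curve", "copies_from_cq",
    "DEFAULT_BASELINE_WINDOW", "DEFAULT_NOISE_FLOOR",
]

#: Cycles averaged for per-trace baseline estimation (inclusive bounds).
DEFAULT_BASELINE_WINDOW = (3, 10)
#: Minimum baseline-subtracted plateau (RFU) for a well to count as
#: positive when averaging plateaus for the run threshold.
DEFAULT_NOISE_FLOOR = 100.0


class DegenerateFitError(ValueError):
    """Standard-curve fit impossible (fewer than two distinct levels)."""


def subtract_baseline(
    values: Sequence[float],
    window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> np.ndarray:
    """Subtract the mean fluorescence of the baseline cycles (1-based,
    inclusive window, clipped to the trace length)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = window
    lo = max(lo, 1)
    hi = min(hi, len(arr))
    if hi < lo:
        return arr - arr[0]
    return arr - arr[lo - 1 : hi].mean()


def plateau(values: Sequence[float], k: int = 5) -> float:
    """Mean of the last *k* fluorescence values — the plateau estimate."""
    if len(values) < k:
        raise ValueError(f"trace of length {len(values)} shorter than k={k}")
    return float(np.mean(np.asarray(values, dtype=float)[-k:]))


def run_threshold(
    bundle: RunBundle,
    dye: str,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    k: int = 5,
) -> float:
    """Per-dye run threshold: 10% of the mean plateau of positive wells.

    A well qualifies when its baseline-subtracted plateau exceeds
    *noise_floor*.  One threshold per dye per run; FAM and VIC are kept
    separate because their plateau levels differ systematically.
    """
    plateaus = []
    for rec in bundle.records:
        if rec.dye != dye or rec.trace is None:
            continue
        p = plateau(subtract_baseline(rec.fluorescence(), baseline_window), k)
        if p >= noise_floor:
            plateaus.append(p)
    if not plateaus:
        raise ValueError(
            f"no positive wells for dye {dye!r}: cannot set a trace threshold; "
            "supply endpoint-dialect data with instrument Cq instead"
        )
    return 0.10 * float(np.mean(plateaus))


def cq_from_trace(
    values: Sequence[float],
    threshold: float,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> Optional[float]:
    """First threshold crossing of the baseline-subtracted trace,
    linearly interpolated between the bracketing cycles.

    Returns ``None`` when the curve never crosses within the run.  With
    noisy non-monotone traces the first crossing wins (warning logged).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    f = subtract_baseline(values, baseline_window)
    above = f >= threshold
    if not above.any():
        return None
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if above[0]:
        logger.warning("trace already above threshold at cycle 1")
        return 1.0
    if len(crossings) > 1:
        logger.warning("multiple threshold crossings; using the first")
    i = int(crossings[0])  # crossing between cycles i+1 and i+2 (1-based)
    c1 = i + 1
    f1, f2 = f[i], f[i + 1]
    return float(c1 + (threshold - f1) / (f2 - f1))


@dataclass(frozen=True)
class StandardCurveFit:
    """Log-linear standard curve for one dye.

    slope is in cycles per decade (negative for a working assay); intercept
    is the Cq at one copy; efficiency = 10^(-1/slope) - 1.
    """

    slope: float
    intercept: float
    efficiency: float
    r2: float
    dye: str
    n_points: int
    cq_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("standard curve needs >= 2 points")
        expected = 10 ** (-1.0 / self.slope) - 1.0
        if not math.isclose(self.efficiency, expected, rel_tol=0, abs_tol=1e-12):
            raise ValueError("efficiency inconsistent with slope")


@dataclass(frozen=True)
class QuantResult:
    well: str
    dye: str
    cq: Optional[float]
    copies: Optional[float]
    extrapolated: bool = False


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    dye: str,
) -> StandardCurveFit:
    """OLS regression of Cq on log10(nominal copies).

    Nominal standard copies are treated as exact.  A positive slope is
    returned with a warning (the caller decides whether to trust it);
    a single dilution level is a hard error.
    """
    if len(points) < 2:
        raise DegenerateFitError("need at least 2 standard points")
    copies = np.array([c for c, _ in points], dtype=float)
    cqs = np.array([q for _, q in points], dtype=float)
    if (copies <= 0).any():
        raise ValueError("standard copies must be > 0")
    x = np.log10(copies)
    if np.allclose(x, x[0]):
        raise DegenerateFitError("all standards at a single copy level")
    res = stats.linregress(x, cqs)
    slope = float(res.slope)
    if slope >= 0:
        logger.warning("standard curve slope is non-negative (%.3f)", slope)
    efficiency = 10 ** (-1.0 / slope) - 1.0
    return StandardCurveFit(
        slope=slope,
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r2=float(res.rvalue ** 2),
        dye=dye,
        n_points=len(points),
        cq_range=(float(cqs.min()), float(cqs.max())),
    )


def copies_from_cq(fit: StandardCurveFit, cq: float) -> float:
    """Invert the standard curve: copies = 10^((cq − intercept)/slope).

    Extrapolation outside the fitted Cq range is allowed; callers can use
    ``fit.cq_range`` to flag it.
    """
    return 10 ** ((cq - fit.intercept) / fit.slope)
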