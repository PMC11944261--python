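"""Normative machinery: TD, PD, probability maps, MD and PSD.

Pointwise sensitivities (dB) are compared against an age-corrected
normative expectation to give total deviation (TD); subtracting the
general height (GH, a high-rank order statistic of TD that absorbs
diffuse loss such as cataract) yields pattern deviation (PD), which
isolates focal loss.  Deviations are then categorised against normative
percentile cutoffs (p<5%, p<2%, p<1%, p<0.5%) to form the probability
maps that the clinical cluster criteria are stated over.

The package ships a synthetic normative reference (linear age decay,
eccentricity-dependent intercepts and variability); real HFA normative
data are proprietary and no attempt is made to reproduce them.  A loader
for user-supplied references in the documented plain-text schema is
provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid24_2, build_grid

__all__ = [
    "NormativeReference",
    "VFExam",
    "synthetic_reference",
    "total_deviation",
    "general_height",
    "pattern_deviation",
    "probability_map",
    "mean_deviation",
    "pattern_standard_deviation",
    "PROB_LEVELS",
    "PROB_LABELS",
]

log = logging.getLogger(__name__)

# Probability categories, least to most extreme.  Integer codes are used
# internally; 0 = within normal limits.
PROB_LEVELS = (0.05, 0.02, 0.01, 0.005)
PROB_LABELS = {0: "normal", 1: "p<5%", 2: "p<2%", 3: "p<1%", 4: "p<0.5%"}

_REFERENCE_AGE = 45.0


@dataclass
class NormativeReference:
    """Per-location normative model over the 52 analysed 24-2 locations.

    ``intercept`` is the expected sensitivity (dB) at the reference age,
    ``slope`` the age decay (dB/year, non-positive).  ``td_cutoffs`` and
    ``pd_cutoffs`` are (52, 4) arrays of deviation cutoffs (dB, negative)
    at the 5/2/1/0.5 % levels, most extreme last.  ``psd_p95`` is the 95th
    normal percentile of the simplified PSD, used by criteria that require
    an abnormal PSD.
    """

    intercept: np.ndarray
    slope: np.ndarray
    td_cutoffs: np.ndarray
    pd_cutoffs: np.ndarray
    gh_rank: int = 7
    psd_p95: float = 0.0
    reference_age: float = _REFERENCE_AGE
    age_range: tuple[float, float] = (18.0, 95.0)

    def __post_init__(self) -> None:
        for name in ("intercept", "slope", "td_cutoffs", "pd_cutoffs"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.intercept.shape != (52,) or self.slope.shape != (52,):
            raise ValueError("intercept and slope must have shape (52,)")
        if self.td_cutoffs.shape != (52, 4) or self.pd_cutoffs.shape != (52, 4):
            raise ValueError("cutoff tables must have shape (52, 4)")
        if np.any(self.slope > 0):
            raise ValueError("age slope must be <= 0 (sensitivity does not improve with age)")
        for cuts in (self.td_cutoffs, self.pd_cutoffs):
            if np.any(cuts >= 0) or np.any(np.diff(cuts, axis=1) >= 0):
                raise ValueError(
                    "cutoffs must be negative and strictly ordered "
                    "cutoff(0.5%) < cutoff(1%) < cutoff(2%) < cutoff(5%) < 0"
                )

    def expected_sensitivity(self, age: float) -> np.ndarray:
        """Age-expected normal sensitivity at every analysed location."""
        lo, hi = self.age_range
        if age < lo or age > hi:
            warnings.warn(
                f"age {age} outside the reference range {self.age_range}; "
                "using the boundary value",
                stacklevel=2,
            )
            age = min(max(age, lo), hi)
        return self.intercept + self.slope * (age - self.reference_age)

    def to_table(self, path) -> None:
        """Documented plain-text serialization (one row per location)."""
        cols = {"position": np.arange(1, 53), "intercept": self.intercept, "slope": self.slope}
        for j, lvl in enumerate(PROB_LEVELS):
            cols[f"td_cutoff_{lvl:g}"] = self.td_cutoffs[:, j]
        for j, lvl in enumerate(PROB_LEVELS):
            cols[f"pd_cutoff_{lvl:g}"] = self.pd_cutoffs[:, j]
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write(f"# gh_rank={self.gh_rank} psd_p95={self.psd_p95:.6f} "
                     f"reference_age={self.reference_age:g}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_table(cls, path) -> "NormativeReference":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            df = pd.read_csv(fh)
        td = df[[f"td_cutoff_{l:g}" for l in PROB_LEVELS]].to_numpy()
        pd_ = df[[f"pd_cutoff_{l:g}" for l in PROB_LEVELS]].to_numpy()
        return cls(
            intercept=df["intercept"].to_numpy(),
            slope=df["slope"].to_numpy(),
            td_cutoffs=td,
            pd_cutoffs=pd_,
            gh_rank=int(meta["gh_rank"]),
            psd_p95=float(meta["psd_p95"]),
            reference_age=float(meta["reference_age"]),
        )


def synthetic_reference(grid: Optional[Grid24_2] = None, gh_rank: int = 7,
                        age_slope: float = -0.065) -> NormativeReference:
    """Build the packaged synthetic normative reference.

    Expected sensitivity declines linearly with eccentricity (the hill of
    vision) and with age; between-subject variability grows with
    eccentricity, which produces the familiar pattern of wider deviation
    cutoffs in the periphery.  Cutoffs are Gaussian quantiles of the
    location's variability; PD cutoffs are slightly tighter than TD
    cutoffs because GH subtraction removes the common diffuse component.
    """
    grid = grid or build_grid("OD")
    test = [l for l in grid.locations if not l.is_blind_spot]
    ecc = np.array([np.hypot(l.x, l.y) for l in test])
    intercept = 34.0 - 0.10 * ecc
    slope = np.full(52, age_slope)
    sd = 2.2 + 0.06 * ecc
    z = stats.norm.ppf(PROB_LEVELS)  # negative, increasingly extreme
    td_cutoffs = sd[:, None] * z[None, :]
    pd_cutoffs = 0.9 * sd[:, None] * z[None, :]
    # 95th normal percentile of the simplified PSD via a fixed Monte Carlo
    rng = np.random.default_rng(20240202)
    fields = rng.standard_normal((4000, 52)) * sd
    psd = fields.std(axis=1, ddof=1)
    return NormativeReference(
        intercept=intercept,
        slope=slope,
        td_cutoffs=td_cutoffs,
        pd_cutoffs=pd_cutoffs,
        gh_rank=gh_rank,
        psd_p95=float(np.percentile(psd, 95)),
    )


@dataclass
class VFExam:
    """One Humphrey 24-2 visual field test of one eye.

    Array fields are length 52 and aligned to the grid's non-blind-spot
    indices in ascending order (compact positions 1..52).  ``td_prob`` and
    ``pd_prob`` hold integer category codes (see :data:`PROB_LABELS`).
    """

    patient_id: str
    eye: str
    test_date: date
    age: float
    gender: int
    race: int
    follow_up: float
    fpr: Optional[float]
    sensitivities: Optional[np.ndarray] = None
    td: Optional[np.ndarray] = None
    pd: Optional[np.ndarray] = None
    td_prob: Optional[np.ndarray] = None
    pd_prob: Optional[np.ndarray] = None
    md: Optional[float] = None
    label: Optional[int] = None  # 1 = GL, 0 = non-GL
    true_deviation: Optional[np.ndarray] = None  # generator ground truth

    def __post_init__(self) -> None:
        for name in ("sensitivities", "td", "pd", "true_deviation"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (52,):
                    raise ValueError(f"{name} must have shape (52,), got {v.shape}")
                setattr(self, name, v)
        if self.sensitivities is not None and np.any(self.sensitivities < 0):
            raise ValueError("sensitivities are floored at 0 dB (not seen)")
        if self.fpr is not None and not 0.0 <= self.fpr <= 1.0:
            raise ValueError(f"fpr must lie in [0, 1], got {self.fpr}")

    def prob_map(self, kind: str) -> np.ndarray:
        m = self.td_prob if kind == "TD" else self.pd_prob if kind == "PD" else None
        if kind not in ("TD", "PD"):
            raise ValueError(f"map kind must be 'TD' or 'PD', got {kind!r}")
        if m is None:
            raise ValueError(f"exam has no {kind} probability map")
        return m


def total_deviation(exam: VFExam, norm: NormativeReference) -> np.ndarray:
    """TD[i] = sensitivity[i] - age-expected normal sensitivity[i]."""
    if exam.sensitivities is None:
        raise ValueError("exam has no sensitivities; cannot compute TD")
    td = exam.sensitivities - norm.expected_sensitivity(exam.age)
    exam.td = td
    return td


def general_height(td: Sequence[float], rank: int = 7) -> float:
    """The rank-th highest TD value (default 7th of 52, ~85th percentile)."""
    td = np.asarray(td, dtype=float)
    if not 1 <= rank <= td.size:
        raise ValueError(f"rank must lie in [1, {td.size}], got {rank}")
    return float(np.sort(td)[::-1][rank - 1])


def pattern_deviation(td: Sequence[float], rank: int = 7) -> np.ndarray:
    """PD[i] = TD[i] - GH; removes diffuse loss, keeps focal loss."""
    td = np.asarray(td, dtype=float)
    return td - general_height(td, rank)


def probability_map(dev: Sequence[float], norm: NormativeReference, kind: str) -> np.ndarray:
    """Categorise deviations against the reference's percentile cutoffs.

    Returns integer codes 0..4 (0 = normal, 4 = p<0.5%): the most extreme
    category whose cutoff exceeds the deviation.
    """
    if kind == "TD":
        cuts = norm.td_cutoffs
    elif kind == "PD":
        cuts = norm.pd_cutoffs
    else:
        raise ValueError(f"map kind must be 'TD' or 'PD', got {kind!r}")
    dev = np.asarray(dev, dtype=float)
    # cuts[:, j] decreasing in j; category = count of cutoffs above dev
    return (dev[:, None] < cuts).sum(axis=1).astype(int)


def mean_deviation(td: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Weighted mean of TD (unweighted by default; HFA's proprietary
    variance weights are not published)."""
    td = np.asarray(td, dtype=float)
    if weights is None:
        return float(td.mean())
    w = np.asarray(weights, dtype=float)
    return float(np.average(td, weights=w))


def pattern_standard_deviation(td: Sequence[float]) -> float:
    """Simplified PSD: unweighted SD of TD about its mean."""
    td = np.asarray(td, dtype=float)
    return float(td.std(ddof=1))


def annotate_exam(exam: VFExam, norm: NormativeReference) -> VFExam:
    """Fill TD, PD, probability maps and MD on an exam from sensitivities
    (or from a pre-existing TD map)."""
    if exam.td is None:
        total_deviation(exam, norm)
    if exam.pd is None:
        exam.pd = pattern_deviation(exam.td, norm.gh_rank)
    exam.td_prob = probability_map(exam.td, norm, "TD")
    exam.pd_prob = probability_map(exam.pd, norm, "PD")
    if exam.md is None:
        exam.md = mean_deviation(exam.td)
    return exam
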