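"""Cohort assembly: reliability/longitudinal filters, severity staging,
patient-level train/test splitting and characteristics summaries.

A :class:`Cohort` is a collection of :class:`~vfstack.normative.VFExam`
objects indexed by patient.  The CSV interchange schema (one row per
exam) is: ``patient_id, eye, date, age, gender, race, follow_up_years,
fpr, md, s1..s52, td1..td52, pd1..pd52, label`` with ISO-8601 dates;
missing numeric cells are allowed and median-imputed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .normative import VFExam

__all__ = [
    "Cohort",
    "SeverityStage",
    "filter_reliability",
    "filter_longitudinal",
    "stage_severity",
    "split_train_test",
    "summarize_cohort",
    "SEVERITY_BOUNDS",
]

log = logging.getLogger(__name__)

# Mean-deviation bands (dB): mild MD > -4.20; moderate -8.17 < MD <= -4.20;
# severe MD <= -8.17.
SEVERITY_BOUNDS = {"mild": -4.20, "severe": -8.17}


@dataclass(frozen=True)
class SeverityStage:
    stage: str  # "mild" | "moderate" | "severe"


@dataclass
class Cohort:
    """Visual-field exams grouped by patient, date-sorted within patient."""

    exams: List[VFExam] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        by_patient: Dict[str, List[VFExam]] = {}
        for e in self.exams:
            by_patient.setdefault(e.patient_id, []).append(e)
        for pid in by_patient:
            by_patient[pid].sort(key=lambda e: (e.test_date, e.eye))
        self.by_patient = by_patient

    @property
    def patient_ids(self) -> List[str]:
        return sorted(self.by_patient)

    @property
    def n_patients(self) -> int:
        return len(self.by_patient)

    @property
    def n_exams(self) -> int:
        return len(self.exams)

    def eyes(self) -> Dict[Tuple[str, str], List[VFExam]]:
        """Exams grouped by (patient_id, eye), date-sorted."""
        out: Dict[Tuple[str, str], List[VFExam]] = {}
        for e in self.exams:
            out.setdefault((e.patient_id, e.eye), []).append(e)
        for key in out:
            out[key].sort(key=lambda e: e.test_date)
        return out

    # ---------------------------------------------------------------- CSV IO

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.exams:
            row = {
                "patient_id": e.patient_id,
                "eye": e.eye,
                "date": e.test_date.isoformat(),
                "age": e.age,
                "gender": e.gender,
                "race": e.race,
                "follow_up_years": e.follow_up,
                "fpr": e.fpr,
                "md": e.md,
            }
            for name, arr in (("s", e.sensitivities), ("td", e.td), ("pd", e.pd)):
                for k in range(52):
                    row[f"{name}{k + 1}"] = None if arr is None else arr[k]
            row["label"] = e.label
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        exams = []
        for _, r in df.iterrows():
            def block(prefix):
                vals = np.array([r.get(f"{prefix}{k + 1}", np.nan) for k in range(52)], dtype=float)
                return None if np.all(np.isnan(vals)) else vals

            exams.append(
                VFExam(
                    patient_id=str(r["patient_id"]),
                    eye=str(r["eye"]),
                    test_date=date.fromisoformat(str(r["date"])),
                    age=float(r["age"]),
                    gender=int(r["gender"]),
                    race=int(r["race"]),
                    follow_up=float(r["follow_up_years"]),
                    fpr=None if pd.isna(r.get("fpr")) else float(r["fpr"]),
                    sensitivities=block("s"),
                    td=block("td"),
                    pd=block("pd"),
                    md=None if pd.isna(r.get("md")) else float(r["md"]),
                    label=None if pd.isna(r.get("label")) else int(r["label"]),
                )
            )
        return cls(exams)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_dataframe(pd.read_csv(path))


def filter_reliability(cohort: Cohort, max_fpr: float = 0.33) -> Cohort:
    """Drop exams whose false-positive rate *exceeds* ``max_fpr``.

    The boundary is retained (an exam at exactly the threshold passes);
    exams with a missing FPR are excluded with a warning.
    """
    kept, dropped, missing = [], 0, 0
    for e in cohort.exams:
        if e.fpr is None:
            missing += 1
        elif e.fpr <= max_fpr:
            kept.append(e)
        else:
            dropped += 1
    if missing:
        log.warning("filter_reliability: %d exams had no FPR and were excluded", missing)
    log.info("filter_reliability: removed %d of %d exams (fpr > %.2f)",
             dropped + missing, cohort.n_exams, max_fpr)
    return Cohort(kept)


def filter_longitudinal(cohort: Cohort, min_tests: int = 2,
                        min_follow_up: float = 0.5) -> Cohort:
    """Keep patients with >= ``min_tests`` exams on distinct dates and a
    first-to-last span of >= ``min_follow_up`` years (boundary inclusive)."""
    kept: List[VFExam] = []
    for pid, exams in cohort.by_patient.items():
        dates = sorted({e.test_date for e in exams})
        if len(dates) < min_tests:
            continue
        span_years = (dates[-1] - dates[0]).days / 365.25
        if span_years + 1e-9 < min_follow_up:
            continue
        kept.extend(exams)
    log.info("filter_longitudinal: kept %d of %d patients",
             len({e.patient_id for e in kept}), cohort.n_patients)
    return Cohort(kept)


def stage_severity(md: float) -> SeverityStage:
    """Stage a mean deviation into mild/moderate/severe bands."""
    if not np.isfinite(md):
        raise ValueError(f"MD must be finite, got {md}")
    if md > SEVERITY_BOUNDS["mild"]:
        return SeverityStage("mild")
    if md > SEVERITY_BOUNDS["severe"]:
        return SeverityStage("moderate")
    return SeverityStage("severe")


def split_train_test(ids: Iterable | int, train_fraction: float = 0.825,
                     seed: int = 0) -> Tuple[list, list]:
    """Deterministic patient-level split with |train| = round(n * fraction)."""
    if isinstance(ids, int):
        ids = list(range(ids))
    ids = sorted(ids)
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 ids to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def summarize_cohort(cohort: Cohort) -> dict:
    """Characteristics summary (counts, age, gender/race mix, follow-up,
    visits per eye, MD overall and per severity stage)."""
    if cohort.n_exams == 0:
        raise ValueError("cannot summarize an empty cohort")
    ages = np.array([e.age for e in cohort.exams], dtype=float)
    mds = np.array([e.md for e in cohort.exams if e.md is not None], dtype=float)
    fu = np.array([e.follow_up for e in cohort.exams], dtype=float)
    genders = pd.Series([e.gender for e in cohort.exams])
    races = pd.Series([e.race for e in cohort.exams])
    visits = np.array([len(v) for v in cohort.eyes().values()], dtype=float)

    def pct(series):
        return (series.value_counts(normalize=True).sort_index() * 100).to_dict()

    out = {
        "n_patients": cohort.n_patients,
        "n_exams": cohort.n_exams,
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=0)) if ages.size == 1 else float(ages.std(ddof=1)),
        "gender_pct": pct(genders),
        "race_pct": pct(races),
        "follow_up_median": float(np.median(fu)),
        "follow_up_iqr": (float(np.percentile(fu, 25)), float(np.percentile(fu, 75))),
        "visits_per_eye_mean": float(visits.mean()),
        "visits_per_eye_sd": float(visits.std(ddof=1)) if visits.size > 1 else 0.0,
    }
    if mds.size:
        out["md_mean"] = float(mds.mean())
        out["md_sd"] = float(mds.std(ddof=1)) if mds.size > 1 else 0.0
        for stage in ("mild", "moderate", "severe"):
            sel = mds[[stage_severity(m).stage == stage for m in mds]]
            out[f"md_mean_{stage}"] = float(sel.mean()) if sel.size else float("nan")
            out[f"n_{stage}"] = int(sel.size)
    return out
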