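"""Synthetic Humphrey 24-2 cohorts with ground-truth labels.

The generator emulates the statistical structure the pipeline assumes
about a real perimetry database: age-dependent normal sensitivities,
glaucomatous defects drawn from retinal-nerve-fibre-bundle-shaped
archetypes concentrated in the superior-temporal and inferior-nasal
sectors, diffuse loss, measurement noise, severity strata defined by
mean-deviation bands, and an exam-level false-positive reliability
index.  Archetype masks ship as an editable location-index table
(``vfstack/data/archetypes.csv``).

Everything is deterministic given the config seed; each patient draws
from an independent substream so cohorts are reproducible regardless of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import Grid24_2, build_grid
from .normative import (NormativeReference, VFExam, annotate_exam,
                        synthetic_reference)
from .cohort import Cohort, SEVERITY_BOUNDS

__all__ = ["SimulationConfig", "simulate_exam", "simulate_cohort", "load_archetypes"]

# Severity-band MD targets (dB): (mean, sd) per band, matching the
# mild/moderate/severe characteristics the staging bounds describe.
_BAND_TARGETS = {
    "mild": (-1.13, 1.0),
    "moderate": (-5.83, 1.12),
    "severe": (-16.34, 4.0),
}
_MAX_FOCAL_DEPTH = 28.0  # dB; beyond this the location is effectively blind


def load_archetypes() -> Dict[str, Optional[List[int]]]:
    """Defect archetype masks as grid-index lists ('diffuse' -> None)."""
    with resources.files("vfstack.data").joinpath("archetypes.csv").open() as fh:
        df = pd.read_csv(fh)
    out: Dict[str, Optional[List[int]]] = {}
    for _, r in df.iterrows():
        tok = str(r["indices"])
        out[str(r["name"])] = None if tok == "all" else [int(t) for t in tok.split(";")]
    return out


@dataclass
class SimulationConfig:
    """Study conditions of a simulated cohort.

    Defaults emulate a tertiary-care perimetry population: age 61.9 +/-
    17.4 years, 58% female, the published race mix, a lognormal follow-up
    with median ~2.5 years, 2-5 visits per eye, glaucoma prevalence 0.5
    (the clinically labelled subset is roughly balanced), severity mix
    half mild, and Beta-distributed false-positive rates with a small
    tail beyond the 33% reliability cutoff.
    """

    n_patients: int = 160
    exams_per_patient: Tuple[int, int] = (2, 5)  # inclusive range
    age_mean: float = 61.86
    age_sd: float = 17.40
    p_female: float = 0.5806
    race_probs: Tuple[float, ...] = (0.7018, 0.1170, 0.0602, 0.0398, 0.0812)
    prevalence: float = 0.5
    archetype_mix: Dict[str, float] = field(default_factory=lambda: {
        "st_arcuate": 0.30, "in_arcuate": 0.25, "nasal_step": 0.15,
        "paracentral": 0.15, "diffuse": 0.15,
    })
    severity_mix: Dict[str, float] = field(default_factory=lambda: {
        "mild": 0.50, "moderate": 0.25, "severe": 0.25,
    })
    defect_depth_db: Optional[float] = None  # fixed focal depth; None -> severity-targeted
    noise_sd_db: float = 2.0
    fpr_beta: Tuple[float, float] = (1.2, 8.0)
    follow_up_lognorm: Tuple[float, float] = (0.912, 1.2)  # ln-scale mu, sigma
    progression_db_per_year: float = 0.0  # defaults off: cross-sectional framing
    seed: int = 0

    def validate(self) -> None:
        for name, mix in (("archetype_mix", self.archetype_mix),
                          ("severity_mix", self.severity_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} proportions must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} proportions must be non-negative")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.noise_sd_db < 0 or self.age_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(sum(self.race_probs) - 1.0) > 1e-6:
            raise ValueError("race_probs must sum to 1")


@dataclass
class _PatientState:
    patient_id: str
    eye: str
    age0: float
    gender: int
    race: int
    follow_up: float
    label: int
    archetype: Optional[str]
    focal_depth: float
    diffuse_depth: float
    mask: Optional[List[int]]


def _plan_defect(stratum: str, archetype: str, mask_size: int,
                 cfg: SimulationConfig, rng: np.random.Generator
                 ) -> Tuple[float, float]:
    """Split a severity-targeted MD into focal depth on the mask plus a
    diffuse remainder spread over all locations."""
    if cfg.defect_depth_db is not None:
        return float(cfg.defect_depth_db), 0.0
    mean, sd = _BAND_TARGETS[stratum]
    target_md = min(rng.normal(mean, sd), -0.25)
    total_loss = -target_md  # dB, positive
    if archetype == "diffuse":
        return 0.0, total_loss
    focal = min(total_loss * 52.0 / mask_size, _MAX_FOCAL_DEPTH)
    diffuse = max(0.0, total_loss - focal * mask_size / 52.0)
    return focal, diffuse


def simulate_exam(state: _PatientState, cfg: SimulationConfig,
                  norm: NormativeReference, grid: Grid24_2,
                  rng: np.random.Generator, test_date: date,
                  years_from_baseline: float = 0.0) -> VFExam:
    """One exam: age-expected normals minus the patient's defect plus
    Gaussian noise, floored at 0 dB, with TD/PD/probability maps filled
    in through the normative module and ground truth retained."""
    cfg.validate()
    age = min(state.age0 + years_from_baseline, 95.0)
    expected = norm.expected_sensitivity(age)
    deviation = np.zeros(52)
    if state.label == 1:
        depth = state.focal_depth + cfg.progression_db_per_year * years_from_baseline
        if state.mask is not None:
            pos = {idx: k for k, idx in enumerate(grid.test_indices)}
            for idx in state.mask:
                deviation[pos[idx]] -= depth
        deviation -= state.diffuse_depth
    noise = rng.normal(0.0, cfg.noise_sd_db, size=52) if cfg.noise_sd_db > 0 else 0.0
    sens = np.maximum(expected + deviation + noise, 0.0)
    exam = VFExam(
        patient_id=state.patient_id,
        eye=state.eye,
        test_date=test_date,
        age=age,
        gender=state.gender,
        race=state.race,
        follow_up=state.follow_up,
        fpr=float(np.clip(rng.beta(*cfg.fpr_beta), 0.0, 1.0)),
        sensitivities=sens,
        label=state.label,
        true_deviation=deviation.copy(),
    )
    return annotate_exam(exam, norm)


def simulate_cohort(cfg: SimulationConfig,
                    norm: Optional[NormativeReference] = None,
                    grid: Optional[Grid24_2] = None
                    ) -> Tuple[Cohort, pd.DataFrame]:
    """Simulate a longitudinal cohort; returns the cohort and a
    ground-truth table (patient, eye, label, archetype, depths)."""
    cfg.validate()
    grid = grid or build_grid("OD")
    norm = norm or synthetic_reference(grid)
    archetypes = load_archetypes()
    for name in cfg.archetype_mix:
        if name not in archetypes:
            raise ValueError(f"unknown archetype {name!r} in archetype_mix")

    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_patients)
    exams: List[VFExam] = []
    truth_rows = []
    arch_names = sorted(cfg.archetype_mix)
    arch_p = np.array([cfg.archetype_mix[a] for a in arch_names])
    sev_names = sorted(cfg.severity_mix)
    sev_p = np.array([cfg.severity_mix[s] for s in sev_names])

    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:05d}"
        eye = "OD" if rng.random() < 0.5 else "OS"
        label = int(rng.random() < cfg.prevalence)
        age0 = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 20.0, 95.0))
        gender = int(rng.random() >= cfg.p_female)  # 0 = female
        race = int(rng.choice(len(cfg.race_probs), p=cfg.race_probs))
        follow_up = float(np.clip(
            rng.lognormal(*cfg.follow_up_lognorm), 0.5, 25.0))
        archetype = stratum = None
        focal = diffuse = 0.0
        mask = None
        if label == 1:
            archetype = str(rng.choice(arch_names, p=arch_p))
            stratum = str(rng.choice(sev_names, p=sev_p))
            mask = archetypes[archetype]
            focal, diffuse = _plan_defect(
                stratum, archetype, len(mask) if mask else 52, cfg, rng)
        state = _PatientState(pid, eye, age0, gender, race, follow_up,
                              label, archetype, focal, diffuse, mask)

        n_exams = int(rng.integers(cfg.exams_per_patient[0],
                                   cfg.exams_per_patient[1] + 1))
        baseline = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 2000)))
        # visit times spread over the follow-up window, baseline first
        offsets = np.sort(rng.uniform(0.0, state.follow_up, size=n_exams - 1)) \
            if n_exams > 1 else np.array([])
        times = np.concatenate([[0.0], offsets]) if n_exams > 1 else np.array([0.0])
        times[-1] = state.follow_up if n_exams > 1 else 0.0
        seen_dates = set()
        for t in times:
            d = baseline + timedelta(days=int(round(t * 365.25)))
            while d in seen_dates:  # force distinct test dates
                d += timedelta(days=1)
            seen_dates.add(d)
            exams.append(simulate_exam(state, cfg, norm, grid, rng, d, float(t)))
        truth_rows.append({
            "patient_id": pid, "eye": eye, "label": label,
            "archetype": archetype, "severity_target": stratum,
            "focal_depth_db": focal, "diffuse_depth_db": diffuse,
        })
    return Cohort(exams), pd.DataFrame(truth_rows)
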