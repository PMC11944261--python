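"""The five rule-based glaucomatous-field criteria through one generic
parameterized cluster-rule engine.

Each criterion (LoGTS, UKGTS, Kang, HAP2_p1, Foster) is expressed as a
:class:`CriterionSpec`: a cluster requirement on the TD or PD
probability map (``cluster_min_size`` contiguous locations at or beyond
``cluster_level``, at least one at or beyond ``anchor_level``, optionally
restricted to non-edge locations and a single hemifield), optionally
AND-ed with a glaucoma-hemifield-test (GHT) "outside normal limits"
requirement and/or an abnormal pattern standard deviation.  An eye is
called glaucomatous when at least ``confirmation_tests`` exams on
distinct dates qualify.

The default parameter sets ship as an editable YAML config
(``vfstack/data/criteria.yaml``); the GHT here is a simplified
mirrored-zone score comparison with a packaged zone table, documented as
an approximation of the proprietary instrument test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .grid import Grid24_2, find_clusters
from .normative import VFExam, pattern_standard_deviation, PROB_LABELS
from .cohort import Cohort

__all__ = [
    "CriterionSpec",
    "CriterionVerdict",
    "evaluate_cluster_rule",
    "glaucoma_hemifield_test",
    "classify",
    "run_all_criteria",
    "load_criteria",
    "save_criteria",
    "default_criteria",
    "CRITERION_NAMES",
]

CRITERION_NAMES = ("LoGTS", "UKGTS", "Kang", "HAP2_p1", "Foster")

_LEVEL_CODE = {"normal": 0, "p<5%": 1, "p<2%": 2, "p<1%": 3, "p<0.5%": 4}

# GHT zone-pair score difference thresholds (simplified): a pair whose
# summed category scores differ by >= _GHT_OUTSIDE is outside normal
# limits; >= _GHT_BORDERLINE is borderline.
_GHT_OUTSIDE = 6
_GHT_BORDERLINE = 4


@dataclass
class CriterionSpec:
    """Parameterization of one rule-based classifier."""

    name: str
    map_kind: str  # "TD" | "PD"
    cluster_min_size: int = 3
    cluster_level: str = "p<5%"
    anchor_level: str = "p<1%"
    non_edge_only: bool = False
    same_hemifield: bool = False
    require_ght_outside: bool = False
    require_psd_abnormal: bool = False
    psd_percentile: float = 0.05
    confirmation_tests: int = 1

    def __post_init__(self) -> None:
        if self.map_kind not in ("TD", "PD"):
            raise ValueError(f"map_kind must be 'TD' or 'PD', got {self.map_kind!r}")
        if self.cluster_min_size < 1:
            raise ValueError("cluster_min_size must be >= 1")
        if self.confirmation_tests < 1:
            raise ValueError("confirmation_tests must be >= 1")
        if _LEVEL_CODE[self.anchor_level] < _LEVEL_CODE[self.cluster_level]:
            raise ValueError("anchor_level must be at least as extreme as cluster_level")


@dataclass
class CriterionVerdict:
    """Outcome of one criterion on one eye, with supporting evidence."""

    name: str
    is_glaucoma: bool
    clusters: List[FrozenSet[int]] = field(default_factory=list)
    ght_results: List[str] = field(default_factory=list)
    psd_values: List[float] = field(default_factory=list)
    qualifying_dates: List = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.is_glaucoma and not self.qualifying_dates:
            raise ValueError("a positive verdict requires qualifying evidence")


def _zone_table() -> List[Tuple[List[int], List[int]]]:
    with resources.files("vfstack.data").joinpath("ght_zones.csv").open() as fh:
        df = pd.read_csv(fh)
    pairs = []
    for _, r in df.iterrows():
        sup = [int(t) for t in str(r["superior_indices"]).split(";")]
        inf = [int(t) for t in str(r["inferior_indices"]).split(";")]
        pairs.append((sup, inf))
    return pairs


def _prob_by_index(exam: VFExam, grid: Grid24_2, kind: str) -> Dict[int, int]:
    codes = exam.prob_map(kind)
    return dict(zip(grid.test_indices, codes))


def evaluate_cluster_rule(exam: VFExam, spec: CriterionSpec,
                          grid: Grid24_2) -> Tuple[bool, List[FrozenSet[int]]]:
    """Apply the cluster component of a criterion to one exam.

    Returns ``(passes, qualifying_clusters)``; a qualifying cluster has at
    least ``cluster_min_size`` members flagged at or beyond
    ``cluster_level``, of which at least one reaches ``anchor_level``.
    """
    prob = _prob_by_index(exam, grid, spec.map_kind)
    cluster_code = _LEVEL_CODE[spec.cluster_level]
    anchor_code = _LEVEL_CODE[spec.anchor_level]
    flags = {idx: code >= cluster_code for idx, code in prob.items()}
    comps = find_clusters(flags, grid, non_edge_only=spec.non_edge_only,
                          same_hemifield=spec.same_hemifield)
    qualifying = [
        c for c in comps
        if len(c) >= spec.cluster_min_size
        and any(prob[i] >= anchor_code for i in c)
    ]
    return bool(qualifying), qualifying


def glaucoma_hemifield_test(exam: VFExam, grid: Grid24_2) -> str:
    """Simplified GHT: mirrored superior/inferior zone score comparison.

    Each zone scores the sum of PD probability category codes of its
    members (normal=0 .. p<0.5%=4).  If any mirrored pair differs by at
    least 6 the field is 'outside_normal_limits'; by at least 4,
    'borderline'; otherwise 'within_normal_limits'.
    """
    prob = _prob_by_index(exam, grid, "PD")
    worst = 0
    for sup, inf in _zone_table():
        diff = abs(sum(prob[i] for i in sup) - sum(prob[i] for i in inf))
        worst = max(worst, diff)
    if worst >= _GHT_OUTSIDE:
        return "outside_normal_limits"
    if worst >= _GHT_BORDERLINE:
        return "borderline"
    return "within_normal_limits"


def _exam_qualifies(exam: VFExam, spec: CriterionSpec, grid: Grid24_2,
                    psd_cutoff: Optional[float]) -> Tuple[bool, dict]:
    passes, clusters = evaluate_cluster_rule(exam, spec, grid)
    evidence = {"clusters": clusters, "ght": None, "psd": None}
    if passes and spec.require_ght_outside:
        ght = glaucoma_hemifield_test(exam, grid)
        evidence["ght"] = ght
        passes = ght == "outside_normal_limits"
    if passes and spec.require_psd_abnormal:
        if exam.td is None:
            raise ValueError("PSD requirement needs TD values on the exam")
        psd = pattern_standard_deviation(exam.td)
        evidence["psd"] = psd
        passes = psd_cutoff is not None and psd > psd_cutoff
    return passes, evidence


def classify(exams_of_one_eye: Sequence[VFExam], spec: CriterionSpec,
             grid: Grid24_2, psd_cutoff: Optional[float] = None) -> CriterionVerdict:
    """Per-eye verdict: glaucomatous iff >= ``confirmation_tests``
    qualifying exams on distinct dates."""
    if not exams_of_one_eye:
        raise ValueError("classify needs at least one exam")
    exams = sorted(exams_of_one_eye, key=lambda e: e.test_date)
    qualifying_dates = []
    clusters: List[FrozenSet[int]] = []
    ghts: List[str] = []
    psds: List[float] = []
    for exam in exams:
        ok, ev = _exam_qualifies(exam, spec, grid, psd_cutoff)
        if ok:
            if exam.test_date not in qualifying_dates:
                qualifying_dates.append(exam.test_date)
            clusters.extend(ev["clusters"])
            if ev["ght"] is not None:
                ghts.append(ev["ght"])
            if ev["psd"] is not None:
                psds.append(ev["psd"])
    is_gl = len(qualifying_dates) >= spec.confirmation_tests
    return CriterionVerdict(
        name=spec.name,
        is_glaucoma=is_gl,
        clusters=clusters if is_gl else [],
        ght_results=ghts if is_gl else [],
        psd_values=psds if is_gl else [],
        qualifying_dates=qualifying_dates if is_gl else [],
    )


def run_all_criteria(cohort: Cohort, specs: Mapping[str, CriterionSpec],
                     grid: Grid24_2,
                     psd_cutoff: Optional[float] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-eye verdicts for every criterion plus the pairwise agreement
    (Pearson correlation) matrix among the label columns."""
    eyes = cohort.eyes()
    records = []
    for (pid, eye), exams in sorted(eyes.items()):
        row = {"patient_id": pid, "eye": eye}
        for name, spec in specs.items():
            row[name] = int(classify(exams, spec, grid, psd_cutoff).is_glaucoma)
        records.append(row)
    labels = pd.DataFrame(records)
    cols = list(specs)
    mat = labels[cols].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = mat.corr()
    return labels, corr


# ------------------------------------------------------------------ config IO

def _specs_from_mapping(raw: Mapping[str, Mapping]) -> Dict[str, CriterionSpec]:
    return {name: CriterionSpec(name=name, **params) for name, params in raw.items()}


def load_criteria(path=None) -> Dict[str, CriterionSpec]:
    """Load criterion specs from YAML (default: the packaged config)."""
    if path is None:
        with resources.files("vfstack.data").joinpath("criteria.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return _specs_from_mapping(raw)


def save_criteria(specs: Mapping[str, CriterionSpec], path) -> None:
    raw = {}
    for name, spec in specs.items():
        d = asdict(spec)
        d.pop("name")
        raw[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_criteria() -> Dict[str, CriterionSpec]:
    return load_criteria(None)
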