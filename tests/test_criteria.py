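"""The rule-based criterion engine: cluster rules, GHT, confirmation."""

from datetime import date

import numpy as np
import pytest

from vfstack.cohort import Cohort
from vfstack.criteria import (CriterionSpec, classify, default_criteria,
                              evaluate_cluster_rule, glaucoma_hemifield_test,
                              load_criteria, run_all_criteria, save_criteria)
from vfstack.grid import mirror_grid

SPEC = CriterionSpec(name="test", map_kind="PD", cluster_min_size=3,
                     cluster_level="p<5%", anchor_level="p<1%",
                     non_edge_only=True, same_hemifield=True)


def exam_with_defect(exam_factory, indices, depth, grid, norm):
    """Exam with a focal defect (dB) at the given grid indices."""
    pos = {idx: k for k, idx in enumerate(grid.test_indices)}
    td = np.zeros(52)
    for i in indices:
        td[pos[i]] = -depth
    return exam_factory(td=td)


class TestClusterRule:
    def test_normal_field_fails(self, exam_factory, grid):
        exam = exam_factory()
        passes, clusters = evaluate_cluster_rule(exam, SPEC, grid)
        assert not passes and clusters == []

    def test_hodapp_style_triple_passes(self, exam_factory, grid, norm):
        # three contiguous non-edge points, deep enough for p<1% anywhere
        exam = exam_with_defect(exam_factory, (21, 22, 23), 15.0, grid, norm)
        passes, clusters = evaluate_cluster_rule(exam, SPEC, grid)
        assert passes
        assert any({21, 22, 23} <= c for c in clusters)

    def test_edge_member_breaks_non_edge_rule(self, exam_factory, grid, norm):
        # 11 is an edge location: only 2 non-edge members remain
        exam = exam_with_defect(exam_factory, (11, 12, 13), 15.0, grid, norm)
        passes, _ = evaluate_cluster_rule(exam, SPEC, grid)
        assert not passes
        relaxed = CriterionSpec(name="r", map_kind="PD", non_edge_only=False,
                                same_hemifield=True)
        assert evaluate_cluster_rule(exam, relaxed, grid)[0]

    def test_anchor_requirement(self, exam_factory, grid, norm):
        # shallow defect: beyond p<5% everywhere but never p<1%
        pos = {idx: k for k, idx in enumerate(grid.test_indices)}
        td = np.zeros(52)
        for i in (21, 22, 23):
            k = pos[i]
            td[k] = norm.pd_cutoffs[k, 0] - 0.2  # just past the 5% cutoff
        exam = exam_factory(td=td - td.mean() * 0)  # keep GH ~ 0
        assert not evaluate_cluster_rule(exam, SPEC, grid)[0]
        no_anchor = CriterionSpec(name="n", map_kind="PD", anchor_level="p<5%",
                                  non_edge_only=True, same_hemifield=True)
        assert evaluate_cluster_rule(exam, no_anchor, grid)[0]

    def test_missing_map_rejected(self, exam_factory, grid):
        exam = exam_factory()
        exam.pd_prob = None
        with pytest.raises(ValueError, match="probability map"):
            evaluate_cluster_rule(exam, SPEC, grid)

    def test_monotone_in_defect_depth(self, exam_factory, grid, norm):
        shallow = exam_with_defect(exam_factory, (21, 22, 23), 6.0, grid, norm)
        for spec in default_criteria().values():
            if not evaluate_cluster_rule(shallow, spec, grid)[0]:
                continue
            deep = exam_with_defect(exam_factory, (21, 22, 23), 20.0, grid, norm)
            assert evaluate_cluster_rule(deep, spec, grid)[0]


class TestGHT:
    def test_symmetric_field_within_limits(self, exam_factory, grid):
        assert glaucoma_hemifield_test(exam_factory(), grid) == \
            "within_normal_limits"

    def test_deep_superior_arcuate_outside(self, exam_factory, grid, norm):
        exam = exam_with_defect(exam_factory, (11, 12, 13, 14), 18.0, grid, norm)
        assert glaucoma_hemifield_test(exam, grid) == "outside_normal_limits"

    def test_mirrored_field_same_verdict(self, exam_factory, grid, norm):
        sup = exam_with_defect(exam_factory, (11, 12, 13, 14), 18.0, grid, norm)
        inf = exam_with_defect(exam_factory, (37, 38, 39, 40), 18.0, grid, norm)
        assert glaucoma_hemifield_test(sup, grid) == \
            glaucoma_hemifield_test(inf, grid)


class TestClassify:
    def _exams(self, exam_factory, grid, norm, dates, depth=15.0):
        return [
            exam_with_defect(exam_factory, (21, 22, 23), depth, grid, norm)
            for _ in dates
        ]

    def test_confirmation_unmet(self, exam_factory, grid, norm):
        spec = CriterionSpec(name="c", map_kind="PD", confirmation_tests=2,
                             non_edge_only=True, same_hemifield=True)
        exams = self._exams(exam_factory, grid, norm, [date(2020, 1, 1)])
        exams[0].test_date = date(2020, 1, 1)
        verdict = classify(exams, spec, grid)
        assert not verdict.is_glaucoma and verdict.qualifying_dates == []

    def test_confirmation_met_on_distinct_dates(self, exam_factory, grid, norm):
        spec = CriterionSpec(name="c", map_kind="PD", confirmation_tests=2,
                             non_edge_only=True, same_hemifield=True)
        exams = self._exams(exam_factory, grid, norm,
                            [date(2020, 1, 1), date(2020, 8, 1)])
        exams[0].test_date = date(2020, 1, 1)
        exams[1].test_date = date(2020, 8, 1)
        verdict = classify(exams, spec, grid)
        assert verdict.is_glaucoma
        assert len(verdict.qualifying_dates) == 2
        assert verdict.clusters  # evidence populated

    def test_empty_exam_list_rejected(self, grid):
        with pytest.raises(ValueError):
            classify([], SPEC, grid)

    def test_exam_order_irrelevant(self, exam_factory, grid, norm):
        spec = CriterionSpec(name="c", map_kind="PD", confirmation_tests=2,
                             non_edge_only=True, same_hemifield=True)
        exams = self._exams(exam_factory, grid, norm,
                            [date(2020, 1, 1), date(2020, 8, 1)])
        exams[0].test_date = date(2020, 1, 1)
        exams[1].test_date = date(2020, 8, 1)
        a = classify(exams, spec, grid).is_glaucoma
        b = classify(exams[::-1], spec, grid).is_glaucoma
        assert a == b


class TestDefaultsAndConfig:
    def test_five_packaged_criteria(self):
        specs = default_criteria()
        assert set(specs) == {"LoGTS", "UKGTS", "Kang", "HAP2_p1", "Foster"}
        assert specs["UKGTS"].map_kind == "TD"
        assert specs["Foster"].map_kind == "PD"
        assert specs["Foster"].require_ght_outside

    def test_config_round_trip_preserves_verdicts(self, exam_factory, grid,
                                                  norm, tmp_path):
        specs = default_criteria()
        p = tmp_path / "criteria.yaml"
        save_criteria(specs, p)
        reloaded = load_criteria(p)
        exam = exam_with_defect(exam_factory, (13, 14, 15), 16.0, grid, norm)
        for name in specs:
            v1 = classify([exam], specs[name], grid).is_glaucoma
            v2 = classify([exam], reloaded[name], grid).is_glaucoma
            assert v1 == v2
        assert reloaded["Kang"] == specs["Kang"]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="anchor_level"):
            CriterionSpec(name="x", map_kind="TD", cluster_level="p<1%",
                          anchor_level="p<5%")
        with pytest.raises(ValueError, match="map_kind"):
            CriterionSpec(name="x", map_kind="XX")


class TestRunAll:
    def test_archetype_free_cohort_all_negative(self, exam_factory, grid):
        exams = []
        for k in range(6):
            e = exam_factory(patient_id=f"P{k}")
            exams.append(e)
        labels, _ = run_all_criteria(Cohort(exams), default_criteria(), grid)
        assert labels[list(default_criteria())].to_numpy().sum() == 0

    def test_matches_per_eye_classify(self, exam_factory, grid, norm):
        specs = default_criteria()
        exams = [
            exam_with_defect(exam_factory, (13, 14, 15), 16.0, grid, norm),
            exam_factory(patient_id="P2"),
        ]
        exams[0].patient_id = "P1"
        co = Cohort(exams)
        labels, _ = run_all_criteria(co, specs, grid)
        idx = labels.set_index("patient_id")
        for name, spec in specs.items():
            for pid, eye_exams in co.by_patient.items():
                assert idx.loc[pid, name] == int(
                    classify(eye_exams, spec, grid).is_glaucoma)
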