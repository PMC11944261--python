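"""Model/Results front end for the stacked visual-field classifier.

:class:`StackedVFModel` is built from a cohort (or the cohort CSV
schema via :meth:`StackedVFModel.from_dataframe`); :meth:`fit` runs the
full pipeline — QC filters, rule-based criterion verdicts, base-network
training, stacked weight extraction, meta-learner training — and returns
a :class:`StackedVFResults` carrying held-out metrics, ROC curves,
prediction-entropy summaries and diagnostics, with a ``summary()`` table
in the spirit of the field's statistical-modelling packages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import criteria as criteria_mod
from . import evaluation as ev
from . import stacking
from .cohort import Cohort, filter_longitudinal, filter_reliability, split_train_test
from .criteria import CriterionSpec
from .grid import Grid24_2, build_grid
from .normative import NormativeReference, synthetic_reference
from .stacking import PD_CRITERIA, TD_CRITERIA

__all__ = ["StackedVFModel", "StackedVFResults"]

log = logging.getLogger(__name__)

META_KINDS = ("lr", "xgb", "mlp")


def _subcohort(cohort: Cohort, patient_ids) -> Cohort:
    keep = set(patient_ids)
    return Cohort([e for e in cohort.exams if e.patient_id in keep])


def _seed_streams(seed: int) -> Dict[str, int]:
    """Named substreams from one root seed (all below 2**31)."""
    names = ("split", "base_td", "base_pd", "meta_lr", "meta_xgb",
             "meta_mlp", "permutation", "simulation")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


class StackedVFModel:
    """Stacked weight-based glaucoma classifier over a visual-field cohort.

    Parameters
    ----------
    cohort
        Exams with clinical GL labels on at least the most recent exam of
        every eye (the unit of analysis is the eye; features come from
        its most recent exam).
    criteria_specs, grid, norm
        Rule-engine parameter sets, 24-2 grid and normative reference;
        packaged defaults are used when omitted.
    split_fraction
        Patient-level train fraction (default 0.825).
    meta_kinds
        Which meta-learners to train, out of ``("lr", "xgb", "mlp")``.
    apply_qc
        Run the reliability (FPR <= ``max_fpr``) and longitudinal
        (>= 2 dates, >= 0.5 y span) inclusion filters before analysis.
    meta_feature_variant
        Stacked-feature construction: ``weighted`` | ``activations`` |
        ``weights``.
    """

    def __init__(
        self,
        cohort: Cohort,
        criteria_specs: Optional[Mapping[str, CriterionSpec]] = None,
        grid: Optional[Grid24_2] = None,
        norm: Optional[NormativeReference] = None,
        split_fraction: float = 0.825,
        meta_kinds: Sequence[str] = META_KINDS,
        apply_qc: bool = True,
        max_fpr: float = 0.33,
        decision_threshold: float = 0.5,
        meta_feature_variant: str = "weighted",
        entropy_outlier_removal: bool = False,
    ) -> None:
        self.grid = grid or build_grid("OD")
        self.norm = norm or synthetic_reference(self.grid)
        self.criteria_specs = dict(criteria_specs or criteria_mod.default_criteria())
        self.split_fraction = split_fraction
        self.meta_kinds = tuple(meta_kinds)
        unknown = set(self.meta_kinds) - set(META_KINDS)
        if unknown:
            raise ValueError(f"unknown meta-learner kinds: {sorted(unknown)}")
        self.apply_qc = apply_qc
        self.max_fpr = max_fpr
        self.decision_threshold = decision_threshold
        self.meta_feature_variant = meta_feature_variant
        self.entropy_outlier_removal = entropy_outlier_removal
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "StackedVFModel":
        return cls(Cohort.from_dataframe(df), **kwargs)

    # ------------------------------------------------------------------ fit

    def fit(self, seed: int = 0) -> "StackedVFResults":
        streams = _seed_streams(seed)
        cohort = self.cohort
        if self.apply_qc:
            cohort = filter_longitudinal(filter_reliability(cohort, self.max_fpr))
        if cohort.n_patients < 4:
            raise ValueError(
                f"cohort too small after QC ({cohort.n_patients} patients); "
                "check the reliability/longitudinal filters and input data"
            )

        verdicts, criteria_corr = criteria_mod.run_all_criteria(
            cohort, self.criteria_specs, self.grid, psd_cutoff=self.norm.psd_p95)

        train_ids, test_ids = split_train_test(
            cohort.patient_ids, self.split_fraction, seed=streams["split"])
        train_co, test_co = _subcohort(cohort, train_ids), _subcohort(cohort, test_ids)

        feats: Dict[str, Dict[str, stacking.BaseFeatureVector]] = {}
        for kind in ("TD", "PD"):
            tr = stacking.build_features(train_co, kind)
            te = stacking.build_features(test_co, kind, stats_from=tr)
            feats[kind] = {"train": tr, "test": te}

        bundles = {
            "TD": stacking.train_base(feats["TD"]["train"], verdicts,
                                      TD_CRITERIA, seed=streams["base_td"]),
            "PD": stacking.train_base(feats["PD"]["train"], verdicts,
                                      PD_CRITERIA, seed=streams["base_pd"]),
        }

        def clinical_block(cohort_: Cohort) -> np.ndarray:
            rows = []
            for (_, _), exams in sorted(cohort_.eyes().items()):
                e = exams[-1]
                rows.append([e.age, e.gender, e.race, e.follow_up])
            return np.array(rows, dtype=float)

        meta_X = {
            split: stacking.extract_meta_features(
                bundles["TD"], bundles["PD"],
                feats["TD"][split].X, feats["PD"][split].X,
                clinical_block(co), variant=self.meta_feature_variant)
            for split, co in (("train", train_co), ("test", test_co))
        }

        def clinical_labels(cohort_: Cohort) -> np.ndarray:
            out = []
            for (pid, eye), exams in sorted(cohort_.eyes().items()):
                lab = exams[-1].label
                if lab is None:
                    raise ValueError(f"eye ({pid}, {eye}) has no clinical GL label")
                out.append(int(lab))
            return np.array(out)

        y_train, y_test = clinical_labels(train_co), clinical_labels(test_co)

        meta_models, per_model = {}, {}
        for kind in self.meta_kinds:
            model = stacking.train_meta(meta_X["train"], y_train, kind,
                                        seed=streams[f"meta_{kind}"])
            p, yhat = stacking.predict(model, meta_X["test"], self.decision_threshold)
            cm = ev.confusion(y_test, yhat)
            report = ev.metrics_from_confusion(cm)
            curve, auc = ev.roc_auc(y_test, p)
            ent = ev.prediction_entropy(p)
            ent_for_summary = ent
            if self.entropy_outlier_removal and len(p) >= 4:
                ent_for_summary = ent[~ev.iqr_outlier_mask(p)]
            report.auc = auc
            report.entropy_mean = float(np.mean(ent_for_summary))
            report.entropy_sd = float(np.std(ent_for_summary, ddof=1)) if len(
                np.atleast_1d(ent_for_summary)) > 1 else 0.0
            meta_models[kind] = model
            per_model[kind] = {
                "probabilities": p, "predictions": yhat, "confusion": cm,
                "report": report, "roc": curve, "entropy": ent,
            }

        # stand-alone criterion performance on the same held-out eyes
        vidx = verdicts.set_index(["patient_id", "eye"])
        test_eyes = sorted(test_co.eyes())
        criterion_reports = {}
        for name in self.criteria_specs:
            yhat = np.array([int(vidx.loc[sid, name]) for sid in test_eyes])
            cm = ev.confusion(y_test, yhat)
            rep = ev.metrics_from_confusion(cm)
            if len(np.unique(y_test)) == 2 and len(np.unique(yhat)) >= 1:
                _, rep.auc = ev.roc_auc(y_test, yhat.astype(float))
            criterion_reports[name] = {"confusion": cm, "report": rep,
                                       "predictions": yhat}

        return StackedVFResults(
            model=self,
            seed=seed,
            streams=streams,
            cohort=cohort,
            train_ids=train_ids,
            test_ids=test_ids,
            verdicts=verdicts,
            criteria_correlation=criteria_corr,
            features=feats,
            bundles=bundles,
            meta_X=meta_X,
            y_train=y_train,
            y_test=y_test,
            test_eyes=test_eyes,
            meta_models=meta_models,
            per_model=per_model,
            criterion_reports=criterion_reports,
        )


@dataclass
class StackedVFResults:
    """Fitted-pipeline results: held-out metrics, curves and diagnostics."""

    model: StackedVFModel
    seed: int
    streams: Dict[str, int]
    cohort: Cohort
    train_ids: List[str]
    test_ids: List[str]
    verdicts: pd.DataFrame
    criteria_correlation: pd.DataFrame
    features: Dict[str, Dict[str, stacking.BaseFeatureVector]]
    bundles: Dict[str, stacking.BaseModelBundle]
    meta_X: Dict[str, np.ndarray]
    y_train: np.ndarray
    y_test: np.ndarray
    test_eyes: List[Tuple[str, str]]
    meta_models: Dict[str, stacking.MetaModel]
    per_model: Dict[str, dict]
    criterion_reports: Dict[str, dict]

    # ------------------------------------------------------------- metrics

    def metrics_frame(self) -> pd.DataFrame:
        """Held-out metrics (percent) for meta-learners and criteria."""
        rows = []
        for kind, d in self.per_model.items():
            r = d["report"].as_percent()
            rows.append({"classifier": kind.upper(), "kind": "meta", **r,
                         "entropy_mean": d["report"].entropy_mean,
                         "entropy_sd": d["report"].entropy_sd})
        for name, d in self.criterion_reports.items():
            r = d["report"].as_percent()
            rows.append({"classifier": name, "kind": "criterion", **r,
                         "entropy_mean": None, "entropy_sd": None})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.metrics_frame()
        lines = [
            "Stacked visual-field classification results",
            "=" * 61,
            f"patients: {self.cohort.n_patients}  "
            f"(train {len(self.train_ids)} / test {len(self.test_ids)})  "
            f"exams: {self.cohort.n_exams}",
            f"seed: {self.seed}   meta-feature variant: "
            f"{self.model.meta_feature_variant}",
            "-" * 61,
            f"{'classifier':<12}{'acc%':>8}{'prec%':>8}{'sens%':>8}"
            f"{'F%':>8}{'AUC%':>8}{'H mean':>9}",
        ]
        for _, r in df.iterrows():
            def fmt(v, w=8, nd=2):
                return f"{'':>{w}}" if v is None or (isinstance(v, float) and np.isnan(v)) \
                    else f"{v:>{w}.{nd}f}"
            lines.append(
                f"{r['classifier']:<12}" + fmt(r["accuracy"]) + fmt(r["precision"])
                + fmt(r["sensitivity"]) + fmt(r["f_score"]) + fmt(r["auc"])
                + fmt(r["entropy_mean"], 9, 3)
            )
        lines.append("-" * 61)
        return "\n".join(lines)

    # ---------------------------------------------------------- diagnostics

    def compare_models_wilcoxon(self, kind_a: str, kind_b: str,
                                alpha: float = 0.05):
        """Wilcoxon signed-rank test on the paired held-out probabilities."""
        return ev.compare_wilcoxon(self.per_model[kind_a]["probabilities"],
                                   self.per_model[kind_b]["probabilities"], alpha)

    def base_feature_importance(self, map_kind: str, head: str,
                                n_repeats: int = 10) -> pd.DataFrame:
        """Permutation importance of the 56 base inputs for one criterion
        head, with sector aggregation via the grid's sector map."""
        bundle = self.bundles[map_kind]
        if head not in bundle.heads:
            raise ValueError(f"{head!r} is not a head of the {map_kind} network")
        hcol = bundle.heads.index(head)
        fv = self.features[map_kind]["test"]
        vidx = self.verdicts.set_index(["patient_id", "eye"])
        y = np.array([int(vidx.loc[sid, head]) for sid in fv.sample_ids])
        prefix = map_kind.lower()
        names = [f"{prefix}{i}" for i in self.model.grid.test_indices] + \
            list(stacking.CLINICAL_COLUMNS)
        sectors = [self.model.grid.location(i).sector
                   for i in self.model.grid.test_indices] + ["clinical"] * 4

        def predict_fn(X):
            return (bundle.network.predict_proba(X)[:, hcol] >= 0.5).astype(int)

        return ev.permutation_importance(
            predict_fn, fv.X, y, n_repeats=n_repeats,
            seed=self.streams["permutation"], feature_names=names, sectors=sectors)

    # -------------------------------------------------------------- export

    def save_artifacts(self, outdir) -> Dict[str, str]:
        """Write metrics, ROC points, entropies and verdicts as CSVs."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def put(name, df):
            p = os.path.join(outdir, name)
            df.to_csv(p, index=False)
            paths[name] = p

        put("metrics.csv", self.metrics_frame().round(6))
        roc_rows = []
        ent_rows = []
        for kind, d in self.per_model.items():
            for fpr, tpr in d["roc"]:
                roc_rows.append({"classifier": kind, "fpr": fpr, "tpr": tpr})
            for (pid, eye), p, h in zip(self.test_eyes, d["probabilities"],
                                        d["entropy"]):
                ent_rows.append({"classifier": kind, "patient_id": pid,
                                 "eye": eye, "probability": round(float(p), 9),
                                 "entropy": round(float(h), 9)})
        put("roc.csv", pd.DataFrame(roc_rows).round(9))
        put("entropy.csv", pd.DataFrame(ent_rows))
        put("verdicts.csv", self.verdicts)
        put("criteria_correlation.csv",
            self.criteria_correlation.round(6).reset_index(names="criterion"))
        return paths
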