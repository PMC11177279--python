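"""End-to-end orchestration of the multimodal classification pipeline.

Stage order per classification pair (patients vs controls, or
bvFTD vs AD): feature assembly → outer 80/20 split with inner k-fold plan →
site harmonization fitted on training controls → missing-data imputation
under the 30% rule → site-bias audit before and after harmonization →
Gini-rank feature elimination and optimal-N selection → Bayesian tuning of
the boosted ensemble → held-out evaluation with bootstrap CIs → feature
importance report. A manifest records the configuration hash, every derived
seed, and stage runtimes.

Harmonization and imputation statistics are always fitted on the training
80% (and, within the inner CV, on the fold's training rows); held-out test
rows never reach any fitting operation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import subseed
from .classify import (ClassifierReport, compare_auc_permutation,
                       cv_operating_threshold, evaluate_bootstrap,
                       train_gbm, tune_hyperparameters)
from .cohort import SimConfig, SyntheticCohort, simulate_cohort
from .eeg import eeg_feature_vector
from .errors import ConfigError
from .fmri import fmri_feature_vector
from .morphometry import etiv_normalize
from .stabilization import (SelectionResult, SiteAuditReport, select_features,
                            site_audit)
from .table import (FeatureTable, FoldPlan, apply_site_normalizer,
                    assemble_table, build_modality_subsets, fit_site_normalizer,
                    impute_features, make_fold_plan)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PairResult", "extract_features", "run_pair",
           "run_pipeline", "compare_modalities"]

DEFAULT_PAIRS = (("bvFTD", "HC"), ("AD", "HC"), ("bvFTD", "AD"))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    mode: str = "FS"               # SS (complete data) | FS (with missing data)
    test_frac: float = 0.2
    k: int = 10
    impute_threshold: float = 0.30
    tune_budget: int = 30
    n_boot: int = 5000
    n_perm: int = 200
    selection_schedule: str = "default"  # default | geometric | none
    selection_estimators: int = 100
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for pos, neg in self.pairs:
            if pos == neg:
                raise ConfigError(f"degenerate pair {pos}-{neg}")
        if self.mode not in ("SS", "FS"):
            raise ConfigError("mode must be SS or FS")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PairResult:
    """Everything produced for one classification pair."""

    pair: tuple[str, str]
    plan: FoldPlan
    audit_before: SiteAuditReport | None
    audit_after: SiteAuditReport | None
    selection: SelectionResult
    tuned_params: dict
    report: ClassifierReport
    model: object = None
    stage_seconds: dict[str, float] = field(default_factory=dict)


def extract_features(cohort: SyntheticCohort) -> FeatureTable:
    """Assemble the multimodal FeatureTable from a cohort's raw payloads."""
    ids = cohort.subjects.index
    dem = cohort.subjects[["sex", "age", "education"]].copy()
    nps = cohort.cognition
    atrophy = pd.DataFrame({sid: etiv_normalize(recs)
                            for sid, recs in cohort.morphometry.items()}).T
    eeg = pd.DataFrame({sid: eeg_feature_vector(rec)
                        for sid, rec in cohort.eeg.items()}).T
    fmri = pd.DataFrame({sid: fmri_feature_vector(ts)
                         for sid, ts in cohort.fmri.items()}).T
    maps = {"DEM": dem, "NPS": nps, "Atrophy": atrophy.loc[ids],
            "EEG-FC": eeg.loc[ids], "MRI-FC": fmri.loc[ids]}
    return assemble_table(maps, cohort.subjects)


def _prepare(table: FeatureTable, config: RunConfig, seed: int
             ) -> tuple[FeatureTable, FeatureTable, FoldPlan, dict]:
    """Fold plan, harmonization and imputation on the full-cohort table.

    Returns (pre-harmonization imputed table, harmonized imputed table,
    plan, stage timings). Harmonization stats come from training controls;
    imputation means from training rows.
    """
    times: dict[str, float] = {}
    t0 = time.perf_counter()
    plan = make_fold_plan(table, test_frac=config.test_frac, k=config.k,
                          seed=subseed(seed, "plan"))
    times["fold_plan"] = time.perf_counter() - t0

    # harmonization first (control stats are NaN-aware), imputation after:
    # filling site-shifted raw values with a site-agnostic global mean would
    # re-introduce decodable site structure
    t0 = time.perf_counter()
    norm = fit_site_normalizer(table, plan, fold=None)
    harmonized = apply_site_normalizer(norm, table)
    times["harmonization"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.mode == "FS":
        harmonized, _model = impute_features(harmonized, plan, fold=None,
                                             threshold=config.impute_threshold)
    else:
        if table.mask.any().any():
            raise ConfigError("SS mode requires complete data")
    times["imputation"] = time.perf_counter() - t0
    raw = table if config.mode == "SS" else \
        impute_features(table, plan, fold=None,
                        threshold=config.impute_threshold)[0]
    return raw, harmonized, plan, times


def run_pair(table: FeatureTable, pair: tuple[str, str], config: RunConfig,
             audit: bool = True) -> PairResult:
    """Run the full pipeline for one classification pair.

    ``table`` is the full-cohort multimodal table (controls included even
    for the patient–patient pair, since harmonization is control-referenced).
    """
    pos, neg = pair
    seed = subseed(config.seed, "pair", pos, neg)
    raw, harmonized, plan, times = _prepare(table, config, seed)

    train_ids = plan.outer_train_ids
    test_ids = plan.test_ids

    pair_ids = [i for i in harmonized.subjects
                if harmonized.group.loc[i] in (pos, neg)]
    pair_train = [i for i in pair_ids if i in set(train_ids)]
    pair_test = [i for i in pair_ids if i in set(test_ids)]
    tr = harmonized.select_subjects(pair_train)
    te = harmonized.select_subjects(pair_test)

    t0 = time.perf_counter()
    if config.selection_schedule == "none":
        from .stabilization import SelectionResult as SR
        selection = SR(n_optimal=tr.n_features, selected=list(tr.feature_names),
                       max_accuracy=float("nan"), accuracy_at_n=float("nan"),
                       tolerance=0.0)
    else:
        from .stabilization import geometric_schedule
        schedule = (geometric_schedule(tr.n_features)
                    if config.selection_schedule == "geometric" else None)
        k_sel = min(config.k, int(tr.group.value_counts().min()))
        selection, _curve = select_features(
            tr, tr.group, k=k_sel, seed=subseed(seed, "select"),
            schedule=schedule, n_estimators=config.selection_estimators)
    times["stabilization"] = time.perf_counter() - t0

    tr_sel = tr.select_features(selection.selected)
    te_sel = te.select_features(selection.selected)

    # site-bias audit on the selected features, pre vs post harmonization,
    # over the pair's training rows only
    audit_before = audit_after = None
    if audit:
        t0 = time.perf_counter()
        tr_raw = raw.select_subjects(pair_train).select_features(
            [f for f in selection.selected if f in raw.feature_names])
        audit_before = site_audit(
            tr_raw, tr_raw.site, n_perm=config.n_perm,
            seed=subseed(seed, "audit-pre"), k=min(config.k, 5),
            n_estimators=min(config.selection_estimators, 50))
        audit_after = site_audit(
            tr_sel, tr_sel.site, n_perm=config.n_perm,
            seed=subseed(seed, "audit-post"), k=min(config.k, 5),
            n_estimators=min(config.selection_estimators, 50))
        times["site_audit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tuned = tune_hyperparameters(tr_sel, tr_sel.group, budget=config.tune_budget,
                                 k=config.k, seed=subseed(seed, "tune"),
                                 positive=pos, test_ids=test_ids)
    times["tuning"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    thr = cv_operating_threshold(tuned.params, tr_sel, tr_sel.group, k=config.k,
                                 seed=subseed(seed, "thr"), positive=pos)
    report = evaluate_bootstrap(tuned.model, te_sel, te_sel.group, positive=pos,
                                n_boot=config.n_boot, seed=subseed(seed, "boot"),
                                threshold=thr, train_ids=pair_train)
    times["evaluation"] = time.perf_counter() - t0

    return PairResult(pair=pair, plan=plan, audit_before=audit_before,
                      audit_after=audit_after, selection=selection,
                      tuned_params=tuned.params, report=report,
                      model=tuned.model, stage_seconds=times)


def run_pipeline(config: RunConfig,
                 table: FeatureTable | None = None,
                 sim: SimConfig | None = None) -> dict:
    """Run every configured classification pair and bundle the reports.

    Input is either an assembled FeatureTable or a simulator configuration
    (payloads are generated and features extracted). Writes JSON/TSV
    artifacts plus a manifest to ``config.out_dir`` when set.
    """
    if table is None:
        if sim is None:
            raise ConfigError("provide a FeatureTable or a SimConfig")
        cohort = simulate_cohort(sim)
        table = extract_features(cohort)

    results: dict[str, PairResult] = {}
    for pair in config.pairs:
        name = f"{pair[0]}-{pair[1]}"
        logger.info("running pair %s", name)
        results[name] = run_pair(table, pair, config)

    bundle = {"config_hash": config.hash(), "seed": config.seed,
              "pairs": {}, "n_subjects": table.n_subjects,
              "n_features": table.n_features}
    for name, res in results.items():
        bundle["pairs"][name] = {
            "auc": res.report.auc, "auc_ci": list(res.report.auc_ci),
            "sensitivity": res.report.sensitivity,
            "specificity": res.report.specificity,
            "n_selected": res.selection.n_optimal,
            "selected": res.selection.selected,
            "max_validation_accuracy": res.selection.max_accuracy,
            "tuned_params": res.tuned_params,
            "audit_p_before": (res.audit_before.p_value
                               if res.audit_before else None),
            "audit_p_after": (res.audit_after.p_value
                              if res.audit_after else None),
            "stage_seconds": res.stage_seconds,
        }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(bundle, fh, indent=2, default=float)
        for name, res in results.items():
            res.report.roc.to_csv(
                os.path.join(config.out_dir, f"roc_{name}.tsv"), sep="\t", index=False)
            res.report.confusion.to_csv(
                os.path.join(config.out_dir, f"confusion_{name}.tsv"), sep="\t")
            res.model.get_booster().save_model(
                os.path.join(config.out_dir, f"model_{name}.json"))
    bundle["_results"] = results
    return bundle


def compare_modalities(table: FeatureTable, pair: tuple[str, str],
                       config: RunConfig, n_perm: int = 1000) -> pd.DataFrame:
    """Full multimodal table vs each unimodal subset on the same split.

    Trains the boosted ensemble (default configuration) on identical
    train/test rows for the full table and every modality subset, and
    reports AUC per set plus the permutation p-value of the full-vs-subset
    AUC difference.
    """
    pos, neg = pair
    seed = subseed(config.seed, "modalities", pos, neg)
    raw, harmonized, plan, _times = _prepare(table, config, seed)
    pair_ids = [i for i in harmonized.subjects if harmonized.group.loc[i] in (pos, neg)]
    tr_ids = [i for i in pair_ids if i in set(plan.outer_train_ids)]
    te_ids = [i for i in pair_ids if i in set(plan.test_ids)]

    def _auc_scores(tbl: FeatureTable) -> tuple[float, np.ndarray]:
        tr, te = tbl.select_subjects(tr_ids), tbl.select_subjects(te_ids)
        model = train_gbm(tr, tr.group, seed=subseed(seed, "fit"), positive=pos)
        rep = evaluate_bootstrap(model, te, te.group, positive=pos, n_boot=200,
                                 seed=subseed(seed, "boot"), train_ids=tr_ids)
        return rep.auc, model.predict_proba(te.values.to_numpy())[:, 1]

    full_auc, full_scores = _auc_scores(harmonized)
    y_test = harmonized.group.loc[te_ids]
    rows = [{"set": "multimodal", "auc": full_auc, "p_vs_multimodal": None}]
    for mod, sub in build_modality_subsets(harmonized).items():
        auc, scores = _auc_scores(sub)
        _, p = compare_auc_permutation(full_scores, scores, y_test, positive=pos,
                                       n_perm=n_perm, seed=subseed(seed, "perm", mod))
        rows.append({"set": mod, "auc": auc, "p_vs_multimodal": p})
    return pd.DataFrame(rows)
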