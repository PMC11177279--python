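"""Seeded validation experiments on synthetic cohorts.

These harnesses define the package's standard self-checks: each one builds a
synthetic multi-site cohort with known ground truth, runs the relevant
pipeline stages, and returns the measured quantity. They are used by the
test suite and by the results-reproduction script, and are callable directly
for exploratory work.

Problem sizes are chosen so a full validation pass runs in minutes on one
CPU: harmonization/audit checks use a two-group cohort with site offsets of
2 SD; recovery checks use 3 sites × 60 subjects per group per site with 5
informative features (Cohen's d = 1.5) among 200 noise features; audit
forests and permutation counts are scaled down accordingly (the permutation
p-value is exact by construction at any forest size).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from ._rng import subseed
from .classify import evaluate_bootstrap, train_gbm
from .cohort import BlockSpec, simulate_feature_table
from .stabilization import geometric_schedule, select_features, site_audit
from .table import (apply_site_normalizer, build_modality_subsets,
                    fit_site_normalizer, impute_features, make_fold_plan)

__all__ = ["harmonization_residual", "audit_pre_post", "recovery_run",
           "null_run", "dominance_run", "leakage_mutation_check"]


def _harmonized_pair(table, seed, pair=("bvFTD", "HC"), k=10):
    plan = make_fold_plan(table, k=k, seed=seed)
    model = fit_site_normalizer(table, plan, fold=None)
    harm = apply_site_normalizer(model, table)
    pair_ids = [i for i in harm.subjects if harm.group.loc[i] in pair]
    tr_ids = [i for i in pair_ids if i in set(plan.outer_train_ids)]
    te_ids = [i for i in pair_ids if i in set(plan.test_ids)]
    return harm, plan, tr_ids, te_ids


def harmonization_residual(seed: int = 0, n_per_group_per_site: int = 20) -> float:
    """Max |per-site training-control feature mean| after harmonization.

    Exactly zero (to float tolerance) by construction; returned so the
    property can be measured rather than assumed.
    """
    table, _ = simulate_feature_table(n_per_group_per_site=n_per_group_per_site,
                                      seed=seed)
    plan = make_fold_plan(table, k=5, seed=seed)
    model = fit_site_normalizer(table, plan, fold=None)
    harm = apply_site_normalizer(model, table)
    z = harm.values.loc[model.fitted_on]
    sites = harm.site.loc[model.fitted_on]
    return float(max(abs(z.loc[sites == s].mean(axis=0)).max()
                     for s in sites.unique()))


def audit_pre_post(seed: int, site_offset: float = 2.0,
                   n_per_group_per_site: int = 34, n_features: int = 10,
                   n_perm: int = 49, k_audit: int = 3,
                   n_estimators: int = 10) -> tuple[float, float]:
    """Site-audit p-values before and after harmonization.

    A two-group cohort (controls + one patient group) with ±``site_offset``
    SD additive site effects on every non-demographic feature. Returns
    (p_before, p_after) from the label-permutation audit on the outer
    training rows.
    """
    blocks = {"NPS": BlockSpec("NPS", n_features, 0)}
    table, _ = simulate_feature_table(
        n_per_group_per_site=n_per_group_per_site, n_sites=3,
        groups=("HC", "bvFTD"), blocks=blocks,
        site_shift=(0.0, site_offset, -site_offset), seed=seed)
    table = table.select_features(
        [f for f in table.feature_names if f not in ("sex", "age", "education")])
    plan = make_fold_plan(table, k=5, seed=seed)
    tr = table.select_subjects(plan.outer_train_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        before = site_audit(tr, tr.site, n_perm=n_perm, seed=seed, k=k_audit,
                            n_estimators=n_estimators)
        model = fit_site_normalizer(table, plan, fold=None)
        harm = apply_site_normalizer(model, table)
        trh = harm.select_subjects(plan.outer_train_ids)
        after = site_audit(trh, trh.site, n_perm=n_perm, seed=seed, k=k_audit,
                           n_estimators=n_estimators)
    return before.p_value, after.p_value


def _recovery_table(seed: int, d: float, n_noise: int = 200,
                    n_informative: int = 5, n_per_group_per_site: int = 60):
    blocks = {"NPS": BlockSpec("NPS", n_noise + n_informative, n_informative,
                               {"bvFTD": d, "AD": d})}
    return simulate_feature_table(n_per_group_per_site=n_per_group_per_site,
                                  n_sites=3, blocks=blocks, seed=seed)


def recovery_run(seed: int, d: float = 1.5, n_boot: int = 1000,
                 selection_k: int = 5,
                 n_estimators: int = 50) -> tuple[float, float, int]:
    """Planted-feature recovery and held-out AUC for one seed.

    Harmonizes, runs Gini-rank elimination (geometric schedule) on the
    training rows of the patients-vs-controls pair, trains the boosted
    ensemble on the selected features, and evaluates on the held-out 20%.
    Returns (fraction of planted features recovered, test AUC, N selected).
    """
    table, gt = _recovery_table(seed, d)
    harm, plan, tr_ids, te_ids = _harmonized_pair(table, seed)
    tr = harm.select_subjects(tr_ids)
    te = harm.select_subjects(te_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel, _curve = select_features(
            tr, tr.group, k=selection_k, seed=seed,
            schedule=geometric_schedule(tr.n_features), n_estimators=n_estimators)
        planted = set(gt["informative_features"])
        recovered = len(planted & set(sel.selected)) / len(planted)
        model = train_gbm(tr.select_features(sel.selected), tr.group,
                          seed=seed, positive="bvFTD")
        rep = evaluate_bootstrap(model, te.select_features(sel.selected),
                                 te.group, positive="bvFTD", n_boot=n_boot,
                                 seed=seed, train_ids=tr_ids)
    return recovered, rep.auc, sel.n_optimal


def null_run(seed: int, n_boot: int = 1000) -> tuple[bool, float, tuple[float, float]]:
    """Null-cohort calibration: does the test-AUC bootstrap CI cover 0.5?

    Same cohort geometry as :func:`recovery_run` but with all effect sizes
    zero; the ensemble is trained on all features at its default
    configuration. Returns (ci_covers_half, auc, ci).
    """
    table, _ = _recovery_table(seed, d=0.0)
    harm, plan, tr_ids, te_ids = _harmonized_pair(table, seed)
    tr = harm.select_subjects(tr_ids)
    te = harm.select_subjects(te_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_gbm(tr, tr.group, seed=seed, positive="bvFTD")
        rep = evaluate_bootstrap(model, te, te.group, positive="bvFTD",
                                 n_boot=n_boot, seed=seed, train_ids=tr_ids)
    lo, hi = rep.auc_ci
    return (lo <= 0.5 <= hi), rep.auc, rep.auc_ci


def dominance_run(seed: int, d: float = 1.5,
                  n_per_group_per_site: int = 40) -> tuple[float, dict[str, float]]:
    """Multimodal vs unimodal test AUC on one split.

    Effects planted across every modality block (strong cognitive effect,
    moderate atrophy/connectivity); the full table and each modality subset
    are trained and evaluated on identical rows. Returns
    (full_auc, {modality: auc}).
    """
    from sklearn.metrics import roc_auc_score

    table, _ = simulate_feature_table(n_per_group_per_site=n_per_group_per_site,
                                      n_sites=3, seed=seed)
    harm, plan, tr_ids, te_ids = _harmonized_pair(table, seed)

    def _auc(tbl):
        tr, te = tbl.select_subjects(tr_ids), tbl.select_subjects(te_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = train_gbm(tr, tr.group, seed=subseed(seed, "dom"), positive="bvFTD")
        y = (te.group == "bvFTD").astype(int)
        return float(roc_auc_score(y, m.predict_proba(te.values.to_numpy())[:, 1]))

    full = _auc(harm)
    subsets = {mod: _auc(sub) for mod, sub in build_modality_subsets(harm).items()}
    return full, subsets


def leakage_mutation_check(seed: int = 0, n_probe: int = 5) -> int:
    """Delete held-out test subjects one at a time; count changed artifacts.

    For each probed deletion the harmonization statistics, imputation means
    and excluded-feature lists are refitted and compared against the
    originals. Leakage-free fitting means nothing changes; the return value
    is the number of (subject, artifact) discrepancies (0 when clean).
    """
    table, _ = simulate_feature_table(
        n_per_group_per_site=12, seed=seed,
        missing_rates={"CogA": 0.2, "EEG": 0.25})
    plan = make_fold_plan(table, k=5, seed=seed)
    base_norm = fit_site_normalizer(table, plan, fold=None)
    _, base_imp = impute_features(apply_site_normalizer(base_norm, table),
                                  plan, fold=None)

    changes = 0
    probes = list(plan.test_ids)[:n_probe]
    for sid in probes:
        keep = [i for i in table.subjects if i != sid]
        sub = table.select_subjects(keep)
        from .table import FoldPlan
        sub_plan = FoldPlan(fold=plan.fold.drop(sid), k=plan.k, seed=plan.seed)
        norm = fit_site_normalizer(sub, sub_plan, fold=None)
        _, imp = impute_features(apply_site_normalizer(norm, sub),
                                 sub_plan, fold=None)
        if not (imp.means.equals(base_imp.means) and imp.excluded == base_imp.excluded):
            changes += 1
        if not (norm.mu.equals(base_norm.mu) and norm.sigma.equals(base_norm.sigma)):
            changes += 1
    return changes
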