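"""Multimodal feature table, validation plan, and leakage-free preprocessing.

The :class:`FeatureTable` is the exchange object between feature extraction
and the machine-learning stages: a subjects × features matrix with a modality
tag per feature, site and group labels per subject, and an explicit
missingness mask (missing cells hold NaN).

Site harmonization follows the control-referenced z-scoring scheme: each
feature is standardized against the mean and standard deviation of the *same
site's healthy controls*, and those statistics are fitted on training rows of
the current fold only, so no information from validation or test subjects can
leak into the transform. Imputation (training-mean fill for features with at
most 30% missing values, drop beyond) is fold-scoped the same way.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, LeakageError
from ._rng import substream

logger = logging.getLogger(__name__)

#: Canonical modality order used for deterministic feature layout.
MODALITIES = ("DEM", "NPS", "Atrophy", "EEG-FC", "MRI-FC")

HC_LABEL = "HC"


# ---------------------------------------------------------------------------
# FeatureTable


@dataclass
class FeatureTable:
    """Subjects × features matrix with labels, modality tags and missingness.

    Parameters
    ----------
    values
        DataFrame indexed by subject id; NaN marks a missing cell.
    modality
        Series mapping each feature name to one of :data:`MODALITIES`.
    site, group
        Series indexed like ``values`` giving acquisition site and
        diagnostic group per subject.
    """

    values: pd.DataFrame
    modality: pd.Series
    site: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ConfigError("duplicate subject ids")
        if self.values.columns.has_duplicates:
            raise ConfigError("duplicate feature names")
        self.modality = self.modality.reindex(self.values.columns)
        if self.modality.isna().any():
            missing = list(self.modality.index[self.modality.isna()])[:5]
            raise ConfigError(f"features without a modality tag: {missing}")
        bad = set(self.modality.unique()) - set(MODALITIES)
        if bad:
            raise ConfigError(f"unknown modality tags: {sorted(bad)}")
        for lab in (self.site, self.group):
            if not lab.index.equals(self.values.index):
                raise ConfigError("site/group labels must be indexed by subject id")

    # -- basic accessors ----------------------------------------------------

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.values[names].copy(), self.modality[names].copy(),
                            self.site.copy(), self.group.copy())

    def select_subjects(self, ids: Sequence) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.values.loc[ids].copy(), self.modality.copy(),
                            self.site.loc[ids].copy(), self.group.loc[ids].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.modality.copy(),
                            self.site.copy(), self.group.copy())

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path_or_buf) -> None:
        """Write as TSV with ``#modality:`` header metadata lines."""
        buf = io.StringIO()
        for feat, tag in self.modality.items():
            buf.write(f"#modality:\t{feat}\t{tag}\n")
        out = self.values.copy()
        out.insert(0, "group", self.group)
        out.insert(0, "site", self.site)
        out.index.name = "subject_id"
        out.to_csv(buf, sep="\t")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "FeatureTable":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        modality = {}
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#modality:"):
                _, feat, tag = line.split("\t")
                modality[feat] = tag
            else:
                body_lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t", index_col="subject_id")
        site = df.pop("site")
        group = df.pop("group")
        return cls(df, pd.Series(modality), site, group)


def assemble_table(
    feature_maps: Mapping[str, pd.DataFrame],
    subjects: pd.DataFrame,
) -> FeatureTable:
    """Merge per-modality feature frames into one FeatureTable.

    ``feature_maps`` maps a modality tag to a subjects × features frame; a
    subject absent from a modality frame gets NaN (masked missing) for that
    whole block. Feature order is deterministic: modalities in the canonical
    order, feature names sorted within each modality.

    ``subjects`` must carry ``site`` and ``group`` columns indexed by id.
    """
    seen: dict[str, str] = {}
    blocks = []
    tags = {}
    for mod in MODALITIES:
        if mod not in feature_maps:
            continue
        frame = feature_maps[mod]
        if frame.shape[1] == 0:
            continue
        frame = frame[sorted(frame.columns)]
        for feat in frame.columns:
            if feat in seen:
                raise ConfigError(
                    f"feature name {feat!r} appears in both {seen[feat]} and {mod}")
            seen[feat] = mod
            tags[feat] = mod
        blocks.append(frame.reindex(subjects.index))
    unknown = set(feature_maps) - set(MODALITIES)
    if unknown:
        raise ConfigError(f"unknown modality tags: {sorted(unknown)}")
    values = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=subjects.index)
    return FeatureTable(values, pd.Series(tags), subjects["site"].copy(), subjects["group"].copy())


def build_modality_subsets(table: FeatureTable) -> dict[str, FeatureTable]:
    """Split the table into the unimodal analysis sets.

    DEM (sex, age, education), NPS (cognitive screening + executive
    functions), Atrophy, EEG-FC (PLV all bands + wSMI all τ) and MRI-FC
    (SFC + DCFA). Subsets partition the feature set.
    """
    out = {}
    for mod in MODALITIES:
        names = list(table.modality.index[table.modality == mod])
        if names:
            out[mod] = table.select_features(names)
    return out


# ---------------------------------------------------------------------------
# Fold plan


@dataclass
class FoldPlan:
    """Outer 80/20 split plus k-fold assignment on the training 80%.

    ``fold`` maps subject id → inner fold number, or -1 for the held-out
    test set. The test set is stratified by (group, site) and is never to be
    touched by any fitting operation; fit functions in this module raise
    :class:`LeakageError` when offered test rows.
    """

    fold: pd.Series
    k: int
    seed: int
    stratify: tuple[str, ...] = ("group", "site")

    @property
    def test_ids(self) -> pd.Index:
        return self.fold.index[self.fold == -1]

    @property
    def outer_train_ids(self) -> pd.Index:
        return self.fold.index[self.fold >= 0]

    def train_ids(self, fold: int | None) -> pd.Index:
        """Training rows of an inner fold; ``fold=None`` gives the full 80%."""
        if fold is None:
            return self.outer_train_ids
        return self.fold.index[(self.fold >= 0) & (self.fold != fold)]

    def val_ids(self, fold: int) -> pd.Index:
        return self.fold.index[self.fold == fold]

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "seed": self.seed,
                           "stratify": list(self.stratify),
                           "fold": {str(i): int(f) for i, f in self.fold.items()}})


def make_fold_plan(table: FeatureTable, test_frac: float = 0.2, k: int = 10,
                   seed: int = 0) -> FoldPlan:
    """Stratified outer split and inner k-fold assignment.

    Stratification key is (group × site). When a stratum has fewer than
    ``k`` subjects in the training 80%, stratification of the inner folds is
    relaxed to group only, with a warning.
    """
    if not (0 < test_frac < 1):
        raise ConfigError("test_frac must be in (0,1)")
    if k < 2:
        raise ConfigError("k must be >= 2")
    from sklearn.model_selection import StratifiedKFold, train_test_split

    ids = np.asarray(table.subjects)
    strata = (table.group.astype(str) + "|" + table.site.astype(str)).to_numpy()
    rs = substream(seed, "fold-plan").integers(2**31 - 1)
    train_ids, test_ids = train_test_split(
        ids, test_size=test_frac, stratify=strata, random_state=int(rs))

    train_strata = pd.Series(strata, index=ids).loc[train_ids]
    counts = train_strata.value_counts()
    if (counts < k).any():
        warnings.warn("some (group,site) strata have fewer than k training subjects; "
                      "inner folds stratified by group only", stacklevel=2)
        train_strata = table.group.loc[train_ids].astype(str)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rs))
    fold = pd.Series(-1, index=pd.Index(ids, name="subject_id"), dtype=int)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(train_ids)), train_strata)):
        fold.loc[np.asarray(train_ids)[val_idx]] = f
    plan = FoldPlan(fold=fold, k=k, seed=seed)

    # harmonization needs training controls of every site in every fold
    for f in range(k):
        tr = plan.train_ids(f)
        hc_sites = set(table.site.loc[tr][table.group.loc[tr] == HC_LABEL])
        missing = set(table.site.unique()) - hc_sites
        if missing:
            warnings.warn(f"fold {f}: no training healthy controls at "
                          f"site(s) {sorted(missing)}; fold-wise harmonization "
                          "will fail there", stacklevel=2)
    return plan


def _check_no_test_rows(ids: Iterable, plan: FoldPlan, what: str) -> None:
    test = set(plan.test_ids)
    offending = [i for i in ids if i in test]
    if offending:
        raise LeakageError(f"{what} offered held-out test rows: {offending[:5]}")


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizationModel:
    """Per-(site, feature) healthy-control location/scale, training rows only.

    ``mu``/``sigma`` are site × feature frames; ``excluded`` lists features
    dropped because some site's control SD was zero (or undefined).
    """

    mu: pd.DataFrame
    sigma: pd.DataFrame
    fitted_on: list
    excluded: list[str] = field(default_factory=list)


def fit_site_normalizer(table: FeatureTable, plan: FoldPlan, fold: int | None = None,
                        rows: Sequence | None = None) -> HarmonizationModel:
    """Fit per-site healthy-control mean/SD on the fold's training rows.

    ``rows`` may restrict the fitting rows further; offering any test row
    raises :class:`LeakageError`. Sites with fewer than 2 training controls
    are an error; features whose control SD is zero at some site are
    excluded (logged), not fatal.
    """
    if rows is None:
        rows = plan.train_ids(fold)
    _check_no_test_rows(rows, plan, "fit_site_normalizer")
    rows = pd.Index(rows)
    hc_rows = rows[table.group.loc[rows] == HC_LABEL]
    if len(hc_rows) == 0:
        raise ConfigError("no training healthy controls to fit harmonization")

    vals = table.values.loc[hc_rows]
    sites = table.site.loc[hc_rows]
    for s in table.site.unique():
        if (sites == s).sum() < 2:
            raise ConfigError(f"site {s!r} has fewer than 2 training healthy controls")
    grp = vals.groupby(sites.to_numpy())
    mu = grp.mean()
    sigma = grp.std(ddof=1)  # sample SD
    bad = sigma.columns[(sigma <= 0).any(axis=0) | sigma.isna().any(axis=0)]
    excluded = sorted(bad)
    if excluded:
        logger.info("harmonization excluded %d zero-variance features: %s",
                    len(excluded), excluded[:5])
        mu = mu.drop(columns=excluded)
        sigma = sigma.drop(columns=excluded)
    return HarmonizationModel(mu=mu, sigma=sigma, fitted_on=list(hc_rows), excluded=excluded)


def apply_site_normalizer(model: HarmonizationModel, table: FeatureTable) -> FeatureTable:
    """z-score every row (controls and patients) against its site's controls."""
    unseen = set(table.site.unique()) - set(model.mu.index)
    if unseen:
        raise ConfigError(f"sites not covered by harmonization model: {sorted(unseen)}")
    feats = [f for f in table.feature_names if f in model.mu.columns]
    vals = table.values[feats]
    mu = model.mu.loc[table.site, feats].to_numpy()
    sigma = model.sigma.loc[table.site, feats].to_numpy()
    z = (vals.to_numpy() - mu) / sigma
    out = pd.DataFrame(z, index=table.subjects, columns=feats)
    return FeatureTable(out, table.modality[feats].copy(), table.site.copy(), table.group.copy())


# ---------------------------------------------------------------------------
# Imputation


@dataclass
class ImputationModel:
    """Training-row feature means for fill-in, and the dropped feature list."""

    means: pd.Series
    excluded: list[str]
    threshold: float

    def __post_init__(self) -> None:
        overlap = set(self.means.index) & set(self.excluded)
        if overlap:
            raise ConfigError(f"features both imputed and excluded: {sorted(overlap)}")


def impute_features(table: FeatureTable, plan: FoldPlan, fold: int | None = None,
                    threshold: float = 0.30) -> tuple[FeatureTable, ImputationModel]:
    """Mean-impute features with ≤ ``threshold`` missing on training rows.

    The missing fraction is computed on the fold's training rows only, and
    the fill value is the training-row observed mean (a single averaged
    value per feature). Features above the threshold are dropped from the
    returned table. A feature missing in *all* training rows is an error.
    """
    rows = plan.train_ids(fold)
    train = table.values.loc[rows]
    frac = train.isna().mean(axis=0)
    all_missing = list(frac.index[train.isna().all(axis=0)])
    if all_missing:
        raise ConfigError(f"features missing in every training row: {all_missing[:5]}")
    keep = frac.index[frac <= threshold]
    drop = sorted(frac.index[frac > threshold])
    if drop:
        logger.info("imputation dropped %d features over %.0f%% missing", len(drop),
                    100 * threshold)
    means = train[keep].mean(axis=0)
    out_vals = table.values[keep].fillna(means)
    out = FeatureTable(out_vals, table.modality[keep].copy(), table.site.copy(),
                       table.group.copy())
    return out, ImputationModel(means=means, excluded=drop, threshold=threshold)


# ---------------------------------------------------------------------------
# Demographics


@dataclass
class DemographicsReport:
    """Group-comparison statistics for the demographic variables."""

    sex_chi2: float
    sex_p: float
    sex_df: int
    sex_counts: pd.DataFrame
    anova: dict[str, tuple[float, float]]  # variable -> (F, p)
    group_summaries: pd.DataFrame


def sex_chi_square(counts: np.ndarray | pd.DataFrame) -> tuple[float, float, int]:
    """Pearson χ² (no continuity correction) on a groups × sex table."""
    counts = np.asarray(counts, dtype=float)
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def demographics_report(subjects: pd.DataFrame,
                        continuous: Sequence[str] = ("age", "education")) -> DemographicsReport:
    """χ² on group × sex counts; one-way ANOVA on the continuous variables.

    ``subjects`` needs ``group`` and ``sex`` columns plus the continuous
    columns. Groups with zero subjects are an error.
    """
    groups = subjects["group"].unique()
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    counts = pd.crosstab(subjects["group"], subjects["sex"])
    if (counts.sum(axis=1) == 0).any():
        raise ConfigError("a group has zero subjects")
    chi2, p, dof = sex_chi_square(counts)
    anova = {}
    for var in continuous:
        samples = [subjects.loc[subjects["group"] == g, var].dropna() for g in groups]
        f, pv = stats.f_oneway(*samples)
        anova[var] = (float(f), float(pv))
    summaries = subjects.groupby("group")[list(continuous)].agg(["mean", "std"])
    return DemographicsReport(sex_chi2=chi2, sex_p=p, sex_df=dof, sex_counts=counts,
                              anova=anova, group_summaries=summaries)
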