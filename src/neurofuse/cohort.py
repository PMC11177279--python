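"""Synthetic multi-site, multi-group cohort generation with known ground truth.

Emulates a 3-site dementia cohort with three diagnostic groups (healthy
controls, behavioral-variant frontotemporal dementia, Alzheimer's disease):

* demographics (age, education, sex) drawn from configurable distributions;
* raw per-subject payloads — phase-coupled-oscillator EEG (so phase-locking
  is analytically controllable via a coupling strength κ), blockwise
  Gaussian fMRI ROI series with Markov correlation-state switching (so
  static and dynamic connectivity dissociate), FreeSurfer-style morphometry
  stats and 0–30 cognitive screening scores;
* additive/multiplicative site effects applied after group effects;
* modality-block missingness (whole assessments missing at random, at
  configurable per-group rates).

All randomness flows from one seed through counter-based substreams, so the
same configuration reproduces the same cohort bit for bit, and any single
subject's payload can be regenerated in isolation.

Two entry points: :func:`simulate_cohort` produces raw payloads to exercise
the signal-processing feature extractors end to end; the feature-level
:func:`simulate_feature_table` plants group and site effects directly in an
assembled feature table, which is how the machine-learning stages are
stress-tested at realistic cohort sizes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .eeg import EegRecording
from .errors import ConfigError
from .fmri import NETWORKS, RoiTimeSeries
from .morphometry import MorphometryRecord, write_stats_table
from .table import FeatureTable, assemble_table

__all__ = [
    "SimConfig", "SyntheticCohort", "BlockSpec",
    "simulate_cohort", "simulate_eeg", "simulate_fmri", "simulate_tabular",
    "simulate_feature_table", "inject_missingness", "write_cohort",
]

GROUPS = ("HC", "bvFTD", "AD")

#: Modality-block missing rates per group, matching the observed pattern of
#: whole assessments missing in a multi-site full sample.
DEFAULT_MISSING_RATES = {
    "CogA": {"HC": 0.27, "bvFTD": 0.25, "AD": 0.26},
    "EF": {"HC": 0.24, "bvFTD": 0.22, "AD": 0.25},
    "MRI/fMRI": {"HC": 0.28, "bvFTD": 0.27, "AD": 0.28},
    "EEG": {"HC": 0.29, "bvFTD": 0.27, "AD": 0.26},
}

#: Region inventory for the synthetic morphometry tables: a reduced
#: Desikan–Killiany cortical subset plus the subcortical structures most
#: relevant to dementia, with typical adult volumes (mm^3).
MORPH_REGIONS = {
    "hippocampus": 4200.0, "amygdala": 1700.0, "caudate": 3600.0,
    "putamen": 5000.0, "lateral_ventricle": 12000.0, "insula": 7000.0,
    "entorhinal": 1900.0, "temporal_pole": 2400.0, "precuneus": 9500.0,
    "anterior_cingulate": 2500.0, "superior_frontal": 22000.0,
    "middle_temporal": 12000.0,
}

COG_SUBSCORES = {
    "CogA": ("abstraction", "memory", "visuospatial", "recognition", "attention"),
    "EF": ("inhibition", "conflicting", "digits", "proverb", "motor series"),
}


@dataclass
class SimConfig:
    """Full configuration of a payload-level synthetic cohort."""

    n_per_group_per_site: int = 10
    n_sites: int = 3
    groups: tuple[str, ...] = GROUPS
    site_shift: tuple[float, ...] | None = None   # additive, z-units
    site_scale: tuple[float, ...] | None = None   # multiplicative
    #: Cohen's d on informative tabular features, per patient group.
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"bvFTD": 1.5, "AD": 1.5})
    n_informative: int = 5
    #: per-group phase-coupling strength κ for the designated ROI pair
    eeg_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.8, "bvFTD": 0.4, "AD": 0.55})
    #: per-group probability of a correlation-state switch per window
    fmri_state_switch: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.2, "bvFTD": 0.5, "AD": 0.4})
    missing_rates: Mapping[str, Mapping[str, float] | float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    seed: int = 0
    # payload sizing (defaults follow the acquisition protocol being emulated;
    # tests use smaller values through these same knobs)
    eeg_duration: float = 600.0
    eeg_rate: float = 256.0
    eeg_channels: int = 128
    fmri_volumes: int = 200
    fmri_tr: float = 2.0
    rois_per_network: int = 2
    age_mean: float = 72.0
    age_sd: float = 8.0
    edu_mean: float = 14.0
    edu_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_per_group_per_site < 1:
            raise ConfigError("n_per_group_per_site must be >= 1")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.site_shift is None:
            self.site_shift = tuple(0.0 for _ in range(self.n_sites))
        if self.site_scale is None:
            self.site_scale = tuple(1.0 for _ in range(self.n_sites))
        if len(self.site_shift) != self.n_sites or len(self.site_scale) != self.n_sites:
            raise ConfigError("site_shift/site_scale must have n_sites entries")
        for g, k in self.eeg_coupling.items():
            if not (0.0 <= k <= 1.0):
                raise ConfigError(f"eeg_coupling[{g!r}]={k} outside [0,1]")
        for g, p in self.fmri_state_switch.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"fmri_state_switch[{g!r}]={p} outside [0,1]")
        for block, rate in self.missing_rates.items():
            vals = rate.values() if isinstance(rate, Mapping) else [rate]
            for v in vals:
                if not (0.0 <= v <= 1.0):
                    raise ConfigError(f"missing rate for {block!r} outside [0,1]")
        for g, d in self.effect_sizes.items():
            if not np.isfinite(d):
                raise ConfigError(f"effect size for {g!r} not finite")
        if self.eeg_channels % 16 != 0:
            raise ConfigError("eeg_channels must be a multiple of 16 (16 ROIs)")

    @property
    def sites(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]


@dataclass
class SyntheticCohort:
    """Subjects table, raw payloads per subject, and planted ground truth."""

    subjects: pd.DataFrame  # id-indexed: site, group, sex, age, education
    eeg: dict[str, EegRecording]
    fmri: dict[str, RoiTimeSeries]
    morphometry: dict[str, list[MorphometryRecord]]
    cognition: pd.DataFrame
    ground_truth: dict
    config: SimConfig


# ---------------------------------------------------------------------------
# EEG payload


def simulate_eeg(group: str, kappa: float, seed: int, duration: float = 600.0,
                 rate: float = 256.0, n_channels: int = 128,
                 noise_amp: float = 0.5, phase_noise_sd: float = 1.0,
                 base_freq: float = 10.0,
                 coupled_rois: tuple[str, str] = ("ROI01", "ROI02")) -> EegRecording:
    """Phase-coupled-oscillator EEG with 1/f amplitude noise.

    Channels of the two designated ROIs share a common phase process; each
    channel adds an independent random-walk phase perturbation scaled by
    (1 − κ), so κ=1 with zero noise gives identical phases (PLV = 1) and
    κ=0 gives independent phases. All other channels carry fully
    independent phase walks.
    """
    if not (0.0 <= kappa <= 1.0):
        raise ConfigError(f"kappa={kappa} outside [0,1]")
    rng = substream(seed, "eeg", group)
    n = int(round(duration * rate))
    per_roi = n_channels // 16
    rois = [f"ROI{i + 1:02d}" for i in range(16)]
    labels = [f"ch{i + 1:03d}" for i in range(n_channels)]
    roi_map = {labels[i]: rois[i // per_roi] for i in range(n_channels)}

    t = np.arange(n) / rate
    carrier = 2 * np.pi * base_freq * t
    shared = np.cumsum(rng.normal(0.0, phase_noise_sd, size=n))
    signals = np.empty((n_channels, n))
    for i, lab in enumerate(labels):
        walk = np.cumsum(rng.normal(0.0, phase_noise_sd, size=n))
        if roi_map[lab] in coupled_rois:
            phase = carrier + shared + (1.0 - kappa) * walk
        else:
            phase = carrier + walk
        signals[i] = np.cos(phase)
        if noise_amp > 0:
            signals[i] += noise_amp * _pink_noise(n, rng)
    return EegRecording(signals, rate=rate, channel_labels=labels, roi_map=roi_map)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


# ---------------------------------------------------------------------------
# fMRI payload


def simulate_fmri(group: str, switch_prob: float, seed: int,
                  n_volumes: int = 200, tr: float = 2.0,
                  rois_per_network: int = 2, r_level: float = 0.5,
                  r_alt: float | None = None, window: int = 20,
                  noise_sd: float = 0.0) -> RoiTimeSeries:
    """Blockwise-correlated ROI series with Markov correlation-state switching.

    Within each network, ROIs share a latent factor giving equicorrelation
    ``r_level``; every ``window`` volumes the state may switch (probability
    ``switch_prob``) to the alternative level ``r_alt`` (default −r_level
    for 2-ROI networks, r_level/2 otherwise). ``switch_prob=0`` yields a
    stationary series.
    """
    if not (0.0 <= switch_prob <= 1.0):
        raise ConfigError(f"switch_prob={switch_prob} outside [0,1]")
    rng = substream(seed, "fmri", group)
    m = rois_per_network
    if r_alt is None:
        r_alt = -r_level if m == 2 else r_level / 2.0
    for r in (r_level, r_alt):
        if r < 0 and m > 2 and abs(r) > 1.0 / (m - 1):
            raise ConfigError(f"negative equicorrelation {r} not PSD for {m} ROIs")

    roi_names, network_map = [], {}
    for net in NETWORKS:
        for j in range(m):
            name = f"{net}_{j + 1}"
            roi_names.append(name)
            network_map[name] = net

    series = np.empty((len(roi_names), n_volumes))
    for b, net in enumerate(NETWORKS):
        state = r_level
        pos = 0
        cols = []
        while pos < n_volumes:
            length = min(window, n_volumes - pos)
            cols.append(_equicorr_block(m, state, length, rng))
            if rng.random() < switch_prob:
                state = r_alt if state == r_level else r_level
            pos += length
        series[b * m:(b + 1) * m] = np.concatenate(cols, axis=1)
    if noise_sd > 0:
        series += rng.normal(0.0, noise_sd, size=series.shape)
    return RoiTimeSeries(series, tr=tr, network_map=network_map, roi_names=roi_names)


def _equicorr_block(m: int, r: float, length: int, rng: np.random.Generator) -> np.ndarray:
    """m series of given length with pairwise correlation r (|r| allowed for m=2)."""
    g = rng.normal(size=length)
    eps = rng.normal(size=(m, length))
    a = np.sqrt(abs(r))
    out = a * g[None, :] + np.sqrt(1 - abs(r)) * eps
    if r < 0:
        if m != 2:
            # sign pattern only realizes -r exactly for pairs
            raise ConfigError("negative r requires 2-ROI networks")
        out[1] = -a * g + np.sqrt(1 - abs(r)) * eps[1]
    return out


# ---------------------------------------------------------------------------
# Tabular payloads (cognition, morphometry, demographics)


def simulate_tabular(group: str, site_idx: int, config: SimConfig, seed: int,
                     subject_key: int = 0
                     ) -> tuple[list[MorphometryRecord], pd.Series, pd.Series]:
    """Morphometry records, cognition scores and demographics for one subject.

    Patient groups get informative features shifted by d·σ (cognition totals
    down, atrophy-sensitive volumes down); the site's additive shift and
    multiplicative scale are applied after the group effect. Cognition
    totals are clipped to the 0–30 instrument range.
    """
    rng = substream(seed, "tabular", group, site_idx, subject_key)
    d = config.effect_sizes.get(group, 0.0)
    shift = config.site_shift[site_idx]
    scale = config.site_scale[site_idx]

    # demographics
    sex = int(rng.random() < 0.5)
    age = rng.normal(config.age_mean, config.age_sd)
    edu = max(0.0, rng.normal(config.edu_mean, config.edu_sd))
    demo = pd.Series({"sex": float(sex), "age": age, "education": edu})

    # cognition: totals are the informative features
    cog = {}
    for block, subs in COG_SUBSCORES.items():
        sub_sd = 1.0
        base = 26.0 if block == "CogA" else 24.0
        total_sd = 2.0
        total = rng.normal(base, total_sd) - d * total_sd
        total = float(np.clip(scale * (total + shift * total_sd) , 0.0, 30.0))
        cog[f"{block} total"] = total
        for s in subs:
            v = rng.normal(4.5, sub_sd) - 0.5 * d * sub_sd
            cog[f"{block} {s}"] = float(np.clip(scale * (v + shift * sub_sd), 0.0, 30.0))
    cognition = pd.Series(cog)

    # morphometry: dementia-sensitive regions atrophied in patients
    atrophic = {"bvFTD": ("insula", "temporal_pole", "anterior_cingulate"),
                "AD": ("hippocampus", "entorhinal", "amygdala")}
    etiv = float(rng.normal(1.5e6, 1.2e5))
    records = []
    for hemi in ("lh", "rh"):
        for region, base_vol in MORPH_REGIONS.items():
            sd_vol = 0.08 * base_vol
            v = rng.normal(base_vol, sd_vol)
            if region in atrophic.get(group, ()):
                v -= d * sd_vol
            v = scale * (v + shift * sd_vol)
            records.append(MorphometryRecord(f"{hemi}_{region}", "volume",
                                             max(v, 1.0), etiv))
    return records, cognition, demo


# ---------------------------------------------------------------------------
# Whole-cohort simulation


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full payload-level cohort described by ``config``."""
    rows = []
    eeg, fmri, morph = {}, {}, {}
    cog_rows = {}
    idx = 0
    for s, site in enumerate(config.sites):
        for group in config.groups:
            for j in range(config.n_per_group_per_site):
                sid = f"sub{idx + 1:04d}"
                records, cognition, demo = simulate_tabular(
                    group, s, config, config.seed, subject_key=idx)
                rows.append({"subject_id": sid, "site": site, "group": group,
                             "sex": demo["sex"], "age": demo["age"],
                             "education": demo["education"]})
                cog_rows[sid] = cognition
                morph[sid] = records
                eeg[sid] = simulate_eeg(
                    group, config.eeg_coupling.get(group, 0.0),
                    seed=config.seed + idx + 1,
                    duration=config.eeg_duration, rate=config.eeg_rate,
                    n_channels=config.eeg_channels)
                fmri[sid] = simulate_fmri(
                    group, config.fmri_state_switch.get(group, 0.0),
                    seed=config.seed + idx + 1,
                    n_volumes=config.fmri_volumes, tr=config.fmri_tr,
                    rois_per_network=config.rois_per_network)
                idx += 1
    subjects = pd.DataFrame(rows).set_index("subject_id")
    cognition = pd.DataFrame(cog_rows).T
    gt = {
        "informative_features": ["CogA total", "EF total"],
        "effect_sizes": dict(config.effect_sizes),
        "site_shift": list(config.site_shift),
        "site_scale": list(config.site_scale),
        "eeg_coupling": dict(config.eeg_coupling),
        "fmri_state_switch": dict(config.fmri_state_switch),
    }
    return SyntheticCohort(subjects=subjects, eeg=eeg, fmri=fmri, morphometry=morph,
                           cognition=cognition, ground_truth=gt, config=config)


# ---------------------------------------------------------------------------
# Feature-level fast path


@dataclass
class BlockSpec:
    """One feature block of the feature-level simulator.

    ``effect`` maps a (patient) group to Cohen's d on this block's
    informative features. The second and later patient groups get an
    alternating ±d sign pattern so that patient–patient pairs remain
    separable, not just patient–control.
    """

    modality: str
    n_features: int
    n_informative: int = 0
    effect: Mapping[str, float] = field(default_factory=dict)
    prefix: str | None = None

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative > n_features")


def default_blocks(d: float = 1.5) -> dict[str, BlockSpec]:
    """Multimodal default schema: strong cognitive effect, moderate atrophy
    and connectivity effects, plus pure-noise features in every block."""
    eff = lambda x: {"bvFTD": x, "AD": x}
    return {
        "NPS": BlockSpec("NPS", 12, 2, eff(d), prefix="CogA"),
        "Atrophy": BlockSpec("Atrophy", 60, 1, eff(0.8 * d), prefix="Vol%"),
        "EEG-FC": BlockSpec("EEG-FC", 136, 1, eff(0.5 * d), prefix="PLV:beta"),
        "MRI-FC": BlockSpec("MRI-FC", 10, 1, eff(0.5 * d), prefix="DCFA"),
    }


def simulate_feature_table(
    n_per_group_per_site: int = 20,
    n_sites: int = 3,
    groups: Sequence[str] = GROUPS,
    blocks: Mapping[str, BlockSpec] | None = None,
    site_shift: Sequence[float] | None = None,
    site_scale: Sequence[float] | None = None,
    missing_rates: Mapping[str, Mapping[str, float] | float] | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, dict]:
    """Assembled feature table with planted group effects and site effects.

    Features are unit-normal noise; each block's informative features are
    shifted by d·σ for the patient groups named in its ``effect`` map (the
    second patient group with an alternating sign pattern); the site's
    additive shift and multiplicative scale are applied afterwards to all
    non-demographic features. Returns the table and a ground-truth dict
    naming the informative features and planted parameters.
    """
    if blocks is None:
        blocks = default_blocks()
    if site_shift is None:
        site_shift = [0.0] * n_sites
    if site_scale is None:
        site_scale = [1.0] * n_sites
    if len(site_shift) != n_sites or len(site_scale) != n_sites:
        raise ConfigError("site_shift/site_scale must have n_sites entries")

    rng = substream(seed, "feature-table")
    sites = [f"site{i + 1}" for i in range(n_sites)]
    rows = []
    for s in sites:
        for g in groups:
            for _ in range(n_per_group_per_site):
                rows.append((s, g))
    n = len(rows)
    site_lab = pd.Series([r[0] for r in rows])
    group_lab = pd.Series([r[1] for r in rows])
    ids = pd.Index([f"sub{i + 1:04d}" for i in range(n)], name="subject_id")
    site_lab.index = group_lab.index = ids

    patient_groups = [g for g in groups if g != "HC"]
    maps: dict[str, pd.DataFrame] = {}
    informative: list[str] = []
    planted: dict[str, dict[str, float]] = {}
    for name, spec in blocks.items():
        prefix = spec.prefix or name
        feats = [f"{prefix} f{j + 1:03d}" for j in range(spec.n_features)]
        x = rng.normal(size=(n, spec.n_features))
        for j in range(spec.n_informative):
            feat = feats[j]
            informative.append(feat)
            planted[feat] = {}
            for gi, g in enumerate(patient_groups):
                d = spec.effect.get(g, 0.0)
                sign = 1.0 if gi == 0 else (1.0 if j % 2 == 0 else -1.0)
                planted[feat][g] = sign * d
                x[(group_lab == g).to_numpy(), j] += sign * d
        shift = site_lab.map(dict(zip(sites, site_shift))).to_numpy()[:, None]
        scale = site_lab.map(dict(zip(sites, site_scale))).to_numpy()[:, None]
        x = scale * (x + shift)
        maps[spec.modality] = pd.DataFrame(x, index=ids, columns=feats)

    demo = pd.DataFrame({
        "sex": (rng.random(n) < 0.5).astype(float),
        "age": rng.normal(72.0, 8.0, size=n),
        "education": rng.normal(14.0, 4.0, size=n),
    }, index=ids)
    maps["DEM"] = demo
    subjects = pd.DataFrame({"site": site_lab, "group": group_lab})
    table = assemble_table(maps, subjects)
    gt = {"informative_features": informative, "planted_effects": planted,
          "site_shift": list(site_shift), "site_scale": list(site_scale),
          "seed": seed}
    if missing_rates:
        table = inject_missingness(table, missing_rates, seed=seed)
    return table, gt


# ---------------------------------------------------------------------------
# Missingness


def _feature_block(feature: str, modality: str) -> str:
    """Map a feature name to its missingness block (whole-assessment level)."""
    if feature.startswith("CogA"):
        return "CogA"
    if feature.startswith("EF"):
        return "EF"
    if modality in ("Atrophy", "MRI-FC"):
        return "MRI/fMRI"
    if modality == "EEG-FC":
        return "EEG"
    if modality == "NPS":
        return "CogA"
    return modality


def inject_missingness(table: FeatureTable,
                       rates: Mapping[str, Mapping[str, float] | float],
                       seed: int = 0) -> FeatureTable:
    """Mask whole modality blocks missing-completely-at-random.

    ``rates`` maps block name (CogA, EF, MRI/fMRI, EEG, or a modality tag)
    to a fraction, or to a per-group fraction map. A subject drawn missing
    for a block loses every feature of that block; observed values are
    untouched.
    """
    for block, rate in rates.items():
        vals = rate.values() if isinstance(rate, Mapping) else [rate]
        for v in vals:
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"missing rate for {block!r} outside [0,1]")
    out = table.values.copy()
    blocks: dict[str, list[str]] = {}
    for feat in table.feature_names:
        blocks.setdefault(_feature_block(feat, table.modality[feat]), []).append(feat)
    rng = substream(seed, "missingness")
    for block, feats in blocks.items():
        if block not in rates:
            continue
        rate = rates[block]
        for i, sid in enumerate(table.subjects):
            r = rate.get(table.group.loc[sid], 0.0) if isinstance(rate, Mapping) else rate
            if rng.random() < r:
                out.loc[sid, feats] = np.nan
    return FeatureTable(out, table.modality.copy(), table.site.copy(), table.group.copy())


# ---------------------------------------------------------------------------
# Disk layout


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> None:
    """Write the cohort as the documented directory layout.

    ``subjects.tsv``, per-subject ``eeg/<id>.tsv`` and ``fmri/<id>.tsv``
    matrices, ``morphometry/<id>.stats`` text, and ``ground_truth.json``.
    """
    os.makedirs(out_dir, exist_ok=True)
    cohort.subjects.to_csv(os.path.join(out_dir, "subjects.tsv"), sep="\t")
    cohort.cognition.to_csv(os.path.join(out_dir, "cognition.tsv"), sep="\t")
    for sub in ("eeg", "fmri", "morphometry"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for sid, rec in cohort.eeg.items():
        np.savetxt(os.path.join(out_dir, "eeg", f"{sid}.tsv"), rec.samples,
                   delimiter="\t")
    for sid, ts in cohort.fmri.items():
        np.savetxt(os.path.join(out_dir, "fmri", f"{sid}.tsv"), ts.values,
                   delimiter="\t")
    for sid, records in cohort.morphometry.items():
        write_stats_table(records, os.path.join(out_dir, "morphometry", f"{sid}.stats"))
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2)
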