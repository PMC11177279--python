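"""Resting-state fMRI connectivity features and head-motion QC.

Three statistics over ROI × volume time series:

* **SFC** — static functional connectivity: the Pearson correlation between
  ROI pairs over the whole series, averaged within each of the five
  canonical resting-state networks (default-mode, salience, executive,
  visual, motor). Pair correlations are Fisher-z transformed before
  averaging and the network mean is transformed back to r-units.

* **DCFA** — dynamic connectivity fluctuation: correlations are recomputed
  in sliding windows and the feature is the standard deviation across
  windows of the window-mean Fisher-z connectivity, per network. A
  stationary series gives DCFA near 0; correlation-state switching inflates
  it. This is a reconstruction of the dynamic-fluctuation statistic as the
  standard sliding-window construction (window 20 volumes, step 2 by
  default), not a verbatim port of any particular toolbox.

* **FD** — framewise displacement: the per-volume sum of absolute backward
  differences of the six realignment parameters, rotations converted to mm
  on a 50 mm sphere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries", "DcfaParams", "FdSeries", "NETWORKS",
    "sfc_features", "dcfa_features", "framewise_displacement",
    "fmri_feature_vector",
]

#: Canonical resting-state networks.
NETWORKS = ("DMN", "SN", "EN", "Visual", "Motor")


@dataclass
class RoiTimeSeries:
    """ROI × volumes matrix with a ROI → network map and the TR in seconds."""

    values: np.ndarray
    tr: float
    network_map: dict[str, str]  # ROI name -> network
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("values must be ROI x volumes")
        if self.roi_names is None:
            self.roi_names = [f"roi{i}" for i in range(self.values.shape[0])]
        if len(self.roi_names) != self.values.shape[0]:
            raise ConfigError("roi_names length mismatch")
        unmapped = [r for r in self.roi_names if r not in self.network_map]
        if unmapped:
            raise ConfigError(f"ROIs without network assignment: {unmapped[:5]}")
        for net in set(self.network_map.values()):
            members = [r for r in self.roi_names if self.network_map[r] == net]
            if len(members) < 2:
                raise ConfigError(f"network {net!r} has fewer than 2 ROIs")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    def network_indices(self) -> dict[str, list[int]]:
        nets: dict[str, list[int]] = {}
        for idx, roi in enumerate(self.roi_names):
            nets.setdefault(self.network_map[roi], []).append(idx)
        return nets


@dataclass
class DcfaParams:
    """Sliding-window parameters for the dynamic-fluctuation statistic."""

    window: int = 20  # volumes
    step: int = 2
    fisher_z: bool = True

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ConfigError("DCFA window must be >= 3 volumes")
        if self.step < 1:
            raise ConfigError("DCFA step must be >= 1")


@dataclass
class FdSeries:
    """Per-volume framewise displacement (mm) and its mean."""

    fd: np.ndarray
    mean_fd: float


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def _network_pair_corr(block: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise Pearson correlations of a ROI-block series."""
    r = np.corrcoef(block)
    iu = np.triu_indices(block.shape[0], k=1)
    return r[iu]


def sfc_features(ts: RoiTimeSeries) -> pd.Series:
    """Static FC per network: Fisher-z mean of within-network pair correlations.

    Returned in r-units (back-transformed); features named ``SFC:<network>``.
    """
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.roi_names[i] for i in np.where(sd == 0)[0]]
        raise ConfigError(f"zero-variance ROI series: {bad}")
    feats = {}
    for net, idx in sorted(ts.network_indices().items()):
        rs = _network_pair_corr(ts.values[idx])
        feats[f"SFC:{net}"] = float(np.tanh(np.mean(_fisher_z(rs))))
    return pd.Series(feats)


def dcfa_features(ts: RoiTimeSeries, params: DcfaParams = DcfaParams()) -> pd.Series:
    """Dynamic connectivity fluctuation per network.

    Sliding windows of ``params.window`` volumes advanced by ``params.step``;
    per window, the mean Fisher-z within-network pair correlation; the
    feature is the SD of that windowed series (in z-units). Windows
    containing a zero-variance ROI are dropped with a warning rather than
    poisoning the statistic. Features named ``DCFA:<network>``.
    """
    T = ts.n_volumes
    if T < params.window:
        raise ConfigError(f"{T} volumes < DCFA window {params.window}")
    starts = range(0, T - params.window + 1, params.step)
    feats = {}
    for net, idx in sorted(ts.network_indices().items()):
        block = ts.values[idx]
        zs = []
        dropped = 0
        for s in starts:
            win = block[:, s:s + params.window]
            if np.any(win.std(axis=1) == 0):
                dropped += 1
                continue
            rs = _network_pair_corr(win)
            zs.append(np.mean(_fisher_z(rs) if params.fisher_z else rs))
        if dropped:
            warnings.warn(f"DCFA:{net}: dropped {dropped} zero-variance windows",
                          stacklevel=2)
        if len(zs) < 2:
            feats[f"DCFA:{net}"] = 0.0
        else:
            feats[f"DCFA:{net}"] = float(np.std(zs, ddof=0))
    return pd.Series(feats)


def fmri_feature_vector(ts: RoiTimeSeries,
                        params: DcfaParams = DcfaParams()) -> pd.Series:
    """SFC + DCFA features (10 features with the five canonical networks)."""
    return pd.concat([sfc_features(ts), dcfa_features(ts, params)])


def framewise_displacement(rp: np.ndarray, head_radius: float = 50.0) -> FdSeries:
    """Framewise displacement from a T × 6 realignment-parameter matrix.

    Columns 0–2 are translations (mm), 3–5 rotations (radians). FD(t) is the
    sum of absolute backward differences, rotations scaled by
    ``head_radius`` mm; FD of the first volume is 0 by convention.
    """
    rp = np.asarray(rp, dtype=float)
    if rp.ndim != 2 or rp.shape[1] != 6:
        raise ConfigError("realignment parameters must be T x 6")
    if not np.all(np.isfinite(rp)):
        raise ConfigError("non-finite realignment parameters")
    scaled = rp.copy()
    scaled[:, 3:] *= head_radius
    diffs = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], diffs])
    return FdSeries(fd=fd, mean_fd=float(fd.mean()))


def read_realignment_params(path) -> np.ndarray:
    """Read a 6-column whitespace-delimited realignment-parameter text file."""
    rp = np.loadtxt(path)
    if rp.ndim == 1:
        rp = rp[None, :]
    if rp.shape[1] != 6:
        raise ConfigError(f"expected 6 columns, got {rp.shape[1]}")
    return rp


def read_roi_series(path, network_map: Mapping[str, str], tr: float = 2.0,
                    roi_names: list[str] | None = None) -> RoiTimeSeries:
    """Load a ROI × volume matrix from delimited text."""
    vals = np.loadtxt(path, delimiter="\t") if str(path).endswith(".tsv") else np.loadtxt(path)
    return RoiTimeSeries(vals, tr=tr, network_map=dict(network_map), roi_names=roi_names)
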