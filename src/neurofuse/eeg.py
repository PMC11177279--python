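"""EEG functional connectivity: band-limited PLV and wSMI over a τ grid.

The recording is band-filtered (zero-phase Butterworth) as a continuous
signal, cut into non-overlapping 1000 ms segments, and a connectivity
adjacency matrix is computed per segment then averaged across segments.

Two metrics are implemented:

* **PLV** (phase-locking value): the magnitude of the time-averaged unit
  phasor of the instantaneous phase difference between two channels, with
  phases taken from the analytic (Hilbert) signal of the band-filtered data.
  PLV is 1 for a constant phase lag and near 0 for independent phases.

* **wSMI** (weighted symbolic mutual information): each channel is mapped to
  a sequence of ordinal patterns of ``k`` samples spaced ``tau`` apart; the
  mutual information between the two channels' pattern sequences is computed
  with pairs of identical or sign-opposite patterns weighted out (so common
  sources and volume conduction do not contribute), normalized by log(k!).

Channel-level matrices are reduced to 16-ROI features by averaging all
inter-electrode connections within a ROI or linking any two ROIs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .errors import ChannelError, ConfigError

__all__ = [
    "EegRecording", "BandSpec", "WsmiParams", "ConnectivityMatrix",
    "DEFAULT_BANDS", "epoch_and_filter", "phase_locking", "plv_adjacency", "wsmi_adjacency",
    "roi_aggregate", "eeg_feature_vector",
]

#: Default analysis bands (Hz). Edges are the conventional clinical bands,
#: clipped to the 0.5–45 Hz offline filter range.
DEFAULT_BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

#: Default wSMI τ grid in milliseconds.
DEFAULT_TAU_MS = (8.0, 16.0, 32.0, 64.0)


@dataclass
class BandSpec:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.5 <= self.low < self.high <= 45.0):
            raise ConfigError(
                f"band {self.name}: edges must satisfy 0.5 <= low < high <= 45, "
                f"got [{self.low}, {self.high}]")


def default_bands() -> list[BandSpec]:
    return [BandSpec(n, lo, hi) for n, lo, hi in DEFAULT_BANDS]


@dataclass
class WsmiParams:
    """Symbolic-transform parameters: pattern length k and sample spacing τ."""

    k: int = 3
    tau: int = 1  # samples

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("wSMI kernel k must be >= 2")
        if self.tau < 1:
            raise ConfigError("wSMI tau must be >= 1 sample")

    @classmethod
    def from_ms(cls, tau_ms: float, rate: float, k: int = 3) -> "WsmiParams":
        """τ from a millisecond spacing at the given sampling rate (floor, min 1)."""
        return cls(k=k, tau=max(1, int(math.floor(tau_ms * rate / 1000.0))))

    @property
    def span(self) -> int:
        """Samples covered by one ordinal pattern."""
        return (self.k - 1) * self.tau + 1


@dataclass
class EegRecording:
    """Channels × samples recording with a channel → ROI map."""

    samples: np.ndarray  # channels x time, microvolts
    rate: float          # Hz
    channel_labels: list[str]
    roi_map: dict[str, str]  # channel label -> ROI name

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigError("samples must be channels x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ConfigError("channel_labels length mismatch")
        unmapped = [c for c in self.channel_labels if c not in self.roi_map]
        if unmapped:
            raise ConfigError(f"channels without ROI assignment: {unmapped[:5]}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate


@dataclass
class ConnectivityMatrix:
    """Symmetric node × node adjacency tagged with its metric."""

    values: np.ndarray
    metric: str              # e.g. "PLV:beta", "wSMI:16ms", "SFC", "DCFA"
    node_ids: list[str]
    diagonal_excluded: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ConfigError("adjacency must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ConfigError("adjacency must be symmetric")
        if len(self.node_ids) != n:
            raise ConfigError("node_ids length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_ids, columns=self.node_ids)


# ---------------------------------------------------------------------------
# Readers


def read_roi_map(path) -> dict[str, str]:
    """Two-column text file (channel, ROI) → channel → ROI dict."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            out[parts[0]] = parts[1]
    return out


def read_channel_matrix(path, rate: float, roi_map: Mapping[str, str],
                        channel_labels: Sequence[str] | None = None) -> EegRecording:
    """Channels × samples matrix from delimited text."""
    data = np.loadtxt(path, delimiter="\t") if str(path).endswith(".tsv") \
        else np.loadtxt(path)
    if channel_labels is None:
        channel_labels = [f"ch{i + 1:03d}" for i in range(data.shape[0])]
    return EegRecording(data, rate=rate, channel_labels=list(channel_labels),
                        roi_map=dict(roi_map))


def read_edf(path, roi_map: Mapping[str, str]) -> EegRecording:
    """EDF recording via mne (optional dependency for real data)."""
    import mne  # local import: only needed for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EegRecording(raw.get_data() * 1e6, rate=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names), roi_map=dict(roi_map))


# ---------------------------------------------------------------------------
# Filtering and segmentation


def epoch_and_filter(recording: EegRecording, band: BandSpec | None,
                     segment_ms: float = 1000.0) -> list[np.ndarray]:
    """Zero-phase band filtering of the continuous record, then segmentation.

    Filtering (4th-order Butterworth, forward-backward) is applied to the
    whole recording *before* cutting, so segment edges carry no filter
    transients. Segments are consecutive, non-overlapping windows of
    ``segment_ms``; a trailing partial segment is discarded.
    """
    seg_len = int(round(segment_ms * recording.rate / 1000.0))
    n = recording.samples.shape[1]
    if n < seg_len:
        raise ConfigError(f"recording shorter than one {segment_ms:.0f} ms segment")
    data = recording.samples
    if band is not None:
        if band.high >= recording.rate / 2:
            raise ConfigError("band edge above Nyquist frequency")
        sos = butter(4, [band.low, band.high], btype="bandpass",
                     fs=recording.rate, output="sos")
        data = sosfiltfilt(sos, data, axis=1)
    n_seg = n // seg_len
    return [data[:, i * seg_len:(i + 1) * seg_len] for i in range(n_seg)]


# ---------------------------------------------------------------------------
# PLV


def _instantaneous_phase(segment: np.ndarray) -> np.ndarray:
    if np.any(np.ptp(segment, axis=1) == 0):
        idx = np.where(np.ptp(segment, axis=1) == 0)[0]
        raise ChannelError(f"constant channel(s) {idx.tolist()}: phase undefined")
    return np.angle(hilbert(segment, axis=1))


def phase_locking(phases: np.ndarray) -> np.ndarray:
    """PLV matrix from an instantaneous-phase matrix (channels × samples).

    ``PLV(i,j) = |mean_t exp(i (phi_i(t) - phi_j(t)))|``, computed as a Gram
    product of the unit phasors.
    """
    z = np.exp(1j * np.asarray(phases, dtype=float))
    return np.abs(z @ z.conj().T / phases.shape[1])


def plv_adjacency(segments: Sequence[np.ndarray], band: BandSpec,
                  node_ids: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Phase-locking value adjacency, averaged across segments.

    Per segment, ``PLV(i,j) = |mean_t exp(i (phi_i(t) - phi_j(t)))|`` with
    phases from the analytic signal of the (already band-filtered) data.
    """
    if len(segments) == 0:
        raise ConfigError("need at least one segment")
    n_ch = segments[0].shape[0]
    acc = np.zeros((n_ch, n_ch))
    for seg in segments:
        acc += phase_locking(_instantaneous_phase(seg))
    plv = acc / len(segments)
    np.fill_diagonal(plv, 1.0)
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    ids = list(node_ids) if node_ids is not None else [f"ch{i}" for i in range(n_ch)]
    return ConnectivityMatrix(plv, f"PLV:{band.name}", ids)


# ---------------------------------------------------------------------------
# wSMI


def ordinal_symbols(x: np.ndarray, params: WsmiParams) -> np.ndarray:
    """Map a 1-D signal to its sequence of ordinal-pattern indices.

    Each pattern takes ``k`` samples spaced ``tau`` apart; the symbol is the
    lexicographic rank of the argsort permutation. Ties are broken by
    temporal order (the earlier sample ranks lower), which is what a stable
    argsort gives.
    """
    x = np.asarray(x, dtype=float)
    k, tau = params.k, params.tau
    n_pat = x.shape[-1] - (k - 1) * tau
    if n_pat < 1:
        raise ConfigError(f"segment too short for k={k}, tau={tau}")
    windows = np.stack([x[..., i * tau:i * tau + n_pat] for i in range(k)], axis=-1)
    perm = np.argsort(windows, axis=-1, kind="stable")
    # lexicographic rank of the permutation (Lehmer code)
    sym = np.zeros(perm.shape[:-1], dtype=np.int64)
    for i in range(k):
        smaller = np.zeros(perm.shape[:-1], dtype=np.int64)
        for j in range(i + 1, k):
            smaller += perm[..., j] < perm[..., i]
        sym = sym * (k - i) + smaller
    return sym


def _opposite_symbol_table(k: int) -> np.ndarray:
    """Map each pattern index to the index of its sign-flipped pattern."""
    perms = list(itertools.permutations(range(k)))
    rank = {p: i for i, p in enumerate(perms)}
    table = np.zeros(len(perms), dtype=np.int64)
    for p, i in rank.items():
        # negating the signal reverses the sample ordering: the argsort
        # sequence of -x is the argsort sequence of x read backwards
        table[i] = rank[p[::-1]]
    return table


def _argsort_rank(values: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(np.argsort(np.asarray(values), kind="stable"))


def _symbol_weights(k: int) -> np.ndarray:
    """w(x,y): 0 for identical and sign-opposite pattern pairs, else 1."""
    nk = math.factorial(k)
    w = np.ones((nk, nk))
    np.fill_diagonal(w, 0.0)
    opp = _opposite_symbol_table(k)
    w[np.arange(nk), opp] = 0.0
    return w



def _wsmi_from_joint(joint: np.ndarray, w: np.ndarray, nk: int) -> float:
    joint = joint / joint.sum()
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log(np.where(joint > 0, joint / np.outer(px, py), 1.0))
    return float(np.sum(w * joint * logratio) / np.log(nk))


def wsmi_pair(sx: np.ndarray, sy: np.ndarray, k: int) -> float:
    """wSMI between two symbol sequences (natural log, normalized by log k!)."""
    nk = math.factorial(k)
    joint = np.bincount(sx * nk + sy, minlength=nk * nk).reshape(nk, nk).astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    return _wsmi_from_joint(joint, _symbol_weights(k), nk)


def wsmi_adjacency(segments: Sequence[np.ndarray], params: WsmiParams,
                   node_ids: Sequence[str] | None = None,
                   pool_segments: bool = False,
                   tau_label: str | None = None) -> ConnectivityMatrix:
    """wSMI adjacency over all channel pairs, averaged across segments.

    By default pattern probabilities are pooled within each segment, the
    metric is evaluated per segment, and values are averaged across
    segments. ``pool_segments=True`` instead pools pattern counts across the
    whole recording before a single evaluation.
    """
    if len(segments) == 0:
        raise ConfigError("need at least one segment")
    k = params.k
    n_ch = segments[0].shape[0]
    n_pat = segments[0].shape[1] - (k - 1) * params.tau
    if n_pat < 1:
        raise ConfigError(f"segment too short for k={k}, tau={params.tau}")
    if n_pat < 10 * math.factorial(k):
        import warnings
        warnings.warn(f"only {n_pat} pattern observations per segment for k={k} "
                      f"({10 * math.factorial(k)} recommended)", stacklevel=2)

    symbols = [ordinal_symbols(seg, params) for seg in segments]
    nk = math.factorial(k)
    w = _symbol_weights(k)
    out = np.zeros((n_ch, n_ch))

    def _eval(joint: np.ndarray) -> float:
        return _wsmi_from_joint(joint, w, nk)

    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            if pool_segments:
                joint = np.zeros((nk, nk))
                for sym in symbols:
                    joint += np.bincount(sym[i] * nk + sym[j],
                                         minlength=nk * nk).reshape(nk, nk)
                val = _eval(joint)
            else:
                vals = []
                for sym in symbols:
                    joint = np.bincount(sym[i] * nk + sym[j],
                                        minlength=nk * nk).reshape(nk, nk).astype(float)
                    vals.append(_eval(joint))
                val = float(np.mean(vals))
            out[i, j] = out[j, i] = val
    ids = list(node_ids) if node_ids is not None else [f"ch{i}" for i in range(n_ch)]
    label = tau_label if tau_label is not None else f"tau{params.tau}"
    return ConnectivityMatrix(out, f"wSMI:{label}", ids)


# ---------------------------------------------------------------------------
# ROI aggregation


def roi_aggregate(matrix: ConnectivityMatrix, roi_map: Mapping[str, str]) -> pd.Series:
    """Average inter-electrode connections within and between ROIs.

    For each ROI, the within feature is the mean over its unordered channel
    pairs (diagonal excluded); for each ROI pair, the between feature is the
    mean over all cross pairs. With 16 ROIs that is 16 + 120 = 136 features
    per metric, named ``<metric>:<ROIa>-<ROIb>``.
    """
    unmapped = [n for n in matrix.node_ids if n not in roi_map]
    if unmapped:
        raise ConfigError(f"nodes without ROI assignment: {unmapped[:5]}")
    rois: dict[str, list[int]] = {}
    for idx, node in enumerate(matrix.node_ids):
        rois.setdefault(roi_map[node], []).append(idx)
    roi_names = sorted(rois)
    vals = matrix.values
    feats = {}
    for a_i, a in enumerate(roi_names):
        ia = rois[a]
        if len(ia) < 2:
            raise ConfigError(f"ROI {a!r} has fewer than 2 channels; "
                              "within-ROI feature undefined")
        block = vals[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        feats[f"{matrix.metric}:{a}-{a}"] = float(block[iu].mean())
        for b in roi_names[a_i + 1:]:
            ib = rois[b]
            feats[f"{matrix.metric}:{a}-{b}"] = float(vals[np.ix_(ia, ib)].mean())
    return pd.Series(feats)


def eeg_feature_vector(recording: EegRecording,
                       bands: Sequence[BandSpec] | None = None,
                       tau_ms: Sequence[float] = DEFAULT_TAU_MS,
                       k: int = 3,
                       wsmi_band: BandSpec | None = None) -> pd.Series:
    """Full per-subject EEG feature vector: PLV per band + wSMI per τ.

    PLV is computed on each band-filtered version of the recording; wSMI on
    the broadband (0.5–45 Hz default offline filter) signal per τ. With 5
    bands and 4 τ values this yields 5·136 + 4·136 = 680 + 544 features.
    """
    bands = list(bands) if bands is not None else default_bands()
    parts = []
    for band in bands:
        segs = epoch_and_filter(recording, band)
        adj = plv_adjacency(segs, band, node_ids=recording.channel_labels)
        parts.append(roi_aggregate(adj, recording.roi_map))
    broadband = wsmi_band if wsmi_band is not None else BandSpec("broadband", 0.5, 45.0)
    segs = epoch_and_filter(recording, broadband if recording.rate > 90 else None)
    for ms in tau_ms:
        params = WsmiParams.from_ms(ms, recording.rate, k=k)
        adj = wsmi_adjacency(segs, params, node_ids=recording.channel_labels,
                             tau_label=f"{ms:g}ms")
        parts.append(roi_aggregate(adj, recording.roi_map))
    return pd.concat(parts)
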