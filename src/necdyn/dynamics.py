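"""Data-facing validation metrics: FC, dynamic FC, phase synchrony.

These are the zero-lag and sliding-window summaries used to judge whether a
fitted generative model reproduces the empirical recording: static functional
connectivity (Pearson correlation matrix), dynamic FC (window-by-window
correlation of sliding-window FC patterns, compared through a two-sample
Kolmogorov-Smirnov statistic), and Kuramoto phase statistics (synchronization
= temporal mean of the order parameter R(t), metastability = its temporal
standard deviation).

All zero-lag quantities are invariant under time reversal by construction,
which is precisely why they cannot detect irreversibility and why the
differential cross-covariance analysis is needed alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .exceptions import DataError
from .synthetic import BoldRecording

__all__ = [
    "FcSummary",
    "KuramotoSummary",
    "bandpass",
    "static_fc",
    "sfc_similarity",
    "dynamic_fc",
    "dfc_ks_distance",
    "instantaneous_phase",
    "kuramoto_order",
]


@dataclass
class FcSummary:
    """Static FC plus the window x window dynamic-FC (FCD) matrix."""

    sfc: np.ndarray
    fcd: np.ndarray
    window_s: float
    step_s: float


@dataclass
class KuramotoSummary:
    """Order-parameter time series and its two summary indices."""

    R_t: np.ndarray
    synchronization: float
    metastability: float


def bandpass(
    recording: BoldRecording, low_hz: float = 0.01, high_hz: float = 0.1
) -> BoldRecording:
    """Zero-phase 2nd-order Butterworth band-pass; the mean is removed first."""
    nyq = 0.5 / recording.TR
    if not 0 < low_hz < high_hz < nyq:
        raise DataError(
            f"band ({low_hz}, {high_hz}) Hz infeasible at TR = {recording.TR} s "
            f"(Nyquist {nyq:.4g} Hz)"
        )
    x = recording.data - recording.data.mean(axis=0)
    sos = signal.butter(2, [low_hz, high_hz], btype="band", fs=1.0 / recording.TR,
                        output="sos")
    y = signal.sosfiltfilt(sos, x, axis=0)
    return BoldRecording(data=y, TR=recording.TR, labels=list(recording.labels))


def static_fc(recording: BoldRecording | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the recording."""
    data = recording.data if isinstance(recording, BoldRecording) else np.asarray(recording)
    if data.shape[0] < 3:
        raise DataError("need at least 3 time points for a correlation matrix")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        labels = (
            recording.labels
            if isinstance(recording, BoldRecording)
            else [str(i) for i in range(data.shape[1])]
        )
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"constant signal, correlation undefined for region(s): {bad}")
    return np.corrcoef(data, rowvar=False)


def sfc_similarity(empirical_sfc: np.ndarray, simulated_sfc: np.ndarray) -> float:
    """Pearson correlation between the strict upper triangles of two sFC matrices."""
    a = np.asarray(empirical_sfc)
    b = np.asarray(simulated_sfc)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DataError(f"sFC shapes do not match: {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


def dynamic_fc(
    recording: BoldRecording, window_s: float = 50.0, step_s: float = 25.0
) -> FcSummary:
    """Sliding-window FC and the FCD matrix of window-pattern correlations.

    Windows are placed at integer sample offsets (length = round(window_s/TR)
    samples, step = round(step_s/TR)); fcd[w1, w2] is the Pearson correlation
    of the two windows' strict-upper-triangle FC vectors.
    """
    wlen = int(round(window_s / recording.TR))
    step = int(round(step_s / recording.TR))
    if wlen < 3:
        raise DataError(f"window of {wlen} samples is too short (< 3)")
    if step < 1:
        raise DataError("step shorter than one sample")
    T = recording.n_time
    n_win = (T - wlen) // step + 1
    if n_win < 2:
        raise DataError("recording too short for two sliding windows")
    iu = np.triu_indices(recording.n_nodes, k=1)
    vecs = np.empty((n_win, iu[0].size))
    for w in range(n_win):
        seg = recording.data[w * step : w * step + wlen]
        vecs[w] = np.corrcoef(seg, rowvar=False)[iu]
    fcd = np.corrcoef(vecs)
    fcd = (fcd + fcd.T) / 2.0
    np.fill_diagonal(fcd, 1.0)
    return FcSummary(
        sfc=static_fc(recording), fcd=fcd, window_s=window_s, step_s=step_s
    )


def dfc_ks_distance(fcd_a: np.ndarray, fcd_b: np.ndarray) -> float:
    """Two-sample KS statistic between the strict-upper-triangle FCD values."""
    a = np.asarray(fcd_a)
    b = np.asarray(fcd_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("each FCD must contain at least 2 windows")
    va = a[np.triu_indices(a.shape[0], k=1)]
    vb = b[np.triu_indices(b.shape[0], k=1)]
    return float(stats.ks_2samp(va, vb, method="asymp").statistic)


def instantaneous_phase(
    recording: BoldRecording, trim_edges: bool = True
) -> np.ndarray:
    """Analytic-signal phase per node (radians), time x node.

    The signal should be band-passed and zero-mean.  About 5 s of samples are
    trimmed at each end to discard Hilbert edge artifacts (disable with
    ``trim_edges=False``).
    """
    x = recording.data - recording.data.mean(axis=0)
    if np.any(x.std(axis=0) == 0):
        raise DataError("constant signal has no defined phase")
    phases = np.angle(signal.hilbert(x, axis=0))
    if trim_edges:
        trim = int(np.ceil(5.0 / recording.TR))
        if 2 * trim >= phases.shape[0]:
            raise DataError("recording too short to trim Hilbert edges")
        phases = phases[trim:-trim]
    return phases


def kuramoto_order(phases: np.ndarray) -> KuramotoSummary:
    """Kuramoto order parameter R(t) = |sum_k exp(i phi_k(t))| / n per time point."""
    phases = np.asarray(phases)
    if phases.ndim != 2 or phases.shape[1] < 2:
        raise DataError("phases must be time x node with at least 2 nodes")
    R_t = np.abs(np.exp(1j * phases).mean(axis=1))
    return KuramotoSummary(
        R_t=R_t,
        synchronization=float(R_t.mean()),
        metastability=float(R_t.std()),
    )
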