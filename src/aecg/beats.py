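"""Beat detection, cross-correlation signal averaging, and fiducial location.

A 10-s recording holds ~6-17 beats; the scalar parameters downstream are
computed on a single averaged PQRST template built from all adequately
cross-correlated complexes. Detection runs on the spatial magnitude of the
band-passed Kors-derived VCG; averaging aligns beats at the lag of maximal
cross-correlation against a running template and rejects beats whose QRS
correlation falls below a threshold (default 0.97, conventional
signal-averaged-ECG practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import AveragingError, DetectionError, FiducialError
from .io import EcgRecord, LEADS_8, LEADS_12
from .vcg import DEFAULT_KORS


@dataclass
class BeatSet:
    """Detected R peaks with per-beat acceptance bookkeeping."""

    r_indices: np.ndarray
    accepted: np.ndarray = field(default=None)
    correlation: np.ndarray = field(default=None)

    def __post_init__(self):
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if np.any(np.diff(self.r_indices) <= 0):
            raise DetectionError("r_indices must be strictly increasing")
        if self.accepted is None:
            self.accepted = np.ones(len(self.r_indices), dtype=bool)
        if self.correlation is None:
            self.correlation = np.full(len(self.r_indices), np.nan)

    @property
    def n_beats(self) -> int:
        return len(self.r_indices)


@dataclass
class AveragedBeat:
    """Signal-averaged PQRST template, [window_samples x 12] mV."""

    template: np.ndarray
    sampling_rate: float
    n_beats_averaged: int
    r_index: int | None = None  # R position within the template, if known

    def __post_init__(self):
        self.template = np.asarray(self.template, dtype=float)
        if self.template.ndim != 2 or self.template.shape[1] != 12:
            raise AveragingError(f"template must be [n, 12], got {self.template.shape}")
        if self.n_beats_averaged < 1:
            raise AveragingError("n_beats_averaged must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.template.shape[0]

    def independent_leads(self) -> np.ndarray:
        idx = [LEADS_12.index(l) for l in LEADS_8]
        return self.template[:, idx]


@dataclass
class Fiducials:
    """Wave landmarks as 0-based sample indices within the template.

    All windows downstream are half-open ``[onset, offset)``.
    """

    p_onset: int
    p_offset: int
    qrs_onset: int
    qrs_offset: int
    t_offset: int

    def __post_init__(self):
        ok = (self.p_onset < self.p_offset <= self.qrs_onset
              < self.qrs_offset < self.t_offset)
        if not ok:
            raise FiducialError(
                "ordering", f"fiducials out of order: {self.__dict__}")

    def shifted(self, k: int) -> "Fiducials":
        return Fiducials(self.p_onset + k, self.p_offset + k, self.qrs_onset + k,
                         self.qrs_offset + k, self.t_offset + k)


def _spatial_detection_function(ecg: EcgRecord, kors: np.ndarray) -> np.ndarray:
    """Band-passed spatial VCG magnitude, the QRS detection function."""
    xyz = ecg.independent_leads() @ kors.T
    nyq = ecg.sampling_rate / 2.0
    lo, hi = 5.0 / nyq, min(25.0 / nyq, 0.99)
    b, a = sps.butter(2, [lo, hi], btype="band")
    filtered = sps.filtfilt(b, a, xyz, axis=0)
    return np.linalg.norm(filtered, axis=1)


def detect_beats(ecg: EcgRecord, kors_matrix: np.ndarray | None = None,
                 refractory_ms: float = 250.0,
                 height_fraction: float = 0.5) -> BeatSet:
    """Locate one index per QRS complex.

    Peaks of the spatial detection function above ``height_fraction`` of its
    maximum, separated by at least ``refractory_ms``.
    """
    if ecg.duration < 2.0:
        raise DetectionError(f"record too short ({ecg.duration:.2f} s < 2 s)")
    kors = DEFAULT_KORS if kors_matrix is None else np.asarray(kors_matrix)
    env = _spatial_detection_function(ecg, kors)
    peak = float(env.max())
    if peak <= 0.0 or np.ptp(ecg.samples) == 0.0:
        raise DetectionError("flat signal: no beats found")
    distance = max(1, int(round(refractory_ms / 1000.0 * ecg.sampling_rate)))
    idx, _ = sps.find_peaks(env, height=height_fraction * peak, distance=distance)
    if len(idx) == 0:
        raise DetectionError("no beats found")
    return BeatSet(idx)


def _beat_windows(ecg: EcgRecord, beats: BeatSet, pre: int, post: int):
    """Indices of beats whose [r-pre, r+post) window fits in the record."""
    fits = [(i, r) for i, r in enumerate(beats.r_indices)
            if r - pre >= 0 and r + post <= ecg.n_samples]
    return fits


def average_beats(ecg: EcgRecord, beats: BeatSet, corr_threshold: float = 0.97,
                  pre_ms: float = 300.0, post_ms: float = 450.0,
                  max_shift_ms: float = 50.0, qrs_half_ms: float = 100.0,
                  baseline_ms: float = 40.0) -> AveragedBeat:
    """Cross-correlation signal averaging of the detected beats.

    Each beat window is aligned to a running template (initially the
    element-wise median across beats, robust to a single corrupted complex)
    at the lag maximising the QRS-window cross-correlation; beats whose
    aligned QRS Pearson correlation is below ``corr_threshold`` are rejected.
    The template is the mean of the accepted aligned beats, baseline
    corrected by the mean of its first ``baseline_ms``. Mutates
    ``beats.accepted`` and ``beats.correlation`` in place.
    """
    fs = ecg.sampling_rate
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    shift = int(round(max_shift_ms / 1000.0 * fs))
    qrs_half = int(round(qrs_half_ms / 1000.0 * fs))
    fits = _beat_windows(ecg, beats, pre + shift, post + shift)
    if not fits:
        raise AveragingError("no beat window fits inside the record")
    windows = np.stack([ecg.samples[r - pre:r + post] for _, r in fits])
    template = np.median(windows, axis=0)
    beats.accepted[:] = False
    beats.correlation[:] = np.nan

    q0, q1 = pre - qrs_half, pre + qrs_half
    for _ in range(2):  # one refinement pass after the median seed
        ref_qrs = template[q0:q1].ravel()
        aligned = []
        kept = []
        for (i, r) in fits:
            best_lag, best_score = 0, -np.inf
            for lag in range(-shift, shift + 1):
                seg = ecg.samples[r - pre + lag:r + post + lag]
                score = float(np.dot(seg[q0:q1].ravel(), ref_qrs))
                if score > best_score:
                    best_score, best_lag = score, lag
            seg = ecg.samples[r - pre + best_lag:r + post + best_lag]
            a = seg[q0:q1].ravel()
            b = ref_qrs
            denom = np.std(a) * np.std(b)
            corr = 0.0 if denom == 0 else float(
                np.mean((a - a.mean()) * (b - b.mean())) / denom)
            beats.correlation[i] = corr
            if corr >= corr_threshold:
                aligned.append(seg)
                kept.append(i)
        if not aligned:
            raise AveragingError(
                f"all beats rejected at correlation threshold {corr_threshold}")
        template = np.mean(aligned, axis=0)
        beats.accepted[:] = False
        beats.accepted[kept] = True

    base = int(round(baseline_ms / 1000.0 * fs))
    template = template - template[:max(base, 1)].mean(axis=0, keepdims=True)
    return AveragedBeat(template, fs, int(beats.accepted.sum()), r_index=pre)


# ---------------------------------------------------------------------------
# fiducial location
# ---------------------------------------------------------------------------

def _quiet_edge(below: np.ndarray, start: int, stop: int, step: int, run: int):
    """First index (scanning from start by step) opening a run of `run` quiet samples."""
    count = 0
    i = start
    while 0 <= i and i != stop:
        count = count + 1 if below[i] else 0
        if count >= run:
            return i - step * (run - 1)
        i += step
    return None


def locate_fiducials(beat: AveragedBeat, kors_matrix: np.ndarray | None = None,
                     velocity_fraction: float = 0.2, hysteresis_ms: float = 10.0,
                     qrs_search_ms: float = 120.0, t_gap_ms: float = 40.0,
                     t_min_fraction: float = 0.05,
                     p_min_fraction: float = 0.02) -> Fiducials:
    """Locate P bounds, QRS on/offset and T offset on an averaged template.

    QRS bounds come from threshold crossings of the spatial velocity
    |d(X,Y,Z)/dt| of the Kors-derived template (threshold =
    ``velocity_fraction`` of the peak QRS velocity, sustained for
    ``hysteresis_ms``); the T offset uses the tangent method on the spatial
    T-wave magnitude; P bounds by local-maximum search before the QRS.
    """
    kors = DEFAULT_KORS if kors_matrix is None else np.asarray(kors_matrix)
    fs = beat.sampling_rate
    xyz = beat.independent_leads() @ kors.T
    # landmark detection runs on a 40 Hz low-passed copy so residual template
    # noise does not dominate the spatial-velocity signal
    if fs > 100.0:
        b, a = sps.butter(4, 40.0 / (fs / 2.0), btype="low")
        xyz = sps.filtfilt(b, a, xyz, axis=0)
    mag = np.linalg.norm(xyz, axis=1)
    if np.ptp(mag) == 0.0:
        raise FiducialError("qrs_onset", "flat template")
    n = beat.n_samples
    vel = np.linalg.norm(np.diff(xyz, axis=0), axis=1) * fs
    smooth = max(1, int(round(0.005 * fs)))
    vel = np.convolve(vel, np.ones(smooth) / smooth, mode="same")
    vel = np.concatenate([vel, vel[-1:]])  # same length as template

    r = int(np.argmax(mag))
    search = int(round(qrs_search_ms / 1000.0 * fs))
    lo, hi = max(0, r - search), min(n, r + search)
    vpeak = float(vel[lo:hi].max())
    if vpeak <= 0.0:
        raise FiducialError("qrs_onset", "no QRS velocity peak")
    below = vel < velocity_fraction * vpeak
    run = max(1, int(round(hysteresis_ms / 1000.0 * fs)))

    edge = _quiet_edge(below, r, -1, -1, run)
    qrs_onset = (edge + 1) if edge is not None else max(0, r - search)
    edge = _quiet_edge(below, r, n, +1, run)
    qrs_offset = edge if edge is not None else min(n - 1, r + search)
    if qrs_offset <= qrs_onset:
        raise FiducialError("qrs_offset", "degenerate QRS window")

    # --- T offset: tangent method on the spatial T magnitude
    t_start = qrs_offset + int(round(t_gap_ms / 1000.0 * fs))
    if t_start >= n - 2:
        raise FiducialError("t_offset", "no samples after the QRS")
    t_peak = t_start + int(np.argmax(mag[t_start:]))
    if mag[t_peak] < t_min_fraction * mag[r]:
        raise FiducialError("t_offset", "T wave absent (flat after QRS)")
    tail = mag[t_peak:]
    slope = np.gradient(tail) * fs  # mV/s
    steep_rel = int(np.argmin(slope))
    steep = t_peak + steep_rel
    if slope[steep_rel] >= 0.0:
        raise FiducialError("t_offset", "no descending T limb")
    dt = mag[steep] / (-slope[steep_rel])  # s to baseline along the tangent
    t_offset = min(n - 1, steep + int(round(dt * fs)))
    if t_offset <= qrs_offset:
        raise FiducialError("t_offset", "tangent intersection inside the QRS")

    # --- P wave: local maximum before QRS onset
    p_stop = qrs_onset - int(round(0.020 * fs))
    if p_stop <= 1:
        raise FiducialError("p_onset", "no room before the QRS for a P wave")
    p_peak = int(np.argmax(mag[:p_stop]))
    if mag[p_peak] < p_min_fraction * mag[r]:
        raise FiducialError("p_onset", "P wave absent")
    p_thr = 0.1 * mag[p_peak]
    i = p_peak
    while i > 0 and mag[i - 1] >= p_thr:
        i -= 1
    p_onset = i
    i = p_peak
    while i < p_stop - 1 and mag[i + 1] >= p_thr:
        i += 1
    p_offset = min(i + 1, qrs_onset)
    if p_offset <= p_onset:
        p_offset = p_onset + 1
    return Fiducials(p_onset, p_offset, qrs_onset, qrs_offset, t_offset)
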