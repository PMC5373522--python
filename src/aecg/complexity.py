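"""SVD-based QRS and T waveform complexity.

The [window_samples x 8] matrix of the 8 independent leads is decomposed by
singular value decomposition. The first three singular components span the
part of the signal a single fixed-origin moving dipole can explain
("dipolar" content); the residual five components quantify nondipolar
complexity. The PCA ratio 100*sigma2^2/sigma1^2 measures repolarisation
(or depolarisation) loop non-planarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .beats import AveragedBeat, Fiducials


@dataclass
class SvdFeatures:
    """Per-beat complexity summary; singular values descending, voltages in mV."""

    qrs_singular_values: np.ndarray
    t_singular_values: np.ndarray
    qrs_pca_ratio: float
    t_pca_ratio: float
    qrs_dipolar_voltage: float
    qrs_nondipolar_voltage: float
    t_dipolar_voltage: float
    t_nondipolar_voltage: float

    def as_dict(self) -> dict[str, float]:
        return {
            "qrs_pca_ratio": self.qrs_pca_ratio,
            "t_pca_ratio": self.t_pca_ratio,
            "qrs_dipolar_voltage": self.qrs_dipolar_voltage,
            "qrs_nondipolar_voltage": self.qrs_nondipolar_voltage,
            "t_dipolar_voltage": self.t_dipolar_voltage,
            "t_nondipolar_voltage": self.t_nondipolar_voltage,
        }


def svd_singular_values(matrix: np.ndarray) -> np.ndarray:
    """Descending singular values of a [n_samples x 8] lead matrix.

    Only the 8 linearly independent leads may enter: a 9th, linearly
    dependent column (e.g. lead III) would silently distort the spectrum,
    so any other width is rejected.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 8:
        raise DomainError(
            f"expected [n_samples, 8] independent-lead matrix, got {matrix.shape}")
    if matrix.shape[0] < 8:
        raise DomainError(f"window too short for SVD: {matrix.shape[0]} < 8 samples")
    if not np.any(matrix):
        raise DomainError("degenerate (all-zero) window")
    return np.linalg.svd(matrix, compute_uv=False)


def svd_decompose(beat: AveragedBeat, window: str,
                  fiducials: Fiducials) -> np.ndarray:
    """Singular values of the QRS or T window of an averaged beat."""
    if window == "qrs":
        lo, hi = fiducials.qrs_onset, fiducials.qrs_offset
    elif window == "t":
        lo, hi = fiducials.qrs_offset, fiducials.t_offset
    else:
        raise ValueError("window must be 'qrs' or 't'")
    return svd_singular_values(beat.independent_leads()[lo:hi])


def pca_ratio(sv: np.ndarray) -> float:
    """PCA ratio in percent: 100 * sigma2^2 / sigma1^2."""
    sv = np.asarray(sv, dtype=float)
    if sv[0] <= 0.0:
        raise DomainError("PCA ratio undefined for sigma1 = 0")
    return float(100.0 * sv[1] ** 2 / sv[0] ** 2)


def dipolar_voltages(sv: np.ndarray, n_samples: int,
                     normalize_by_n: bool = True) -> tuple[float, float]:
    """RMS-voltage equivalents of the dipolar (first 3) and nondipolar subspaces.

    dipolar = sqrt((s1^2+s2^2+s3^2)/n); nondipolar = sqrt((s4^2+..+s8^2)/n).
    With ``normalize_by_n=False`` the raw root-power sums are returned. By
    Parseval, dipolar^2 + nondipolar^2 equals the total mean-square signal
    power of the window (summed over the 8 leads, averaged over samples).
    """
    sv = np.asarray(sv, dtype=float)
    if len(sv) != 8:
        raise DomainError(f"expected 8 singular values, got {len(sv)}")
    if n_samples <= 0:
        raise DomainError("n_samples must be positive")
    denom = float(n_samples) if normalize_by_n else 1.0
    dipolar = float(np.sqrt((sv[:3] ** 2).sum() / denom))
    nondipolar = float(np.sqrt((sv[3:] ** 2).sum() / denom))
    return dipolar, nondipolar


def compute_svd_features(beat: AveragedBeat, fiducials: Fiducials,
                         normalize_by_n: bool = True) -> SvdFeatures:
    """QRS and T complexity parameters of one averaged beat."""
    qrs_sv = svd_decompose(beat, "qrs", fiducials)
    t_sv = svd_decompose(beat, "t", fiducials)
    n_qrs = fiducials.qrs_offset - fiducials.qrs_onset
    n_t = fiducials.t_offset - fiducials.qrs_offset
    qrs_dip, qrs_non = dipolar_voltages(qrs_sv, n_qrs, normalize_by_n)
    t_dip, t_non = dipolar_voltages(t_sv, n_t, normalize_by_n)
    return SvdFeatures(
        qrs_singular_values=qrs_sv,
        t_singular_values=t_sv,
        qrs_pca_ratio=pca_ratio(qrs_sv),
        t_pca_ratio=pca_ratio(t_sv),
        qrs_dipolar_voltage=qrs_dip,
        qrs_nondipolar_voltage=qrs_non,
        t_dipolar_voltage=t_dip,
        t_nondipolar_voltage=t_non,
    )
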