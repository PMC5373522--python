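"""Derived vectorcardiography and spatial A-ECG parameters.

The vectorcardiogram (VCG) is the trajectory of the cardiac dipole in 3-D,
reconstructed here from the 8 independent leads of the 12-lead ECG via the
Kors regression matrix. Axis convention: X positive leftward, Y positive
inferior, Z positive posterior (so anterior forces are negative Z, and the
posterior-to-leftward QRS loop ratio reads off the positive Z and X
excursions directly). A ``z_anterior_positive`` flag flips Z for data
digitised in the opposite convention.

All time integrals are trapezoidal, expressed in mV*ms; window bounds are
half-open ``[onset, offset)`` sample indices, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import ConfigError, DomainError
from .io import LEADS_8

if TYPE_CHECKING:  # pragma: no cover
    from .beats import AveragedBeat, Fiducials


def load_kors_matrix(path=None) -> np.ndarray:
    """Load a 3x8 VCG reconstruction matrix (rows X,Y,Z; columns I,II,V1-V6).

    With no ``path``, the packaged Kors regression coefficients are used.
    """
    if path is None:
        text = resources.files("aecg.data").joinpath("kors_matrix.txt").read_text()
    else:
        text = Path(path).read_text()
    rows = [[float(v) for v in line.split()]
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")]
    matrix = np.asarray(rows, dtype=float)
    if matrix.shape != (3, 8):
        raise ConfigError(f"VCG reconstruction matrix must be 3x8, got {matrix.shape}")
    return matrix


DEFAULT_KORS = load_kors_matrix()


def kors_right_inverse(kors: np.ndarray | None = None) -> np.ndarray:
    """Minimum-norm 8x3 right inverse R of the Kors matrix (K @ R = I3).

    Projecting a known VCG through R yields 8 leads whose Kors-derived VCG
    reproduces the original exactly; the synthetic ECG generator relies on this.
    """
    kors = DEFAULT_KORS if kors is None else np.asarray(kors, dtype=float)
    if kors.shape != (3, 8):
        raise ConfigError(f"expected 3x8 matrix, got {kors.shape}")
    return kors.T @ np.linalg.inv(kors @ kors.T)


@dataclass
class Vcg:
    """Derived X,Y,Z leads (mV) with the fiducials of the source template."""

    xyz: np.ndarray
    sampling_rate: float
    fiducials: "Fiducials"
    z_anterior_positive: bool = False

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ConfigError(f"xyz must be [n, 3], got {self.xyz.shape}")

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]


@dataclass
class VcgFeatures:
    """Scalar spatial A-ECG parameters of one averaged beat.

    Angles in degrees; integrals in mV*ms; voltages in mV.
    """

    spatial_mean_qrst_angle: float
    spatial_peaks_qrst_angle: float
    svg_magnitude: float
    svg_azimuth: float
    svg_elevation: float
    mean_qrs_azimuth: float
    mean_qrs_elevation: float
    mean_t_azimuth: float
    mean_t_elevation: float
    sai_qrst: float
    qrs_pl_ratio: float
    z_qrs_integral: float
    total_qrs_voltage: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def derive_vcg(beat: "AveragedBeat", kors_matrix: np.ndarray | None = None,
               fiducials: "Fiducials | None" = None,
               z_anterior_positive: bool = False) -> Vcg:
    """Apply the Kors transform to an averaged 12-lead template.

    ``xyz[t] = K @ (I, II, V1..V6)[t]`` for every sample.
    """
    kors = DEFAULT_KORS if kors_matrix is None else np.asarray(kors_matrix, dtype=float)
    if kors.shape != (3, 8):
        raise ConfigError(f"Kors matrix must be 3x8, got {kors.shape}")
    eight = beat.independent_leads()
    xyz = eight @ kors.T
    if z_anterior_positive:
        xyz = xyz.copy()
        xyz[:, 2] *= -1.0
    fid = fiducials if fiducials is not None else getattr(beat, "fiducials", None)
    if fid is None:
        from .beats import locate_fiducials
        fid = locate_fiducials(beat, kors_matrix=kors)
    return Vcg(xyz, beat.sampling_rate, fid, z_anterior_positive)


# ---------------------------------------------------------------------------
# vector helpers
# ---------------------------------------------------------------------------

def azimuth_elevation(vec: np.ndarray) -> tuple[float, float]:
    """Orientation of a 3-vector in the Frank axes.

    Azimuth is measured in the horizontal (X-Z) plane, 0 deg = leftward,
    +90 deg = posterior, range (-180, 180]. Elevation is the angle out of the
    horizontal plane, positive inferior (+Y), range [-90, 90].
    """
    x, y, z = (float(v) for v in vec)
    if x == 0.0 and y == 0.0 and z == 0.0:
        raise DomainError("orientation of the zero vector is undefined")
    azimuth = float(np.degrees(np.arctan2(z, x)))
    elevation = float(np.degrees(np.arctan2(y, np.hypot(x, z))))
    return azimuth, elevation


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """3-D angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DomainError("angle with a zero-magnitude vector is undefined")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def _window_ms(vcg: Vcg, onset: int, offset: int) -> np.ndarray:
    """Time axis in ms for the half-open sample window [onset, offset)."""
    if not 0 <= onset < offset <= vcg.n_samples:
        raise DomainError(f"invalid window [{onset}, {offset}) for {vcg.n_samples} samples")
    return np.arange(onset, offset) * 1000.0 / vcg.sampling_rate


def _integral(vcg: Vcg, onset: int, offset: int) -> np.ndarray:
    """Trapezoidal time integral of xyz over [onset, offset), mV*ms (3-vector)."""
    t = _window_ms(vcg, onset, offset)
    return np.trapezoid(vcg.xyz[onset:offset], t, axis=0)


def mean_vector(vcg: Vcg, onset: int, offset: int) -> np.ndarray:
    """Time-averaged dipole vector over a window (mV)."""
    t = _window_ms(vcg, onset, offset)
    span = t[-1] - t[0]
    if span <= 0:
        raise DomainError("window too short for a mean vector")
    return _integral(vcg, onset, offset) / span


@dataclass
class QrstAngles:
    mean_angle: float
    peaks_angle: float
    mean_qrs_vector: np.ndarray
    mean_t_vector: np.ndarray
    mean_qrs_azimuth: float
    mean_qrs_elevation: float
    mean_t_azimuth: float
    mean_t_elevation: float


def spatial_qrst_angles(vcg: Vcg) -> QrstAngles:
    """Spatial mean and peaks QRS-T angles plus orientation angles.

    The mean QRS (T) vector is the time-average of the VCG over the QRS
    (J point to T offset) window; the peaks variant uses the sample of
    maximal spatial magnitude within each window.
    """
    fid = vcg.fiducials
    q = mean_vector(vcg, fid.qrs_onset, fid.qrs_offset)
    t = mean_vector(vcg, fid.qrs_offset, fid.t_offset)
    mean_angle = angle_between(q, t)
    mag = np.linalg.norm(vcg.xyz, axis=1)
    q_peak = fid.qrs_onset + int(np.argmax(mag[fid.qrs_onset:fid.qrs_offset]))
    t_peak = fid.qrs_offset + int(np.argmax(mag[fid.qrs_offset:fid.t_offset]))
    peaks_angle = angle_between(vcg.xyz[q_peak], vcg.xyz[t_peak])
    q_az, q_el = azimuth_elevation(q)
    t_az, t_el = azimuth_elevation(t)
    return QrstAngles(mean_angle, peaks_angle, q, t, q_az, q_el, t_az, t_el)


def ventricular_gradient(vcg: Vcg) -> tuple[float, float, float]:
    """Spatial ventricular gradient: (magnitude mV*ms, azimuth deg, elevation deg).

    The SVG is the time integral of the VCG over the whole QRST window
    [qrs_onset, t_offset); its magnitude indexes global repolarisation
    heterogeneity.
    """
    fid = vcg.fiducials
    svg = _integral(vcg, fid.qrs_onset, fid.t_offset)
    magnitude = float(np.linalg.norm(svg))
    if magnitude == 0.0:
        raise DomainError("zero-magnitude ventricular gradient has no orientation")
    azimuth, elevation = azimuth_elevation(svg)
    return magnitude, azimuth, elevation


def sai_qrst(vcg: Vcg) -> float:
    """Sum absolute QRST integral: integral of |X|+|Y|+|Z| over [qrs_onset, t_offset), mV*ms."""
    fid = vcg.fiducials
    t = _window_ms(vcg, fid.qrs_onset, fid.t_offset)
    absolute = np.abs(vcg.xyz[fid.qrs_onset:fid.t_offset])
    return float(np.trapezoid(absolute, t, axis=0).sum())


def qrs_loop_pl_ratio(vcg: Vcg) -> float:
    """Posterior-to-leftward QRS loop ratio in the horizontal (X-Z) plane.

    Ratio of the maximal posterior excursion (largest positive Z within the
    QRS) to the maximal leftward excursion (largest positive X). A loop with
    no posterior component yields 0; no leftward excursion is undefined.
    """
    fid = vcg.fiducials
    window = vcg.xyz[fid.qrs_onset:fid.qrs_offset]
    leftward = float(window[:, 0].max())
    posterior = float(max(window[:, 2].max(), 0.0))
    if leftward <= 0.0:
        raise DomainError("no leftward QRS excursion; P/L ratio undefined")
    return posterior / leftward


def qrs_integrals_and_voltages(beat: "AveragedBeat", vcg: Vcg) -> tuple[float, float]:
    """(Frank Z-lead QRS integral mV*ms (signed), total 12-lead QRS voltage mV).

    The total QRS voltage sums the peak-to-trough QRS amplitude of each of
    the 12 standard leads.
    """
    fid = vcg.fiducials
    t = _window_ms(vcg, fid.qrs_onset, fid.qrs_offset)
    z_integral = float(np.trapezoid(vcg.xyz[fid.qrs_onset:fid.qrs_offset, 2], t))
    window = beat.template[fid.qrs_onset:fid.qrs_offset]
    total_voltage = float((window.max(axis=0) - window.min(axis=0)).sum())
    return z_integral, total_voltage


def compute_vcg_features(beat: "AveragedBeat", kors_matrix: np.ndarray | None = None,
                         fiducials: "Fiducials | None" = None) -> VcgFeatures:
    """All spatial parameters of one averaged beat in a single call."""
    vcg = derive_vcg(beat, kors_matrix, fiducials)
    angles = spatial_qrst_angles(vcg)
    svg_mag, svg_az, svg_el = ventricular_gradient(vcg)
    z_integral, total_voltage = qrs_integrals_and_voltages(beat, vcg)
    return VcgFeatures(
        spatial_mean_qrst_angle=angles.mean_angle,
        spatial_peaks_qrst_angle=angles.peaks_angle,
        svg_magnitude=svg_mag,
        svg_azimuth=svg_az,
        svg_elevation=svg_el,
        mean_qrs_azimuth=angles.mean_qrs_azimuth,
        mean_qrs_elevation=angles.mean_qrs_elevation,
        mean_t_azimuth=angles.mean_t_azimuth,
        mean_t_elevation=angles.mean_t_elevation,
        sai_qrst=sai_qrst(vcg),
        qrs_pl_ratio=qrs_loop_pl_ratio(vcg),
        z_qrs_integral=z_integral,
        total_qrs_voltage=total_voltage,
    )


# keep the 8-lead order visible to complexity/simulation modules
INDEPENDENT_LEADS = LEADS_8
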