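"""Synthetic ECGs with analytic ground truth and synthetic cohorts.

The ECG generator builds a dipole-model vectorcardiogram directly: the QRS
and T waves are loops with raised-cosine envelopes of compact support
around configurable spatial mean vectors, plus a zero-time-integral
quadrature component (scaled by the loop eccentricity) that widens each
loop in the plane spanned by the mean vector and the loop normal. The loop
normal is chosen perpendicular to both mean vectors, so truncating an
integration window perturbs only vector magnitudes, never the QRS-T angle.
The 8 independent leads are produced by projecting the VCG through the
minimum-norm right inverse of the Kors matrix, which makes the Kors-derived
VCG reproduce the ground-truth VCG exactly on noiseless data; limb leads
are completed by the Einthoven/Goldberger identities.

The cohort generator emulates a two-group observational table (246
non-event vs 49 event patients by default) with the spatial QRS-T angle
distributed Normal(112, 38) / Normal(134, 33) per group, correlated
covariates, and survival columns; a "prospective" design instead draws
exponential event times whose hazard jumps by a configurable true hazard
ratio above the angle cutoff, for estimator-recovery studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import CohortTable, EcgRecord, complete_limb_leads, write_ecg_csv
from .vcg import DEFAULT_KORS, angle_between, kors_right_inverse


# ---------------------------------------------------------------------------
# ECG simulation
# ---------------------------------------------------------------------------

@dataclass
class EcgSimConfig:
    """Dipole-model ECG simulator settings.

    ``qrs_mean_vector`` / ``t_mean_vector`` are 3-vectors in mV whose angle
    is the ground-truth spatial mean QRS-T angle. Durations in ms; noise is
    white Gaussian per lead in mV; beat timing jitter in ms.
    """

    sampling_rate: float = 500.0
    n_beats: int = 10
    heart_rate: float = 60.0
    qrs_mean_vector: tuple[float, float, float] = (1.1, 0.9, 0.5)
    t_mean_vector: tuple[float, float, float] = (0.30, 0.25, 0.05)
    qrs_duration: float = 100.0
    t_duration: float = 200.0
    loop_eccentricity: float = 0.2
    noise_sd: float = 0.0
    beat_jitter_sd: float = 2.0
    seed: int = 0
    p_amplitude: float = 0.15
    p_duration: float = 80.0
    p_center_offset: float = -180.0  # ms relative to the QRS centre
    t_center_offset: float = 280.0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.n_beats < 1 or self.heart_rate <= 0:
            raise ConfigError("sampling_rate, n_beats, heart_rate must be positive")
        if self.qrs_duration <= 0 or self.t_duration <= 0 or self.p_duration <= 0:
            raise ConfigError("wave durations must be positive")
        if self.noise_sd < 0 or self.beat_jitter_sd < 0:
            raise ConfigError("noise_sd and beat_jitter_sd must be >= 0")
        if np.linalg.norm(self.qrs_mean_vector) == 0 or np.linalg.norm(self.t_mean_vector) == 0:
            raise ConfigError("mean vectors must be nonzero")


def config_for_angle(angle_deg: float, qrs_magnitude: float = 1.5,
                     t_magnitude: float = 0.4, **overrides) -> EcgSimConfig:
    """An :class:`EcgSimConfig` whose ground-truth QRS-T angle is ``angle_deg``.

    The QRS mean vector points along a fixed reference direction; the T mean
    vector is rotated by the requested angle within a fixed plane.
    """
    ref = np.array([1.1, 0.9, 0.5])
    ref /= np.linalg.norm(ref)
    other = np.array([0.0, 0.0, 1.0])
    perp = other - (other @ ref) * ref
    perp /= np.linalg.norm(perp)
    theta = math.radians(angle_deg)
    t_dir = math.cos(theta) * ref + math.sin(theta) * perp
    return EcgSimConfig(
        qrs_mean_vector=tuple(qrs_magnitude * ref),
        t_mean_vector=tuple(t_magnitude * t_dir),
        **overrides)


@dataclass
class EcgGroundTruth:
    """Analytic truth accompanying one simulated record."""

    mean_qrst_angle: float
    peaks_qrst_angle: float
    qrs_duration_ms: float
    t_duration_ms: float
    r_times_s: np.ndarray
    svg_vector: np.ndarray        # mV*ms, closed form
    svg_magnitude: float
    sai_qrst: float               # mV*ms, dense numeric integral of the clean beat
    qrs_mean_vector: np.ndarray
    t_mean_vector: np.ndarray


def _loop_normal(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to both mean vectors (any perpendicular if parallel)."""
    n = np.cross(q, t)
    norm = np.linalg.norm(n)
    if norm < 1e-12 * np.linalg.norm(q) * max(np.linalg.norm(t), 1e-30):
        fallback = np.array([1.0, 0.0, 0.0])
        if abs(q @ fallback) > 0.9 * np.linalg.norm(q):
            fallback = np.array([0.0, 1.0, 0.0])
        n = np.cross(q, fallback)
        norm = np.linalg.norm(n)
    return n / norm


def _add_wave(xyz: np.ndarray, times: np.ndarray, center: float, duration_s: float,
              main: np.ndarray, perp: np.ndarray) -> None:
    """Raised-cosine loop: main * env + perp * quadrature, compact support."""
    phase = 2.0 * np.pi * (times - center) / duration_s
    mask = np.abs(times - center) < duration_s / 2.0
    env = np.where(mask, 0.5 * (1.0 + np.cos(phase)), 0.0)
    osc = np.where(mask, -np.sin(phase), 0.0)
    xyz += np.outer(env, main) + np.outer(osc, perp)


def _clean_beat_xyz(config: EcgSimConfig, times: np.ndarray,
                    center: float) -> np.ndarray:
    q = np.asarray(config.qrs_mean_vector, dtype=float)
    t = np.asarray(config.t_mean_vector, dtype=float)
    normal = _loop_normal(q, t)
    xyz = np.zeros((len(times), 3))
    ecc = config.loop_eccentricity
    _add_wave(xyz, times, center, config.qrs_duration / 1000.0,
              q, ecc * np.linalg.norm(q) * normal)
    _add_wave(xyz, times, center + config.t_center_offset / 1000.0,
              config.t_duration / 1000.0, t, ecc * np.linalg.norm(t) * normal)
    p_dir = np.array([0.4, 0.85, 0.2])
    p_dir /= np.linalg.norm(p_dir)
    _add_wave(xyz, times, center + config.p_center_offset / 1000.0,
              config.p_duration / 1000.0, config.p_amplitude * p_dir,
              np.zeros(3))
    return xyz


def _ground_truth(config: EcgSimConfig, r_times: np.ndarray) -> EcgGroundTruth:
    q = np.asarray(config.qrs_mean_vector, dtype=float)
    t = np.asarray(config.t_mean_vector, dtype=float)
    angle = angle_between(q, t)
    # closed form: integral of the raised-cosine envelope is duration/2,
    # the quadrature term integrates to zero over its full support
    svg = 0.5 * (config.qrs_duration * q + config.t_duration * t)
    # dense numeric SAI over the full QRST support of one clean beat
    fs_dense = 8000.0
    centre = 1.0
    start = centre - config.qrs_duration / 2000.0
    stop = centre + config.t_center_offset / 1000.0 + config.t_duration / 2000.0
    times = np.arange(start, stop, 1.0 / fs_dense)
    xyz = _clean_beat_xyz(config, times, centre)
    sai = float(np.trapezoid(np.abs(xyz), times * 1000.0, axis=0).sum())
    return EcgGroundTruth(
        mean_qrst_angle=angle,
        peaks_qrst_angle=angle,
        qrs_duration_ms=config.qrs_duration,
        t_duration_ms=config.t_duration,
        r_times_s=r_times,
        svg_vector=svg,
        svg_magnitude=float(np.linalg.norm(svg)),
        sai_qrst=sai,
        qrs_mean_vector=q,
        t_mean_vector=t,
    )


def simulate_ecg(config: EcgSimConfig,
                 kors_matrix: np.ndarray | None = None
                 ) -> tuple[EcgRecord, EcgGroundTruth]:
    """Generate a 12-lead record plus its analytic ground truth.

    Same seed, same config => bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    rr = 60.0 / config.heart_rate
    duration = max(config.n_beats * rr, 2.5)
    n = int(round(duration * fs))
    times = np.arange(n) / fs
    jitter = rng.normal(0.0, config.beat_jitter_sd / 1000.0, config.n_beats)
    centers = (np.arange(config.n_beats) + 0.5) * rr + jitter
    xyz = np.zeros((n, 3))
    for c in centers:
        xyz += _clean_beat_xyz(config, times, c)
    kors = DEFAULT_KORS if kors_matrix is None else np.asarray(kors_matrix)
    right_inv = kors_right_inverse(kors)
    eight = xyz @ right_inv.T
    twelve = complete_limb_leads(eight)
    if config.noise_sd > 0:
        twelve = twelve + rng.normal(0.0, config.noise_sd, twelve.shape)
    record = EcgRecord(twelve, fs, subject_id=f"sim-{config.seed}")
    return record, _ground_truth(config, centers)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Two-group cohort emulation (defaults follow the study's baseline table).

    ``design="case_control"`` fixes the group sizes and draws the angle from
    each group's normal; ``design="prospective"`` draws angles from the
    group-size-weighted mixture and event times from an exponential hazard
    multiplied by ``exp(log_hr)`` above the angle cutoff.
    """

    n_no_event: int = 246
    n_event: int = 49
    angle_mean_no_event: float = 112.0
    angle_sd_no_event: float = 38.0
    angle_mean_event: float = 134.0
    angle_sd_event: float = 33.0
    angle_cutoff: float = 110.0
    log_hr: float = math.log(3.4)
    log_hr_hf: float = math.log(4.1)
    baseline_hazard: float = 1e-4       # events/day below the cutoff
    baseline_hazard_hf: float = 4e-5
    censoring_horizon_days: float = 1814.0
    min_followup_days: float = 6.0
    diabetes_prevalence: tuple[float, float] = (0.21, 0.37)
    age_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((60, 12), (64, 9))
    lvef_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((36, 2.9), (35, 2.9))
    pl_ratio_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((1.15, 0.8), (2.15, 0.8))
    latent_rho: float = 0.7
    design: str = "case_control"
    seed: int = 0

    def validate(self) -> None:
        if self.n_no_event < 1 or self.n_event < 1:
            raise ConfigError("group sizes must be >= 1")
        if min(self.angle_sd_no_event, self.angle_sd_event) <= 0:
            raise ConfigError("angle SDs must be positive")
        if not all(0.0 <= p <= 1.0 for p in self.diabetes_prevalence):
            raise ConfigError("prevalences must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censoring_horizon_days <= 0:
            raise ConfigError("hazard and horizon must be positive")
        if self.design not in ("case_control", "prospective"):
            raise ConfigError(f"unknown design {self.design!r}")


def _binormal_auc(mu0, sd0, mu1, sd1) -> float:
    """Closed-form AUC of a normal score: Phi(dmu / sqrt(sd0^2 + sd1^2))."""
    from scipy.stats import norm
    return float(norm.cdf((mu1 - mu0) / math.hypot(sd0, sd1)))


def _event_probability(lam: float, horizon: float) -> float:
    """P(T <= C) for T ~ Exp(lam), C ~ Uniform(0, horizon)."""
    x = lam * horizon
    return 1.0 - (1.0 - math.exp(-x)) / x


def _correlated(rng, z, mean, sd, rho, sign=1.0):
    eps = rng.normal(0.0, 1.0, len(z))
    return mean + sd * (sign * rho * z + math.sqrt(1.0 - rho ** 2) * eps)


def simulate_cohort(config: CohortSimConfig | None = None
                    ) -> tuple[CohortTable, dict]:
    """Generate a per-patient table plus a dict of the true parameters."""
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    h = config.censoring_horizon_days
    lo = config.min_followup_days

    if config.design == "case_control":
        event = np.concatenate([np.zeros(config.n_no_event, dtype=int),
                                np.ones(config.n_event, dtype=int)])
    else:
        n_total = config.n_no_event + config.n_event
        w1 = config.n_event / n_total
        group = rng.random(n_total) < w1
        event = group.astype(int)  # provisional; overwritten by the hazard draw
    n = len(event)
    z = rng.normal(0.0, 1.0, n)  # latent severity shared by the features
    rho = config.latent_rho

    means = {
        "angle": (config.angle_mean_no_event, config.angle_sd_no_event,
                  config.angle_mean_event, config.angle_sd_event),
    }
    mu0, sd0, mu1, sd1 = means["angle"]
    ang_mu = np.where(event == 1, mu1, mu0)
    ang_sd = np.where(event == 1, sd1, sd0)
    angle = ang_mu + ang_sd * (rho * z + math.sqrt(1 - rho ** 2) * rng.normal(size=n))

    (a0, s_a0), (a1, s_a1) = config.age_mean_sd
    age = _correlated(rng, z, np.where(event == 1, a1, a0),
                      np.where(event == 1, s_a1, s_a0), 0.3)
    (l0, s_l0), (l1, s_l1) = config.lvef_mean_sd
    lvef = _correlated(rng, z, np.where(event == 1, l1, l0),
                       np.where(event == 1, s_l1, s_l0), 0.3, sign=-1.0)
    # repolarisation family shares the severity loading: these parameters
    # intercorrelate strongly in real A-ECG metadata
    (p0, s_p0), (p1, s_p1) = config.pl_ratio_mean_sd
    pl = np.clip(_correlated(rng, z, np.where(event == 1, p1, p0),
                             np.where(event == 1, s_p1, s_p0), rho), 0.05, None)
    prev = np.where(event == 1, config.diabetes_prevalence[1],
                    config.diabetes_prevalence[0])
    diabetes = (rng.random(n) < prev).astype(int)
    sai = np.clip(_correlated(rng, z, np.where(event == 1, 220.0, 180.0),
                              60.0, rho), 10.0, None)
    lvsd_score = _correlated(rng, z, np.where(event == 1, -2.2, -1.0),
                             1.5, rho, sign=-1.0)
    dsi = np.clip(_correlated(rng, z, np.where(event == 1, 0.61, 0.68),
                              0.12, 0.3, sign=-1.0), 0.2, 1.2)
    la_ao = np.clip(_correlated(rng, z, np.where(event == 1, 1.45, 1.30),
                                0.25, 0.3), 0.5, None)
    lvedd = _correlated(rng, z, np.where(event == 1, 60.0, 57.0), 6.0, 0.5)
    # LV mass tracks cavity size tightly, as in real echo metadata
    lv_mass = 4.0 * lvedd + rng.normal(0.0, 12.0, n)

    above = (angle > config.angle_cutoff).astype(float)
    lam = config.baseline_hazard * np.exp(config.log_hr * above)
    censor = rng.uniform(lo, h, n)
    if config.design == "case_control":
        # events: exponential time truncated at the censoring draw
        u = rng.random(n)
        t_event = -np.log1p(-u * (1.0 - np.exp(-lam * censor))) / lam
        time = np.where(event == 1, t_event, censor)
    else:
        t_event = rng.exponential(1.0 / lam)
        event = (t_event <= censor).astype(int)
        time = np.minimum(t_event, censor)

    lam_hf = config.baseline_hazard_hf * np.exp(config.log_hr_hf * above)
    t_hf = rng.exponential(1.0 / lam_hf)
    censor_hf = rng.uniform(lo, h, n)
    hf_event = (t_hf <= censor_hf).astype(int)
    hf_time = np.minimum(t_hf, censor_hf)

    frame = pd.DataFrame({
        "spatial_mean_qrst_angle": angle,
        "age": age,
        "lvef": lvef,
        "type2_diabetes": diabetes,
        "qrs_pl_ratio": pl,
        "sai_qrst": sai,
        "lvsd_score": lvsd_score,
        "dsi": dsi,
        "la_ao_ratio": la_ao,
        "lvedd_mm": lvedd,
        "lv_mass_g": lv_mass,
        "event": event,
        "time_days": time,
        "hf_event": hf_event,
        "hf_time_days": hf_time,
    }, index=pd.Index([f"P{i:04d}" for i in range(n)], name="subject_id"))

    p_above = {
        "no_event": 1.0 - _norm_cdf(config.angle_cutoff, mu0, sd0),
        "event": 1.0 - _norm_cdf(config.angle_cutoff, mu1, sd1),
    }
    w1 = config.n_event / (config.n_event + config.n_no_event)
    frac_above = (1 - w1) * p_above["no_event"] + w1 * p_above["event"]
    lam0, lam1 = config.baseline_hazard, config.baseline_hazard * math.exp(config.log_hr)
    expected_event_fraction = ((1 - frac_above) * _event_probability(lam0, h)
                               + frac_above * _event_probability(lam1, h))
    truth = {
        "expected_auc": _binormal_auc(mu0, sd0, mu1, sd1),
        "true_hr": math.exp(config.log_hr),
        "true_hr_hf": math.exp(config.log_hr_hf),
        "angle_cutoff": config.angle_cutoff,
        "expected_event_fraction": expected_event_fraction,
        "design": config.design,
        "n": n,
        "seed": config.seed,
    }
    return CohortTable(frame), truth


def _norm_cdf(x, mu, sd) -> float:
    return 0.5 * (1.0 + math.erf((x - mu) / (sd * math.sqrt(2.0))))


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def export_ecg_fixture(record: EcgRecord, truth: EcgGroundTruth, out_dir) -> None:
    """Write a simulated record as CSV plus a JSON sidecar of the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_ecg_csv(record, out_dir / f"{record.subject_id}.csv")
    payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in truth.__dict__.items()}
    (out_dir / f"{record.subject_id}.truth.json").write_text(
        json.dumps(payload, indent=1))


def export_cohort_fixture(table: CohortTable, truth: dict, out_dir,
                          stem: str = "cohort") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(out_dir / f"{stem}.csv")
    (out_dir / f"{stem}.truth.json").write_text(json.dumps(truth, indent=1))
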