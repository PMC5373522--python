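import numpy as np
import pytest

from aecg.beats import AveragedBeat, Fiducials, average_beats, detect_beats, locate_fiducials
from aecg.io import complete_limb_leads
from aecg.simulate import EcgSimConfig, simulate_ecg
from aecg.vcg import Vcg, kors_right_inverse


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, jitter-free default simulated record with ground truth."""
    config = EcgSimConfig(seed=0, noise_sd=0.0, beat_jitter_sd=0.0)
    record, truth = simulate_ecg(config)
    return config, record, truth


@pytest.fixture(scope="session")
def clean_beat(clean_sim):
    """Averaged template + fiducials of the clean default record."""
    _, record, _ = clean_sim
    beats = detect_beats(record)
    beat = average_beats(record, beats)
    fiducials = locate_fiducials(beat)
    return beat, fiducials


def make_vcg(xyz, sampling_rate=1000.0, qrs=(0, None), t_offset=None):
    """Construct a Vcg directly from an xyz trajectory for unit tests.

    Default fiducials: QRS spans the first half, T the second half. A
    minimal valid P window is synthesised before the QRS when it fits,
    otherwise the QRS is shifted to leave room.
    """
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    q0, q1 = qrs
    if q1 is None:
        q1 = n // 2
    t_off = n - 1 if t_offset is None else t_offset
    if q0 < 2:  # leave room for a (dummy) P window
        pad = 3 - q0
        xyz = np.vstack([np.zeros((pad, 3)), xyz])
        q0, q1, t_off, n = q0 + pad, q1 + pad, t_off + pad, n + pad
    fid = Fiducials(0, 1, q0, q1, t_off)
    beat_like = AveragedBeat(np.zeros((n, 12)), sampling_rate, 1)
    return Vcg(xyz, sampling_rate, fid), beat_like


def beat_from_vcg(xyz, sampling_rate=1000.0):
    """Project an xyz trajectory to 12 leads via the Kors right inverse."""
    eight = np.asarray(xyz, float) @ kors_right_inverse().T
    return AveragedBeat(complete_limb_leads(eight), sampling_rate, 1)
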