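"""The 5-parameter A-ECG LVSD score and derived echocardiographic indices.

The LVSD score is a published logistic-regression score over five A-ECG
parameters: spatial mean QRS-T angle (deg), derived Frank Z-lead QRS
integral (mV*ms), total 12-lead QRS voltage (mV), QRS nondipolar voltage
(mV) and T-wave dipolar voltage (mV). The published coefficients are not
bundled; they are read from a key=value config file. A clearly labelled
*synthetic* example file ships for testing only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .exceptions import ConfigError, DomainError, ScoringError

#: Feature names the score consumes, in config-file order.
LVSD_FEATURES = (
    "spatial_mean_qrst_angle",
    "z_qrs_integral",
    "total_qrs_voltage",
    "qrs_nondipolar_voltage",
    "t_dipolar_voltage",
)


@dataclass
class LvsdScoreCoefficients:
    """Intercept plus one slope per feature of the 5-parameter LVSD score.

    ``negative_is_diseased`` records the orientation of the scale: the
    published cutoff (<= -2.04) and the per-unit hazard ratio of 0.8 are
    consistent with more-negative scores marking more diseased patients.
    """

    intercept: float
    slopes: dict[str, float]
    negative_is_diseased: bool = True

    def __post_init__(self):
        if set(self.slopes) != set(LVSD_FEATURES):
            raise ConfigError(
                f"need exactly the slopes {LVSD_FEATURES}, got {sorted(self.slopes)}")

    @classmethod
    def from_file(cls, path=None) -> "LvsdScoreCoefficients":
        """Parse a key=value coefficient file.

        Without ``path`` the bundled synthetic example is loaded; it is for
        demonstration and unit tests only.
        """
        if path is None:
            text = resources.files("aecg.data").joinpath(
                "lvsd_coefficients_synthetic.txt").read_text()
        else:
            text = Path(path).read_text()
        values: dict[str, float] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            try:
                values[key.strip()] = float(raw)
            except ValueError as exc:
                raise ConfigError(f"bad coefficient line: {line!r}") from exc
        if "intercept" not in values:
            raise ConfigError("coefficient file must define 'intercept'")
        intercept = values.pop("intercept")
        return cls(intercept, values)


def lvsd_score(features: Mapping[str, float],
               coeffs: LvsdScoreCoefficients) -> tuple[float, float]:
    """(linear predictor in logit units, logistic probability).

    ``features`` maps the five :data:`LVSD_FEATURES` names to finite values;
    a missing or non-finite feature raises :class:`ScoringError` naming it.
    """
    lp = coeffs.intercept
    for name in LVSD_FEATURES:
        if name not in features:
            raise ScoringError(f"missing feature: {name}")
        value = float(features[name])
        if not math.isfinite(value):
            raise ScoringError(f"non-finite feature: {name}")
        lp += coeffs.slopes[name] * value
    probability = 1.0 / (1.0 + math.exp(-lp))
    return lp, probability


def energy_loss_index(ava: float, aa: float, bsa: float | None = None) -> float:
    """Aortic energy loss index (AVA*Aa)/(Aa-AVA) in cm^2, optionally /m^2 of BSA.

    AVA is the continuity-equation aortic valve area, Aa the aortic area;
    the index corrects the valve area for pressure recovery in the aorta and
    is only defined for Aa > AVA > 0.
    """
    if ava <= 0.0 or aa <= 0.0:
        raise DomainError("AVA and Aa must be positive")
    if aa <= ava:
        raise DomainError("ELI undefined unless aortic area exceeds valve area")
    eli = (ava * aa) / (aa - ava)
    if bsa is not None:
        if bsa <= 0.0:
            raise DomainError("BSA must be positive")
        eli /= bsa
    return eli


def dimensionless_severity_index(v_lvot: float, v_av: float) -> float:
    """DSI: LVOT-to-aortic peak velocity ratio (unitless)."""
    if v_lvot <= 0.0 or v_av <= 0.0:
        raise DomainError("velocities must be positive")
    return v_lvot / v_av


def dsi_predicts_response(dsi: float, cutoff: float = 0.64) -> bool:
    """True when the DSI exceeds the response cutoff (default 0.64)."""
    return dsi > cutoff


def classify_response(lvef_baseline: float, lvef_followup: float) -> str:
    """Classify medical-therapy response from paired LVEF measurements.

    Delta is in absolute LVEF percentage points: >10 up -> 'responder',
    >10 down -> 'deteriorator', anything with |delta| <= 10 ->
    'nonresponder' (a 10-point drop is exactly the boundary and counts as
    nonresponse).
    """
    for value in (lvef_baseline, lvef_followup):
        if not 0.0 < value < 100.0:
            raise DomainError(f"LVEF out of range (0, 100): {value}")
    delta = lvef_followup - lvef_baseline
    if delta > 10.0:
        return "responder"
    if delta < -10.0:
        return "deteriorator"
    return "nonresponder"
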