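"""Blue-light illumination model for a surgical operating microscope.

The excitation field of a fluorescence-mode operating microscope is
approximated by three separable factors:

* a linear response to the lamp power setting (fraction of maximum),
* a power-law fall-off of peak power density with working distance,
  ``P(D) = P_ref * (D_ref / D) ** gamma`` — the beam is cone-shaped, so the
  exponent is calibrated from measured anchors rather than assumed to be 2,
* a bell-shaped (two-sided Gaussian) transverse profile across the field of
  view, slightly skewed along the vertical axis because the scope is tilted
  relative to the target surface.

Units are explicit throughout: power density in mW/cm^2, radiant exposure
(dose) in J/cm^2, working distance in cm, field-of-view coordinates in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    """Raised when anchors cannot support a distance-exponent calibration."""


@dataclass(frozen=True)
class MicroscopeConfig:
    """Operating state of the microscope's blue illumination.

    Parameters
    ----------
    light_setting:
        Lamp output as a fraction of maximum, in [0, 1].
    working_distance_cm:
        Focus (working) distance from objective to target, > 0.
    gain:
        Dimensionless per-microscope scale factor; different scopes emit
        noticeably different power at identical settings.
    tilt_skew:
        Vertical asymmetry of the beam: the Gaussian half-width above the
        beam centre is ``sigma_y * tilt_skew`` (>= 1; 1 means symmetric).
    """

    light_setting: float = 1.0
    working_distance_cm: float = 20.0
    gain: float = 1.0
    tilt_skew: float = 1.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.light_setting <= 1.0:
            raise ValueError(f"light_setting must be in [0, 1], got {self.light_setting}")
        if self.working_distance_cm <= 0:
            raise ValueError("working_distance_cm must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.tilt_skew < 1:
            raise ValueError("tilt_skew must be >= 1")


@dataclass(frozen=True)
class IlluminationModel:
    """Calibrated distance/setting response plus beam-profile geometry.

    ``P_ref`` is the peak power density (mW/cm^2) at the reference distance
    ``D_ref`` (cm) with light setting 1.0 and gain 1.0.  ``sigma_x_mm`` /
    ``sigma_y_mm`` are the transverse Gaussian half-widths at ``D_ref``; the
    spot grows linearly with distance (``spot_scale_mm_per_cm``), consistent
    with a cone-shaped beam.
    """

    P_ref: float
    D_ref: float
    gamma: float
    sigma_x_mm: float = 20.0
    sigma_y_mm: float = 20.0
    spot_scale_mm_per_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.P_ref <= 0:
            raise ValueError("P_ref must be positive")
        if self.D_ref <= 0:
            raise ValueError("D_ref must be positive")
        if self.gamma <= 0:
            raise ValueError(
                "gamma must be positive: power density must strictly decrease "
                f"with distance (got gamma={self.gamma})"
            )
        if self.sigma_x_mm <= 0 or self.sigma_y_mm <= 0:
            raise ValueError("beam half-widths must be positive")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "IlluminationModel":
        return cls(**json.loads(Path(path).read_text()))


def calibrate_distance_exponent(
    anchors: list[tuple[float, float]],
    sigma_x_mm: float = 20.0,
    sigma_y_mm: float = 20.0,
    spot_scale_mm_per_cm: float = 1.0,
) -> IlluminationModel:
    """Fit the power-law distance exponent from (distance, power) anchors.

    Least-squares regression of ``log(power)`` on ``-log(distance)`` gives
    the exponent ``gamma``; ``P_ref``/``D_ref`` are taken from the nearest
    (smallest-distance) anchor.  With exactly two anchors the model passes
    through both exactly.

    Parameters
    ----------
    anchors:
        ``[(distance_cm, power_mw_cm2), ...]`` with at least two entries,
        distinct positive distances and positive powers.

    Raises
    ------
    CalibrationError
        Fewer than two anchors, or a non-increasing power/distance relation
        (gamma <= 0 violates the strictly-decreasing invariant).
    ValueError
        Non-positive distance or power.
    """
    if len(anchors) < 2:
        raise CalibrationError("need at least 2 (distance, power) anchors")
    d = np.asarray([a[0] for a in anchors], dtype=float)
    p = np.asarray([a[1] for a in anchors], dtype=float)
    if np.any(d <= 0) or np.any(p <= 0):
        raise ValueError("distances and powers must be positive")
    if len(np.unique(d)) < 2:
        raise CalibrationError("anchors must span at least two distinct distances")

    # slope of log(p) against -log(d): gamma, intercept absorbed into P_ref
    gamma, _ = np.polyfit(-np.log(d), np.log(p), 1)
    i_ref = int(np.argmin(d))
    try:
        return IlluminationModel(
            P_ref=float(p[i_ref]),
            D_ref=float(d[i_ref]),
            gamma=float(gamma),
            sigma_x_mm=sigma_x_mm,
            sigma_y_mm=sigma_y_mm,
            spot_scale_mm_per_cm=spot_scale_mm_per_cm,
        )
    except ValueError as exc:
        raise CalibrationError(str(exc)) from exc


def incident_power_density(cfg: MicroscopeConfig, model: IlluminationModel) -> float:
    """Peak incident power density (mW/cm^2) at the field-of-view centre.

    ``gain * light_setting * P_ref * (D_ref / D) ** gamma`` — linear in the
    light setting, homogeneous in gain, strictly decreasing in distance.
    """
    return (
        cfg.gain
        * cfg.light_setting
        * model.P_ref
        * (model.D_ref / cfg.working_distance_cm) ** model.gamma
    )


def beam_field(
    cfg: MicroscopeConfig,
    model: IlluminationModel,
    shape: tuple[int, int],
    pitch_mm: float,
) -> np.ndarray:
    """Render the 2D incident power-density field over a pixel grid.

    The field is a two-sided asymmetric Gaussian centred on the grid centre:
    the horizontal half-width is ``sigma_x * (D / D_ref)`` (beam cone), the
    vertical half-width is ``sigma_y`` below the centre and
    ``sigma_y * tilt_skew`` above it (row index increasing downward; "above"
    means smaller row index).  The peak equals
    :func:`incident_power_density`.

    Parameters
    ----------
    shape:
        ``(rows, cols)`` of the grid.
    pitch_mm:
        Physical pixel pitch in mm, > 0.
    """
    if pitch_mm <= 0:
        raise ValueError("pixel pitch must be positive")
    rows, cols = shape
    peak = incident_power_density(cfg, model)
    scale = cfg.working_distance_cm / model.D_ref
    sx = model.sigma_x_mm * scale
    sy = model.sigma_y_mm * scale

    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    y = (np.arange(rows) - r0)[:, None] * pitch_mm  # positive = below centre
    x = (np.arange(cols) - c0)[None, :] * pitch_mm

    sy_eff = np.where(y < 0, sy * cfg.tilt_skew, sy)
    return peak * np.exp(-0.5 * ((x / sx) ** 2 + (y / sy_eff) ** 2))


def dose_to_time(dose_j_cm2: float, power_mw_cm2: float) -> float:
    """Seconds of exposure needed to deliver a radiant exposure.

    ``t = dose * 1000 / power`` (J = W*s; power is in mW/cm^2).
    """
    if power_mw_cm2 <= 0:
        raise ValueError("power density must be positive")
    if dose_j_cm2 < 0:
        raise ValueError("dose must be non-negative")
    return dose_j_cm2 * 1000.0 / power_mw_cm2


def time_to_dose(seconds: float, power_mw_cm2: float) -> float:
    """Radiant exposure (J/cm^2) accumulated over ``seconds`` — exact inverse
    of :func:`dose_to_time`."""
    if power_mw_cm2 <= 0:
        raise ValueError("power density must be positive")
    if seconds < 0:
        raise ValueError("time must be non-negative")
    return seconds * power_mw_cm2 / 1000.0


def read_power_meter_csv(path: str | Path) -> pd.DataFrame:
    """Load sparse power-meter readings.

    Expects a header with columns ``distance_cm, setting_pct, power_mw_cm2``.
    """
    df = pd.read_csv(path)
    required = {"distance_cm", "setting_pct", "power_mw_cm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"power-meter CSV missing columns: {sorted(missing)}")
    return df


def calibrate_from_power_meter(df: pd.DataFrame, **kwargs) -> IlluminationModel:
    """Calibrate the distance exponent from 100%-setting power-meter rows."""
    full = df[df["setting_pct"] >= 100]
    if len(full) < 2:
        raise CalibrationError("need >= 2 readings at 100% setting")
    anchors = list(zip(full["distance_cm"], full["power_mw_cm2"]))
    return calibrate_distance_exponent(anchors, **kwargs)


#: Model calibrated from the two printed peak-power anchors:
#: 25.2 mW/cm^2 at 20 cm and 4.7 mW/cm^2 at 35 cm (gamma ~= 3.00).
DEFAULT_ANCHORS = [(20.0, 25.2), (35.0, 4.7)]


def default_illumination_model() -> IlluminationModel:
    """The package's reference illumination model (see DEFAULT_ANCHORS)."""
    return calibrate_distance_exponent(DEFAULT_ANCHORS)
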