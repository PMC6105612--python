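"""Camera models rendering scene radiance to 8-bit RGB frames.

Two detector configurations matter for red-fluorescence quantification:

* the microscope's **internal colour CCD**, whose out-of-band rejection is
  poor enough that blue excitation light spills into the red channel, and
* an **external camera behind a long-wave-pass red filter**, which rejects
  reflected blue light by a factor of at least 1000.

Rendering is linear before quantization: red counts are
``red_gain * red + leak * blue_gain * blue (+ noise)``, blue counts are
``blue_gain * blue (+ noise)``; the green channel carries no signal (red
PpIX emission plus blue excitation only).  Noise is additive Gaussian
applied before rounding and clipping to the 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CameraModel:
    """Linear RGB camera with blue-to-red channel crosstalk.

    Parameters
    ----------
    red_gain, blue_gain:
        Counts per radiance unit for the respective channels (> 0).
    leak_blue_to_red:
        Fraction of the blue-channel signal added to the red channel,
        in [0, 1].  ~0.05 for a typical colour CCD without a rejection
        filter; <= 1e-3 behind a long-wave-pass filter with >= 1000x
        blue attenuation.
    read_noise_sd:
        Additive Gaussian noise (counts) applied per pixel per channel
        before quantization.
    """

    name: str = "camera"
    red_gain: float = 2.0
    blue_gain: float = 6.0
    leak_blue_to_red: float = 0.0
    read_noise_sd: float = 2.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.red_gain <= 0 or self.blue_gain <= 0:
            raise ValueError("channel gains must be positive")
        if not 0.0 <= self.leak_blue_to_red <= 1.0:
            raise ValueError("leak_blue_to_red must be in [0, 1]")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit rendering is supported")

    @property
    def max_count(self) -> int:
        return (1 << self.bit_depth) - 1


def internal_ccd(leak: float = 0.05, **kwargs) -> CameraModel:
    """The microscope's internal colour CCD (blue->red spillover)."""
    return CameraModel(name="internal", leak_blue_to_red=leak, **kwargs)


def external_camera(leak: float = 1e-3, **kwargs) -> CameraModel:
    """External camera behind a red long-wave-pass filter (>=1000x blue
    rejection, i.e. residual leak <= 1e-3)."""
    return CameraModel(name="external", leak_blue_to_red=leak, **kwargs)


def render_frame(
    red_radiance: np.ndarray,
    blue_radiance: np.ndarray,
    cam: CameraModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render red/blue radiance fields to an 8-bit RGB image.

    Parameters
    ----------
    red_radiance, blue_radiance:
        2D non-negative fields of identical shape (arbitrary radiance
        units; the camera gains set the counts-per-unit scale).
    rng:
        Seed or Generator for the read noise; rendering is deterministic
        given the seed.  ``None`` renders noiselessly regardless of
        ``read_noise_sd``.

    Returns
    -------
    ``(rows, cols, 3)`` uint8 array, channel order RGB.
    """
    red = np.asarray(red_radiance, dtype=float)
    blue = np.asarray(blue_radiance, dtype=float)
    if red.shape != blue.shape:
        raise ValueError(f"field shapes differ: {red.shape} vs {blue.shape}")
    if red.ndim != 2:
        raise ValueError("radiance fields must be 2D")
    if np.any(red < 0) or np.any(blue < 0):
        raise ValueError("radiance must be non-negative")

    r = cam.red_gain * red + cam.leak_blue_to_red * cam.blue_gain * blue
    b = cam.blue_gain * blue
    if rng is not None and cam.read_noise_sd > 0:
        gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        r = r + gen.normal(0.0, cam.read_noise_sd, size=r.shape)
        b = b + gen.normal(0.0, cam.read_noise_sd, size=b.shape)

    out = np.zeros(red.shape + (3,), dtype=np.uint8)
    out[..., 0] = np.clip(np.rint(r), 0, cam.max_count).astype(np.uint8)
    out[..., 2] = np.clip(np.rint(b), 0, cam.max_count).astype(np.uint8)
    return out
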