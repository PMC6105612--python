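"""Synthetic fluorescence scenes with ground truth.

Emulates a bleaching experiment under an operating microscope's blue
excitation: photostable dye-in-polymer reference standards arranged around
an exposed brain bearing a fluorescent tumor, imaged repeatedly over 30
minutes while the tissue photobleaches.

The scene model:

* **Standards** emit red radiance proportional to dye concentration times
  sheet thickness, modulated by the local excitation power; they are nearly
  photostable (a bounded slow drift, +3.5% max over 30 min).
* **Tissue** (tumor, normal brain) starts at a fixed radiance and bleaches
  logarithmically, ``I(t) = max(0, I0 + c * ln(t + 1))`` with the decay
  coefficient scaled by the local excitation power — brighter regions of
  the field of view bleach faster.
* The **dark floor** (field around the specimen) is a constant low radiance
  unaffected by excitation.

Default tissue constants are calibrated so that the noiseless trajectories
hit the benchmark values: tumor-to-brain ratio 4.6 at t=0 falling to 2.8 at
10 min, brain 8.0 a.u. at t=0 falling to 4.4 a.u. at 30 min, and
brain-to-dark-floor 2.86 at 30 min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .camera import CameraModel, external_camera, internal_ccd, render_frame
from .optics import IlluminationModel, MicroscopeConfig, beam_field, default_illumination_model


class LayoutError(ValueError):
    """Raised when scene regions overlap or fall outside the image."""


# -- emission models -------------------------------------------------------

@dataclass(frozen=True)
class StandardSpec:
    """A dye-in-polymer reference sheet.

    Red emission is linear in sheet thickness with a concentration-dependent
    slope, scaled by local excitation power; ``drift_30min`` is the signed
    fractional intensity change accumulated linearly over 30 minutes
    (photostability bound: |drift| <= 0.035).
    """

    standard_id: int
    thickness_in: float
    concentration_ppt: float
    slope_per_ppt: float = 350.0  # radiance per inch per ppt at reference power
    drift_30min: float = 0.035

    def __post_init__(self) -> None:
        if self.thickness_in < 0:
            raise ValueError("thickness must be non-negative")
        if self.concentration_ppt <= 0:
            raise ValueError("concentration must be positive")
        if abs(self.drift_30min) > 0.035:
            raise ValueError("|drift over 30 min| must be <= 0.035")


@dataclass(frozen=True)
class TissueSpec:
    """A disc of tissue (or dark floor) with logarithmic photobleaching."""

    role: str  # "tumor" | "brain" | "dark_background"
    I0: float
    c_log: float  # a.u. per ln(min); <= 0 for fluorescing tissue
    center_mm: tuple[float, float] = (0.0, 0.0)  # (row, col) offset from field centre
    radius_mm: float = 5.8

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "brain", "dark_background"):
            raise ValueError(f"unknown tissue role {self.role!r}")
        if self.I0 < 0:
            raise ValueError("I0 must be non-negative")
        if self.role == "dark_background" and self.c_log != 0:
            raise ValueError("dark background must not bleach (c_log = 0)")
        if self.role != "dark_background" and self.c_log > 0:
            raise ValueError("fluorescing tissue must have c_log <= 0")


def drift_fraction(spec: StandardSpec, t_min: float) -> float:
    """Signed fractional drift at time ``t_min`` (linear ramp to 30 min)."""
    return spec.drift_30min * t_min / 30.0


def standard_emission(
    spec: StandardSpec, local_power: float, t_min: float, p_ref: float = 25.2
) -> float:
    """Red radiance of a standard under ``local_power`` mW/cm^2 at ``t_min``.

    ``slope * concentration * thickness * (local_power / p_ref) * (1 + drift(t))``.
    """
    if t_min < 0 or local_power < 0:
        raise ValueError("time and power must be non-negative")
    return (
        spec.slope_per_ppt
        * spec.concentration_ppt
        * spec.thickness_in
        * (local_power / p_ref)
        * (1.0 + drift_fraction(spec, t_min))
    )


def tissue_emission(
    spec: TissueSpec, local_power: float, t_min: float, p_ref: float = 25.2
) -> float:
    """Red radiance of tissue at ``t_min`` under ``local_power`` mW/cm^2.

    The bleaching rate scales with local irradiance:
    ``max(0, I0 + c_log * (local_power / p_ref) * ln(t + 1))``.  With no
    light there is no bleaching; at t=0 the radiance is exactly ``I0``.
    """
    if t_min < 0:
        raise ValueError("time must be non-negative")
    c_local = spec.c_log * (local_power / p_ref)
    return max(0.0, spec.I0 + c_local * np.log(t_min + 1.0))


# -- default scenario ------------------------------------------------------

#: Acquisition schedule (min): every 1 min for 10 min, then every 5 min to 30.
DEFAULT_TIMES_MIN: tuple[float, ...] = tuple(range(11)) + (15.0, 20.0, 25.0, 30.0)

#: Constant dark-floor radiance (a.u.).
DARK_FLOOR = 1.54

#: Sheet geometry of the four standards placed around the specimen
#: (id, thickness inches, concentration ppt by weight).
DEFAULT_STANDARD_SHEETS = (
    (1, 0.02, 0.5),
    (4, 0.02, 2.7),
    (6, 0.08, 2.7),
    (9, 0.08, 8.1),
)


def default_standards() -> tuple[StandardSpec, ...]:
    return tuple(
        StandardSpec(standard_id=i, thickness_in=th, concentration_ppt=c)
        for i, th, c in DEFAULT_STANDARD_SHEETS
    )


def default_tissues() -> tuple[TissueSpec, ...]:
    """Tumor/brain discs near the field centre plus the dark floor.

    Calibration (noiseless, centre irradiance): tumor 36.8 - 8.94 ln(t+1),
    brain 8.0 - 1.048 ln(t+1); both discs sit symmetrically about the
    vertical midline so they see identical excitation.
    """
    return (
        TissueSpec(role="tumor", I0=36.8, c_log=-8.94, center_mm=(0.0, -6.0)),
        TissueSpec(role="brain", I0=8.0, c_log=-1.048, center_mm=(0.0, 6.0)),
        TissueSpec(role="dark_background", I0=DARK_FLOOR, c_log=0.0,
                   center_mm=(18.0, 0.0), radius_mm=5.8),
    )


@dataclass(frozen=True)
class StudyDesign:
    """Full specification of a simulated bleaching study."""

    n_specimens: int = 6
    times_min: tuple[float, ...] = DEFAULT_TIMES_MIN
    shape: tuple[int, int] = (512, 512)
    pitch_mm: float = 0.1
    microscope: MicroscopeConfig = field(default_factory=MicroscopeConfig)
    illumination: IlluminationModel = field(default_factory=default_illumination_model)
    cameras: tuple[CameraModel, ...] = field(
        default_factory=lambda: (external_camera(), internal_ccd())
    )
    standards: tuple[StandardSpec, ...] = field(default_factory=default_standards)
    tissues: tuple[TissueSpec, ...] = field(default_factory=default_tissues)
    standard_positions_mm: tuple[tuple[float, float], ...] = (
        (-14.0, -14.0), (-14.0, 14.0), (14.0, -14.0), (14.0, 14.0)
    )
    standard_radius_mm: float = 5.8
    specimen_gain_sigma: float = 0.3   # lognormal sigma, common to tumor+brain
    tumor_jitter_sigma: float = 0.15   # lognormal sigma, tumor only
    roi_radius_px: int = 51
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        t = np.asarray(self.times_min, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("acquisition times must start at 0 and strictly increase")
        if len(self.standard_positions_mm) != len(self.standards):
            raise ValueError("one position per standard required")
        if self.pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["schema_version"] = 1
        Path(path).write_text(json.dumps(d, indent=2, default=list) + "\n")


@dataclass
class SimulatedStudy:
    """Output bundle of :func:`generate_series`."""

    design: StudyDesign
    #: camera name -> list (per specimen) of (T, H, W, 3) uint8 stacks
    frames: dict[str, list[np.ndarray]]
    #: ROI layout shared by all specimens: id, row, col, radius_px, label
    rois: list[dict]
    #: noiseless ROI-centre radiance: specimen, roi, label, time_min, radiance
    ground_truth: pd.DataFrame
    #: per-specimen common gain and tumor jitter actually drawn
    specimen_gains: np.ndarray
    tumor_jitters: np.ndarray


def _mm_to_px(offset_mm: tuple[float, float], shape: tuple[int, int], pitch: float
              ) -> tuple[float, float]:
    r0 = (shape[0] - 1) / 2.0
    c0 = (shape[1] - 1) / 2.0
    return r0 + offset_mm[0] / pitch, c0 + offset_mm[1] / pitch


def _disc_indices(center_px: tuple[float, float], radius_px: float,
                  shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px**2
    return np.flatnonzero(mask.ravel())


def _check_layout(centers_mm: list[tuple[float, float]], radii_mm: list[float],
                  half_extent_mm: tuple[float, float]) -> None:
    for i, ((ri, ci), rad_i) in enumerate(zip(centers_mm, radii_mm)):
        if abs(ri) + rad_i > half_extent_mm[0] or abs(ci) + rad_i > half_extent_mm[1]:
            raise LayoutError(f"region {i} extends outside the field of view")
        for j in range(i):
            (rj, cj), rad_j = centers_mm[j], radii_mm[j]
            if np.hypot(ri - rj, ci - cj) < rad_i + rad_j:
                raise LayoutError(f"regions {j} and {i} overlap")


def generate_series(design: StudyDesign) -> SimulatedStudy:
    """Simulate the full study: render frames and record ground truth.

    For each specimen the standards sit at the four corners of the field,
    the tumor and brain discs near the centre, and dark floor elsewhere.
    A per-specimen lognormal gain (sigma ``specimen_gain_sigma``) scales
    both tumor and brain emission; an independent lognormal jitter (sigma
    ``tumor_jitter_sigma``) scales the tumor only, so the tumor-to-brain
    ratio varies across specimens while staying centred on the calibrated
    trajectory.  Everything is deterministic given ``design.seed``.
    """
    shape, pitch = design.shape, design.pitch_mm
    half_extent = ((shape[0] - 1) / 2 * pitch, (shape[1] - 1) / 2 * pitch)

    centers = [tuple(p) for p in design.standard_positions_mm]
    radii = [design.standard_radius_mm] * len(design.standards)
    centers += [t.center_mm for t in design.tissues]
    radii += [t.radius_mm for t in design.tissues]
    _check_layout(centers, radii, half_extent)

    beam = beam_field(design.microscope, design.illumination, shape, pitch)
    p_ref = design.illumination.P_ref
    beam_norm = (beam / p_ref).ravel()

    # region index lists + ROI layout (shared across specimens)
    regions = []  # (kind, spec, flat indices, centre beam_norm)
    rois: list[dict] = []
    for spec, pos in zip(design.standards, design.standard_positions_mm):
        cpx = _mm_to_px(pos, shape, pitch)
        idx = _disc_indices(cpx, design.standard_radius_mm / pitch, shape)
        regions.append(("standard", spec, idx))
        rois.append({"id": f"standard-{spec.standard_id}",
                     "row": round(cpx[0]), "col": round(cpx[1]),
                     "radius": design.roi_radius_px,
                     "label": f"standard-{spec.standard_id}"})
    for tspec in design.tissues:
        cpx = _mm_to_px(tspec.center_mm, shape, pitch)
        idx = _disc_indices(cpx, tspec.radius_mm / pitch, shape)
        regions.append(("tissue", tspec, idx))
        rois.append({"id": tspec.role, "row": round(cpx[0]), "col": round(cpx[1]),
                     "radius": design.roi_radius_px, "label": tspec.role})
    roi_beam_norm = [beam_norm[r["row"] * shape[1] + r["col"]] for r in rois]

    root = np.random.SeedSequence(design.seed)
    gain_rng = np.random.default_rng(root.spawn(1)[0])
    gains = np.exp(gain_rng.normal(0.0, design.specimen_gain_sigma, design.n_specimens))
    jitters = np.exp(gain_rng.normal(0.0, design.tumor_jitter_sigma, design.n_specimens))

    frames: dict[str, list[np.ndarray]] = {cam.name: [] for cam in design.cameras}
    gt_rows = []
    times = np.asarray(design.times_min, dtype=float)
    blue = beam  # reflected excitation light, beam-shaped

    for s in range(design.n_specimens):
        noise_seq = root.spawn(1)[0]
        stacks = {cam.name: np.empty((len(times),) + shape + (3,), dtype=np.uint8)
                  for cam in design.cameras}
        for ti, t in enumerate(times):
            red = np.full(shape[0] * shape[1], DARK_FLOOR)
            lt = np.log(t + 1.0)
            for kind, spec, idx in regions:
                if kind == "standard":
                    base = (spec.slope_per_ppt * spec.concentration_ppt
                            * spec.thickness_in * (1.0 + drift_fraction(spec, t)))
                    red[idx] = base * beam_norm[idx]
                elif spec.role == "dark_background":
                    red[idx] = spec.I0
                else:
                    g = gains[s] * (jitters[s] if spec.role == "tumor" else 1.0)
                    red[idx] = g * np.maximum(0.0, spec.I0 + spec.c_log * beam_norm[idx] * lt)
            red = red.reshape(shape)
            for cam in design.cameras:
                child = np.random.default_rng(noise_seq.spawn(1)[0])
                stacks[cam.name][ti] = render_frame(red, blue, cam, rng=child)

            for roi, bn in zip(rois, roi_beam_norm):
                label = roi["label"]
                if label.startswith("standard"):
                    k = int(label.split("-")[1])
                    spec = next(x for x in design.standards if x.standard_id == k)
                    rad = standard_emission(spec, bn * p_ref, t, p_ref)
                elif label == "dark_background":
                    rad = DARK_FLOOR
                else:
                    tspec = next(x for x in design.tissues if x.role == label)
                    g = gains[s] * (jitters[s] if label == "tumor" else 1.0)
                    rad = g * tissue_emission(tspec, bn * p_ref, t, p_ref)
                gt_rows.append({"specimen": s, "roi": roi["id"], "label": label,
                                "time_min": t, "radiance": rad})
        for cam in design.cameras:
            frames[cam.name].append(stacks[cam.name])

    gt = pd.DataFrame(gt_rows)
    return SimulatedStudy(design=design, frames=frames, rois=rois,
                          ground_truth=gt, specimen_gains=gains,
                          tumor_jitters=jitters)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write TIFF stacks, ROI map, ground truth and design to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cam_name, stacks in study.frames.items():
        for s, stack in enumerate(stacks):
            tifffile.imwrite(out / f"specimen{s:02d}_{cam_name}.tif", stack,
                             photometric="rgb")
    (out / "rois.json").write_text(
        json.dumps({"schema_version": 1, "rois": study.rois}, indent=2) + "\n")
    study.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    meta = {
        "schema_version": 1,
        "seed": study.design.seed,
        "times_min": list(study.design.times_min),
        "specimen_gains": study.specimen_gains.tolist(),
        "tumor_jitters": study.tumor_jitters.tolist(),
        "rois": study.rois,
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2) + "\n")
    study.design.to_json(out / "design.json")
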