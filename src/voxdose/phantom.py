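"""Synthetic voxelized mouse phantom with ground-truth kinetics.

Stands in for the study animals and scanner: an analytic body plan
(ellipsoids and a spine cylinder voxelized on a 0.6 mm isotropic grid)
carrying the organ set of a flank-tumor xenograft mouse — tumor, heart,
lung, kidneys, urinary bladder, liver, intestine and a whole-body
remainder — plus a CT-like Hounsfield-unit volume consistent with the
material labels, and a kinetic ground truth that turns into
decay-uncorrected PET activity frames with optional Poisson noise and a
Gaussian point-spread blur.

The default geometry approximates a 25 g mouse with a 0.18 cc
subcutaneous flank tumor; the default kinetics emulate a renally excreted
PSMA ligand: rapid blood-pool/lung/liver washout, monotonically
accumulating kidneys and bladder, and tumor uptake peaking near 2 h at
~4.5 %ID/g.  No anatomical realism beyond that is attempted — the point
is a fully known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .decay import DecayScheme, ga68_scheme
from .kinetics import TimeActivityCurve
from .materials import MaterialMap, default_materials
from .volume import ImageVolume, save_nifti

__all__ = [
    "Ellipsoid",
    "PhantomConfig",
    "VoiSet",
    "OrganKinetics",
    "KineticTruth",
    "NoiseModel",
    "build_mouse_phantom",
    "default_kinetic_truth",
    "simulate_tacs",
    "render_pet_frames",
    "default_frame_schedule",
    "write_phantom_dataset",
]

#: HU values synthesized per material (air, interface, soft tissue, bone);
#: chosen to round-trip through the default segmentation thresholds.
DEFAULT_HU_VALUES = (-1000.0, -400.0, 0.0, 700.0)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and semi-axes in mm (grid coordinates
    relative to the volume centre)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _default_organs() -> dict[str, list[Ellipsoid]]:
    return {
        "heart": [Ellipsoid((0.0, 3.0, 16.0), (3.5, 3.5, 4.0))],
        "lung": [Ellipsoid((-6.9, 1.0, 17.0), (2.8, 2.6, 5.5)),
                 Ellipsoid((6.9, 1.0, 17.0), (2.8, 2.6, 5.5))],
        "liver": [Ellipsoid((0.0, -2.0, 6.0), (9.0, 5.0, 6.0))],
        "kidneys": [Ellipsoid((-7.0, -4.5, -3.0), (2.8, 2.5, 4.0)),
                    Ellipsoid((7.0, -4.5, -3.0), (2.8, 2.5, 4.0))],
        "intestine": [Ellipsoid((0.0, 2.5, -8.5), (6.5, 4.5, 6.5))],
        "urinary_bladder": [Ellipsoid((0.0, 0.0, -22.0), (2.8, 2.8, 2.8))],
    }


@dataclass
class PhantomConfig:
    """Geometry and grid of the synthetic mouse."""

    shape: tuple[int, int, int] = (64, 64, 128)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    body: Ellipsoid = field(default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (13.0, 13.0, 34.0)))
    organs: dict[str, list[Ellipsoid]] = field(default_factory=_default_organs)
    tumor_center: tuple[float, float, float] = (8.5, 0.0, -14.0)
    tumor_volume_cc: float = 0.18
    spine_radius_mm: float = 1.2
    spine_y_mm: float = -9.0
    spine_half_length_mm: float = 30.0
    hu_values: tuple[float, float, float, float] = DEFAULT_HU_VALUES

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("phantom grid must be at least 32 voxels per axis")
        if self.tumor_volume_cc <= 0:
            raise ValueError("tumor volume must be positive")


@dataclass
class VoiSet:
    """Named, pairwise-disjoint organ masks sharing one grid."""

    masks: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        names = list(self.masks)
        shape = None
        for name in names:
            m = np.asarray(self.masks[name], dtype=bool)
            self.masks[name] = m
            if not m.any():
                raise ValueError(f"VOI {name!r} is empty")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError(f"VOI {name!r} is on a different grid")
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"VOIs overlap: {a!r} and {b!r}")

    @property
    def organs(self) -> list[str]:
        return list(self.masks)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape  # type: ignore[return-value]

    def volume_ml(self, organ: str) -> float:
        voxel_ml = float(np.prod(self.spacing_mm)) / 1000.0
        return int(np.count_nonzero(self.masks[organ])) * voxel_ml

    def union(self, organs: list[str] | None = None) -> np.ndarray:
        names = self.organs if organs is None else organs
        out = np.zeros(self.shape, dtype=bool)
        for n in names:
            out |= self.masks[n]
        return out


def _grid_coords(shape, spacing):
    """Voxel-centre coordinates in mm, origin at the volume centre."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _voxelize_tumor(x, y, z, center, target_cc, voxel_cc, inside_body):
    """Digitized sphere hitting the target volume within one voxel.

    The voxel count of a thresholded sphere is a step function of the
    radius and can skip the target count, so the mask is instead the k
    voxels nearest the centre, k = round(target volume / voxel volume) —
    a sphere up to the digitization of its outermost shell.
    """
    k = int(round(target_cc / voxel_cc))
    cx, cy, cz = center
    r2 = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2).reshape(-1)
    nearest = np.argsort(r2, kind="stable")[:k]
    mask = np.zeros(r2.shape, dtype=bool)
    mask[nearest] = True
    return mask.reshape(x.shape)


def build_mouse_phantom(
    config: PhantomConfig | None = None,
    seed: int | None = None,
) -> tuple[MaterialMap, VoiSet, ImageVolume]:
    """Voxelize the analytic mouse: material labels, organ VOIs, HU volume.

    The construction is fully deterministic given the config (the seed is
    accepted for interface symmetry with the stochastic generators and is
    currently unused).  Organ masks are checked pairwise; an overlapping
    organ specification is rejected naming the colliding pair.  The flank
    tumor is voxelized to the configured volume within one voxel.
    """
    cfg = config if config is not None else PhantomConfig()
    x, y, z = _grid_coords(cfg.shape, cfg.spacing_mm)
    voxel_cc = float(np.prod(cfg.spacing_mm)) / 1000.0

    body_ellipsoid = cfg.body.contains(x, y, z)
    tumor = _voxelize_tumor(x, y, z, cfg.tumor_center, cfg.tumor_volume_cc,
                            voxel_cc, body_ellipsoid)
    if not body_ellipsoid[tuple(np.array(cfg.shape) // 2)] or not tumor.any():
        raise ValueError("tumor or body specification degenerate")
    # subcutaneous tumor may bulge out of the trunk ellipsoid; the body is
    # the union
    body = body_ellipsoid | tumor

    masks: dict[str, np.ndarray] = {"tumor": tumor}
    for name, parts in cfg.organs.items():
        m = np.zeros(cfg.shape, dtype=bool)
        for e in parts:
            part = e.contains(x, y, z)
            if np.any(part & ~body_ellipsoid):
                raise ValueError(f"organ {name!r} does not fit inside the body outline")
            m |= part
        masks[name] = m

    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"overlapping organ specification: {a!r} and {b!r}")

    spine = ((x**2 + (y - cfg.spine_y_mm) ** 2 <= cfg.spine_radius_mm**2)
             & (np.abs(z) <= cfg.spine_half_length_mm) & body_ellipsoid)
    for name in names:
        if np.any(spine & masks[name]):
            raise ValueError(f"overlapping organ specification: 'spine' and {name!r}")

    remainder = body & ~spine
    for m in masks.values():
        remainder &= ~m
    masks["remainder"] = remainder
    voi = VoiSet(masks=masks, spacing_mm=cfg.spacing_mm)

    # materials: air outside, one-voxel interface shell at the body surface,
    # soft tissue inside, bone at the spine
    labels = np.zeros(cfg.shape, dtype=np.int8)  # air
    shell = binary_dilation(body) & ~body
    labels[shell] = 1
    labels[body] = 2
    labels[spine] = 3
    materials = default_materials()
    mat = MaterialMap(labels=labels, materials=materials, spacing=cfg.spacing_mm)

    hu_lut = np.asarray(cfg.hu_values, dtype=float)
    hu = ImageVolume(values=hu_lut[labels], spacing=cfg.spacing_mm, unit="HU")
    return mat, voi, hu


@dataclass(frozen=True)
class OrganKinetics:
    """One-organ ground-truth model in decay-corrected %ID/g.

    ``association``/``accumulating``: ``y = P (1 - exp(-k t))``;
    ``dissociation``: ``y = (y0 - P) exp(-k t) + P``.
    """

    model: str  # association | dissociation | accumulating
    amplitude: float  # plateau P, %ID/g
    rate_per_min: float
    y0: float = 0.0  # dissociation initial value

    def __post_init__(self) -> None:
        if self.model not in ("association", "dissociation", "accumulating"):
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if self.rate_per_min < 0 or self.amplitude < 0 or self.y0 < 0:
            raise ValueError("rates and amplitudes must be non-negative")

    def concentration(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.model == "dissociation":
            return (self.y0 - self.amplitude) * np.exp(-self.rate_per_min * t) + self.amplitude
        return self.amplitude * (1.0 - np.exp(-self.rate_per_min * t))


@dataclass
class KineticTruth:
    """Ground-truth kinetics for every organ plus the remainder compartment.

    Organ curves are decay-corrected %ID/g; the remainder is a bi-exponential
    whole-body background expressed directly as a fraction of the injected
    activity, with amplitudes normalised so the whole-body total at t=0
    equals the injected activity.
    """

    organs: dict[str, OrganKinetics]
    masses_g: dict[str, float]
    remainder_rates_per_min: tuple[float, float] = (0.12, 0.008)
    remainder_split: float = 0.65  # share of the remainder on the fast rate
    scheme: DecayScheme = field(default_factory=ga68_scheme)

    def __post_init__(self) -> None:
        missing = set(self.organs) - set(self.masses_g)
        if missing:
            raise ValueError(f"organs missing a mass: {sorted(missing)}")
        a0 = 1.0 - sum(self.organs[o].concentration(np.array(0.0)) * self.masses_g[o]
                       for o in self.organs) / 100.0
        if a0 < 0:
            raise ValueError("organ activity at t=0 exceeds the injected activity")
        self._remainder_amplitudes = (a0 * self.remainder_split,
                                      a0 * (1.0 - self.remainder_split))
        t = np.linspace(0.0, 600.0, 1201)
        if np.any(self.total_fraction(t) > 1.0 + 1e-9):
            raise ValueError("summed decay-corrected activity exceeds the injected "
                             "activity at some time")

    def organ_fraction(self, organ: str, t_min: np.ndarray) -> np.ndarray:
        """Decay-corrected fraction of injected activity in one organ."""
        ok = self.organs[organ]
        return ok.concentration(t_min) * self.masses_g[organ] / 100.0

    def remainder_fraction(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        a1, a2 = self._remainder_amplitudes
        k1, k2 = self.remainder_rates_per_min
        return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)

    def total_fraction(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        total = self.remainder_fraction(t)
        for o in self.organs:
            total = total + self.organ_fraction(o, t)
        return total


def default_kinetic_truth(voi: VoiSet, scheme: DecayScheme | None = None,
                          soft_tissue_density: float = 1.04) -> KineticTruth:
    """Table-style default kinetics bound to a phantom's organ masses.

    Renal-tract organs accumulate monotonically; blood-pool organs wash out
    quickly; the tumor rises to ~4.5 %ID/g with a ~2 h plateau time.
    """
    organs = {
        "tumor": OrganKinetics("association", 4.6, 0.024),
        "heart": OrganKinetics("dissociation", 0.35, np.log(2) / 30.24, y0=30.7),
        "lung": OrganKinetics("dissociation", 0.45, np.log(2) / 51.93, y0=12.8),
        "liver": OrganKinetics("dissociation", 0.55, np.log(2) / 100.5, y0=8.6),
        "intestine": OrganKinetics("dissociation", 1.45, np.log(2) / 11.6, y0=4.0),
        "kidneys": OrganKinetics("accumulating", 58.0, 0.0085),
        "urinary_bladder": OrganKinetics("accumulating", 32.0, 0.008),
    }
    masses = {o: voi.volume_ml(o) * soft_tissue_density for o in organs}
    masses["remainder"] = voi.volume_ml("remainder") * soft_tissue_density
    return KineticTruth(organs=organs, masses_g=masses,
                        scheme=scheme if scheme is not None else ga68_scheme())


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """Frame midpoints (min) and durations (s) of the default 9-point study:
    dynamic 60 s frames early, 1200 s late statics."""
    mid = np.array([2.0, 5.0, 10.0, 30.0, 60.0, 90.0, 180.0, 240.0, 300.0])
    dur = np.array([60.0, 60.0, 60.0, 60.0, 60.0, 60.0, 1200.0, 1200.0, 1200.0])
    return mid, dur


def simulate_tacs(
    truth: KineticTruth,
    times_min: np.ndarray,
    injected_mbq: float,
    frame_durations_s: np.ndarray | None = None,
) -> tuple[dict[str, TimeActivityCurve], dict[str, np.ndarray]]:
    """Evaluate the ground truth at the frame midpoints.

    Returns the decay-corrected per-organ TACs (%ID/g) and, separately, the
    decay-uncorrected activity series in MBq per compartment (organs plus
    ``remainder``): ``A_unc(t) = A_inj * fraction(t) * exp(-lambda t)``.
    """
    times = np.asarray(times_min, dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and start at >= 0")
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    if frame_durations_s is None:
        frame_durations_s = np.full(times.shape, 60.0)
    decay = truth.scheme.decay_factor(times)
    tacs: dict[str, TimeActivityCurve] = {}
    uncorrected: dict[str, np.ndarray] = {}
    for organ, ok in truth.organs.items():
        conc = ok.concentration(times)
        tacs[organ] = TimeActivityCurve(organ, times, conc,
                                        np.asarray(frame_durations_s, float), injected_mbq)
        uncorrected[organ] = injected_mbq * truth.organ_fraction(organ, times) * decay
    uncorrected["remainder"] = injected_mbq * truth.remainder_fraction(times) * decay
    return tacs, uncorrected


@dataclass
class NoiseModel:
    """Poisson counting noise plus an optional Gaussian point-spread blur.

    Expected counts per voxel are ``concentration x voxel volume x frame
    duration x sensitivity``; the noisy concentration is the Poisson draw
    scaled back.  ``psf_sigma_mm`` smooths the noisy frame (0 disables).
    """

    poisson: bool = True
    sensitivity_counts_per_bq_s: float = 0.01
    psf_sigma_mm: float = 0.8


def render_pet_frames(
    voi: VoiSet,
    uncorrected_mbq: dict[str, np.ndarray],
    times_min: np.ndarray,
    frame_durations_s: np.ndarray,
    calibration_factor: float = 1.0,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> list[ImageVolume]:
    """Paint per-organ activity into voxels and emit decay-uncorrected frames.

    Every voxel of an organ carries that organ's mean concentration
    ``A_unc(t) * 1e6 / VOI volume [ml]`` in Bq/ml, multiplied by the scanner
    calibration (gain) factor.  Compartments present in the activity series
    must exist in the VOI set.
    """
    if calibration_factor <= 0:
        raise ValueError("calibration factor must be positive")
    times = np.asarray(times_min, dtype=float)
    durations = np.asarray(frame_durations_s, dtype=float)
    missing = set(uncorrected_mbq) - set(voi.organs)
    if missing:
        raise ValueError(f"activity series for organs absent from the VOI set: "
                         f"{sorted(missing)}")
    for organ, series in uncorrected_mbq.items():
        if len(np.asarray(series)) != len(times):
            raise ValueError(f"activity series for {organ!r} does not match the "
                             "frame schedule")
    rng = np.random.default_rng(seed)
    voxel_ml = float(np.prod(voi.spacing_mm)) / 1000.0
    frames: list[ImageVolume] = []
    for i, (t, dur) in enumerate(zip(times, durations)):
        frame = np.zeros(voi.shape, dtype=np.float64)
        for organ, series in uncorrected_mbq.items():
            conc_bq_ml = float(np.asarray(series)[i]) * 1e6 / voi.volume_ml(organ)
            frame[voi.masks[organ]] = conc_bq_ml
        if noise is not None and noise.poisson:
            expected = frame * voxel_ml * dur * noise.sensitivity_counts_per_bq_s
            counts = rng.poisson(expected)
            frame = counts / (voxel_ml * dur * noise.sensitivity_counts_per_bq_s)
        if noise is not None and noise.psf_sigma_mm > 0:
            sigma_vox = [noise.psf_sigma_mm / s for s in voi.spacing_mm]
            frame = gaussian_filter(frame, sigma_vox)
        frames.append(ImageVolume(values=frame * calibration_factor,
                                  spacing=voi.spacing_mm, unit="Bq/ml",
                                  frame_start=t * 60.0 - dur / 2.0,
                                  frame_duration=dur))
    return frames


def write_phantom_dataset(
    out_dir: str | Path,
    hu: ImageVolume,
    voi: VoiSet,
    frames: list[ImageVolume],
    truth: KineticTruth,
    injected_mbq: float,
    calibration_factor: float = 1.0,
) -> Path:
    """Write the synthetic study to disk: NIfTI volumes plus JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(hu, out / "ct_hu.nii.gz")
    for organ, mask in voi.masks.items():
        save_nifti(ImageVolume(mask.astype(float), voi.spacing_mm, "unitless"),
                   out / f"mask_{organ}.nii.gz")
    meta = {"injected_mbq": injected_mbq, "calibration_factor": calibration_factor,
            "frames": []}
    for i, f in enumerate(frames):
        save_nifti(f, out / f"pet_frame_{i:02d}.nii.gz")
        meta["frames"].append({"index": i, "start_s": f.frame_start,
                               "duration_s": f.frame_duration})
    (out / "frames.json").write_text(json.dumps(meta, indent=2))
    truth_json = {
        "organs": {o: {"model": k.model, "amplitude_pct_id_g": k.amplitude,
                       "rate_per_min": k.rate_per_min, "y0_pct_id_g": k.y0}
                   for o, k in truth.organs.items()},
        "masses_g": truth.masses_g,
        "remainder_rates_per_min": list(truth.remainder_rates_per_min),
        "remainder_split": truth.remainder_split,
        "half_life_min": truth.scheme.half_life_min,
    }
    (out / "kinetic_truth.json").write_text(json.dumps(truth_json, indent=2))
    return out
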