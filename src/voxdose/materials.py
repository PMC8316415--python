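"""Voxel material maps and photon cross-section data.

The dose engine works on four materials segmented from a CT-like
Hounsfield-unit volume: air, the air-body interface, soft tissue and bone.
Each material carries a mass density and interpolated photon attenuation
data.  Total attenuation is split into a Klein-Nishina Compton component,
computed from the material's electron density, and a residual
local-absorption component (photoelectric-dominated; the small coherent
contribution is folded in rather than transported).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .volume import ImageVolume

__all__ = [
    "Material",
    "MaterialMap",
    "AttenuationTable",
    "default_materials",
    "segment_materials",
    "DEFAULT_HU_THRESHOLDS",
]

ELECTRON_REST_MEV = 0.51099895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23

#: HU bin edges separating air | interface | soft tissue | bone
DEFAULT_HU_THRESHOLDS = (-700.0, -150.0, 300.0)

#: material index order used throughout the engine
MATERIAL_NAMES = ("air", "interface", "soft_tissue", "bone")


@dataclass(frozen=True)
class Material:
    name: str
    density_g_cm3: float
    composition_id: str  # column in the attenuation table
    z_over_a: float  # electrons per atomic mass unit

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError(f"material {self.name!r} has non-positive density")

    @property
    def electron_density_per_cm3(self) -> float:
        return self.density_g_cm3 * self.z_over_a * AVOGADRO


def default_materials() -> list[Material]:
    """Air, air-body interface, soft tissue (1.04 g/cm3) and cortical-type bone."""
    return [
        Material("air", 0.0012, "air", 0.499),
        Material("interface", 0.50, "soft_tissue", 0.555),
        Material("soft_tissue", 1.04, "soft_tissue", 0.555),
        Material("bone", 1.92, "bone", 0.515),
    ]


def klein_nishina_total_cm2(energy_mev: np.ndarray | float) -> np.ndarray:
    """Total Klein-Nishina cross-section per electron [cm^2]."""
    a = np.asarray(energy_mev, dtype=np.float64) / ELECTRON_REST_MEV
    term1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    term2 = np.log1p(2 * a) / (2 * a) - (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * (term1 + term2)


class AttenuationTable:
    """Per-material linear attenuation, log-log interpolated in energy.

    ``mu_total`` is read from the shipped table; ``mu_compton`` is the
    Klein-Nishina value for the material electron density; the residual
    ``mu_total - mu_compton`` (clipped at zero) is treated as local
    absorption.
    """

    def __init__(self, materials: list[Material] | None = None):
        self.materials = materials if materials is not None else default_materials()
        with resources.files("voxdose.data").joinpath("mu_photon.csv").open() as fh:
            table = pd.read_csv(fh, comment="#")
        self._log_e = np.log(table["energy_mev"].to_numpy())
        self.energy_range_mev = (float(table["energy_mev"].min()),
                                 float(table["energy_mev"].max()))
        self._log_mu_rho = {
            col: np.log(table[col].to_numpy()) for col in table.columns[1:]
        }

    def mu_over_rho(self, composition_id: str, energy_mev: np.ndarray) -> np.ndarray:
        e = np.clip(np.asarray(energy_mev, dtype=np.float64), *self.energy_range_mev)
        return np.exp(np.interp(np.log(e), self._log_e, self._log_mu_rho[composition_id]))

    def mu_total_per_mm(self, material_index: int, energy_mev: np.ndarray) -> np.ndarray:
        m = self.materials[material_index]
        return self.mu_over_rho(m.composition_id, energy_mev) * m.density_g_cm3 / 10.0

    def mu_compton_per_mm(self, material_index: int, energy_mev: np.ndarray) -> np.ndarray:
        m = self.materials[material_index]
        return klein_nishina_total_cm2(energy_mev) * m.electron_density_per_cm3 / 10.0

    def mu_majorant_per_mm(self, energy_mev: np.ndarray) -> np.ndarray:
        """Majorant over all materials, used by delta tracking."""
        mus = [self.mu_total_per_mm(i, energy_mev) for i in range(len(self.materials))]
        return np.maximum.reduce(mus)


@dataclass
class MaterialMap:
    """Per-voxel material labels plus the material definitions."""

    labels: np.ndarray  # integer indices into `materials`
    materials: list[Material]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("material labels must be a 3-D array")
        if self.labels.min() < 0 or self.labels.max() >= len(self.materials):
            raise ValueError("voxel label outside the defined material list")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def density_volume(self) -> np.ndarray:
        """Per-voxel density in g/cm^3."""
        rho = np.array([m.density_g_cm3 for m in self.materials])
        return rho[self.labels]

    def voxel_mass_g(self) -> np.ndarray:
        return self.density_volume() * self.voxel_volume_cm3


def segment_materials(
    hu: ImageVolume,
    thresholds: tuple[float, float, float] = DEFAULT_HU_THRESHOLDS,
    materials: list[Material] | None = None,
) -> MaterialMap:
    """Threshold a Hounsfield-unit volume into the four engine materials.

    Voxels below the first threshold are air, then air-body interface, then
    soft tissue, then bone.  HU values outside [-1100, 3000] are clamped
    with a warning.
    """
    if hu.unit != "HU":
        raise ValueError(f"expected an HU volume, got unit {hu.unit!r}")
    t = tuple(float(x) for x in thresholds)
    if not (t[0] < t[1] < t[2]):
        raise ValueError(f"thresholds must be strictly increasing, got {t}")
    values = hu.values
    if values.min() < -1100 or values.max() > 3000:
        import warnings

        warnings.warn("HU values outside [-1100, 3000] clamped before segmentation")
        values = np.clip(values, -1100, 3000)
    labels = np.digitize(values, t).astype(np.int8)
    return MaterialMap(labels=labels,
                       materials=materials if materials is not None else default_materials(),
                       spacing=hu.spacing)
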