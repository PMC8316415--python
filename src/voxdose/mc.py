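"""Voxel-level Monte Carlo dose engine for positron emitters.

Simulates radioactive decays drawn from a voxelized PET source against a
voxelized material phantom and scores per-voxel energy deposition, per-voxel
statistical uncertainty (batch estimator) and the energy ledger
(deposited + escaped = emitted).

Reduced physics, chosen for a desk-scale engine with an auditable error
budget:

* beta-plus: kinetic energy sampled from the nuclide spectrum and deposited
  uniformly along a straight track of density-scaled CSDA range (or locally,
  ``positron_mode="local"``); annihilation into two antiparallel 511 keV
  photons at the track end.
* photons: delta (Woodcock) tracking through the voxel grid with an
  energy-dependent majorant; Klein-Nishina Compton scattering with the
  recoil electron absorbed locally (kerma approximation); the residual,
  photoelectric-dominated attenuation absorbs locally; photons below the
  cutoff (default 20 keV) deposit locally.  Rayleigh scattering and
  bremsstrahlung are not transported.
* optional prompt gamma line when the decay scheme carries one.

Per-voxel uncertainty follows the standard batch convention: decays are
grouped into equal batches (default 100) and the standard error of a voxel's
total comes from the spread of its batch sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decay import ANNIHILATION_MEV, DecayScheme, csda_range_mm, ga68_scheme
from .materials import (
    ELECTRON_REST_MEV,
    AttenuationTable,
    MaterialMap,
    default_materials,
)
from .volume import ImageVolume

__all__ = [
    "DecayPrimaries",
    "DoseRateMap",
    "DoseRateCurve",
    "sample_decay",
    "transport_photons",
    "transport_photon",
    "simulate_frame",
    "organ_dose_rate",
    "integrate_dose_rate",
    "validate_reference_cube",
    "ReferenceCubeReport",
]

MEV_TO_J = 1.602176634e-13
#: photon energy below which the remaining energy is deposited locally
DEFAULT_CUTOFF_MEV = 0.020
#: substeps used to spread a positron track's kinetic energy over voxels
POSITRON_TRACK_SUBSTEPS = 8


# ---------------------------------------------------------------------------
# decay sampling
# ---------------------------------------------------------------------------

def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


@dataclass
class DecayPrimaries:
    """Primary particles of a block of decays.

    ``has_beta`` marks decays taking the beta-plus branch; those carry a
    sampled kinetic energy, an emission direction and the isotropic axis of
    their (antiparallel) annihilation photon pair.  ``has_prompt`` marks
    decays emitting the prompt gamma line.
    """

    has_beta: np.ndarray
    beta_energy_mev: np.ndarray
    beta_direction: np.ndarray
    pair_axis: np.ndarray
    has_prompt: np.ndarray
    prompt_direction: np.ndarray
    prompt_energy_mev: float

    def __len__(self) -> int:
        return len(self.has_beta)

    def annihilation_photon_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """The two photons of each pair: axis and its negation (they sum to
        the zero vector)."""
        return self.pair_axis, -self.pair_axis


def sample_decay(scheme: DecayScheme, rng: np.random.Generator, n: int = 1) -> DecayPrimaries:
    """Sample the primary particles of ``n`` decays of ``scheme``."""
    has_beta = rng.random(n) < scheme.beta_plus_branching
    energies = np.zeros(n)
    energies[has_beta] = scheme.spectrum.sample(rng, int(has_beta.sum()))
    has_prompt = rng.random(n) < scheme.prompt_gamma_intensity
    return DecayPrimaries(
        has_beta=has_beta,
        beta_energy_mev=energies,
        beta_direction=_isotropic_directions(rng, n),
        pair_axis=_isotropic_directions(rng, n),
        has_prompt=has_prompt,
        prompt_direction=_isotropic_directions(rng, n),
        prompt_energy_mev=scheme.prompt_gamma_mev,
    )


# ---------------------------------------------------------------------------
# photon transport
# ---------------------------------------------------------------------------

def _rotate(directions: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(cos_t) and azimuth phi."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    helper = np.zeros_like(directions)
    use_z = np.abs(directions[:, 2]) < 0.99
    helper[use_z, 2] = 1.0
    helper[~use_z, 0] = 1.0
    u = np.cross(helper, directions)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(directions, u)
    out = (cos_t[:, None] * directions
           + sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _sample_compton(energy_mev: np.ndarray, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the scattered-to-incident energy ratio eps and cos(theta)
    from the Klein-Nishina differential cross-section (composition/rejection
    sampling with 1/eps and eps proposal terms)."""
    a = energy_mev / ELECTRON_REST_MEV
    eps0 = 1.0 / (1.0 + 2.0 * a)
    alpha1 = -np.log(eps0)
    alpha2 = 0.5 * (1.0 - eps0**2)
    eps = np.empty_like(a)
    undecided = np.ones(len(a), dtype=bool)
    while undecided.any():
        idx = np.nonzero(undecided)[0]
        u1, u2, u3 = rng.random((3, len(idx)))
        use_inv = u1 * (alpha1[idx] + alpha2[idx]) < alpha1[idx]
        cand = np.where(use_inv,
                        eps0[idx] ** u2,
                        np.sqrt(eps0[idx] ** 2 + (1.0 - eps0[idx] ** 2) * u2))
        t = (1.0 - cand) / (a[idx] * cand)  # 1 - cos(theta)
        sin2 = t * (2.0 - t)
        accept = u3 <= 1.0 - cand * sin2 / (1.0 + cand**2)
        eps[idx[accept]] = cand[accept]
        undecided[idx[accept]] = False
    cos_t = 1.0 - (1.0 - eps) / (a * eps)
    return eps, np.clip(cos_t, -1.0, 1.0)


class _Grid:
    """Voxel-grid bookkeeping shared by the transport kernels."""

    def __init__(self, material_map: MaterialMap):
        self.mat = material_map
        self.shape = np.array(material_map.shape)
        self.spacing = np.array(material_map.spacing)
        self.extent = self.shape * self.spacing
        self.n_voxels = int(np.prod(self.shape))
        self.labels_flat = material_map.labels.reshape(-1)

    def flat_index(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(inside mask, flat voxel index) for positions in mm (grid corner
        at the origin)."""
        idx = np.floor(pos / self.spacing).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < self.shape), axis=1)
        flat = ((idx[:, 0] * self.shape[1]) + idx[:, 1]) * self.shape[2] + idx[:, 2]
        return inside, np.where(inside, flat, 0)


def transport_photons(
    positions: np.ndarray,
    directions: np.ndarray,
    energies_mev: np.ndarray,
    material_map: MaterialMap,
    rng: np.random.Generator,
    attenuation: AttenuationTable | None = None,
    cutoff_mev: float = DEFAULT_CUTOFF_MEV,
    edep_out: np.ndarray | None = None,
    interactions_out: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Delta-tracking photon transport; returns (per-voxel MeV, escaped MeV).

    Positions are mm with the grid corner at the origin.  Flight lengths are
    sampled against the energy-dependent majorant attenuation; virtual
    collisions are rejected with probability ``1 - mu/mu_maj``.  Real
    collisions split into Klein-Nishina Compton scattering (recoil deposited
    locally) and residual local absorption.
    """
    grid = _Grid(material_map)
    att = attenuation if attenuation is not None else AttenuationTable(material_map.materials)
    pos = np.array(positions, dtype=np.float64).reshape(-1, 3)
    dirs = np.array(directions, dtype=np.float64).reshape(-1, 3)
    e = np.array(energies_mev, dtype=np.float64).reshape(-1)
    if not np.all(np.isfinite(dirs)):
        raise ValueError("non-finite photon direction")
    if np.any(e <= 0):
        raise ValueError("photon energies must be positive")
    edep = edep_out if edep_out is not None else np.zeros(grid.n_voxels)
    escaped = 0.0
    alive = np.ones(len(e), dtype=bool)

    n_mat = len(att.materials)
    for _ in range(100000):
        if not alive.any():
            break
        ia = np.nonzero(alive)[0]
        ea = e[ia]
        mu_maj = att.mu_majorant_per_mm(ea)
        step = rng.exponential(1.0, len(ia)) / mu_maj
        pos[ia] += dirs[ia] * step[:, None]
        inside, flat = grid.flat_index(pos[ia])
        out = ~inside
        if out.any():
            escaped += float(ea[out].sum())
            alive[ia[out]] = False
        ia = ia[inside]
        if len(ia) == 0:
            continue
        ea = e[ia]
        flat = flat[inside]
        labels = grid.labels_flat[flat]
        mu_by_mat = np.stack([att.mu_total_per_mm(m, ea) for m in range(n_mat)])
        mu_tot = mu_by_mat[labels, np.arange(len(ia))]
        mu_maj_in = att.mu_majorant_per_mm(ea)
        real = rng.random(len(ia)) < mu_tot / mu_maj_in
        if not real.any():
            continue
        ia = ia[real]
        if interactions_out is not None:
            interactions_out[ia] += 1
        flat = flat[real]
        labels = labels[real]
        ea = e[ia]
        mu_tot = mu_tot[real]
        mu_c_by_mat = np.stack([att.mu_compton_per_mm(m, ea) for m in range(n_mat)])
        mu_c = np.minimum(mu_c_by_mat[labels, np.arange(len(ia))], mu_tot)
        compton = rng.random(len(ia)) < mu_c / mu_tot
        # local absorption (photoelectric-dominated residual)
        absorb = ~compton
        if absorb.any():
            np.add.at(edep, flat[absorb], ea[absorb])
            alive[ia[absorb]] = False
        if compton.any():
            ic = ia[compton]
            fc = flat[compton]
            ec = e[ic]
            eps, cos_t = _sample_compton(ec, rng)
            recoil = ec * (1.0 - eps)
            scattered = ec * eps
            np.add.at(edep, fc, recoil)
            below = scattered < cutoff_mev
            if below.any():
                np.add.at(edep, fc[below], scattered[below])
                alive[ic[below]] = False
            keep = ~below
            if keep.any():
                phi = rng.uniform(0.0, 2.0 * np.pi, int(keep.sum()))
                dirs[ic[keep]] = _rotate(dirs[ic[keep]], cos_t[keep], phi)
                e[ic[keep]] = scattered[keep]
    else:  # pragma: no cover - safety valve
        warnings.warn("photon transport iteration cap reached; depositing remainder")
        inside, flat = grid.flat_index(pos[alive])
        np.add.at(edep, flat[inside], e[alive][inside])
        escaped += float(e[alive][~inside].sum())
    return edep, escaped


def transport_photon(
    position,
    direction,
    energy_mev: float,
    material_map: MaterialMap,
    rng: np.random.Generator,
    cutoff_mev: float = DEFAULT_CUTOFF_MEV,
) -> list[tuple[tuple[int, int, int], float]]:
    """Single-photon convenience wrapper: list of (voxel index, MeV deposited)."""
    edep, _ = transport_photons(np.atleast_2d(position), np.atleast_2d(direction),
                                np.atleast_1d(energy_mev), material_map, rng,
                                cutoff_mev=cutoff_mev)
    hits = np.nonzero(edep)[0]
    shape = material_map.shape
    return [(tuple(int(v) for v in np.unravel_index(h, shape)), float(edep[h]))
            for h in hits]


# ---------------------------------------------------------------------------
# positron transport
# ---------------------------------------------------------------------------

def _transport_positrons(
    pos: np.ndarray,
    primaries: DecayPrimaries,
    grid: _Grid,
    edep: np.ndarray,
    mode: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Deposit positron kinetic energy; returns (escaped MeV, annihilation
    positions, mask of annihilations occurring inside the grid)."""
    beta = primaries.has_beta
    n = int(beta.sum())
    p0 = pos[beta]
    e_k = primaries.beta_energy_mev[beta]
    escaped = 0.0
    if mode == "local":
        inside, flat = grid.flat_index(p0)
        np.add.at(edep, flat[inside], e_k[inside])
        escaped += float(e_k[~inside].sum())
        return escaped, p0, np.ones(n, dtype=bool)
    # straight track of density-scaled CSDA range, energy spread uniformly
    inside0, flat0 = grid.flat_index(p0)
    rho = np.full(n, 1.0)
    rho[inside0] = np.array([m.density_g_cm3 for m in grid.mat.materials]
                            )[grid.labels_flat[flat0[inside0]]]
    track = csda_range_mm(e_k, rho)
    d = primaries.beta_direction[beta]
    k = POSITRON_TRACK_SUBSTEPS
    e_sub = e_k / k
    for j in range(k):
        p_j = p0 + d * (track * (j + 0.5) / k)[:, None]
        inside, flat = grid.flat_index(p_j)
        np.add.at(edep, flat[inside], e_sub[inside])
        escaped += float(e_sub[~inside].sum())
    p_end = p0 + d * track[:, None]
    inside_end, _ = grid.flat_index(p_end)
    return escaped, p_end, inside_end


# ---------------------------------------------------------------------------
# frame simulation
# ---------------------------------------------------------------------------

@dataclass
class DoseRateMap:
    """Per-voxel dose rate for one PET frame, with batch uncertainties."""

    dose_rate: ImageVolume  # Gy/s on the frame's own clock
    rel_uncertainty: np.ndarray  # fractional SE of each voxel's dose
    edep_mev: np.ndarray  # per-voxel deposited energy D_k over all decays
    n_decays: int
    frame_duration_s: float
    time_fraction: float
    frame_id: int = 0
    emitted_mev: float = 0.0
    escaped_mev: float = 0.0
    organ_batch_mev: dict[str, np.ndarray] = field(default_factory=dict)
    n_batches: int = 100

    @property
    def deposited_mev(self) -> float:
        return float(self.edep_mev.sum())


@dataclass
class DoseRateCurve:
    """Organ-mean dose rate (Gy/s) versus frame midpoints (min)."""

    organ: str
    times_min: np.ndarray
    dose_rate_gy_s: np.ndarray
    uncertainty_gy_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.dose_rate_gy_s = np.asarray(self.dose_rate_gy_s, dtype=float)
        self.uncertainty_gy_s = np.asarray(self.uncertainty_gy_s, dtype=float)
        if np.any(self.dose_rate_gy_s < -1e-30):
            raise ValueError("dose rates must be non-negative")


def simulate_frame(
    source: ImageVolume,
    material_map: MaterialMap,
    frame_duration_s: float,
    time_fraction: float = 0.1,
    seed: int | None = None,
    scheme: DecayScheme | None = None,
    voi=None,
    n_batches: int = 100,
    positron_mode: str = "track",
    cutoff_mev: float = DEFAULT_CUTOFF_MEV,
    frame_id: int = 0,
    attenuation: AttenuationTable | None = None,
) -> DoseRateMap:
    """Monte Carlo dose-rate map for one PET frame.

    The number of simulated decays is the frame's physical decay count
    scaled by ``time_fraction`` (default one-tenth, the usual acquisition
    time reduction): ``N = sum_k conc_k x voxel volume x duration x
    fraction``; emission voxels are sampled proportionally to their decay
    count.  The dose rate is the frame dose divided by the frame duration,
    after rescaling the scored energy by ``1/time_fraction`` — i.e. Gy/s on
    the frame's own clock.

    Passing a ``voi`` (a :class:`~voxdose.phantom.VoiSet`) additionally
    records per-batch organ deposits so organ-level uncertainties include
    voxel-to-voxel correlation.
    """
    if source.unit != "Bq/ml":
        raise ValueError("source must be an activity-concentration volume (Bq/ml)")
    if not source.same_grid(material_map.labels):
        raise ValueError("source and material phantom are not co-registered")
    if not (0.0 < time_fraction <= 1.0):
        raise ValueError("time_fraction must lie in (0, 1]")
    scheme = scheme if scheme is not None else ga68_scheme()
    grid = _Grid(material_map)
    att = attenuation if attenuation is not None else AttenuationTable(material_map.materials)

    decays_per_voxel = source.values.reshape(-1) * source.voxel_volume_ml \
        * frame_duration_s * time_fraction
    total = float(decays_per_voxel.sum())
    n_decays = int(round(total))
    spacing = grid.spacing
    rng = np.random.default_rng(seed)

    edep_sum = np.zeros(grid.n_voxels)
    edep_sumsq = np.zeros(grid.n_voxels)
    organ_batch: dict[str, np.ndarray] = {}
    organ_flat = {}
    if voi is not None:
        for organ in voi.organs:
            organ_flat[organ] = np.nonzero(voi.masks[organ].reshape(-1))[0]
            organ_batch[organ] = np.zeros(n_batches)
    emitted = 0.0
    escaped_total = 0.0

    if n_decays == 0:
        warnings.warn("all-zero (or negligible) source: returning a zero dose map")
    else:
        prob = decays_per_voxel / total
        batch_sizes = np.full(n_batches, n_decays // n_batches)
        batch_sizes[: n_decays % n_batches] += 1
        for b, n_b in enumerate(batch_sizes):
            if n_b == 0:
                continue
            edep_b = np.zeros(grid.n_voxels)
            flat_idx = rng.choice(grid.n_voxels, size=int(n_b), p=prob)
            idx3 = np.column_stack(np.unravel_index(flat_idx, tuple(grid.shape)))
            pos = (idx3 + rng.random((int(n_b), 3))) * spacing
            prim = sample_decay(scheme, rng, int(n_b))
            emitted += float(prim.beta_energy_mev.sum())
            emitted += 2.0 * ANNIHILATION_MEV * int(prim.has_beta.sum())
            emitted += prim.prompt_energy_mev * int(prim.has_prompt.sum())

            esc_p, p_ann, ann_inside = _transport_positrons(
                pos, prim, grid, edep_b, positron_mode)
            escaped_total += esc_p
            # annihilation photons: antiparallel pair along the sampled axis;
            # pairs born outside the grid escape outright
            axis = prim.pair_axis[prim.has_beta]
            esc_out = 2.0 * ANNIHILATION_MEV * int((~ann_inside).sum())
            escaped_total += esc_out
            p_in = p_ann[ann_inside]
            ax_in = axis[ann_inside]
            gamma_pos = np.concatenate([p_in, p_in])
            gamma_dir = np.concatenate([ax_in, -ax_in])
            gamma_e = np.full(2 * len(p_in), ANNIHILATION_MEV)
            if prim.has_prompt.any():
                gamma_pos = np.concatenate([gamma_pos, pos[prim.has_prompt]])
                gamma_dir = np.concatenate([gamma_dir,
                                            prim.prompt_direction[prim.has_prompt]])
                gamma_e = np.concatenate([gamma_e, np.full(int(prim.has_prompt.sum()),
                                                           prim.prompt_energy_mev)])
            if len(gamma_e):
                _, esc_g = transport_photons(gamma_pos, gamma_dir, gamma_e,
                                             material_map, rng, attenuation=att,
                                             cutoff_mev=cutoff_mev, edep_out=edep_b)
                escaped_total += esc_g
            edep_sum += edep_b
            edep_sumsq += edep_b**2
            for organ, fidx in organ_flat.items():
                organ_batch[organ][b] = edep_b[fidx].sum()

    # batch standard error of each voxel's total deposit
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_b = edep_sum / n_batches
        var_b = np.maximum(edep_sumsq - n_batches * mean_b**2, 0.0) / max(n_batches - 1, 1)
        se_total = np.sqrt(n_batches * var_b)
        rel = np.where(edep_sum > 0, se_total / edep_sum, 0.0)

    mass_kg = material_map.voxel_mass_g().reshape(-1) / 1000.0
    dose_gy = edep_sum * MEV_TO_J / mass_kg / time_fraction
    rate = dose_gy / frame_duration_s
    rate_vol = ImageVolume(rate.reshape(material_map.shape),
                           spacing=material_map.spacing, unit="Gy/s",
                           frame_duration=frame_duration_s)
    return DoseRateMap(
        dose_rate=rate_vol,
        rel_uncertainty=rel.reshape(material_map.shape),
        edep_mev=edep_sum.reshape(material_map.shape),
        n_decays=n_decays,
        frame_duration_s=frame_duration_s,
        time_fraction=time_fraction,
        frame_id=frame_id,
        emitted_mev=emitted,
        escaped_mev=escaped_total,
        organ_batch_mev=organ_batch,
        n_batches=n_batches,
    )


def organ_dose_rate(dose_map: DoseRateMap, voi, material_map: MaterialMap
                    ) -> dict[str, tuple[float, float]]:
    """Mass-weighted mean dose rate (and SE) per organ VOI, in Gy/s.

    When the map carries per-batch organ deposits (``simulate_frame(...,
    voi=...)``) the SE comes from batch statistics; otherwise per-voxel SEs
    are combined assuming independence.
    """
    if dose_map.dose_rate.shape != next(iter(voi.masks.values())).shape:
        raise ValueError("dose map and VOI grids do not match")
    mass = material_map.voxel_mass_g()
    rate = dose_map.dose_rate.values
    out: dict[str, tuple[float, float]] = {}
    for organ in voi.organs:
        m = voi.masks[organ]
        if not m.any():
            raise ValueError(f"empty VOI {organ!r}")
        w = mass[m]
        total_mass = w.sum()
        mean_rate = float((rate[m] * w).sum() / total_mass)
        if organ in dose_map.organ_batch_mev:
            b = dose_map.organ_batch_mev[organ]
            nb = dose_map.n_batches
            se_edep = float(np.std(b, ddof=1) * np.sqrt(nb))
            scale = MEV_TO_J / (total_mass / 1000.0) / dose_map.time_fraction \
                / dose_map.frame_duration_s
            se = se_edep * scale
        else:
            se_vox = dose_map.rel_uncertainty[m] * rate[m]
            se = float(np.sqrt(((se_vox * w) ** 2).sum()) / total_mass)
        out[organ] = (mean_rate, se)
    return out


def integrate_dose_rate(
    curve: DoseRateCurve,
    lambda_phys_per_min: float,
    injected_mbq: float,
) -> tuple[float, float]:
    """Absorbed dose per injected activity (Gy/MBq) from a dose-rate curve.

    Trapezoid in seconds over the observations — with a linear leading
    segment from (0, 0) when the first observation is after t=0 — plus the
    physical-decay tail ``r(t_last)/lambda``, divided by the injected
    activity.  Returns (dose, propagated SE).
    """
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    if np.any(curve.dose_rate_gy_s < 0):
        raise ValueError("negative dose rates")
    lam_s = lambda_phys_per_min / 60.0
    t_s = curve.times_min * 60.0
    r = curve.dose_rate_gy_s
    dose = float(np.trapezoid(r, t_s)) + float(r[-1] / lam_s)
    if t_s[0] > 0:
        dose += 0.5 * t_s[0] * r[0]
    # propagate per-point SEs through the same quadrature weights
    w = np.zeros_like(t_s)
    if len(t_s) > 1:
        dt = np.diff(t_s)
        w[:-1] += dt / 2.0
        w[1:] += dt / 2.0
    w[0] += t_s[0] / 2.0
    w[-1] += 1.0 / lam_s
    se = float(np.sqrt(((w * curve.uncertainty_gy_s) ** 2).sum()))
    return dose / injected_mbq, se / injected_mbq


# ---------------------------------------------------------------------------
# reference validation cube
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCubeReport:
    emitted_mev: float
    deposited_mev: float
    escaped_mev: float
    beta_kinetic_emitted_mev: float
    beta_kinetic_deposited_mev: float
    escape_fraction: float
    rel_uncertainty_center: float
    rel_uncertainty_median_source: float
    n_decays: int

    @property
    def ledger_residual(self) -> float:
        """|deposited + escaped - emitted| / emitted."""
        return abs(self.deposited_mev + self.escaped_mev - self.emitted_mev) \
            / self.emitted_mev


def validate_reference_cube(
    scheme: DecayScheme | None = None,
    n_decays: int = 100_000,
    seed: int | None = None,
    cube_mm: float = 100.0,
    voxel_mm: float = 4.0,
    n_batches: int = 100,
) -> ReferenceCubeReport:
    """Accuracy audit on the reference soft-tissue cube.

    A 100 x 100 x 100 mm cube of soft tissue (1.04 g/cm3) with a centred
    point source: reports the energy ledger, the escape fraction, the
    locally absorbed share of the positron kinetic energy, and the per-voxel
    uncertainty at the centre.
    """
    scheme = scheme if scheme is not None else ga68_scheme()
    n_side = int(round(cube_mm / voxel_mm))
    soft = default_materials()[2]
    mat = MaterialMap(labels=np.full((n_side,) * 3, 0, dtype=np.int8),
                      materials=[soft], spacing=(voxel_mm,) * 3)
    source = np.zeros((n_side,) * 3)
    center = (n_side // 2,) * 3
    # unit concentration in the central voxel; scale so the expected decay
    # count equals n_decays with duration 1 s and fraction 1
    source[center] = n_decays / (voxel_mm**3 / 1000.0)
    src = ImageVolume(source, spacing=(voxel_mm,) * 3, unit="Bq/ml")
    dm = simulate_frame(src, mat, frame_duration_s=1.0, time_fraction=1.0,
                        seed=seed, scheme=scheme, n_batches=n_batches)

    # separate accounting of the positron kinetic component: re-run the
    # positron step alone with the same seed stream structure is not needed;
    # in track/local mode the kinetic energy not flagged escaped was
    # absorbed, so the deposited share follows from the ledger of a
    # photon-free run
    rng = np.random.default_rng(seed)
    grid = _Grid(mat)
    prim = sample_decay(scheme, rng, n_decays)
    pos = np.full((n_decays, 3), (n_side * voxel_mm) / 2.0)
    edep_beta = np.zeros(grid.n_voxels)
    esc_beta, _, _ = _transport_positrons(pos, prim, grid, edep_beta, "track")
    beta_emitted = float(prim.beta_energy_mev.sum())

    rel = dm.rel_uncertainty
    return ReferenceCubeReport(
        emitted_mev=dm.emitted_mev,
        deposited_mev=dm.deposited_mev,
        escaped_mev=dm.escaped_mev,
        beta_kinetic_emitted_mev=beta_emitted,
        beta_kinetic_deposited_mev=beta_emitted - esc_beta,
        escape_fraction=dm.escaped_mev / dm.emitted_mev,
        rel_uncertainty_center=float(rel[center]),
        rel_uncertainty_median_source=float(rel[center]),
        n_decays=dm.n_decays,
    )
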