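"""Organ-level (phantom-based) dosimetry: the MIRD schema.

Absorbed dose in a target region is the sum over source regions of the
cumulated activity times the S value, ``D(r_t) = sum_s A~_s S(r_t <- r_s)``,
with S in Gy/(MBq s) for a fixed-mass animal model.  The module also
computes residence times, mouse-to-human residence-time scaling by relative
organ mass ``(B_r/O_r) x (O_h/B_h)``, a tissue-weighted effective-dose
estimate over a small fixture human model, and the uniform-sphere
self-dose model used for tumors that have no S value of their own.

No published S-value database is redistributed; tables are read from a
documented CSV schema, and a synthetic table can be generated with the
package's own Monte Carlo engine (`svalue_table_from_mc`), which also
serves as a cross-check between the organ-level and voxel-level routes.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import CumulatedActivity

__all__ = [
    "SValueTable",
    "ResidenceTimes",
    "SphereSValueCurve",
    "mird_dose",
    "residence_time",
    "scale_residence_to_human",
    "effective_dose",
    "sphere_tumor_dose",
    "svalue_table_from_mc",
    "sphere_self_svalues",
    "default_human_model",
]


@dataclass
class SValueTable:
    """Source -> target S values [Gy/(MBq s)] plus model organ masses [g]."""

    s_values: dict[tuple[str, str], float]  # (source, target) -> S
    organ_masses_g: dict[str, float]
    body_mass_g: float
    units: str = "Gy/(MBq*s)"

    def __post_init__(self) -> None:
        for (s, t), v in self.s_values.items():
            if v < 0:
                raise ValueError(f"negative S value for {s}->{t}")
        sources = {s for s, _ in self.s_values}
        for s in sources:
            if (s, s) not in self.s_values:
                raise ValueError(f"missing self-irradiation entry for source {s!r}")
        for o, m in self.organ_masses_g.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for organ {o!r}")
        if self.body_mass_g <= 0:
            raise ValueError("body mass must be positive")

    @property
    def sources(self) -> list[str]:
        return sorted({s for s, _ in self.s_values})

    @property
    def targets(self) -> list[str]:
        return sorted({t for _, t in self.s_values})

    def get(self, source: str, target: str) -> float | None:
        return self.s_values.get((source, target))

    # -- CSV schema: metadata header lines `# body_mass_g: ...` and
    #    `# mass_g <organ>: ...`, then `source,target,s_gy_per_mbq_s` rows.
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"# body_mass_g: {self.body_mass_g}"]
        for o, m in sorted(self.organ_masses_g.items()):
            lines.append(f"# mass_g {o}: {m}")
        lines.append("source,target,s_gy_per_mbq_s")
        for (s, t), v in sorted(self.s_values.items()):
            lines.append(f"{s},{t},{v:.10e}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SValueTable":
        text = Path(path).read_text()
        body_mass = None
        masses: dict[str, float] = {}
        data_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                meta = line[1:].strip()
                if meta.startswith("body_mass_g:"):
                    body_mass = float(meta.split(":")[1])
                elif meta.startswith("mass_g"):
                    head, val = meta.split(":")
                    masses[head.split()[1]] = float(val)
            elif line.strip():
                data_lines.append(line)
        if body_mass is None:
            raise ValueError("S-value CSV lacks a '# body_mass_g:' header")
        df = pd.read_csv(io.StringIO("\n".join(data_lines)))
        s = {(r.source, r.target): float(r.s_gy_per_mbq_s) for r in df.itertuples()}
        return cls(s_values=s, organ_masses_g=masses, body_mass_g=body_mass)


@dataclass
class ResidenceTimes:
    """Per-organ residence time R = A~ / A_inj, in seconds."""

    values_s: dict[str, float]
    injected_mbq: float

    def __post_init__(self) -> None:
        for o, r in self.values_s.items():
            if r < 0:
                raise ValueError(f"negative residence time for {o!r}")
        if self.injected_mbq <= 0:
            raise ValueError("injected activity must be positive")


def mird_dose(
    cumulated: list[CumulatedActivity],
    table: SValueTable,
    injected_mbq: float | None = None,
    self_only: bool = False,
) -> tuple[dict[str, float], dict[str, float] | None]:
    """MIRD absorbed dose per target organ: ``D(r_t) = sum_s A~_s S(r_t <- r_s)``.

    Returns (dose in Gy, dose in Gy/MBq or None when no injected activity is
    given).  Source organs missing from the table are an error; missing
    cross terms contribute zero with a logged warning.  ``self_only``
    restricts the sum to self-irradiation terms.
    """
    if table.units != "Gy/(MBq*s)":
        raise ValueError(f"unexpected S-value units {table.units!r}")
    sources = [c.organ for c in cumulated]
    missing_sources = [s for s in sources if s not in table.sources]
    if missing_sources:
        raise ValueError(f"source organs absent from the S-value table: {missing_sources}")
    doses: dict[str, float] = {t: 0.0 for t in table.targets}
    for target in table.targets:
        for c in cumulated:
            if self_only and c.organ != target:
                continue
            s = table.get(c.organ, target)
            if s is None:
                warnings.warn(f"no S value for {c.organ}->{target}; term treated as zero")
                continue
            doses[target] += c.a_tilde_mbq_s * s
    per_mbq = None
    if injected_mbq is not None:
        if injected_mbq <= 0:
            raise ValueError("injected activity must be positive")
        per_mbq = {t: d / injected_mbq for t, d in doses.items()}
    return doses, per_mbq


def residence_time(cumulated: list[CumulatedActivity], injected_mbq: float
                   ) -> ResidenceTimes:
    """Residence time per organ, ``R [s] = A~ [MBq s] / A_inj [MBq]``.

    The organ mass is already inside A~ (it enters via the %ID/g-to-activity
    conversion), so no further mass factor appears here.
    """
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    return ResidenceTimes(
        values_s={c.organ: c.a_tilde_mbq_s / injected_mbq for c in cumulated},
        injected_mbq=injected_mbq,
    )


def scale_residence_to_human(
    residence: ResidenceTimes,
    mouse_body_mass_g: float,
    mouse_organ_masses_g: dict[str, float],
    human_organ_masses_g: dict[str, float],
    human_body_mass_g: float,
) -> ResidenceTimes:
    """Relative-organ-mass scaling of residence times to the human:
    ``R_h = R_m x (B_r/O_r) x (O_h/B_h)``.

    Organs without a human mass are skipped with a warning.
    """
    if mouse_body_mass_g <= 0 or human_body_mass_g <= 0:
        raise ValueError("body masses must be positive")
    out: dict[str, float] = {}
    for organ, r_m in residence.values_s.items():
        if organ not in human_organ_masses_g:
            warnings.warn(f"no human mass for organ {organ!r}; skipped")
            continue
        o_r = mouse_organ_masses_g[organ]
        o_h = human_organ_masses_g[organ]
        if o_r <= 0 or o_h <= 0:
            raise ValueError(f"non-positive organ mass for {organ!r}")
        out[organ] = r_m * (mouse_body_mass_g / o_r) * (o_h / human_body_mass_g)
    return ResidenceTimes(values_s=out, injected_mbq=residence.injected_mbq)


def effective_dose(
    residence_human: ResidenceTimes,
    human_s_table: SValueTable,
    tissue_weights: dict[str, float],
) -> tuple[float, dict[str, float]]:
    """Tissue-weighted effective dose in mSv/MBq from human residence times.

    Equivalent dose per target (radiation weighting 1 for photons and
    electrons/positrons) is ``H_t = sum_s R_s S_h(t <- s)``; the effective
    dose is ``E = sum_t w_t H_t``.  Returns (E in mSv/MBq, per-target
    equivalent doses in mSv/MBq).  A weight set not summing to 1 draws a
    warning.
    """
    w_sum = sum(tissue_weights.values())
    if abs(w_sum - 1.0) > 1e-6:
        warnings.warn(f"tissue weighting factors sum to {w_sum:.4f}, not 1")
    missing = [o for o in residence_human.values_s if o not in human_s_table.sources]
    if missing:
        raise ValueError(f"human model lacks S values for source organs: {missing}")
    equivalent: dict[str, float] = {}
    for target in human_s_table.targets:
        h = 0.0
        for source, r in residence_human.values_s.items():
            s = human_s_table.get(source, target)
            if s is None:
                continue
            h += r * s  # Gy/MBq == Sv/MBq at w_R = 1
        equivalent[target] = h * 1000.0  # mSv/MBq
    e = sum(tissue_weights.get(t, 0.0) * h for t, h in equivalent.items())
    return e, equivalent


@dataclass
class SphereSValueCurve:
    """Self-dose S of uniform unit-density spheres versus mass, log-log
    interpolated; masses strictly increasing, S strictly decreasing."""

    masses_g: np.ndarray
    s_gy_per_mbq_s: np.ndarray

    def __post_init__(self) -> None:
        self.masses_g = np.asarray(self.masses_g, dtype=float)
        self.s_gy_per_mbq_s = np.asarray(self.s_gy_per_mbq_s, dtype=float)
        if np.any(np.diff(self.masses_g) <= 0):
            raise ValueError("sphere masses must be strictly increasing")
        if np.any(np.diff(self.s_gy_per_mbq_s) >= 0):
            raise ValueError("sphere self-dose S must be strictly decreasing in mass")

    def interpolate(self, mass_g: float) -> float:
        if not (self.masses_g[0] <= mass_g <= self.masses_g[-1]):
            raise ValueError(f"sphere mass {mass_g} g outside the tabulated range "
                             f"[{self.masses_g[0]}, {self.masses_g[-1]}] g; "
                             "no extrapolation")
        return float(np.exp(np.interp(np.log(mass_g), np.log(self.masses_g),
                                      np.log(self.s_gy_per_mbq_s))))


def sphere_tumor_dose(
    tumor_cumulated: CumulatedActivity,
    curve: SphereSValueCurve,
    injected_mbq: float,
) -> float:
    """Uniform-sphere tumor dose in Gy/MBq: interpolated self-dose S times
    the tumor cumulated activity, normalised to the injected activity."""
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    s = curve.interpolate(tumor_cumulated.organ_mass_g)
    return tumor_cumulated.a_tilde_mbq_s * s / injected_mbq


# ---------------------------------------------------------------------------
# fixture human model (synthetic; not a validated phantom)
# ---------------------------------------------------------------------------

#: reference-adult-style organ masses in g for the minimal fixture model
HUMAN_ORGAN_MASSES_G = {
    "kidneys": 310.0,
    "liver": 1800.0,
    "lung": 1200.0,
    "heart": 330.0,
    "urinary_bladder": 50.0,
    "remainder": 69310.0,
}
HUMAN_BODY_MASS_G = 73000.0

#: tissue weighting factors over the modeled organ set (remainder absorbs
#: every tissue not explicitly modeled); they sum to 1 by construction
HUMAN_TISSUE_WEIGHTS = {
    "lung": 0.12,
    "liver": 0.04,
    "urinary_bladder": 0.04,
    "kidneys": 0.01,
    "heart": 0.02,
    "remainder": 0.77,
}


def default_human_model(scheme=None) -> tuple[SValueTable, dict[str, float]]:
    """Synthetic human S-value fixture plus tissue weighting factors.

    A deliberately minimal stand-in for a reference adult model, generated
    from a two-component closed form rather than any published database:
    the non-penetrating energy per decay (positron kinetic energy) is
    absorbed entirely in the source organ, and the penetrating energy
    (annihilation photons) is absorbed with a sphere-equivalent absorbed
    fraction ``phi = 1 - exp(-mu_en * r_eq)`` in the source and shared with
    every other organ through a whole-body bath term.  Explicitly not a
    validated reference-phantom replacement; it exists so the effective-dose
    chain can run end to end with plausible magnitudes.
    """
    from .decay import ga68_scheme

    scheme = scheme if scheme is not None else ga68_scheme()
    e_nonpen = scheme.beta_plus_branching * scheme.spectrum.mean_mev
    e_pen = scheme.beta_plus_branching * 1.022 \
        + scheme.prompt_gamma_intensity * scheme.prompt_gamma_mev
    mu_en_per_mm = 0.0033  # soft-tissue energy absorption at 511 keV
    organs = list(HUMAN_ORGAN_MASSES_G)
    s: dict[tuple[str, str], float] = {}

    def dose_per_decay(mev: float, mass_g: float) -> float:
        return mev * 1.602176634e-13 / (mass_g / 1000.0)

    for src in organs:
        m_src = HUMAN_ORGAN_MASSES_G[src]
        r_eq = (3.0 * m_src * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
        phi_self = 1.0 - np.exp(-mu_en_per_mm * r_eq)
        e_escaping = e_pen * (1.0 - phi_self)
        for tgt in organs:
            if tgt == src:
                e_abs = e_nonpen + e_pen * phi_self
            else:
                # escaping photon energy shared across the rest of the body
                # in proportion to mass, half lost outside the body
                share = HUMAN_ORGAN_MASSES_G[tgt] / (HUMAN_BODY_MASS_G - m_src)
                e_abs = 0.5 * e_escaping * share
            s[(src, tgt)] = dose_per_decay(e_abs, HUMAN_ORGAN_MASSES_G[tgt]) * 1e6
    table = SValueTable(s_values=s, organ_masses_g=dict(HUMAN_ORGAN_MASSES_G),
                        body_mass_g=HUMAN_BODY_MASS_G)
    return table, dict(HUMAN_TISSUE_WEIGHTS)


# ---------------------------------------------------------------------------
# synthetic tables generated with the Monte Carlo engine
# ---------------------------------------------------------------------------

def svalue_table_from_mc(
    voi,
    material_map,
    scheme=None,
    decays_per_source: int = 50_000,
    seed: int | None = None,
    organs: list[str] | None = None,
    return_uncertainty: bool = False,
):
    """Generate a synthetic S-value table for the phantom with the MC engine.

    For each source organ, a uniform unit-time activity distribution is
    simulated and the mean absorbed dose per decay in every target organ is
    converted to Gy/(MBq s) via 1 MBq s = 1e6 decays.  With
    ``return_uncertainty=True`` also returns the per-entry Monte Carlo SE
    (same units) from the engine's batch estimator.
    """
    from .mc import simulate_frame, organ_dose_rate
    from .volume import ImageVolume
    from .decay import ga68_scheme

    scheme = scheme if scheme is not None else ga68_scheme()
    organs = organs if organs is not None else voi.organs
    voxel_ml = float(np.prod(voi.spacing_mm)) / 1000.0
    masses = {}
    mass_vol = material_map.voxel_mass_g()
    for o in voi.organs:
        masses[o] = float(mass_vol[voi.masks[o]].sum())
    body_mass = float(mass_vol[material_map.labels >= 2].sum())

    s_values: dict[tuple[str, str], float] = {}
    s_se: dict[tuple[str, str], float] = {}
    rng = np.random.default_rng(seed)
    for source_organ in organs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        conc = np.zeros(voi.shape)
        conc[voi.masks[source_organ]] = decays_per_source / (
            int(np.count_nonzero(voi.masks[source_organ])) * voxel_ml)
        src = ImageVolume(conc, spacing=voi.spacing_mm, unit="Bq/ml")
        dm = simulate_frame(src, material_map, frame_duration_s=1.0,
                            time_fraction=1.0, seed=sub_seed, scheme=scheme,
                            voi=voi)
        rates = organ_dose_rate(dm, voi, material_map)
        for target_organ in organs:
            rate, se = rates[target_organ]
            s_values[(source_organ, target_organ)] = rate / dm.n_decays * 1e6
            s_se[(source_organ, target_organ)] = se / dm.n_decays * 1e6
    table = SValueTable(s_values=s_values, organ_masses_g=masses,
                        body_mass_g=body_mass)
    if return_uncertainty:
        return table, s_se
    return table


def sphere_self_svalues(
    masses_g: list[float],
    scheme=None,
    decays: int = 30_000,
    seed: int | None = None,
    voxels_per_diameter: int = 17,
) -> SphereSValueCurve:
    """Self-dose S of uniform unit-density spheres, computed with the MC
    engine on a voxelized sphere per mass node."""
    from .mc import simulate_frame
    from .materials import Material, MaterialMap
    from .volume import ImageVolume
    from .decay import ga68_scheme

    scheme = scheme if scheme is not None else ga68_scheme()
    rng = np.random.default_rng(seed)
    water = Material("sphere_tissue", 1.0, "soft_tissue", 0.555)
    air = Material("air", 0.0012, "air", 0.499)
    s_out = []
    for mass in masses_g:
        radius_mm = (3.0 * mass * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        n = voxels_per_diameter + 4
        spacing = 2.0 * radius_mm / voxels_per_diameter
        ax = (np.arange(n) - (n - 1) / 2.0) * spacing
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = x**2 + y**2 + z**2 <= radius_mm**2
        labels = np.where(inside, 1, 0).astype(np.int8)
        mat = MaterialMap(labels=labels, materials=[air, water],
                          spacing=(spacing,) * 3)
        conc = np.zeros((n,) * 3)
        conc[inside] = decays / (int(inside.sum()) * spacing**3 / 1000.0)
        src = ImageVolume(conc, spacing=(spacing,) * 3, unit="Bq/ml")
        dm = simulate_frame(src, mat, frame_duration_s=1.0, time_fraction=1.0,
                            seed=int(rng.integers(0, 2**31 - 1)), scheme=scheme)
        mass_vox = mat.voxel_mass_g()
        dose = float((dm.dose_rate.values[inside] * mass_vox[inside]).sum()
                     / mass_vox[inside].sum())
        s_out.append(dose / dm.n_decays * 1e6)
    return SphereSValueCurve(np.asarray(masses_g, float), np.asarray(s_out))
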