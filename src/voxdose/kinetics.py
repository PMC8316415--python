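"""Time-activity curves and organ pharmacokinetics.

A TAC holds an organ's decay-corrected activity concentration in %ID/g
(percent of injected dose per gram of tissue) versus minutes post
injection.  From it the module derives the standard PK summary (C_max,
T_max, T_1/2, AUC), the area under the curve with a physical-decay tail,
and the cumulated activity A-tilde (MBq s) that feeds the MIRD organ-level
dose calculation.

Kinetic fits use the one-phase association model
``y(t) = P (1 - exp(-k t))`` and the one-phase dissociation model
``y(t) = (y0 - P) exp(-k t) + P``; ``auto`` picks the lower residual sum
of squares.  Organs that accumulate monotonically (renal tract for a
PSMA ligand) are reported with the half-life flag "accumulated".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .volume import ImageVolume

__all__ = [
    "TimeActivityCurve",
    "PKParams",
    "CumulatedActivity",
    "extract_tac",
    "estimate_organ_mass",
    "fit_kinetic_model",
    "auc_with_decay_tail",
    "cumulated_activity",
    "association_model",
    "dissociation_model",
]

SOFT_TISSUE_DENSITY_G_ML = 1.04


@dataclass
class TimeActivityCurve:
    """Per-organ %ID/g versus minutes post injection."""

    organ: str
    times_min: np.ndarray
    values_pct_id_g: np.ndarray
    frame_durations_s: np.ndarray
    injected_mbq: float

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values_pct_id_g = np.asarray(self.values_pct_id_g, dtype=float)
        self.frame_durations_s = np.asarray(self.frame_durations_s, dtype=float)
        if not (len(self.times_min) == len(self.values_pct_id_g) == len(self.frame_durations_s)):
            raise ValueError("times, values and durations must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.times_min[0] < 0:
            raise ValueError("first time point must be >= 0")
        if np.any(self.values_pct_id_g < 0):
            raise ValueError("%ID/g values must be non-negative")
        if self.injected_mbq <= 0:
            raise ValueError("injected activity must be positive")

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass
class PKParams:
    """Pharmacokinetic summary of one organ TAC."""

    organ: str
    c_max: float  # %ID/g
    t_max: float  # min
    t_half: float | str  # min, or the flag "accumulated"
    auc: float  # %ID/g min
    model: str  # association | dissociation
    params: dict = field(default_factory=dict)
    rss: float = float("nan")
    degenerate: bool = False


@dataclass
class CumulatedActivity:
    """Time-integrated activity of one organ."""

    organ: str
    a_tilde_mbq_s: float
    organ_mass_g: float

    def __post_init__(self) -> None:
        if self.a_tilde_mbq_s < 0:
            raise ValueError("cumulated activity must be non-negative")
        if self.organ_mass_g <= 0:
            raise ValueError("organ mass must be positive")


def association_model(t: np.ndarray, plateau: float, k: float) -> np.ndarray:
    return plateau * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def dissociation_model(t: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    return (y0 - plateau) * np.exp(-k * np.asarray(t, dtype=float)) + plateau


def extract_tac(
    frames: list[ImageVolume],
    mask: np.ndarray,
    injected_mbq: float,
    calibration_factor: float = 1.0,
    tissue_density_g_ml: float = SOFT_TISSUE_DENSITY_G_ML,
    organ: str = "organ",
    decay_lambda_per_min: float | None = None,
) -> TimeActivityCurve:
    """Quantify the mean activity concentration in a VOI as %ID/g per frame.

    Each frame value is the VOI-mean concentration (Bq/ml), corrected by the
    scanner calibration factor, normalised to the injected activity and
    divided by the tissue density:

    ``%ID/g = mean(Bq/ml) * CF / (A_inj * 1e6 Bq) * 100 / rho``

    Frames must carry ``frame_start``/``frame_duration`` metadata; the TAC
    time base is the frame midpoint in minutes.  When
    ``decay_lambda_per_min`` is given, decay-uncorrected frames are
    corrected back to injection time by ``exp(+lambda t_mid)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("VOI mask is empty")
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    times, values, durations = [], [], []
    for i, frame in enumerate(frames):
        if frame.shape != mask.shape:
            raise ValueError(f"frame {i} grid {frame.shape} does not match mask {mask.shape}")
        if frame.frame_start is None or frame.frame_duration is None:
            raise ValueError(f"frame {i} lacks start/duration metadata")
        t_mid = (frame.frame_start + frame.frame_duration / 2.0) / 60.0
        conc = float(frame.values[mask].mean()) * calibration_factor
        pct = conc / (injected_mbq * 1e6) * 100.0 / tissue_density_g_ml
        if decay_lambda_per_min is not None:
            pct *= float(np.exp(decay_lambda_per_min * t_mid))
        times.append(t_mid)
        values.append(pct)
        durations.append(frame.frame_duration)
    return TimeActivityCurve(organ, np.array(times), np.array(values),
                             np.array(durations), injected_mbq)


def estimate_organ_mass(
    masks: np.ndarray | list[np.ndarray],
    spacing_mm: tuple[float, float, float],
    density_g_cm3: float = SOFT_TISSUE_DENSITY_G_ML,
) -> float:
    """Organ mass from VOI voxel counts: count x voxel volume x density.

    When per-time-point masks are supplied their voxel counts are averaged
    before the multiplication.
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    if isinstance(masks, np.ndarray):
        masks = [masks]
    counts = [int(np.count_nonzero(np.asarray(m, dtype=bool))) for m in masks]
    if any(c == 0 for c in counts):
        raise ValueError("empty VOI mask")
    voxel_cm3 = float(np.prod(spacing_mm)) / 1000.0
    return float(np.mean(counts)) * voxel_cm3 * density_g_cm3


def _fit_one(tac: TimeActivityCurve, model: str) -> PKParams:
    t, y = tac.times_min, tac.values_pct_id_g
    span = max(t[-1] - t[0], 1.0)
    try:
        if model == "association":
            p0 = (max(y.max(), 1e-6), 1.0 / span)
            popt, _ = curve_fit(association_model, t, y, p0=p0, maxfev=20000,
                                bounds=([0.0, 0.0], [np.inf, np.inf]))
            params = {"plateau": popt[0], "k": popt[1]}
            fitted = association_model(t, *popt)
        elif model == "dissociation":
            p0 = (max(y[0], 1e-6), max(min(y.min(), y[-1]), 0.0), 1.0 / span)
            popt, _ = curve_fit(dissociation_model, t, y, p0=p0, maxfev=20000,
                                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]))
            params = {"y0": popt[0], "plateau": popt[1], "k": popt[2]}
            fitted = dissociation_model(t, *popt)
        else:
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError as err:
        raise RuntimeError(f"kinetic fit did not converge for organ "
                           f"{tac.organ!r} with model {model!r}") from err
    rss = float(np.sum((fitted - y) ** 2))
    k = params["k"]
    degenerate = bool(k <= 0.0)

    # summary statistics from the fitted curve over the observed window
    grid = np.linspace(t[0], t[-1], 2001)
    curve = (association_model(grid, params["plateau"], k) if model == "association"
             else dissociation_model(grid, params["y0"], params["plateau"], k))
    i_max = int(np.argmax(curve))
    c_max, t_max = float(curve[i_max]), float(grid[i_max])

    # "accumulated": an accumulating organ with no washout phase in the
    # study window.  A rising dissociation fit (y0 < plateau) is the same
    # curve family as association with a free intercept, so the flag keys
    # on the fitted shape: the curve rises throughout and either the raw
    # data never decreases or the fitted accumulation has not plateaued by
    # the last observation (robust to noise breaking strict monotonicity).
    rising_fit = model == "association" or params.get("y0", np.inf) < params["plateau"]
    monotone_up = bool(np.all(np.diff(tac.values_pct_id_g) >= 0))
    still_rising = bool(params["plateau"] > 0
                        and curve[-1] < 0.95 * params["plateau"])
    if rising_fit and (monotone_up or still_rising):
        t_half: float | str = "accumulated"
        c_max = float(tac.values_pct_id_g[-1])
        t_max = float(tac.times_min[-1])
    elif degenerate:
        t_half = float("inf")
    else:
        t_half = float(np.log(2.0) / k)

    auc = float(np.trapezoid(curve, grid))
    return PKParams(tac.organ, c_max, t_max, t_half, auc, model,
                    params=params, rss=rss, degenerate=degenerate)


def fit_kinetic_model(tac: TimeActivityCurve, model: str = "auto") -> PKParams:
    """Least-squares fit of the one-phase association or dissociation model.

    ``model='auto'`` fits both and keeps the lower residual sum of squares.
    Monotonically increasing data best fit by the association model are
    flagged ``t_half='accumulated'`` with C_max/T_max at the last
    observation.  A zero rate constant at the optimum is flagged degenerate.
    """
    if len(tac) < 3:
        raise ValueError("kinetic fitting needs at least 3 time points")
    if model in ("association", "dissociation"):
        return _fit_one(tac, model)
    if model != "auto":
        raise ValueError(f"unknown model {model!r}")
    fits = []
    for m in ("association", "dissociation"):
        try:
            fits.append(_fit_one(tac, m))
        except RuntimeError:
            pass
    if not fits:
        raise RuntimeError(f"no kinetic model converged for organ {tac.organ!r}")
    return min(fits, key=lambda p: p.rss)


def auc_with_decay_tail(tac: TimeActivityCurve, lambda_phys_per_min: float) -> float:
    """AUC in %ID/g min: trapezoid over the observations plus a decay tail.

    The observed span is integrated by the trapezoid rule, with a leading
    linear segment from (0, 0) to the first observation; beyond the last
    observation the curve is assumed to follow physical decay only, giving
    a closed-form tail ``y(t_last) / lambda``.
    """
    if lambda_phys_per_min <= 0:
        raise ValueError("physical decay constant must be positive")
    t, y = tac.times_min, tac.values_pct_id_g
    if t[-1] > 300.0:
        warnings.warn("TAC extends beyond 300 min; tail extrapolation starts "
                      "at the last observation")
    tail = float(y[-1] / lambda_phys_per_min)
    if len(t) == 1:
        warnings.warn("single time point: AUC is the decay tail only")
        return tail
    leading = float(0.5 * t[0] * y[0]) if t[0] > 0 else 0.0
    return leading + float(np.trapezoid(y, t)) + tail


def cumulated_activity(
    tac: TimeActivityCurve,
    organ_mass_g: float,
    lambda_phys_per_min: float,
    injected_mbq: float | None = None,
    decay_corrected: bool = True,
) -> CumulatedActivity:
    """Cumulated activity A-tilde [MBq s] of an organ from its TAC.

    ``A~ = AUC[%ID/g min] / 100 * O_m[g] * A_inj[MBq] * 60 s/min``

    A-tilde counts physical decays, so the AUC must be taken over the
    decay-*uncorrected* curve (trapezoid plus physical-decay tail).  With
    ``decay_corrected=True`` (the convention for stored TACs) the curve is
    multiplied by ``exp(-lambda t)`` before integration.
    """
    a_inj = tac.injected_mbq if injected_mbq is None else injected_mbq
    if a_inj <= 0 or organ_mass_g <= 0:
        raise ValueError("organ mass and injected activity must be positive")
    curve = tac
    if decay_corrected:
        curve = TimeActivityCurve(
            tac.organ, tac.times_min,
            tac.values_pct_id_g * np.exp(-lambda_phys_per_min * tac.times_min),
            tac.frame_durations_s, a_inj)
    auc = auc_with_decay_tail(curve, lambda_phys_per_min)
    a_tilde = auc / 100.0 * organ_mass_g * a_inj * 60.0
    return CumulatedActivity(tac.organ, a_tilde, organ_mass_g)
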