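"""Result tables: voxel-vs-organ dose comparison, group statistics, DVHs.

Aggregation convention: per-subject pipeline outputs are summarised as
mean +/- SEM, and method or group comparisons use the two-sided unpaired
Student t-test with pooled variance (df = n1 + n2 - 2); a Welch option and
a paired option exist.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import ImageVolume

__all__ = ["DoseComparison", "DVHCurve", "compare_methods", "group_stats", "dvh"]


@dataclass
class GroupStats:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    df: int
    p: float


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of the VOI receiving at
    least each dose level."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("DVH must be monotone non-increasing")


#: columns of the comparison table
DoseComparison = pd.DataFrame


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def group_stats(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    welch: bool = False,
) -> GroupStats:
    """Two-sided t-test between two groups of per-subject values.

    Default is the unpaired pooled-variance Student test (df = n1+n2-2);
    ``welch=True`` drops the equal-variance assumption, ``paired=True``
    runs the paired test.  Two identical constant groups give t=0, P=1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal group sizes")
        res = stats.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = int(res.df) if welch else len(a) + len(b) - 2
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups
        t, p = 0.0, 1.0
    return GroupStats(float(a.mean()), _sem(a), float(b.mean()), _sem(b), t, df, p)


def compare_methods(
    voxel_by_subject: dict[str, np.ndarray],
    organ_by_subject: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-organ comparison of voxel-level and organ-level absorbed dose.

    Inputs map organ -> per-subject Gy/MBq arrays (same organs and subject
    count on both sides).  Output columns: the two means with SEMs, the
    difference organ - voxel, and the unpaired Student t statistic,
    df = n1+n2-2 and two-sided P.  With a single subject only the
    difference is reported.  An organ present on the voxel side only (a
    tumor without an S value) gets NaN organ-level entries.
    """
    rows = []
    for organ, vox in voxel_by_subject.items():
        vox = np.atleast_1d(np.asarray(vox, dtype=float))
        org = organ_by_subject.get(organ)
        if org is None:
            rows.append({"organ": organ, "voxel_gy_mbq": vox.mean(),
                         "voxel_sem": _sem(vox), "organ_gy_mbq": np.nan,
                         "organ_sem": np.nan, "difference": np.nan,
                         "t": np.nan, "df": np.nan, "p": np.nan})
            continue
        org = np.atleast_1d(np.asarray(org, dtype=float))
        if len(org) != len(vox):
            raise ValueError(f"subject count mismatch for organ {organ!r}")
        row = {"organ": organ, "voxel_gy_mbq": vox.mean(), "voxel_sem": _sem(vox),
               "organ_gy_mbq": org.mean(), "organ_sem": _sem(org),
               "difference": org.mean() - vox.mean()}
        if len(vox) >= 2:
            gs = group_stats(org, vox)
            row.update({"t": gs.t, "df": gs.df, "p": gs.p})
        else:
            row.update({"t": np.nan, "df": np.nan, "p": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def dvh(dose_map: ImageVolume, mask: np.ndarray, bins: int | np.ndarray = 100
        ) -> DVHCurve:
    """Cumulative DVH of a VOI: fraction of its volume receiving >= dose.

    The curve starts at 1 at dose 0 and reaches 0 above the maximum voxel
    dose.  ``bins`` is a count (grid spans 0 to just past the max) or an
    explicit dose grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty VOI mask")
    doses = dose_map.values[mask]
    if np.any(doses < 0):
        raise ValueError("negative doses in the DVH input")
    if isinstance(bins, (int, np.integer)):
        top = doses.max() * 1.001 if doses.max() > 0 else 1.0
        grid = np.linspace(0.0, top, int(bins) + 1)
    else:
        grid = np.asarray(bins, dtype=float)
    frac = np.array([(doses >= d).mean() if d > 0 else 1.0 for d in grid])
    return DVHCurve(dose_gy=grid, volume_fraction=frac)
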