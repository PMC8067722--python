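"""Global and local agreement metrics between model and measured fields.

Global: percent error in predicted tumor volume (the model volume counts
voxels with phi_T at or above the tumor-extent threshold) and the Dice
overlap of model and measured tumor masks.  Local: Pearson (PCC) and Lin
concordance (CCC) correlation of the voxelwise volume fractions over the
union of the measured and model masks.  Forecast evaluation computes every
metric at each comparison visit for each sampled parameter set, averages
across visits per set, and summarizes the per-set values as box-plot
statistics; selected-vs-ensemble differences are tested with the two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import AnimalDataset, Grid3D

METRIC_NAMES = ("volume_error_pct", "dice", "pcc_T", "ccc_T", "pcc_V", "ccc_V")


def percent_volume_error(model_phi_T: np.ndarray, measured_mask: np.ndarray,
                         threshold: float, voxel_volume: float = 1.0) -> float:
    """100 * (V_model - V_meas) / V_meas with thresholded model volume."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    v_meas = float(np.asarray(measured_mask, bool).sum()) * voxel_volume
    if v_meas == 0:
        raise ValueError("measured tumor volume is zero")
    v_model = float((np.asarray(model_phi_T) >= threshold).sum()) * voxel_volume
    return 100.0 * (v_model - v_meas) / v_meas


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B|/(|A|+|B|); two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two voxel samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two evaluation voxels")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin concordance: 2 cov / (var_x + var_y + (mean_x - mean_y)^2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two evaluation voxels")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise ValueError("zero variance; concordance undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


@dataclass
class MetricReport:
    """Per-parameter-set time-averaged metrics plus raw per-visit values."""

    per_set: pd.DataFrame          # rows: parameter sets; cols: METRIC_NAMES
    per_visit: pd.DataFrame        # long: sample, day, metric, value
    threshold: float
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.summary = self.per_set.describe(percentiles=[0.25, 0.5, 0.75])


def _visit_metrics(phi_T_model, phi_V_model, visit, threshold, voxel_volume,
                   brain_mask) -> dict[str, float]:
    meas_mask = np.asarray(visit.tumor_mask, dtype=bool)
    model_mask = (phi_T_model >= threshold) & brain_mask
    support = (meas_mask | model_mask)
    out = {
        "volume_error_pct": percent_volume_error(np.where(brain_mask, phi_T_model, 0.0),
                                                 meas_mask, threshold, voxel_volume),
        "dice": dice(model_mask, meas_mask),
    }
    if support.sum() >= 2:
        for name, model, meas in (("T", phi_T_model, visit.phi_T),
                                  ("V", phi_V_model, visit.phi_V)):
            x = np.asarray(meas)[support]
            y = np.asarray(model)[support]
            try:
                out[f"pcc_{name}"] = pcc(x, y)
                out[f"ccc_{name}"] = ccc(x, y)
            except ValueError:
                out[f"pcc_{name}"] = np.nan
                out[f"ccc_{name}"] = np.nan
    else:
        out.update({k: np.nan for k in ("pcc_T", "ccc_T", "pcc_V", "ccc_V")})
    return out


def evaluate_forecast(trajectories, dataset: AnimalDataset, visit_indices,
                      threshold: float) -> MetricReport:
    """Metrics of an ensemble of sampled-parameter trajectories.

    ``trajectories`` is a sequence (one per sampled parameter set) of
    objects with ``phi_T[day]``/``phi_V[day]`` field dictionaries.  For
    each set, metrics are computed at every comparison visit and averaged
    across visits.
    """
    visits = [dataset.visits[i] for i in visit_indices]
    if not visits:
        raise ValueError("no comparison visits")
    grid = dataset.grid
    rows_visit = []
    rows_set = []
    for j, traj in enumerate(trajectories):
        per_visit_vals = {m: [] for m in METRIC_NAMES}
        for v in visits:
            if v.day not in traj.phi_T:
                raise ValueError(f"trajectory lacks day {v.day}")
            vals = _visit_metrics(traj.phi_T[v.day], traj.phi_V[v.day], v,
                                  threshold, grid.voxel_volume, grid.brain_mask)
            for m in METRIC_NAMES:
                per_visit_vals[m].append(vals[m])
                rows_visit.append({"sample": j, "day": v.day, "metric": m,
                                   "value": vals[m]})
        rows_set.append({m: float(np.nanmean(per_visit_vals[m])) for m in METRIC_NAMES})
    per_set = pd.DataFrame(rows_set)
    per_visit = pd.DataFrame(rows_visit)
    return MetricReport(per_set=per_set, per_visit=per_visit, threshold=threshold)


def compare_selected_vs_ensemble(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value between two
    metric samples; exact for small tie-free samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if np.array_equal(a, b) and np.ptp(a) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
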