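"""Segmentation evaluation: DSC, HD95, volume-difference statistics.

Per case and tissue class the evaluation reports the Dice similarity
coefficient (DSC), the 95th-percentile Hausdorff distance (HD95, mm) and
the signed average volume difference

    AVD% = (V_GT - V_M) / V_GT * 100,

negative when the model overestimates.  Model comparison uses Welch's
t-test on per-case DSC with Bonferroni correction, and uncertainty is
quantified with delete-one jackknife confidence intervals.

Conventions pinned here: HD95 is the 95th percentile (linear interpolation
between order statistics) of the pooled bidirectional set of border-to-
nearest-border distances, with border voxels defined by 6-connectivity
(a mask voxel with at least one face-adjacent non-mask neighbour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import CLASS_NAMES, TISSUE_CLASSES, TissueLabelMap


class UndefinedMetricError(ValueError):
    """A metric is undefined for this input (e.g. empty mask); record the
    value as missing, never as 0."""


# ---------------------------------------------------------------------------
# per-mask metrics
# ---------------------------------------------------------------------------

def dsc(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)``.

    Defined as 1.0 when both masks are empty (perfect agreement on absence).
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes disagree: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent (6-connected) non-mask
    neighbour; voxels on the array boundary count as border."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~interior


def hd95(pred_mask: np.ndarray, gt_mask: np.ndarray,
         spacing: tuple[float, float, float]) -> float:
    """95th-percentile symmetric surface distance in mm.

    Border voxels of each mask are extracted, both directed nearest-
    neighbour distance sets are computed in physical units, and the 95th
    percentile of the pooled bidirectional set is returned.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes disagree: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise UndefinedMetricError("hd95 undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(border_voxels(a)) * spacing
    pb = np.argwhere(border_voxels(b)) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def volume_of_class(labels: TissueLabelMap, c: int,
                    spacing: tuple[float, float, float] | None = None) -> float:
    """Volume of class ``c`` in millilitres (voxel count x voxel volume)."""
    data = labels.data if isinstance(labels, TissueLabelMap) else np.asarray(labels)
    if spacing is None:
        if not isinstance(labels, TissueLabelMap):
            raise ValueError("spacing required when labels is a bare array")
        spacing = labels.spacing
    count = int((data == c).sum())
    return count * float(np.prod(spacing)) / 1000.0


def signed_avd(v_gt: float, v_model: float) -> float:
    """Signed average volume difference in percent.

    ``(V_GT - V_M) / V_GT * 100``; negative when the model overestimates.
    """
    if v_gt <= 0:
        raise UndefinedMetricError(f"signed AVD undefined for V_GT = {v_gt}")
    return (v_gt - v_model) / v_gt * 100.0


# ---------------------------------------------------------------------------
# per-case records
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    """Evaluation of one (case, tissue class) pair.

    ``hd95_mm`` is ``None`` when either mask is empty (metric undefined).
    """

    case_id: str
    tissue: str
    dsc: float
    hd95_mm: float | None
    v_gt_ml: float
    v_model_ml: float
    avd_signed_pct: float
    avd_abs_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"DSC out of [0, 1]: {self.dsc}")
        if self.hd95_mm is not None and self.hd95_mm < 0:
            raise ValueError(f"negative HD95: {self.hd95_mm}")
        if self.v_gt_ml < 0 or self.v_model_ml < 0:
            raise ValueError("volumes must be non-negative")
        if not math.isclose(self.avd_abs_pct, abs(self.avd_signed_pct),
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("avd_abs must equal |avd_signed|")


def evaluate_case(pred: TissueLabelMap, truth: TissueLabelMap,
                  case_id: str = "") -> list[MetricsRecord]:
    """Per-class metrics for one case (WM, GM, CSF; background excluded)."""
    if pred.shape != truth.shape:
        raise ValueError(f"grids disagree: {pred.shape} vs {truth.shape}")
    records = []
    for c in TISSUE_CLASSES:
        pm = pred.data == c
        gm_ = truth.data == c
        v_gt = volume_of_class(truth, c)
        v_model = volume_of_class(pred, c)
        try:
            h = hd95(pm, gm_, truth.spacing)
        except UndefinedMetricError:
            h = None
        avd = signed_avd(v_gt, v_model) if v_gt > 0 else float("nan")
        records.append(MetricsRecord(
            case_id=case_id, tissue=CLASS_NAMES[c], dsc=dsc(pm, gm_), hd95_mm=h,
            v_gt_ml=v_gt, v_model_ml=v_model,
            avd_signed_pct=avd, avd_abs_pct=abs(avd)))
    return records


def records_to_frame(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def absolute_avd_summary(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Mean absolute AVD per tissue class, plus the all-class grand mean
    (the single-number volumetric-error figure of merit)."""
    frame = records_to_frame(list(records))
    frame = frame.dropna(subset=["avd_abs_pct"])
    if frame.empty:
        raise ValueError("no records with defined AVD")
    rows = []
    for tissue, grp in frame.groupby("tissue", sort=False):
        rows.append({"tissue": tissue,
                     "mean_abs_avd_pct": float(grp["avd_abs_pct"].mean()),
                     "sd_abs_avd_pct": float(grp["avd_abs_pct"].std(ddof=1))
                     if len(grp) > 1 else 0.0,
                     "n": int(len(grp))})
    rows.append({"tissue": "all",
                 "mean_abs_avd_pct": float(
                     np.mean([r["mean_abs_avd_pct"] for r in rows])),
                 "sd_abs_avd_pct": float("nan"),
                 "n": int(len(frame))})
    return pd.DataFrame(rows)


def bland_altman_points(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Agreement points: x = mean of the two volume estimates (mL),
    y = signed AVD (%); one point per record, plus the mean-difference line
    value in the frame attribute ``mean_line``."""
    frame = records_to_frame(list(records))
    pts = pd.DataFrame({
        "case_id": frame["case_id"],
        "tissue": frame["tissue"],
        "mean_volume_ml": (frame["v_gt_ml"] + frame["v_model_ml"]) / 2.0,
        "avd_signed_pct": frame["avd_signed_pct"],
    })
    pts.attrs["mean_line"] = float(frame["avd_signed_pct"].mean())
    return pts


def plot_bland_altman(records: Sequence[MetricsRecord], ax=None):
    """Bland-Altman agreement plot: signed AVD% against mean volume, one
    marker per (case, class), with the mean-difference line."""
    import matplotlib.pyplot as plt

    pts = bland_altman_points(records)
    if ax is None:
        _, ax = plt.subplots()
    for tissue, grp in pts.groupby("tissue", sort=False):
        ax.scatter(grp["mean_volume_ml"], grp["avd_signed_pct"], label=tissue)
    ax.axhline(pts.attrs["mean_line"], linestyle="--", color="grey")
    ax.axhline(0.0, linewidth=0.5, color="black")
    ax.set_xlabel("mean volume (mL)")
    ax.set_ylabel("signed AVD (%)")
    ax.legend()
    return ax


# ---------------------------------------------------------------------------
# uncertainty and testing
# ---------------------------------------------------------------------------

def jackknife_ci(per_case_values: Sequence[float],
                 level: float = 0.95) -> tuple[float, float]:
    """Delete-one jackknife confidence interval for the mean.

    Builds the n leave-one-out replicate means, computes the jackknife
    standard error and returns the normal-approximation interval
    ``mean +- z * SE``.
    """
    values = np.asarray(per_case_values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"jackknife CI needs at least 3 cases, got {n}")
    total = values.sum()
    loo = (total - values) / (n - 1)           # leave-one-out means
    se = math.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    mean = float(values.mean())
    return mean - z * se, mean + z * se


def welch_test(sample_a: Sequence[float], sample_b: Sequence[float],
               ) -> tuple[float, float, float]:
    """Welch's two-sided t-test: ``(t, satterthwaite_dof, p)``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate samples: both variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni(p: float, m: int = 7) -> float:
    """Bonferroni-corrected p-value ``min(1, m * p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    return min(1.0, m * p)


@dataclass
class ComparisonReport:
    """Welch + Bonferroni comparison of one model pair for one tissue."""

    model_a: str
    model_b: str
    tissue: str
    t: float
    dof: float
    p_raw: float
    p_corrected: float

    def __post_init__(self) -> None:
        if self.p_corrected < self.p_raw - 1e-12 or self.p_corrected > 1.0:
            raise ValueError("corrected p must satisfy p_raw <= p_corr <= 1")


def compare_models(dsc_by_model: dict[str, dict[str, Sequence[float]]],
                   reference: str, m: int = 7) -> list[ComparisonReport]:
    """Compare each model's per-case DSC against ``reference``, per tissue.

    ``dsc_by_model`` maps model name -> tissue -> per-case DSC values.
    """
    if reference not in dsc_by_model:
        raise KeyError(f"reference model {reference!r} not in results")
    reports = []
    for name, by_tissue in dsc_by_model.items():
        if name == reference:
            continue
        for tissue, values in by_tissue.items():
            t, dof, p = welch_test(dsc_by_model[reference][tissue], values)
            reports.append(ComparisonReport(
                model_a=reference, model_b=name, tissue=tissue,
                t=t, dof=dof, p_raw=p, p_corrected=bonferroni(p, m)))
    return reports


def summarize(records: Sequence[MetricsRecord], min_ci_n: int = 3) -> pd.DataFrame:
    """Per-class summary: mean DSC / HD95 / absolute AVD with jackknife CIs
    (CIs omitted when fewer than ``min_ci_n`` cases)."""
    frame = records_to_frame(list(records))
    rows = []
    for tissue, grp in frame.groupby("tissue", sort=False):
        row: dict = {"tissue": tissue, "n": int(len(grp))}
        for col, name in [("dsc", "dsc"), ("hd95_mm", "hd95_mm"),
                          ("avd_abs_pct", "abs_avd_pct")]:
            vals = grp[col].dropna().to_numpy(dtype=float)
            row[f"mean_{name}"] = float(vals.mean()) if vals.size else float("nan")
            if vals.size >= min_ci_n:
                lo, hi = jackknife_ci(vals)
                row[f"{name}_ci_lo"], row[f"{name}_ci_hi"] = lo, hi
            else:
                row[f"{name}_ci_lo"] = row[f"{name}_ci_hi"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
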