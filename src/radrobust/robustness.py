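"""Concordance statistics and dual-threshold robustness classification.

Inter-annotator agreement is quantified per feature with the Shrout-Fleiss
ICC(3,1) (two-way mixed model, single rater, consistency) between the two
annotators' values, separately on HD and LD scans.  Inter-protocol
agreement uses Lin's concordance correlation coefficient between HD and LD
values, separately per center.  A feature is *robust* when all four
coefficients reach the threshold (0.75 by default, compared with ``>=``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataset import AnalysisConfig, CohortDataset

__all__ = [
    "dice_coefficient",
    "icc_3_1",
    "lin_ccc",
    "concordance_table",
    "deviation_profile",
]


def dice_coefficient(mask_a, mask_b) -> float:
    """Dice similarity ``2|A∩B| / (|A| + |B|)`` between two binary masks.

    Masks may be boolean arrays on a common grid or iterables of voxel
    coordinates.  Undefined (raises) when both masks are empty.
    """
    def to_voxels(mask):
        # ndarray -> boolean grid; anything else -> iterable of coordinates
        if isinstance(mask, np.ndarray):
            return set(map(tuple, np.argwhere(mask.astype(bool))))
        return {tuple(np.ravel(v)) for v in mask}

    a_set = to_voxels(mask_a)
    b_set = to_voxels(mask_b)
    total = len(a_set) + len(b_set)
    if total == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * len(a_set & b_set) / total


def icc_3_1(x, y) -> float:
    """ICC(3,1): two-way mixed, single-measure, consistency, two raters.

    Computed from the subjects x raters ANOVA decomposition as
    ``(MS_rows - MS_err) / (MS_rows + (k-1) MS_err)`` with ``k = 2``.
    Consistency form: invariant to a constant shift of one rater.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("ICC requires finite values")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        raise ValueError("ICC undefined: no subject variance")
    return float((ms_rows - ms_err) / denom)


def lin_ccc(x, y, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient.

    ``2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with moment
    estimates using ``1/n`` denominators by default (``ddof=0``, Lin 1989);
    ``ddof=1`` gives the sample-moment variant some implementations use.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("CCC requires at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("CCC requires finite values")
    mx, my = x.mean(), y.mean()
    d = n - ddof
    sx2 = ((x - mx) ** 2).sum() / d
    sy2 = ((y - my) ** 2).sum() / d
    sxy = ((x - mx) * (y - my)).sum() / d
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both vectors constant and equal")
    return float(2.0 * sxy / denom)


def _safe(stat, *vectors) -> float:
    try:
        return stat(*vectors)
    except ValueError:
        return float("nan")


def concordance_table(
    dataset: CohortDataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-feature concordance coefficients and robustness flags.

    ``icc_hd``/``icc_ld`` compare annotator A vs B on the dual-annotator
    subset; ``ccc_a``/``ccc_b`` compare HD vs LD (annotator A) within each
    center.  Flags:

    * ``inter_annotator_robust``: min(icc_hd, icc_ld) >= threshold,
    * ``inter_protocol_robust``: min(ccc_a, ccc_b) >= threshold,
    * ``robust``: both.

    A feature with an undefined coefficient gets NaN there and
    ``robust=False``.
    """
    cfg = config or AnalysisConfig()
    dual = dataset.dual_ids
    if len(dual) == 0:
        raise ValueError("concordance_table requires a dual-annotator subset")
    ids_a = dataset.center_ids("A")
    ids_b = dataset.center_ids("B")

    hd_a = dataset.matrices["HD_A"]
    ld_a = dataset.matrices["LD_A"]
    hd_b = dataset.matrices["HD_B"]
    ld_b = dataset.matrices["LD_B"]

    def meets(v: float) -> bool:
        if not np.isfinite(v):
            return False
        t = cfg.robustness_threshold
        return v > t if cfg.strict_threshold else v >= t

    rows = []
    for feat in dataset.feature_names:
        icc_hd = _safe(icc_3_1, hd_a.loc[dual, feat], hd_b.loc[dual, feat])
        icc_ld = _safe(icc_3_1, ld_a.loc[dual, feat], ld_b.loc[dual, feat])
        ccc_a = _safe(lin_ccc, hd_a.loc[ids_a, feat], ld_a.loc[ids_a, feat])
        ccc_b = (
            _safe(lin_ccc, hd_a.loc[ids_b, feat], ld_a.loc[ids_b, feat])
            if len(ids_b) >= 2
            else float("nan")
        )
        ann = meets(icc_hd) and meets(icc_ld)
        prot = meets(ccc_a) and meets(ccc_b)
        rows.append(
            {
                "feature": feat,
                "icc_hd": icc_hd,
                "icc_ld": icc_ld,
                "ccc_a": ccc_a,
                "ccc_b": ccc_b,
                "inter_annotator_robust": ann,
                "inter_protocol_robust": prot,
                "robust": ann and prot,
            }
        )
    return pd.DataFrame(rows)


def deviation_profile(
    dataset: CohortDataset, records: pd.DataFrame
) -> pd.DataFrame:
    """Per patient x feature |Z_A - Z_B| against the segmentation Dice score.

    Both annotators' values are Z-scored with the annotator-A mean/SD over
    the dual-annotator subset (sample SD); constant features are skipped
    with a warning.  Returns a long table with columns ``patient_id,
    feature, protocol, abs_z_delta, dice, robust``.
    """
    dual = dataset.dual_ids
    if len(dual) == 0:
        raise ValueError("deviation_profile requires a dual-annotator subset")
    robust_of = dict(zip(records["feature"], records["robust"]))
    frames = []
    for protocol, dice_col in (("HD", "dice_hd"), ("LD", "dice_ld")):
        a = dataset.matrices[f"{protocol}_A"].loc[dual]
        b = dataset.matrices[f"{protocol}_B"].loc[dual]
        mu = a.mean(axis=0)
        sd = a.std(axis=0, ddof=1)
        keep = sd > 0
        if (~keep).any():
            warnings.warn(
                f"{(~keep).sum()} constant feature(s) skipped in deviation profile",
                stacklevel=2,
            )
        za = (a.loc[:, keep] - mu[keep]) / sd[keep]
        zb = (b.loc[:, keep] - mu[keep]) / sd[keep]
        dz = (za - zb).abs()
        long = dz.rename_axis("patient_id").reset_index().melt(
            id_vars="patient_id", var_name="feature", value_name="abs_z_delta"
        )
        long["protocol"] = protocol
        long["dice"] = long["patient_id"].map(dataset.meta[dice_col])
        long["robust"] = long["feature"].map(robust_of).astype(bool)
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[["patient_id", "feature", "protocol", "abs_z_delta", "dice", "robust"]]
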