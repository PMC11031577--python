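"""Per-feature predictive screening and group comparisons.

Each feature is screened alone: a logistic model (binary endpoints) or a
Cox proportional-hazards model (survival endpoint) is fitted on a whole
center's patients and evaluated on the same patients — apparent
(resubstitution) performance, which is the intended design for this
screening stage.  Effect sizes are odds/hazard ratios of the Z-scored
feature, *oriented* to ``max(r, 1/r)`` so magnitudes are comparable
regardless of effect direction.  Feature groups (robust / non-robust HD /
non-robust LD) are then compared with Wilcoxon-Mann-Whitney tests under
Bonferroni-Holm correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .dataset import AnalysisConfig, CohortDataset

__all__ = [
    "fit_logistic_univariate",
    "fit_cox_univariate",
    "roc_auc",
    "harrell_c",
    "orient_ratio",
    "run_univariate_screen",
    "wilcoxon_mw",
    "holm_adjust",
    "compare_groups",
]

_BETA_CAP = 20.0  # |beta| beyond this on a Z-scored covariate = separation


@dataclass
class UnivariateFit:
    beta: float
    intercept: float
    converged: bool
    flagged: bool  # separation / monotone likelihood


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant covariate")
    return (x - x.mean()) / sd


def fit_logistic_univariate(x, y) -> UnivariateFit:
    """ML logistic fit of ``y`` on the standardized covariate ``x``.

    Complete or quasi-complete separation is flagged and the coefficient
    capped at +/-20 (such fits are excluded from odds-ratio summaries).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    xs = _standardize(x)
    X = sm.add_constant(xs)
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            intercept, beta = res.params
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # PerfectSeparationError and numerical failures
            converged = False
            intercept, beta = 0.0, np.nan
    if not converged or not np.isfinite(beta) or abs(beta) > _BETA_CAP:
        flagged = True
        if not np.isfinite(beta):
            # refit with heavy regularization only to recover the sign
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
            intercept, beta = res.params
        beta = float(np.clip(beta, -_BETA_CAP, _BETA_CAP))
    return UnivariateFit(float(beta), float(intercept), converged, flagged)


def fit_cox_univariate(x, time, event) -> UnivariateFit:
    """Univariate Cox PH fit (Efron ties) of the standardized covariate."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    xs = _standardize(x)
    df = pd.DataFrame({"x": xs, "time": time, "event": event})
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            beta = float(cph.params_["x"])
            converged = True
        except Exception:
            beta = np.nan
            converged = False
    if not converged or not np.isfinite(beta) or abs(beta) > _BETA_CAP:
        flagged = True
        beta = float(np.clip(np.nan_to_num(beta), -_BETA_CAP, _BETA_CAP))
    return UnivariateFit(beta, 0.0, converged, flagged)


def roc_auc(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney rank formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance index for right-censored data.

    Usable pairs: the earlier time carries an event.  Concordant when the
    earlier-event subject has the higher risk; tied risks count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(risk)
    conc = 0.0
    usable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        mask = (time > time[i]) | ((time == time[i]) & (event == 0))
        usable += int(mask.sum())
        conc += (risk[mask] < risk[i]).sum() + 0.5 * (risk[mask] == risk[i]).sum()
    if usable == 0:
        raise ValueError("no usable pairs for concordance")
    return float(conc / usable)


def orient_ratio(r: float) -> float:
    """Map an odds/hazard ratio to ``max(r, 1/r)`` (effect magnitude)."""
    if not r > 0:
        raise ValueError("ratio must be positive")
    return float(max(r, 1.0 / r))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def _assign_groups(
    records: pd.DataFrame, feature_names: list[str], robust_protocol: str
) -> list[tuple[str, str, str]]:
    """(feature, group, protocol) rows to screen.

    Robust features contribute one row (HD values by default); each
    non-robust feature contributes one HD and one LD row.
    """
    robust = set(records.loc[records["robust"], "feature"])
    rows = []
    for feat in feature_names:
        if feat in robust:
            proto = "HD" if robust_protocol == "mean" else robust_protocol
            rows.append((feat, "robust", proto))
        else:
            rows.append((feat, "nonrobust_HD", "HD"))
            rows.append((feat, "nonrobust_LD", "LD"))
    return rows


def run_univariate_screen(
    dataset: CohortDataset,
    records: pd.DataFrame,
    endpoint: str,
    center: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Screen every feature against one endpoint within one center.

    Returns a frame with columns ``feature, group, endpoint, center,
    metric, oriented_ratio, flagged``; ``metric`` is the apparent AUC
    (binary) or Harrell concordance (survival).
    """
    cfg = config or AnalysisConfig()
    ids = dataset.center_ids(center)
    sub = dataset.subset(ids)
    frame = sub.endpoint_frame(endpoint)
    if endpoint in ("recurrence", "recurrence_3y"):
        n_pos = int(frame["y"].sum())
        if min(n_pos, len(frame) - n_pos) < 5:
            warnings.warn(
                f"endpoint {endpoint!r} in center {center!r} has < 5 members in a"
                " class; results flagged",
                stacklevel=2,
            )
    rows = []
    for feat, group, proto in _assign_groups(
        records, sub.feature_names, cfg.robust_protocol
    ):
        mat = sub.matrices[f"{proto}_A"]
        x = mat.loc[frame.index, feat].to_numpy()
        if x.std(ddof=1) == 0:
            continue
        if endpoint == "rfs":
            fit = fit_cox_univariate(x, frame["time"], frame["event"])
            risk = _standardize(x) * fit.beta
            metric = harrell_c(risk, frame["time"], frame["event"])
        else:
            y = frame["y"].to_numpy()
            fit = fit_logistic_univariate(x, y)
            metric = roc_auc(_standardize(x) * np.sign(fit.beta or 1.0), y)
        rows.append(
            {
                "feature": feat,
                "group": group,
                "endpoint": endpoint,
                "center": center,
                "metric": metric,
                "oriented_ratio": orient_ratio(np.exp(fit.beta))
                if not fit.flagged
                else np.nan,
                "flagged": fit.flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def wilcoxon_mw(a, b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p (normal approx., tie-corrected)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def holm_adjust(pvalues: dict) -> dict:
    """Bonferroni-Holm step-down adjustment of a family of p-values."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running_max = 0.0
    for rank, (key, p) in enumerate(items):
        adj = min(1.0, (m - rank) * p)
        running_max = max(running_max, adj)
        adjusted[key] = running_max
    return {k: adjusted[k] for k in pvalues}


def compare_groups(
    results: pd.DataFrame, value_col: str = "metric"
) -> pd.DataFrame:
    """Pairwise group comparisons of a univariate result frame.

    For every (endpoint, center) family, compares ``value_col`` between all
    group pairs with Wilcoxon-Mann-Whitney and Holm-adjusts within the
    family.  Returns columns ``endpoint, center, group_1, group_2, p_raw,
    p_holm``.
    """
    out = []
    for (endpoint, center), block in results.groupby(["endpoint", "center"]):
        groups = sorted(block["group"].unique())
        raw = {}
        for g1, g2 in itertools.combinations(groups, 2):
            a = block.loc[block["group"] == g1, value_col].dropna()
            b = block.loc[block["group"] == g2, value_col].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            raw[(g1, g2)] = wilcoxon_mw(a, b)
        adj = holm_adjust(raw) if raw else {}
        for (g1, g2), p in raw.items():
            out.append(
                {
                    "endpoint": endpoint,
                    "center": center,
                    "group_1": g1,
                    "group_2": g2,
                    "p_raw": p,
                    "p_holm": adj[(g1, g2)],
                }
            )
    return pd.DataFrame(out)
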