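"""Feature preprocessing: Gaussianizing transforms, Z-score, ComBat.

The pipeline order is fixed: per-feature transform search -> Z-score
normalization -> reference-batch ComBat harmonization.  Transform and
Z-score parameters are fitted on the center-A (reference) cohort only and
applied to every cohort, so the external center never leaks into fitted
state.

Transform search
----------------
A feature already compatible with normality (Shapiro-Wilk p > alpha) keeps
the identity transform.  Otherwise the candidates — exponential,
logarithmic, squared, cubed, square root, cube root — are evaluated on the
fitted values where their domain allows, and the candidate maximizing the
Shapiro p-value is kept if that p exceeds alpha; otherwise the identity is
retained.  Domain guards: log needs strictly positive values, square root
non-negative values (cube root is applied sign-preservingly), and the
exponential is skipped when values exceed 700 (overflow).  At apply time,
out-of-domain values in a target cohort are clamped to the fitted domain
edge and counted.

ComBat
------
Parametric empirical-Bayes location/scale harmonization (Johnson 2007) in
its reference-batch variant: features are standardized with the reference
batch's mean and variance, per-batch location/scale estimates are shrunk
toward their across-feature priors (normal prior on locations,
inverse-gamma on scales, moment-matched, iterated to convergence), and
non-reference batches are adjusted while reference-batch rows are returned
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import AnalysisConfig, CohortDataset

__all__ = [
    "TRANSFORMS",
    "select_transform",
    "fit_transforms",
    "apply_transforms",
    "zscore_fit",
    "zscore_apply",
    "HarmonizationModel",
    "combat_fit",
    "combat_apply",
    "preprocess_cohort",
]

_EXP_GUARD = 700.0  # exp overflows past ~709 for float64


def _cbrt(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.abs(v) ** (1.0 / 3.0)


#: name -> (function, domain predicate on the fitted values)
TRANSFORMS: dict[str, tuple] = {
    "exponential": (np.exp, lambda v: v.max() <= _EXP_GUARD),
    "logarithmic": (np.log, lambda v: v.min() > 0),
    "squared": (np.square, lambda v: True),
    "cubed": (lambda v: v**3, lambda v: True),
    "square_root": (np.sqrt, lambda v: v.min() >= 0),
    "cube_root": (_cbrt, lambda v: True),
}


def _shapiro_p(values: np.ndarray) -> float:
    # Shapiro-Wilk is defined for 3 <= n; constant input degenerates
    if np.ptp(values) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def select_transform(values, alpha: float = 0.05) -> dict:
    """Choose the Gaussianizing transform for one feature.

    Returns a dict with keys ``transform``, ``shapiro_p_before``,
    ``shapiro_p_after`` and the domain-clamp bounds used at apply time.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("transform search requires finite values")
    if len(v) < 20:
        warnings.warn("fewer than 20 values; keeping identity transform", stacklevel=2)
        return _spec_row("identity", float("nan"), float("nan"), v)
    if np.ptp(v) == 0:
        warnings.warn("constant feature; keeping identity transform", stacklevel=2)
        return _spec_row("identity", 0.0, 0.0, v)
    p_before = _shapiro_p(v)
    if p_before > alpha:
        return _spec_row("identity", p_before, p_before, v)
    best_name, best_p = "identity", p_before
    for name, (func, domain_ok) in TRANSFORMS.items():
        if not domain_ok(v):
            continue
        with np.errstate(over="ignore"):
            tv = func(v)
        if not np.isfinite(tv).all():
            continue
        p = _shapiro_p(tv)
        if p > best_p:
            best_name, best_p = name, p
    if best_name != "identity" and best_p > alpha:
        return _spec_row(best_name, p_before, best_p, v)
    return _spec_row("identity", p_before, p_before, v)


def _spec_row(name: str, p_before: float, p_after: float, v: np.ndarray) -> dict:
    row = {
        "transform": name,
        "shapiro_p_before": p_before,
        "shapiro_p_after": p_after,
        "clamp_lo": -np.inf,
        "clamp_hi": np.inf,
    }
    if name == "logarithmic":
        row["clamp_lo"] = float(v[v > 0].min()) if (v > 0).any() else np.nan
    elif name == "square_root":
        row["clamp_lo"] = 0.0
    elif name == "exponential":
        row["clamp_hi"] = _EXP_GUARD
    return row


def fit_transforms(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`select_transform` per column; index = feature names."""
    rows = {feat: select_transform(matrix[feat].to_numpy(), alpha) for feat in matrix}
    spec = pd.DataFrame.from_dict(rows, orient="index")
    spec.index.name = "feature"
    return spec


def apply_transforms(matrix: pd.DataFrame, spec: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted transform spec to a (possibly different) cohort.

    Out-of-domain values are clamped to the fitted domain edge; the number
    of clamped cells is recorded in ``apply_transforms.last_clamped``.
    """
    unknown = [f for f in matrix.columns if f not in spec.index]
    if unknown:
        raise KeyError(f"features missing from transform spec: {unknown[:5]}")
    out = {}
    clamped = 0
    for feat in matrix.columns:
        row = spec.loc[feat]
        v = matrix[feat].to_numpy(dtype=float)
        name = row["transform"]
        if name == "identity":
            out[feat] = v
            continue
        lo, hi = row["clamp_lo"], row["clamp_hi"]
        below = v < lo
        above = v > hi
        clamped += int(below.sum() + above.sum())
        v = np.clip(v, lo, hi)
        func = TRANSFORMS[name][0]
        out[feat] = func(v)
    apply_transforms.last_clamped = clamped
    return pd.DataFrame(out, index=matrix.index)


apply_transforms.last_clamped = 0


# ---------------------------------------------------------------------------
# Z-score
# ---------------------------------------------------------------------------


def zscore_fit(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean and sample SD (ddof=1); zero-SD features dropped."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {(~keep).sum()} constant feature(s) from normalization",
            stacklevel=2,
        )
    params = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    params.index.name = "feature"
    return params


def zscore_apply(matrix: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """``(x - mean) / sd`` per feature; restricts to fitted features."""
    feats = [f for f in matrix.columns if f in params.index]
    return (matrix[feats] - params.loc[feats, "mean"]) / params.loc[feats, "sd"]


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


@dataclass
class HarmonizationModel:
    """Fitted reference-batch ComBat state.

    ``gamma_star``/``delta2_star`` frames are indexed by batch with one
    column per feature; the reference batch has gamma 0 and delta^2 1 by
    construction.  ``alpha``/``var_pooled`` are the reference batch's
    per-feature mean and variance used for standardization.
    """

    reference: str
    alpha: pd.Series
    var_pooled: pd.Series
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    eb: bool = True
    hyper: dict = field(default_factory=dict)
    single_batch: bool = False

    def to_text(self) -> str:
        lines = [
            f"reference_batch\t{self.reference}",
            f"mode\t{'parametric_eb' if self.eb else 'location_scale'}",
        ]
        for batch in self.gamma_star.index:
            for feat in self.gamma_star.columns:
                lines.append(
                    f"{batch}\t{feat}\t{self.gamma_star.loc[batch, feat]:.10g}"
                    f"\t{self.delta2_star.loc[batch, feat]:.10g}"
                )
        return "\n".join(lines) + "\n"


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    sdat: np.ndarray,
    g_hat: np.ndarray,
    d_hat2: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional modes for the EB batch estimates (one batch).

    ``sdat`` is samples x features standardized data for the batch.
    """
    n = sdat.shape[0]
    g_old = g_hat.copy()
    d_old = d_hat2.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).clip(1e-12).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).clip(1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_fit(
    matrix: pd.DataFrame,
    batch: pd.Series,
    reference: str = "A",
    eb: bool = True,
) -> HarmonizationModel:
    """Fit reference-batch ComBat location/scale parameters.

    ``batch`` maps each row of ``matrix`` to its batch label; ``reference``
    rows define the standardization and stay unchanged at apply time.
    With ``eb=False`` the raw per-batch estimates are used (no shrinkage).
    """
    batch = batch.loc[matrix.index]
    labels = sorted(batch.unique(), key=str)
    if reference not in labels:
        raise ValueError(f"reference batch {reference!r} absent from data")
    feats = list(matrix.columns)
    if len(labels) == 1:
        warnings.warn("single batch: ComBat is the identity", stacklevel=2)
        model = HarmonizationModel(
            reference=reference,
            alpha=matrix.mean(axis=0),
            var_pooled=matrix.var(axis=0, ddof=1).clip(lower=1e-12),
            gamma_star=pd.DataFrame(0.0, index=labels, columns=feats),
            delta2_star=pd.DataFrame(1.0, index=labels, columns=feats),
            eb=eb,
            single_batch=True,
        )
        return model
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 patients")

    ref_rows = matrix.loc[batch == reference]
    alpha = ref_rows.mean(axis=0)
    var_pooled = ref_rows.var(axis=0, ddof=0)
    degenerate = var_pooled <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s) in reference batch;"
            " left unadjusted",
            stacklevel=2,
        )
        var_pooled = var_pooled.where(~degenerate, 1.0)

    z = (matrix - alpha) / np.sqrt(var_pooled)

    gamma_star = pd.DataFrame(0.0, index=labels, columns=feats)
    delta2_star = pd.DataFrame(1.0, index=labels, columns=feats)
    hyper: dict = {}
    for lab in labels:
        if lab == reference:
            continue
        zb = z.loc[batch == lab].to_numpy()
        g_hat = zb.mean(axis=0)
        d_hat2 = zb.var(axis=0, ddof=1)
        skip = d_hat2 <= 0  # constant feature within this batch
        d_hat2 = np.where(skip, 1.0, d_hat2)
        if eb and len(feats) >= 3 and np.ptp(d_hat2) > 0:
            g_bar = float(g_hat.mean())
            t2 = float(g_hat.var(ddof=1))
            a = _aprior(d_hat2)
            b = _bprior(d_hat2)
            g_star, d2_star = _it_sol(zb, g_hat, d_hat2, g_bar, t2, a, b)
            hyper[lab] = {"gamma_bar": g_bar, "tau2": t2, "a_prior": a, "b_prior": b}
        else:
            g_star, d2_star = g_hat, d_hat2
        g_star = np.where(skip, 0.0, g_star)
        d2_star = np.where(skip, 1.0, d2_star)
        gamma_star.loc[lab] = g_star
        delta2_star.loc[lab] = d2_star
    return HarmonizationModel(
        reference=reference,
        alpha=alpha,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        eb=eb,
        hyper=hyper,
    )


def combat_apply(
    matrix: pd.DataFrame, batch: pd.Series, model: HarmonizationModel
) -> pd.DataFrame:
    """Adjust non-reference batches; reference rows are returned untouched."""
    batch = batch.loc[matrix.index]
    out = matrix.copy()
    if model.single_batch:
        return out
    z = (matrix - model.alpha) / np.sqrt(model.var_pooled)
    for lab in model.gamma_star.index:
        if lab == model.reference:
            continue
        rows = batch == lab
        if not rows.any():
            continue
        zb = z.loc[rows]
        adj = (zb - model.gamma_star.loc[lab]) / np.sqrt(model.delta2_star.loc[lab])
        out.loc[rows] = adj * np.sqrt(model.var_pooled) + model.alpha
    return out


# ---------------------------------------------------------------------------
# Cohort-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessState:
    """Fitted preprocessing state, keyed by protocol."""

    transform_specs: dict[str, pd.DataFrame]
    zscore_params: dict[str, pd.DataFrame]
    combat_models: dict[str, HarmonizationModel]


def preprocess_cohort(
    dataset: CohortDataset,
    config: AnalysisConfig | None = None,
    harmonize: bool = True,
) -> tuple[CohortDataset, PreprocessState]:
    """Transform -> Z-score -> ComBat over all condition matrices.

    Per protocol, the transform and Z-score parameters are fitted on the
    center-A annotator-A values and applied to every matrix of that
    protocol (both centers, both annotators).  ComBat is then fitted per
    protocol on the annotator-A matrix with center as batch and center A
    as reference.  Features dropped (zero SD) are removed consistently
    from all matrices.
    """
    cfg = config or AnalysisConfig()
    ids_a = dataset.center_ids("A")
    specs: dict[str, pd.DataFrame] = {}
    zparams: dict[str, pd.DataFrame] = {}
    models: dict[str, HarmonizationModel] = {}
    new_mats: dict[str, pd.DataFrame] = {}
    kept: set[str] | None = None
    for protocol in ("HD", "LD"):
        fit_mat = dataset.matrices[f"{protocol}_A"].loc[ids_a]
        spec = fit_transforms(fit_mat, cfg.shapiro_alpha)
        specs[protocol] = spec
        transformed_fit = apply_transforms(fit_mat, spec)
        params = zscore_fit(transformed_fit)
        zparams[protocol] = params
        kept = set(params.index) if kept is None else kept & set(params.index)
    assert kept is not None
    keep_order = [f for f in dataset.feature_names if f in kept]
    for protocol in ("HD", "LD"):
        for annot in ("A", "B"):
            cond = f"{protocol}_{annot}"
            if cond not in dataset.matrices:
                continue
            mat = apply_transforms(dataset.matrices[cond], specs[protocol])
            mat = zscore_apply(mat, zparams[protocol])[keep_order]
            new_mats[cond] = mat
        if harmonize and len(dataset.center_ids("B")) >= 2:
            batch = dataset.meta["center"]
            model = combat_fit(new_mats[f"{protocol}_A"], batch, reference="A")
            models[protocol] = model
            new_mats[f"{protocol}_A"] = combat_apply(
                new_mats[f"{protocol}_A"], batch, model
            )
            # annotator-B rows are center A only; reference rows unchanged
    out = CohortDataset(
        meta=dataset.meta.copy(),
        matrices=new_mats,
        outcomes=dataset.outcomes.copy(),
    )
    return out, PreprocessState(specs, zparams, models)
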