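"""Multivariate signature discovery and multi-subset evaluation.

For one feature subset (robust / HD_all / LD_all / HD_and_LD) and one
endpoint, a repetition proceeds as:

1. stratified 70/30 split of the center-A cohort (handled by the caller
   for :func:`run_repetition`, internally by :func:`run_experiment`);
2. stratified k-fold cross-validation on the train set; per fold:
   mRMR feature selection (FCQ for binary endpoints, WCQ for survival) on
   the fold-train rows, keeping the first ``n_selected_features`` features;
   SMOTE + Tomek-links rebalancing of the fold-train rows (binary
   endpoints only); all ``2^m - 1`` signatures fitted on the (rebalanced)
   fold-train rows, recording each signature's AIC;
3. per-signature AICs pooled across folds (a signature absent from a
   fold's candidate set has that fold missing; at least 3 finite folds are
   required), and the one-standard-error rule applied: among signatures
   whose mean AIC is within one SE of the best mean, the smallest wins;
4. the selected signature refitted on the whole (natural-prevalence) train
   set.

Repeating the whole procedure over fresh splits yields distributions of
train / internal-validation / external-validation performance per feature
subset, compared pairwise with Wilcoxon-Mann-Whitney + Holm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import _glm
from .dataset import AnalysisConfig, CohortDataset, kfold_split, stratified_split
from .univariate import harrell_c, holm_adjust, roc_auc, wilcoxon_mw

__all__ = [
    "SUBSET_NAMES",
    "build_design",
    "mrmr_select",
    "smote_tomek",
    "enumerate_signatures",
    "fit_signature",
    "SignatureCandidate",
    "one_se_select",
    "run_repetition",
    "run_experiment",
    "SelectedModel",
]

SUBSET_NAMES = ("robust", "HD_all", "LD_all", "HD_and_LD")

_ENUM_GUARD = 20  # 2^20 - 1 subsets is already ~1e6 model fits per fold


# ---------------------------------------------------------------------------
# Feature-subset design matrices
# ---------------------------------------------------------------------------


def build_design(
    dataset: CohortDataset,
    records: pd.DataFrame,
    subset: str,
    robust_protocol: str = "HD",
) -> pd.DataFrame:
    """Design matrix for one feature subset.

    Columns are suffixed ``__HD`` / ``__LD`` so the combined subset can
    carry both protocol copies of a feature.  The robust subset uses the
    HD copy by default (``robust_protocol`` may be ``"LD"`` or ``"mean"``).
    """
    hd = dataset.matrices["HD_A"].add_suffix("__HD")
    ld = dataset.matrices["LD_A"].add_suffix("__LD")
    if subset == "HD_all":
        return hd.copy()
    if subset == "LD_all":
        return ld.copy()
    if subset == "HD_and_LD":
        return pd.concat([hd, ld], axis=1)
    if subset == "robust":
        robust = [
            f for f in records.loc[records["robust"], "feature"]
            if f in dataset.feature_names
        ]
        if not robust:
            raise ValueError("no robust features available for the robust subset")
        if robust_protocol == "HD":
            return hd[[f + "__HD" for f in robust]].copy()
        if robust_protocol == "LD":
            return ld[[f + "__LD" for f in robust]].copy()
        mean = (
            dataset.matrices["HD_A"][robust] + dataset.matrices["LD_A"][robust]
        ) / 2.0
        return mean.add_suffix("__mean")
    raise ValueError(f"unknown subset {subset!r}")


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------


def _relevance_fcq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic of each column against the binary class."""
    n = len(y)
    out = np.zeros(X.shape[1])
    groups = [X[y == g] for g in (0, 1)]
    k = 2
    grand = X.mean(axis=0)
    ss_between = sum(len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    f[~np.isfinite(f)] = 0.0
    out[:] = f
    return out


def _relevance_wcq(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Squared Wald z of each column in a univariate Cox fit."""
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j : j + 1]
        if col.std() == 0:
            continue
        beta, se, converged = _glm.cox_fit_se(col, time, event)
        if converged and np.isfinite(se[0]) and se[0] > 0:
            out[j] = (beta[0] / se[0]) ** 2
    return out


def mrmr_select(
    X: pd.DataFrame,
    target,
    k: int,
    mode: str,
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance selection.

    ``mode="FCQ"``: relevance is the ANOVA F statistic against a binary
    target (pass ``target`` as a label vector).  ``mode="WCQ"``: relevance
    is the squared Wald z of a univariate Cox fit (pass ``target`` as a
    ``(time, event)`` pair).  Redundancy is the mean absolute Pearson
    correlation with already-selected features; the score is their
    quotient.  The first pick maximizes relevance alone.  Deterministic:
    ties break by feature-name order.
    """
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    order = np.argsort(X.columns)  # name order for deterministic ties
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if mode == "FCQ":
        y = np.asarray(target, dtype=int)
        relevance = _relevance_fcq(Xv, y)
    elif mode == "WCQ":
        time, event = target
        relevance = _relevance_wcq(
            Xv, np.asarray(time, dtype=float), np.asarray(event, dtype=int)
        )
    else:
        raise ValueError("mode must be 'FCQ' or 'WCQ'")

    sd = Xv.std(axis=0, ddof=1)
    constant = sd == 0
    relevance[constant] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (Xv - Xv.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    n = Xv.shape[0]

    selected: list[int] = []
    remaining = set(range(X.shape[1]))
    mean_abs_corr = np.zeros(X.shape[1])
    for step in range(k):
        best_j, best_score = None, -np.inf
        for j in order:
            if j not in remaining:
                continue
            if step == 0:
                score = relevance[j]
            else:
                red = max(mean_abs_corr[j] / len(selected), 1e-6)
                score = relevance[j] / red
            if score > best_score:
                best_j, best_score = j, score
        assert best_j is not None
        selected.append(best_j)
        remaining.discard(best_j)
        # update running sum of |corr| with the newly selected feature
        if step < k - 1:
            c = Z.T @ Z[:, best_j] / (n - 1)
            c[constant] = 1.0  # constant columns: maximal redundancy
            mean_abs_corr += np.abs(c)
    return [names[j] for j in selected]


# ---------------------------------------------------------------------------
# SMOTE + Tomek links
# ---------------------------------------------------------------------------


def smote_tomek(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a binary sample: SMOTE to parity, then drop Tomek links.

    SMOTE synthesizes minority points by interpolating between a minority
    sample and one of its ``k_neighbors`` nearest minority neighbors
    (Euclidean), ``x + u (x_nn - x)`` with ``u ~ U(0, 1)``.  Tomek links
    (mutual nearest neighbors of opposite class) then lose their majority
    member.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    rng = np.random.default_rng(seed)
    X_new, y_new = [X], [y]
    n_needed = n_maj - n_min
    if n_needed > 0:
        X_min = X[y == minority]
        k = min(k_neighbors, n_min - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, n_min, size=n_needed)
        pick = rng.integers(0, k, size=n_needed)
        u = rng.uniform(0.0, 1.0, size=n_needed)
        neigh = idx[base, pick + 1]
        synth = X_min[base] + u[:, None] * (X_min[neigh] - X_min[base])
        X_new.append(synth)
        y_new.append(np.full(n_needed, minority))
    Xb = np.vstack(X_new)
    yb = np.concatenate(y_new)

    # Tomek links on the rebalanced set
    nn = NearestNeighbors(n_neighbors=2).fit(Xb)
    _, idx = nn.kneighbors(Xb)
    nearest = idx[:, 1]
    majority = 1 - minority
    drop = np.zeros(len(yb), dtype=bool)
    for i in range(len(yb)):
        j = nearest[i]
        if nearest[j] == i and yb[i] != yb[j]:
            drop[i if yb[i] == majority else j] = True
    return Xb[~drop], yb[~drop]


# ---------------------------------------------------------------------------
# Signature enumeration, fitting, one-SE selection
# ---------------------------------------------------------------------------


def enumerate_signatures(features: list[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``features``, by size then lexicographic."""
    m = len(features)
    if m < 1:
        raise ValueError("need at least one feature")
    if m > _ENUM_GUARD:
        raise ValueError(
            f"{m} features -> 2^{m} - 1 signatures; refusing beyond "
            f"{_ENUM_GUARD} for combinatorial cost"
        )
    feats = sorted(features)
    out: list[tuple[str, ...]] = []
    for size in range(1, m + 1):
        out.extend(itertools.combinations(feats, size))
    return out


def fit_signature(
    signature: tuple[str, ...],
    X: pd.DataFrame,
    target,
    endpoint: str,
) -> tuple[np.ndarray | None, float]:
    """Fit one signature; returns ``(coef, aic)``.

    Binary endpoints: logistic fit, ``coef`` is (intercept, betas) and
    ``p = len(signature) + 1`` parameters.  Survival: Cox fit, no
    intercept.  Degenerate or non-converged fits get ``aic = inf``.
    """
    Xs = X[list(signature)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xs - Xs.mean(axis=0)) < Xs.shape[1]:
        return None, np.inf
    if endpoint == "rfs":
        time, event = target
        try:
            beta, ll, converged = _glm.cox_fit(
                Xs, np.asarray(time, float), np.asarray(event, int)
            )
        except ValueError:
            return None, np.inf
        n_par = len(signature)
    else:
        y = np.asarray(target, dtype=int)
        if len(np.unique(y)) < 2:
            return None, np.inf
        beta, ll, converged = _glm.logistic_fit(Xs, y)
        n_par = len(signature) + 1
    if not converged or not np.isfinite(ll):
        return None, np.inf
    return beta, float(2.0 * n_par - 2.0 * ll)


@dataclass
class SignatureCandidate:
    """Fold-wise AIC summary for one signature (feature-name set)."""

    signature: tuple[str, ...]
    fold_aics: list[float] = field(default_factory=list)  # NaN = fold missing

    @property
    def finite_folds(self) -> int:
        return int(np.isfinite(self.fold_aics).sum())

    @property
    def mean_aic(self) -> float:
        vals = np.asarray(self.fold_aics)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else np.inf

    @property
    def se_aic(self) -> float:
        vals = np.asarray(self.fold_aics)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            return 0.0
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))


def one_se_select(
    candidates: list[SignatureCandidate], min_folds: int = 3
) -> SignatureCandidate:
    """One-standard-error rule on cross-validated AIC.

    Among candidates with enough finite folds, find the minimum mean AIC;
    eligible candidates have mean AIC within one SE (of the best) above
    it; the smallest signature wins, ties broken by smaller mean AIC, then
    lexicographic signature order.
    """
    finite = [c for c in candidates if np.isfinite(c.mean_aic)]
    if not finite:
        raise ValueError("no signature with a finite fold AIC")
    need = min(min_folds, max(len(c.fold_aics) for c in finite))
    usable = [c for c in finite if c.finite_folds >= need]
    if not usable:
        # folds' candidate sets were too disjoint (small noisy cohorts);
        # degrade to the best-covered signatures rather than failing
        best_cover = max(c.finite_folds for c in finite)
        warnings.warn(
            f"no signature with >= {need} finite folds; using signatures "
            f"covered by {best_cover} fold(s)",
            stacklevel=2,
        )
        usable = [c for c in finite if c.finite_folds == best_cover]
    best = min(usable, key=lambda c: c.mean_aic)
    cutoff = best.mean_aic + best.se_aic
    eligible = [c for c in usable if c.mean_aic <= cutoff]
    return min(
        eligible, key=lambda c: (len(c.signature), c.mean_aic, c.signature)
    )


# ---------------------------------------------------------------------------
# Repetition and experiment drivers
# ---------------------------------------------------------------------------


@dataclass
class SelectedModel:
    """A refitted signature with its selection provenance."""

    signature: tuple[str, ...]
    coef: np.ndarray  # logistic: (intercept, betas); Cox: betas
    endpoint: str
    subset: str
    repetition: int
    mean_aic: float
    se_aic: float

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X[list(self.signature)].to_numpy(dtype=float)
        if self.endpoint == "rfs":
            return Xs @ self.coef
        return self.coef[0] + Xs @ self.coef[1:]


def _target_of(frame: pd.DataFrame, endpoint: str, ids) -> object:
    # ids must already be a subset of frame.index; order is preserved so the
    # target stays aligned with X.loc[ids]
    sub = frame.loc[list(ids)]
    if endpoint == "rfs":
        return (sub["time"].to_numpy(), sub["event"].to_numpy())
    return sub["y"].to_numpy()


def run_repetition(
    X: pd.DataFrame,
    outcome: pd.DataFrame,
    endpoint: str,
    config: AnalysisConfig,
    seed: int,
    subset: str = "",
    repetition: int = 0,
) -> SelectedModel:
    """One signature-selection pass on a training design matrix.

    ``X`` holds the train-set rows of one feature subset; ``outcome`` the
    matching endpoint frame (column ``y``, or ``time``/``event``).  Rows of
    ``X`` without an outcome label (missing 3-year status) are ignored.
    Deterministic given ``seed``.
    """
    ids = list(outcome.index.intersection(X.index))
    stratum = (
        outcome.loc[ids, "event"] if endpoint == "rfs" else outcome.loc[ids, "y"]
    )
    folds = None
    for attempt in range(10):
        trial = kfold_split(ids, config.n_folds, stratum.loc[sorted(ids)], seed + 1000 * attempt)
        ok = True
        for train_ids, _ in trial:
            lab = stratum.loc[train_ids]
            if endpoint != "rfs" and (lab.sum() < 2 or (1 - lab).sum() < 2):
                ok = False
            if endpoint == "rfs" and lab.sum() < 1:
                ok = False
        if ok:
            folds = trial
            break
        warnings.warn(
            f"degenerate fold draw (seed {seed + 1000 * attempt}); redrawing",
            stacklevel=2,
        )
    if folds is None:
        raise ValueError("could not draw folds with both classes in every fold")

    m = min(config.n_selected_features, X.shape[1])
    pool: dict[tuple[str, ...], SignatureCandidate] = {}
    for fold_i, (train_ids, _) in enumerate(folds):
        fold_X = X.loc[train_ids]
        fold_target = _target_of(outcome, endpoint, train_ids)
        if endpoint == "rfs":
            chosen = mrmr_select(fold_X, fold_target, m, "WCQ")
            fit_X, fit_target = fold_X, fold_target
        else:
            chosen = mrmr_select(fold_X, fold_target, m, "FCQ")
            Xb, yb = smote_tomek(
                fold_X.to_numpy(dtype=float),
                np.asarray(fold_target, dtype=int),
                seed=seed + fold_i,
            )
            fit_X = pd.DataFrame(Xb, columns=X.columns)
            fit_target = yb
        for sig in enumerate_signatures(chosen):
            _, aic = fit_signature(sig, fit_X, fit_target, endpoint)
            cand = pool.get(sig)
            if cand is None:
                cand = SignatureCandidate(sig, [np.nan] * len(folds))
                pool[sig] = cand
            cand.fold_aics[fold_i] = aic if np.isfinite(aic) else np.nan

    winner = one_se_select(list(pool.values()))
    full_target = _target_of(outcome, endpoint, ids)
    coef, _ = fit_signature(winner.signature, X.loc[ids], full_target, endpoint)
    if coef is None:
        # degenerate refit on the full train set: fall back to zeros so the
        # model is reportable (score constant, metric 0.5)
        warnings.warn("selected signature did not refit; zero coefficients", stacklevel=2)
        n_par = len(winner.signature) + (0 if endpoint == "rfs" else 1)
        coef = np.zeros(n_par)
    return SelectedModel(
        signature=winner.signature,
        coef=coef,
        endpoint=endpoint,
        subset=subset,
        repetition=repetition,
        mean_aic=winner.mean_aic,
        se_aic=winner.se_aic,
    )


def _evaluate(
    model: SelectedModel, X: pd.DataFrame, outcome: pd.DataFrame, endpoint: str
) -> float:
    ids = outcome.index.intersection(X.index)
    scores = model.linear_predictor(X.loc[ids])
    try:
        if endpoint == "rfs":
            return harrell_c(
                scores, outcome.loc[ids, "time"], outcome.loc[ids, "event"]
            )
        return roc_auc(scores, outcome.loc[ids, "y"])
    except ValueError:
        # single-class labels / no usable pairs on a small evaluation set
        return float("nan")


def run_experiment(
    cohort_a: CohortDataset,
    cohort_b: CohortDataset,
    records: pd.DataFrame,
    config: AnalysisConfig | None = None,
    subsets: tuple[str, ...] = SUBSET_NAMES,
    endpoints: tuple[str, ...] = ("recurrence", "recurrence_3y", "rfs"),
) -> dict:
    """Full multi-subset, multi-endpoint, repeated-split experiment.

    ``cohort_a``/``cohort_b`` must already be preprocessed with
    center-A-fitted parameters (``cohort_b`` may be the center-B rows of
    the same preprocessed dataset).  Returns a dict with:

    * ``metrics``: one row per (subset, endpoint, repetition) with train /
      internal validation / external validation performance;
    * ``comparisons``: pairwise Holm-adjusted subset comparisons per
      endpoint and evaluation set;
    * ``models``: the selected models.
    """
    cfg = config or AnalysisConfig()
    designs_a = {
        s: build_design(cohort_a, records, s, cfg.robust_protocol) for s in subsets
    }
    designs_b = {
        s: build_design(cohort_b, records, s, cfg.robust_protocol) for s in subsets
    }
    rows = []
    models: list[SelectedModel] = []
    for endpoint in endpoints:
        frame_a = cohort_a.endpoint_frame(endpoint)
        frame_b = cohort_b.endpoint_frame(endpoint)
        # the 3-year endpoint drops patients with unknown 3-year status
        cohort_ep = (
            cohort_a.subset(frame_a.index)
            if len(frame_a) < cohort_a.n_patients
            else cohort_a
        )
        strat = cohort_ep.stratum_labels(endpoint)
        for rep in range(cfg.n_repetitions):
            rep_seed = cfg.seed + rep
            train, test = stratified_split(
                cohort_ep, cfg.split_fraction, strat, rep_seed
            )
            for subset in subsets:
                Xa = designs_a[subset]
                model = run_repetition(
                    Xa.loc[Xa.index.intersection(train.patient_ids)],
                    frame_a,
                    endpoint,
                    cfg,
                    seed=rep_seed,
                    subset=subset,
                    repetition=rep,
                )
                models.append(model)
                rows.append(
                    {
                        "subset": subset,
                        "endpoint": endpoint,
                        "repetition": rep,
                        "signature": "+".join(model.signature),
                        "n_features": len(model.signature),
                        "train": _evaluate(
                            model,
                            Xa.loc[Xa.index.intersection(train.patient_ids)],
                            frame_a,
                            endpoint,
                        ),
                        "internal_validation": _evaluate(
                            model,
                            Xa.loc[Xa.index.intersection(test.patient_ids)],
                            frame_a,
                            endpoint,
                        ),
                        "external_validation": _evaluate(
                            model, designs_b[subset], frame_b, endpoint
                        ),
                    }
                )
    metrics = pd.DataFrame(rows)

    comp_rows = []
    for endpoint in endpoints:
        block = metrics[metrics["endpoint"] == endpoint]
        for eval_set in ("train", "internal_validation", "external_validation"):
            raw = {}
            for s1, s2 in itertools.combinations(subsets, 2):
                a = block.loc[block["subset"] == s1, eval_set].dropna()
                b = block.loc[block["subset"] == s2, eval_set].dropna()
                if len(a) == 0 or len(b) == 0:
                    continue
                raw[(s1, s2)] = wilcoxon_mw(a, b)
            adj = holm_adjust(raw)
            for (s1, s2), p in raw.items():
                comp_rows.append(
                    {
                        "endpoint": endpoint,
                        "evaluation_set": eval_set,
                        "subset_1": s1,
                        "subset_2": s2,
                        "p_raw": p,
                        "p_holm": adj[(s1, s2)],
                    }
                )
    comparisons = pd.DataFrame(comp_rows)
    return {"metrics": metrics, "comparisons": comparisons, "models": models}
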