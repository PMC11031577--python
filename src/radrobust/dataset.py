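"""Cohort data model, CSV I/O, and stratified splitting.

A cohort couples per-patient metadata (center, segmentation Dice scores,
inter-scan delay), one radiomic feature matrix per acquisition *condition*
(protocol ``HD``/``LD`` crossed with annotator ``A``/``B``), and an outcome
table holding a binary recurrence indicator, a fixed-horizon (3-year)
recurrence label and a right-censored time-to-event endpoint.

Conventions
-----------
* Conditions are keyed by strings ``"HD_A"``, ``"LD_A"``, ``"HD_B"``,
  ``"LD_B"``.  ``HD_A`` and ``LD_A`` must cover every patient; the ``B``
  matrices exist only for the dual-annotator subset.
* Patient order is canonicalized by lexicographic ``patient_id`` sort at
  construction/read time, so downstream determinism depends only on seeds.
* CSV dialect: comma separated, UTF-8, ``.`` decimal, header row, empty
  string for missing values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PROTOCOLS = ("HD", "LD")
ANNOTATORS = ("A", "B")
#: Conditions every cohort must provide (annotator A segmented all patients).
REQUIRED_CONDITIONS = ("HD_A", "LD_A")
ALL_CONDITIONS = ("HD_A", "LD_A", "HD_B", "LD_B")

META_COLUMNS = ("center", "dice_hd", "dice_ld", "scan_delay_days")
OUTCOME_COLUMNS = ("recurrence", "recurrence_3y", "time_months", "event")

#: Endpoint identifiers used throughout the analysis modules.
ENDPOINTS = ("recurrence", "recurrence_3y", "rfs")


class CohortError(ValueError):
    """Raised when a cohort violates a structural invariant."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters shared by the analysis stages.

    Parameters
    ----------
    robustness_threshold
        Minimum ICC/CCC for a feature to count as robust (compared with
        ``>=`` by default).
    shapiro_alpha
        Significance level of the Shapiro-Wilk normality test driving the
        per-feature transform search.
    split_fraction
        Fraction of center-A patients assigned to the training set.
    n_folds
        Cross-validation folds used during signature selection.
    n_selected_features
        Number of features retained by mRMR in each fold (the signature
        search enumerates all ``2**n - 1`` non-empty subsets of them).
    n_repetitions
        Number of independent split/selection repetitions.
    robust_protocol
        Which protocol's values represent a robust feature in predictive
        models: ``"HD"`` (default), ``"LD"`` or ``"mean"``.
    strict_threshold
        If True, use ``>`` instead of ``>=`` at the robustness threshold.
    ccc_on_transformed
        If True, compute concordance statistics on preprocessed rather than
        raw feature values.
    """

    robustness_threshold: float = 0.75
    shapiro_alpha: float = 0.05
    split_fraction: float = 0.70
    n_folds: int = 5
    n_selected_features: int = 10
    n_repetitions: int = 10
    seed: int = 0
    robust_protocol: str = "HD"
    strict_threshold: bool = False
    ccc_on_transformed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.robustness_threshold < 1.0:
            raise ValueError("robustness_threshold must be in (0, 1)")
        if self.robust_protocol not in ("HD", "LD", "mean"):
            raise ValueError("robust_protocol must be HD, LD or mean")


@dataclass
class CohortDataset:
    """Aligned cohort: metadata, per-condition feature matrices, outcomes.

    All frames are indexed by ``patient_id``.  ``matrices`` values share one
    feature-name list; ``HD_A``/``LD_A`` share the full patient index, while
    ``HD_B``/``LD_B`` are restricted to the dual-annotator subset.
    """

    meta: pd.DataFrame
    matrices: dict[str, pd.DataFrame]
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.sort_index()
        self.outcomes = self.outcomes.sort_index()
        self.matrices = {k: v.sort_index() for k, v in self.matrices.items()}
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        idx = self.meta.index
        if idx.has_duplicates:
            raise CohortError("duplicated patient_id in metadata")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise CohortError(f"metadata missing column {col!r}")
        for col in OUTCOME_COLUMNS:
            if col not in self.outcomes.columns:
                raise CohortError(f"outcome table missing column {col!r}")
        if not self.outcomes.index.equals(idx):
            raise CohortError("outcome table patient set differs from metadata")
        for cond in REQUIRED_CONDITIONS:
            if cond not in self.matrices:
                raise CohortError(f"required condition {cond!r} missing")
            if not self.matrices[cond].index.equals(idx):
                raise CohortError(
                    f"feature matrix {cond!r} patient set differs from metadata"
                )
        names = None
        for cond, mat in self.matrices.items():
            if mat.columns.has_duplicates:
                raise CohortError(f"duplicated feature name in {cond!r}")
            if names is None:
                names = list(mat.columns)
            elif list(mat.columns) != names:
                raise CohortError("feature matrices disagree on feature names")
            vals = mat.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                bad = np.argwhere(~np.isfinite(vals))[0]
                raise CohortError(
                    f"non-finite value in {cond!r} at patient "
                    f"{mat.index[bad[0]]!r}, feature {mat.columns[bad[1]]!r}"
                )
        dual = self.dual_ids
        for cond in ("HD_B", "LD_B"):
            if cond in self.matrices and not self.matrices[cond].index.equals(dual):
                raise CohortError("HD_B and LD_B must cover the same patient subset")

    # -- derived views -----------------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def n_patients(self) -> int:
        return len(self.meta)

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrices["HD_A"].columns)

    @property
    def dual_ids(self) -> pd.Index:
        """Patients segmented by both annotators."""
        if "HD_B" in self.matrices:
            return self.matrices["HD_B"].index
        return self.meta.index[:0]

    def center_ids(self, center: str) -> pd.Index:
        return self.meta.index[self.meta["center"] == center]

    def subset(self, ids: Iterable[str]) -> "CohortDataset":
        """Restrict the cohort to ``ids`` (order canonicalized by sort)."""
        ids = pd.Index(sorted(ids), name="patient_id")
        missing = ids.difference(self.meta.index)
        if len(missing):
            raise CohortError(f"unknown patient ids: {list(missing)[:5]}")
        mats = {}
        for cond, mat in self.matrices.items():
            keep = mat.index.intersection(ids)
            if cond in REQUIRED_CONDITIONS or len(keep):
                mats[cond] = mat.loc[keep]
        # drop B matrices entirely if the subset has no dual patients
        if "HD_B" in mats and len(mats["HD_B"]) == 0:
            mats.pop("HD_B", None)
            mats.pop("LD_B", None)
        return CohortDataset(
            meta=self.meta.loc[ids].copy(),
            matrices=mats,
            outcomes=self.outcomes.loc[ids].copy(),
        )

    def endpoint_frame(self, endpoint: str) -> pd.DataFrame:
        """Return the outcome columns for one endpoint, dropping unusable rows.

        ``recurrence`` -> column ``y``; ``recurrence_3y`` -> ``y`` with
        missing labels dropped; ``rfs`` -> columns ``time`` and ``event``.
        """
        if endpoint == "recurrence":
            return pd.DataFrame({"y": self.outcomes["recurrence"].astype(int)})
        if endpoint == "recurrence_3y":
            lab = self.outcomes["recurrence_3y"].dropna()
            return pd.DataFrame({"y": lab.astype(int)})
        if endpoint == "rfs":
            return pd.DataFrame(
                {
                    "time": self.outcomes["time_months"].astype(float),
                    "event": self.outcomes["event"].astype(int),
                }
            )
        raise ValueError(f"unknown endpoint {endpoint!r}")

    def stratum_labels(self, endpoint: str) -> pd.Series:
        """Binary labels used to stratify splits for ``endpoint``.

        The survival endpoint is stratified on the event indicator.
        """
        if endpoint == "rfs":
            return self.outcomes["event"].astype(int)
        frame = self.endpoint_frame(endpoint)
        return frame["y"]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_indexed_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise CohortError(f"{path}: missing patient_id column")
    return df.set_index("patient_id").sort_index()


def read_cohort(
    feature_paths: Mapping[str, str | Path],
    meta_path: str | Path,
    outcome_path: str | Path,
) -> CohortDataset:
    """Load a cohort from CSV files.

    ``feature_paths`` maps condition keys (``"HD_A"`` ...) to feature-table
    paths.  Rows are matched on ``patient_id``; the required conditions,
    metadata and outcomes must cover identical patient sets.
    """
    meta = _read_indexed_csv(Path(meta_path))
    outcomes = _read_indexed_csv(Path(outcome_path))
    matrices: dict[str, pd.DataFrame] = {}
    for cond, path in feature_paths.items():
        if cond not in ALL_CONDITIONS:
            raise CohortError(f"unknown condition key {cond!r}")
        mat = _read_indexed_csv(Path(path))
        for col in mat.columns:
            if len(mat) and not pd.api.types.is_numeric_dtype(mat[col]):
                bad = mat.index[pd.to_numeric(mat[col], errors="coerce").isna()]
                raise CohortError(
                    f"{path}: non-numeric value in feature {col!r}"
                    f" (e.g. patient {bad[0]!r})"
                )
        matrices[cond] = mat.astype(float)
    for cond in REQUIRED_CONDITIONS:
        if cond not in matrices:
            raise CohortError(f"required condition {cond!r} not provided")
        if not matrices[cond].index.equals(meta.index):
            raise CohortError(
                f"patient set of {cond!r} does not match metadata "
                f"(sym. difference: "
                f"{list(matrices[cond].index.symmetric_difference(meta.index))[:5]})"
            )
    if not outcomes.index.equals(meta.index):
        raise CohortError(
            "patient set of outcome table does not match metadata "
            f"(sym. difference: "
            f"{list(outcomes.index.symmetric_difference(meta.index))[:5]})"
        )
    if "recurrence_3y" in outcomes.columns:
        outcomes["recurrence_3y"] = pd.to_numeric(outcomes["recurrence_3y"])
    return CohortDataset(meta=meta, matrices=matrices, outcomes=outcomes)


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> list[Path]:
    """Write a cohort to CSV files under ``out_dir``; returns the manifest.

    Values are written at full repr precision so a read/write round trip is
    exact; missing values become empty cells.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for cond, mat in dataset.matrices.items():
        p = out / f"features_{cond}.csv"
        mat.to_csv(p, index_label="patient_id")
        manifest.append(p)
    p = out / "meta.csv"
    dataset.meta.to_csv(p, index_label="patient_id")
    manifest.append(p)
    p = out / "outcomes.csv"
    dataset.outcomes.to_csv(p, index_label="patient_id")
    manifest.append(p)
    return manifest


def read_cohort_dir(data_dir: str | Path) -> CohortDataset:
    """Load a cohort previously written by :func:`write_cohort`."""
    d = Path(data_dir)
    feature_paths = {
        cond: d / f"features_{cond}.csv"
        for cond in ALL_CONDITIONS
        if (d / f"features_{cond}.csv").exists()
    }
    return read_cohort(feature_paths, d / "meta.csv", d / "outcomes.csv")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def _train_size(n: int, fraction: float) -> int:
    # round-half-up keeps per-stratum counts within one patient of target
    return int(np.floor(n * fraction + 0.5))


def stratified_split(
    dataset: CohortDataset,
    fraction: float,
    stratum: pd.Series,
    seed: int,
) -> tuple[CohortDataset, CohortDataset]:
    """Stratified train/test partition of a cohort.

    Within every stratum the train share is ``round(fraction * n)``
    (half-up), so proportions are within one patient of the request.  A
    stratum with fewer than two members goes to train with a warning.
    Deterministic in ``seed``; disjoint and exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    stratum = stratum.loc[dataset.patient_ids]
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for value in sorted(stratum.unique(), key=str):
        members = sorted(stratum.index[stratum == value])
        if len(members) < 2:
            warnings.warn(
                f"stratum {value!r} has {len(members)} member(s); assigned to train",
                stacklevel=2,
            )
            train_ids.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_train = _train_size(len(members), fraction)
        ordered = [members[i] for i in perm]
        train_ids.extend(ordered[:n_train])
        test_ids.extend(ordered[n_train:])
    return dataset.subset(train_ids), dataset.subset(test_ids)


def kfold_split(
    ids: Sequence[str],
    k: int,
    stratum: pd.Series | Sequence,
    seed: int,
) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold partition of ``ids``.

    Folds are disjoint, exhaustive and balanced within one member per
    stratum; deterministic in ``seed``.  Returns ``k`` pairs
    ``(train_ids, val_ids)``.
    """
    ids = sorted(ids)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of patients ({n})")
    labels = pd.Series(np.asarray(stratum), index=None)
    if len(labels) != n:
        raise ValueError("stratum labels must match ids length")
    rng = np.random.default_rng(seed)
    # assign fold numbers round-robin within each shuffled stratum
    fold_of = np.empty(n, dtype=int)
    order = np.arange(n)
    start = 0
    for value in sorted(pd.unique(labels), key=str):
        members = order[np.asarray(labels == value)]
        members = rng.permutation(members)
        folds = (np.arange(len(members)) + start) % k
        fold_of[members] = folds
        start += len(members)  # stagger so small strata spread across folds
    splits = []
    for f in range(k):
        val = [ids[i] for i in range(n) if fold_of[i] == f]
        train = [ids[i] for i in range(n) if fold_of[i] != f]
        splits.append((train, val))
    return splits
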