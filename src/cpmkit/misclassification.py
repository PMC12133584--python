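"""Misprediction diagnostics: misclassification index and covariate dissection.

A binary (low vs high scorer, median split) version of the CPM pipeline is run
in leave-one-out cross-validation with repeated random subsampling of the
training participants. The misclassification index (MI) of a subject is the
fraction of iterations in which their class was predicted wrongly. MI is then
dissected against clinical/sociodemographic covariates: correlations of MI
with each covariate within low and high scorers, and of each covariate with
the continuous outcome within correctly (MI < cut) and frequently
misclassified (MI > cut) subjects. Finally, covariate-controlled prediction
reruns the continuous pipeline scoring accuracy as the partial correlation
between predicted and observed scores given the covariate.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .core import (
    DegenerateDataError,
    FeatureMask,
    PredictionResult,
    SplitScheme,
    critical_r,
    run_cpm,
    _edges_array,
)
from .io import BehavioralTable, ConnectomeSet

logger = logging.getLogger(__name__)

_MI_STREAM = 7003


def _stable_hash(subject_id: str) -> int:
    """Order-independent 31-bit integer derived from a subject id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def binarize_outcome(y: np.ndarray) -> np.ndarray:
    """Median split into low (0) and high (1) scorers.

    Subjects exactly at the median go to the low class (deterministic tie
    rule). With distinct values the class sizes differ by at most one.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise DegenerateDataError("outcome has a single value; cannot median-split")
    med = np.median(y)
    classes = (y > med).astype(int)
    logger.info(
        "median split at %g: %d low / %d high (at-median -> low)",
        med, int((classes == 0).sum()), int((classes == 1).sum()),
    )
    return classes


@dataclass
class MIProfile:
    """Per-subject misclassification index with scorer-class labels."""

    subject_ids: list[str]
    scorer_class: np.ndarray  # 0 = low, 1 = high
    mi: np.ndarray
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "scorer_class": np.where(self.scorer_class == 1, "high", "low"),
                "mi": self.mi,
                "n_iterations": self.n_iterations,
            }
        ).set_index("subject_id")

    def fraction_above(self, cut: float = 0.5) -> float:
        """Fraction of subjects with MI above ``cut``."""
        return float(np.mean(self.mi > cut))


def _iteration_features(
    X_train: np.ndarray,
    labels: np.ndarray,
    X_test: np.ndarray,
    p_threshold: float,
    representation: str,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Summary-score (or raw-edge) features for one classifier fit.

    Returns None when no feature can be selected (degenerate iteration).
    """
    # threshold on |r| equivalent to p < p_threshold (saves the per-edge p's)
    lab = labels.astype(float)
    lc = lab - lab.mean()
    sl = np.sqrt((lc**2).sum())
    Xc = X_train - X_train.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    r = (Xc.T @ lc) / (np.where(sx == 0, 1.0, sx) * sl)
    r[sx == 0] = 0.0
    rc = critical_r(p_threshold, len(lab))
    mask = FeatureMask(np.flatnonzero(r > rc), np.flatnonzero(r < -rc), p_threshold)
    if mask.positive.size == 0 and mask.negative.size == 0:
        return None
    if representation == "edges":
        sel = np.concatenate([mask.positive, mask.negative])
        return X_train[:, sel], X_test[:, sel]
    pos_tr = X_train[:, mask.positive].sum(axis=1) if mask.positive.size else np.zeros(len(X_train))
    neg_tr = X_train[:, mask.negative].sum(axis=1) if mask.negative.size else np.zeros(len(X_train))
    pos_te = X_test[:, mask.positive].sum(axis=1) if mask.positive.size else np.zeros(len(X_test))
    neg_te = X_test[:, mask.negative].sum(axis=1) if mask.negative.size else np.zeros(len(X_test))
    return np.column_stack([pos_tr, neg_tr]), np.column_stack([pos_te, neg_te])


def run_misclassification(
    connectomes: ConnectomeSet | np.ndarray,
    classes: np.ndarray,
    n_iterations: int = 100,
    subsample_fraction: float = 0.8,
    p_threshold: float = 0.01,
    seed: int = 0,
    C: float = 1.0,
    representation: str = "summary",
    subject_ids: list[str] | None = None,
) -> MIProfile:
    """Leave-one-out misclassification index over subsampled classifier fits.

    For each left-out subject and iteration: draw ``subsample_fraction`` of
    the remaining subjects, select edges against the binary outcome
    (point-biserial correlation at ``p_threshold``), train a linear-kernel
    support-vector classifier on the standardized 2-D (positive, negative)
    summary-score representation (``representation="edges"`` uses the selected
    raw edges instead), and classify the left-out subject. MI is the fraction
    of iterations misclassified.

    Each subject's iteration RNG is keyed on (seed, hash(subject id)), so MI
    is invariant to the row order of the input.
    """
    X = _edges_array(connectomes)
    classes = np.asarray(classes, dtype=int)
    if subject_ids is None:
        if isinstance(connectomes, ConnectomeSet):
            subject_ids = connectomes.subject_ids
        else:
            subject_ids = [f"S{k:04d}" for k in range(X.shape[0])]
    if (classes == 0).sum() == 0 or (classes == 1).sum() == 0:
        raise DegenerateDataError("both scorer classes must be non-empty")
    if representation not in ("summary", "edges"):
        raise ValueError(f"unknown representation {representation!r}")
    n = X.shape[0]
    n_sub = int(np.floor(subsample_fraction * (n - 1)))
    if n_sub < 10:
        raise DegenerateDataError(
            f"subsample of {n_sub} subjects is too small for feature selection"
        )
    order = np.argsort(np.asarray(subject_ids, dtype=object))
    mi = np.zeros(n)
    n_degenerate = 0
    for j in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=seed, spawn_key=(_MI_STREAM, _stable_hash(subject_ids[j]))
            )
        )
        remaining = order[order != j]  # id-sorted, excludes left-out subject
        wrong = 0
        for _ in range(n_iterations):
            pick = remaining[rng.choice(remaining.size, size=n_sub, replace=False)]
            lab = classes[pick]
            feats = None
            if lab.min() != lab.max():
                feats = _iteration_features(
                    X[pick], lab, X[j:j + 1], p_threshold, representation
                )
            if feats is None:
                # degenerate iteration: fall back to the majority class
                n_degenerate += 1
                pred = int(lab.mean() > 0.5)
            else:
                F_tr, F_te = feats
                mu = F_tr.mean(axis=0)
                sd = F_tr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="linear", C=C)
                clf.fit((F_tr - mu) / sd, lab)
                pred = int(clf.predict((F_te - mu) / sd)[0])
            if pred != classes[j]:
                wrong += 1
        mi[j] = wrong / n_iterations
    if n_degenerate:
        logger.warning(
            "%d/%d iterations fell back to majority-class prediction",
            n_degenerate, n * n_iterations,
        )
    return MIProfile(list(subject_ids), classes.copy(), mi, n_iterations)


# ---------------------------------------------------------------------------
# Covariate dissection
# ---------------------------------------------------------------------------

def encode_covariate(col: pd.Series) -> np.ndarray:
    """Numeric encoding for dissection correlations.

    Numeric columns pass through; categorical columns get ordinal codes in
    lexicographic category order (two categories therefore become 0/1).
    """
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    cats = sorted(col.dropna().astype(str).unique())
    mapping = {c: k for k, c in enumerate(cats)}
    return col.astype(str).map(mapping).to_numpy(dtype=float)


def _safe_pearsonr(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int, bool]:
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = int(keep.sum())
    if n < 4 or np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan"), float("nan"), n, False
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), n, True


def mi_covariate_dissection(
    mi_profile: MIProfile,
    behavior: BehavioralTable | pd.DataFrame,
    outcome_name: str,
    covariates: list[str],
    mi_cut: float = 0.5,
) -> pd.DataFrame:
    """Correlate MI and outcome with covariates across diagnostic strata.

    Two families of Pearson correlations per covariate:

    * ``mi_vs_covariate`` within the ``low_scorers`` and ``high_scorers``
      strata (is the covariate linked to being mispredicted?);
    * ``covariate_vs_outcome`` within the ``correct`` (MI < cut) and
      ``misclassified`` (MI > cut) strata (does the stereotypical
      covariate–outcome association hold in each group?).

    Strata with n < 4 (or a constant variable) are flagged ``computed=False``.
    """
    data = behavior.data if isinstance(behavior, BehavioralTable) else behavior
    data = data.loc[mi_profile.subject_ids]
    y = pd.to_numeric(data[outcome_name], errors="coerce").to_numpy(dtype=float)
    mi = mi_profile.mi
    cls = mi_profile.scorer_class
    strata = {
        "low_scorers": cls == 0,
        "high_scorers": cls == 1,
        "correct": mi < mi_cut,
        "misclassified": mi > mi_cut,
    }
    rows = []
    for cov in covariates:
        v = encode_covariate(data[cov])
        for stratum in ("low_scorers", "high_scorers"):
            sel = strata[stratum]
            r, p, n, ok = _safe_pearsonr(mi[sel], v[sel])
            rows.append(
                dict(covariate=cov, analysis="mi_vs_covariate", stratum=stratum,
                     r=r, p=p, n=n, computed=ok)
            )
        for stratum in ("correct", "misclassified"):
            sel = strata[stratum]
            r, p, n, ok = _safe_pearsonr(v[sel], y[sel])
            rows.append(
                dict(covariate=cov, analysis="covariate_vs_outcome", stratum=stratum,
                     r=r, p=p, n=n, computed=ok)
            )
    return pd.DataFrame(rows)


def covaried_prediction(
    connectomes: ConnectomeSet | np.ndarray,
    y: np.ndarray,
    covariate: np.ndarray,
    scheme: SplitScheme = SplitScheme(),
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    outcome_name: str = "",
) -> PredictionResult:
    """CPM accuracy as test-set partial correlation controlling a covariate."""
    return run_cpm(
        connectomes, y, scheme, p_threshold, score_mode,
        outcome_name=outcome_name, covariate=np.asarray(covariate, dtype=float),
    )
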