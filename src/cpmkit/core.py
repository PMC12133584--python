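"""Connectome-based predictive modeling (CPM).

The pipeline, per train/test split:

1. correlate every edge with the outcome across training subjects (Pearson r,
   two-sided p from the t transform with n−2 df);
2. keep edges with p below the feature-defining threshold, split by the sign
   of r into a positive and a negative feature set;
3. summarize each subject: combined score = sum of positive-set edges minus
   sum of negative-set edges (or one side alone);
4. fit ordinary least squares of outcome on the scalar summary score;
5. predict the test subjects and record Pearson r between predicted and
   observed outcome (optionally the partial r controlling a covariate).

Accuracy is reported as the mean of r over 100 unique 70/30 splits.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .io import ConnectomeSet

logger = logging.getLogger(__name__)

SCORE_MODES = ("combined", "positive_only", "negative_only")


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested computation."""


class EmptyMaskError(RuntimeError):
    """Raised when a score mode needs a feature-set side that is empty."""


# ---------------------------------------------------------------------------
# Edge-wise statistics
# ---------------------------------------------------------------------------

def pearson_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided parametric p of each column of X against y.

    Constant columns get r=0, p=1 with a logged warning; a constant y is an
    error because no feature can then be selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise DegenerateDataError(f"need at least 4 subjects, got {n}")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise DegenerateDataError("outcome is constant; cannot select features")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    const = sx == 0
    if const.any():
        logger.warning("%d constant edge(s) set to r=0, p=1", int(const.sum()))
    sx_safe = np.where(const, 1.0, sx)
    r = (Xc.T @ yc) / (sx_safe * sy)
    r = np.clip(r, -1.0, 1.0)
    r[const] = 0.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[const] = 1.0
    return r, p


def critical_r(p_threshold: float, n: int) -> float:
    """|r| above which the two-sided parametric p falls strictly below
    ``p_threshold`` at sample size n (used by vectorized selection)."""
    t_crit = stats.t.isf(p_threshold / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def partial_pearson(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation of x and y controlling for z.

    Returns NaN when any marginal correlation is degenerate (e.g., z carries
    all of y's variance).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    rxy = _pearson(x, y)
    rxz = _pearson(x, z)
    ryz = _pearson(y, z)
    denom_sq = (1.0 - rxz**2) * (1.0 - ryz**2)
    if not np.isfinite(rxy) or not np.isfinite(denom_sq) or denom_sq <= 0:
        return float("nan")
    return float((rxy - rxz * ryz) / np.sqrt(denom_sq))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((ac * bc).sum() / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Feature masks and models
# ---------------------------------------------------------------------------

@dataclass
class FeatureMask:
    """Disjoint positive / negative edge-index sets at a selection threshold."""

    positive: np.ndarray
    negative: np.ndarray
    p_threshold: float

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=int)
        self.negative = np.asarray(self.negative, dtype=int)
        if np.intersect1d(self.positive, self.negative).size:
            raise ValueError("positive and negative edge sets overlap")

    def sides_for(self, score_mode: str) -> list[np.ndarray]:
        if score_mode == "combined":
            return [self.positive, self.negative]
        if score_mode == "positive_only":
            return [self.positive]
        if score_mode == "negative_only":
            return [self.negative]
        raise ValueError(f"unknown score mode {score_mode!r}")


def select_features(
    r: np.ndarray, p: np.ndarray, p_threshold: float = 0.01
) -> FeatureMask:
    """Threshold edge-wise correlations into positive and negative sets."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError("r and p must have the same length")
    hit = p < p_threshold
    return FeatureMask(
        positive=np.flatnonzero(hit & (r > 0)),
        negative=np.flatnonzero(hit & (r < 0)),
        p_threshold=p_threshold,
    )


def summary_score(
    edges: np.ndarray, mask: FeatureMask, score_mode: str = "combined"
) -> np.ndarray | float:
    """Connectivity-strength summary score(s).

    combined = Σ positive-set edges − Σ negative-set edges. Accepts one edge
    vector (returns a float) or an m×E matrix (returns an m-vector).
    """
    if score_mode not in SCORE_MODES:
        raise ValueError(f"unknown score mode {score_mode!r}")
    edges = np.asarray(edges, dtype=float)
    single = edges.ndim == 1
    X = edges[None, :] if single else edges
    for side_name, side in (("positive", mask.positive), ("negative", mask.negative)):
        needed = score_mode == "combined" or score_mode == f"{side_name}_only"
        if needed and side.size == 0:
            raise EmptyMaskError(
                f"{side_name} feature set is empty but required by "
                f"score mode {score_mode!r}"
            )
    pos = X[:, mask.positive].sum(axis=1) if mask.positive.size else 0.0
    neg = X[:, mask.negative].sum(axis=1) if mask.negative.size else 0.0
    if score_mode == "combined":
        out = pos - neg
    elif score_mode == "positive_only":
        out = pos
    else:
        out = neg
    return float(out[0]) if single else np.asarray(out)


@dataclass
class CPMModel:
    """A fitted CPM: feature mask plus the linear map score → outcome."""

    mask: FeatureMask
    score_mode: str
    slope: float
    intercept: float
    train_n: int
    n_edges: int
    outcome_name: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("model coefficients must be finite")


def fit_cpm(
    train_edges: np.ndarray,
    y: np.ndarray,
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    outcome_name: str = "",
) -> CPMModel:
    """Select features on the training set and fit OLS of y on the score."""
    X = np.asarray(train_edges, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = pearson_columns(X, y)
    mask = select_features(r, p, p_threshold)
    scores = summary_score(X, mask, score_mode)
    return _fit_linear(mask, scores, y, score_mode, X.shape[1], outcome_name)


def _fit_linear(
    mask: FeatureMask,
    scores: np.ndarray,
    y: np.ndarray,
    score_mode: str,
    n_edges_total: int,
    outcome_name: str = "",
) -> CPMModel:
    sc = scores - scores.mean()
    var = (sc**2).sum()
    if var == 0 or np.unique(scores).size < 3:
        raise DegenerateDataError(
            "summary scores have (near-)zero variance; cannot fit a line"
        )
    slope = float((sc * (y - y.mean())).sum() / var)
    intercept = float(y.mean() - slope * scores.mean())
    return CPMModel(
        mask=mask,
        score_mode=score_mode,
        slope=slope,
        intercept=intercept,
        train_n=y.size,
        n_edges=n_edges_total,
        outcome_name=outcome_name,
    )


def predict_cpm(
    model: CPMModel, edges: np.ndarray, invert_scores: bool = False
) -> np.ndarray:
    """Predicted outcome per subject: intercept + slope · summary score.

    ``invert_scores`` negates the summary scores before applying the fixed
    fitted coefficients (the inverted-model experiment).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim == 1:
        edges = edges[None, :]
    if edges.shape[1] != model.n_edges:
        raise ValueError(
            f"edge count {edges.shape[1]} != model's training E={model.n_edges}"
        )
    scores = np.asarray(summary_score(edges, model.mask, model.score_mode))
    if invert_scores:
        scores = -scores
    return model.intercept + model.slope * scores


# ---------------------------------------------------------------------------
# Cross-validated prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitScheme:
    """Repeated random subject-level train/test splits."""

    n_splits: int = 100
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def generate_splits(n_subjects: int, scheme: SplitScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded unique train/test index splits.

    Each split's RNG derives deterministically from (master seed, split index,
    attempt), so any split is reproducible in isolation; duplicate training
    sets are rejected and redrawn.
    """
    n_train = int(np.floor(n_subjects * scheme.train_fraction))
    n_train = min(max(n_train, 1), n_subjects - 1)
    if n_subjects - n_train < 1:
        raise ValueError("test set would be empty")
    from math import comb
    if comb(n_subjects, n_train) < scheme.n_splits:
        raise ValueError(
            f"cannot draw {scheme.n_splits} unique splits of {n_train} from "
            f"{n_subjects} subjects"
        )
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    seen: set[tuple[int, ...]] = set()
    for i in range(scheme.n_splits):
        for attempt in range(1000):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=scheme.seed, spawn_key=(i, attempt))
            )
            perm = rng.permutation(n_subjects)
            train = np.sort(perm[:n_train])
            key = tuple(train.tolist())
            if key not in seen:
                seen.add(key)
                splits.append((train, np.sort(perm[n_train:])))
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to draw a unique split in 1000 attempts")
    return splits


@dataclass
class PredictionResult:
    """Cross-validated prediction accuracy for one outcome/configuration."""

    per_split_r: np.ndarray
    outcome_name: str
    score_mode: str
    p_threshold: float
    n_failed_splits: int = 0
    permutation_p: float | None = None
    permutation_p_label: str | None = None
    corrected_p: float | None = None
    masks: list[FeatureMask] | None = None
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def mean_r(self) -> float:
        """Mean accuracy over splits with a defined r."""
        valid = self.per_split_r[np.isfinite(self.per_split_r)]
        return float(valid.mean()) if valid.size else float("nan")


def _edges_array(connectomes: ConnectomeSet | np.ndarray) -> np.ndarray:
    if isinstance(connectomes, ConnectomeSet):
        return connectomes.edges
    return np.asarray(connectomes, dtype=float)


def run_cpm(
    connectomes: ConnectomeSet | np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme = SplitScheme(),
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    outcome_name: str = "",
    covariate: np.ndarray | None = None,
    keep_masks: bool = False,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> PredictionResult:
    """Cross-validated CPM over repeated random splits.

    Per split, records the Pearson r between predicted and observed test
    outcomes (partial r controlling ``covariate`` within the test set when
    one is given). Splits whose required feature-set side is empty, or whose
    test r is undefined, are recorded as NaN and excluded from the mean; if
    more than half the splits fail, the run aborts with guidance to relax the
    threshold.
    """
    X = _edges_array(connectomes)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("edge matrix and outcome have different subject counts")
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.size != y.size:
            raise ValueError("covariate length mismatch")
        if np.isnan(covariate).any():
            raise DegenerateDataError("covariate has missing values")
    if splits is None:
        splits = generate_splits(X.shape[0], scheme)
    per_r = np.full(len(splits), np.nan)
    masks: list[FeatureMask | None] = []
    n_empty = 0
    for k, (tr, te) in enumerate(splits):
        try:
            model = fit_cpm(X[tr], y[tr], p_threshold, score_mode, outcome_name)
        except (EmptyMaskError, DegenerateDataError) as err:
            logger.warning("split %d of outcome %r skipped: %s", k, outcome_name, err)
            n_empty += 1
            masks.append(None)
            continue
        masks.append(model.mask)
        pred = predict_cpm(model, X[te])
        if covariate is None:
            r = _pearson(pred, y[te])
        else:
            z = covariate[te]
            if np.unique(z).size < 2:
                logger.warning("split %d: constant test covariate; r missing", k)
                continue
            r = partial_pearson(pred, y[te], z)
        if np.isfinite(r):
            per_r[k] = r
        else:
            logger.warning("split %d: undefined test-set correlation", k)
    if n_empty > len(splits) / 2:
        raise RuntimeError(
            f"{n_empty}/{len(splits)} splits produced an empty required feature "
            f"set; relax p_threshold (currently {p_threshold})"
        )
    return PredictionResult(
        per_split_r=per_r,
        outcome_name=outcome_name,
        score_mode=score_mode,
        p_threshold=p_threshold,
        n_failed_splits=int(np.sum(~np.isfinite(per_r))),
        masks=masks if keep_masks else None,
        splits=splits,
    )


def external_validate(
    full_model: CPMModel, target_edges: np.ndarray, target_y: np.ndarray
) -> tuple[float, float]:
    """Apply a model fitted on one cohort to another, without refitting.

    Returns the Pearson r and two-sided parametric p between predicted and
    observed outcomes in the target cohort.
    """
    target_y = np.asarray(target_y, dtype=float)
    if target_y.size < 4:
        raise DegenerateDataError(
            f"external validation needs >=4 subjects, got {target_y.size}"
        )
    pred = predict_cpm(full_model, target_edges)
    res = stats.pearsonr(pred, target_y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Model serialization (plain-text JSON)
# ---------------------------------------------------------------------------

def save_model(model: CPMModel, path: str | Path) -> None:
    """Write a fitted model to a structured text (JSON) file."""
    payload = {
        "format": "cpmkit-model-v1",
        "outcome_name": model.outcome_name,
        "score_mode": model.score_mode,
        "slope": model.slope,
        "intercept": model.intercept,
        "train_n": model.train_n,
        "n_edges": model.n_edges,
        "p_threshold": model.mask.p_threshold,
        "positive_edges": model.mask.positive.tolist(),
        "negative_edges": model.mask.negative.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> CPMModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "cpmkit-model-v1":
        raise ValueError(f"{path} is not a cpmkit model file")
    mask = FeatureMask(
        positive=np.asarray(payload["positive_edges"], dtype=int),
        negative=np.asarray(payload["negative_edges"], dtype=int),
        p_threshold=float(payload["p_threshold"]),
    )
    return CPMModel(
        mask=mask,
        score_mode=payload["score_mode"],
        slope=float(payload["slope"]),
        intercept=float(payload["intercept"]),
        train_n=int(payload["train_n"]),
        n_edges=int(payload["n_edges"]),
        outcome_name=payload.get("outcome_name", ""),
    )
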