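"""Permutation-based significance of CPM accuracy and Bonferroni correction.

The permutation null shuffles the outcome over subjects and reruns the full
cross-validated pipeline (feature selection inside every split), recording the
mean test-set r per permutation. The p-value is the proportion of permuted
mean accuracies numerically greater than the observed mean accuracy; when no
permutation exceeds it, the p is reported as a bound "< 1/n_permutations".

Permutations reuse the same split definitions as the observed run, so the
shuffling of y is the only varying factor. The inner loop is vectorized: per
split, the edge–outcome correlations for every permutation are one matrix
product, which keeps thousand-permutation runs at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .core import (
    PredictionResult,
    SplitScheme,
    critical_r,
    generate_splits,
    run_cpm,
    _edges_array,
)
from .io import ConnectomeSet

logger = logging.getLogger(__name__)

#: spawn key marking the permutation RNG stream derived from the master seed.
_PERM_STREAM = 7001

#: target bytes for one permutation chunk's E×chunk correlation matrix.
_CHUNK_BYTES = 1.2e8


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_corrected = min(1, m·p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the {p.size} p-values supplied")
    return np.minimum(1.0, m * p)


@dataclass
class PermutationNull:
    """Null distribution of mean cross-validated accuracy."""

    n_permutations: int
    null_mean_r: np.ndarray
    observed_mean_r: float
    p_value: float
    p_label: str
    estimator: str = "strict"
    splits_per_perm: int | None = None


def _column_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matched columns of A and B (NaN when degenerate)."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    den = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=0) / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _null_means_chunk(
    X: np.ndarray,
    Yperm: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    p_threshold: float,
    score_mode: str,
    covariate: np.ndarray | None,
) -> np.ndarray:
    """Mean-over-splits test r for each permuted outcome column."""
    n_perm = Yperm.shape[1]
    r_sum = np.zeros(n_perm)
    r_cnt = np.zeros(n_perm, dtype=int)
    for tr, te in splits:
        Xtr = X[tr]
        Xte = X[te]
        Xc = Xtr - Xtr.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        const = sx == 0
        sx_safe = np.where(const, 1.0, sx)
        Ytr = Yperm[tr]
        Yc = Ytr - Ytr.mean(axis=0)
        sy = np.sqrt((Yc**2).sum(axis=0))
        sy_safe = np.where(sy == 0, 1.0, sy)
        R = (Xc.T @ Yc) / (sx_safe[:, None] * sy_safe[None, :])
        R[const, :] = 0.0
        rc = critical_r(p_threshold, tr.size)
        pos = R > rc
        neg = R < -rc
        if score_mode == "combined":
            S = pos.astype(float) - neg.astype(float)
            valid = pos.any(axis=0) & neg.any(axis=0)
        elif score_mode == "positive_only":
            S = pos.astype(float)
            valid = pos.any(axis=0)
        elif score_mode == "negative_only":
            S = neg.astype(float)
            valid = neg.any(axis=0)
        else:
            raise ValueError(f"unknown score mode {score_mode!r}")
        valid &= sy > 0
        Str = Xtr @ S
        Ste = Xte @ S
        Strc = Str - Str.mean(axis=0)
        var = (Strc**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = (Strc * Yc).sum(axis=0) / var
        valid &= var > 0
        Yte = Yperm[te]
        pred = slope[None, :] * Ste
        r = _column_pearson(pred, Yte)
        if covariate is not None:
            z = covariate[te]
            Z = np.broadcast_to(z[:, None], pred.shape)
            rxz = _column_pearson(pred, Z)
            ryz = _column_pearson(Yte, Z)
            den_sq = (1.0 - rxz**2) * (1.0 - ryz**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (r - rxz * ryz) / np.sqrt(den_sq)
            r[~(den_sq > 0)] = np.nan
        ok = valid & np.isfinite(r)
        r_sum[ok] += r[ok]
        r_cnt[ok] += 1
    means = np.full(n_perm, np.nan)
    nonzero = r_cnt > 0
    means[nonzero] = r_sum[nonzero] / r_cnt[nonzero]
    return means


def permutation_test(
    connectomes: ConnectomeSet | np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme = SplitScheme(),
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    n_permutations: int = 1000,
    splits_per_perm: int | None = None,
    covariate: np.ndarray | None = None,
    estimator: str = "strict",
    n_jobs: int = 1,
    observed: PredictionResult | None = None,
    outcome_name: str = "",
) -> PermutationNull:
    """Permutation test of mean cross-validated prediction accuracy.

    Parameters
    ----------
    splits_per_perm
        Optional reduced number of splits evaluated per permutation (the
        first k of the observed run's splits) for desk-scale runs; the
        observed mean always uses the full scheme. Logged prominently.
    estimator
        ``"strict"`` (default): p = #(null > observed) / n_permutations,
        reported as "< 1/n" when the count is zero. ``"add_one"``: the
        conventional (k+1)/(n+1) estimator.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations < 20 cannot resolve any useful p-value")
    if n_permutations < 100:
        logger.warning("n_permutations=%d is low; p resolution is coarse", n_permutations)
    if estimator not in ("strict", "add_one"):
        raise ValueError(f"unknown estimator {estimator!r}")
    X = _edges_array(connectomes)
    y = np.asarray(y, dtype=float)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
    if observed is None:
        observed = run_cpm(
            X, y, scheme, p_threshold, score_mode,
            outcome_name=outcome_name, covariate=covariate,
        )
    splits = observed.splits
    if splits is None:
        splits = generate_splits(X.shape[0], scheme)
    if splits_per_perm is not None:
        if splits_per_perm < 1 or splits_per_perm > len(splits):
            raise ValueError("splits_per_perm out of range")
        logger.warning(
            "fast mode: permutations use the first %d of %d splits",
            splits_per_perm, len(splits),
        )
        splits = splits[:splits_per_perm]

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scheme.seed, spawn_key=(_PERM_STREAM,))
    )
    n = y.size
    perm_idx = np.column_stack([rng.permutation(n) for _ in range(n_permutations)])
    Yperm = y[perm_idx]  # n × n_permutations

    chunk = max(1, int(_CHUNK_BYTES / (X.shape[1] * 8)))
    bounds = list(range(0, n_permutations, chunk))
    tasks = [Yperm[:, b:b + chunk] for b in bounds]
    if n_jobs != 1 and len(tasks) > 1:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_null_means_chunk)(X, t, splits, p_threshold, score_mode, covariate)
            for t in tasks
        )
    else:
        parts = [
            _null_means_chunk(X, t, splits, p_threshold, score_mode, covariate)
            for t in tasks
        ]
    null_means = np.concatenate(parts)
    n_nan = int(np.sum(~np.isfinite(null_means)))
    if n_nan:
        logger.warning("%d/%d permutations yielded no valid split", n_nan, n_permutations)

    obs = observed.mean_r
    exceed = int(np.sum(null_means > obs))  # NaN compares False
    if estimator == "strict":
        p = exceed / n_permutations
        label = f"< {1 / n_permutations:g}" if exceed == 0 else f"{p:g}"
    else:
        p = (exceed + 1) / (n_permutations + 1)
        label = f"{p:g}"
    return PermutationNull(
        n_permutations=n_permutations,
        null_mean_r=null_means,
        observed_mean_r=obs,
        p_value=float(p),
        p_label=label,
        estimator=estimator,
        splits_per_perm=splits_per_perm,
    )
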