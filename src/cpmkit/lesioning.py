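"""Virtual network lesioning: feature importance for CPM.

A lesion removes every edge incident to one atlas network from the input edge
matrix and reruns the whole cross-validated pipeline — including feature
selection — on the remaining edges, with the same splits as the intact run.
The network's importance is the per-split change in accuracy
(delta = lesioned r − full r), summarized as mean ± SE with a matched-split
sign-flip permutation p, Bonferroni-corrected over the 12 networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PredictionResult, SplitScheme, run_cpm, _edges_array
from .inference import bonferroni
from .io import (
    CANONICAL_NETWORKS,
    ConnectomeSet,
    NetworkAtlas,
    edge_pairs,
    edges_of_network,
)

logger = logging.getLogger(__name__)

_FLIP_STREAM = 7002


@dataclass
class LesionResult:
    """Change in prediction accuracy after lesioning one network."""

    network_label: str
    score_mode: str
    delta_r: np.ndarray
    mean_delta: float
    se_delta: float
    p_value: float
    p_corrected: float | None = None
    n_matched: int = 0
    full_mean_r: float = float("nan")
    lesioned_mean_r: float = float("nan")


def signflip_pvalue(deltas: np.ndarray, n_flips: int = 10000, seed: int = 0) -> float:
    """Two-sided sign-flip permutation p for a mean of paired differences.

    Uses the conventional (k+1)/(n+1) estimator so the p never reaches zero.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return float("nan")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_FLIP_STREAM,))
    )
    signs = rng.choice([-1.0, 1.0], size=(n_flips, deltas.size))
    flipped = (signs * deltas).mean(axis=1)
    observed = abs(deltas.mean())
    k = int(np.sum(np.abs(flipped) >= observed))
    return (k + 1) / (n_flips + 1)


def lesion_and_rerun(
    connectomes: ConnectomeSet | np.ndarray,
    y: np.ndarray,
    atlas: NetworkAtlas,
    label: str,
    scheme: SplitScheme = SplitScheme(),
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    full_result: PredictionResult | None = None,
    n_sign_flips: int = 10000,
    within_only: bool = False,
) -> LesionResult:
    """Lesion one network and measure the matched-split change in accuracy.

    ``full_result`` (the intact run under the same scheme) is recomputed when
    not supplied; supplying it guarantees split matching and saves a run.
    """
    X = _edges_array(connectomes)
    lesioned_edges = edges_of_network(atlas, label, within_only=within_only)
    keep = np.setdiff1d(np.arange(X.shape[1]), lesioned_edges)
    if keep.size == 0:
        raise ValueError(f"lesioning {label!r} would remove every edge")
    if full_result is None:
        full_result = run_cpm(X, y, scheme, p_threshold, score_mode)
    splits = full_result.splits
    lesioned = run_cpm(
        X[:, keep], y, scheme, p_threshold, score_mode, splits=splits
    )
    both = np.isfinite(full_result.per_split_r) & np.isfinite(lesioned.per_split_r)
    deltas = lesioned.per_split_r[both] - full_result.per_split_r[both]
    mean_delta = float(deltas.mean()) if deltas.size else float("nan")
    se_delta = (
        float(deltas.std(ddof=1) / np.sqrt(deltas.size)) if deltas.size > 1 else float("nan")
    )
    p = signflip_pvalue(deltas, n_flips=n_sign_flips, seed=scheme.seed)
    return LesionResult(
        network_label=label,
        score_mode=score_mode,
        delta_r=deltas,
        mean_delta=mean_delta,
        se_delta=se_delta,
        p_value=p,
        n_matched=int(deltas.size),
        full_mean_r=full_result.mean_r,
        lesioned_mean_r=lesioned.mean_r,
    )


def lesion_sweep(
    connectomes: ConnectomeSet | np.ndarray,
    y: np.ndarray,
    atlas: NetworkAtlas,
    scheme: SplitScheme = SplitScheme(),
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    full_result: PredictionResult | None = None,
    n_sign_flips: int = 10000,
    networks: tuple[str, ...] | None = None,
) -> list[LesionResult]:
    """Lesion each canonical network in turn, Bonferroni-corrected.

    Correction is over the networks actually lesioned within this
    (outcome, score_mode) family.
    """
    X = _edges_array(connectomes)
    if full_result is None:
        full_result = run_cpm(X, y, scheme, p_threshold, score_mode)
    if networks is None:
        networks = tuple(n for n in CANONICAL_NETWORKS if (atlas.labels == n).any())
    results = [
        lesion_and_rerun(
            X, y, atlas, label, scheme, p_threshold, score_mode,
            full_result=full_result, n_sign_flips=n_sign_flips,
        )
        for label in networks
    ]
    corrected = bonferroni([r.p_value for r in results], m=len(results))
    for res, pc in zip(results, corrected):
        res.p_corrected = float(pc)
    return results


def lesion_table(results: list[LesionResult]) -> pd.DataFrame:
    """Tabulate a sweep in the supplementary-table layout."""
    return pd.DataFrame(
        {
            "network": [r.network_label for r in results],
            "score_mode": [r.score_mode for r in results],
            "mean_delta_r": [r.mean_delta for r in results],
            "se_delta_r": [r.se_delta for r in results],
            "p_value": [r.p_value for r in results],
            "p_corrected": [r.p_corrected for r in results],
            "n_matched_splits": [r.n_matched for r in results],
        }
    )


def selection_fraction_matrix(
    result: PredictionResult,
    atlas: NetworkAtlas,
    side: str = "positive",
) -> pd.DataFrame:
    """Average fraction of selected edges per network pair, over splits.

    Entry (A, B) is the mean over cross-validation splits of the number of
    selected edges with endpoints in networks A and B divided by the number of
    possible A–B edges. Requires ``run_cpm(..., keep_masks=True)``. Edges with
    an unassigned endpoint are not counted.
    """
    if result.masks is None:
        raise ValueError("run_cpm must be called with keep_masks=True")
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    nets = list(CANONICAL_NETWORKS)
    net_of = {n: k for k, n in enumerate(nets)}
    iu, ju = edge_pairs(atlas.n_parcels)
    lab_i = atlas.labels[iu]
    lab_j = atlas.labels[ju]
    # per-edge (network, network) cell, -1 for unassigned endpoints
    cell_a = np.array([net_of.get(l, -1) for l in lab_i])
    cell_b = np.array([net_of.get(l, -1) for l in lab_j])
    ok = (cell_a >= 0) & (cell_b >= 0)
    lo = np.minimum(cell_a, cell_b)
    hi = np.maximum(cell_a, cell_b)
    denom = np.zeros((len(nets), len(nets)))
    np.add.at(denom, (lo[ok], hi[ok]), 1)
    counts = np.zeros_like(denom)
    n_masks = 0
    for mask in result.masks:
        if mask is None:
            continue
        n_masks += 1
        sel = getattr(mask, side)
        sel = sel[ok[sel]]
        np.add.at(counts, (lo[sel], hi[sel]), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, counts / np.maximum(denom, 1) / max(n_masks, 1), 0.0)
    frac = np.triu(frac) + np.triu(frac, k=1).T  # symmetric
    return pd.DataFrame(frac, index=nets, columns=nets)
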