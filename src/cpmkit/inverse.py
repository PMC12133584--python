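"""Inverted-model experiment for frequently misclassified subjects.

Fit a full-sample CPM on the correctly classified subgroup (low MI), apply it
unchanged to the frequently misclassified subgroup (high MI), then reapply it
with every summary score negated before the fixed fitted linear map. Because
negating the input of a fixed linear map negates the predicted–observed
Pearson correlation exactly, r_inverted = −r_direct holds to machine
precision; a strongly negative r_direct together with a positive r_inverted
is the signature of a subgroup whose edge–behavior coupling is sign-reversed
relative to the training majority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CPMModel, fit_cpm, predict_cpm, _edges_array, _pearson
from .io import ConnectomeSet
from .misclassification import MIProfile

logger = logging.getLogger(__name__)


@dataclass
class InverseModelResult:
    """Direct and sign-inverted accuracy of a low-MI-trained model."""

    outcome_name: str
    r_direct: float
    r_inverted: float
    n_train: int
    n_test: int
    model: CPMModel | None = None


def run_inverse_experiment(
    connectomes: ConnectomeSet | np.ndarray,
    y: np.ndarray,
    mi_profile: MIProfile,
    train_cut: float = 0.4,
    test_cut: float = 0.5,
    p_threshold: float = 0.01,
    score_mode: str = "combined",
    outcome_name: str = "",
    refit_inverted: bool = False,
) -> InverseModelResult:
    """Train on MI < ``train_cut`` subjects, test on MI > ``test_cut`` ones.

    ``refit_inverted=True`` refits the linear map on the training subjects'
    negated scores instead of keeping the coefficients fixed (a documented
    variant under which |r_inverted| need not equal |r_direct|; with a fixed
    map the refit only flips the slope sign, so it differs once the training
    pool or selection changes).
    """
    X = _edges_array(connectomes)
    y = np.asarray(y, dtype=float)
    mi = np.asarray(mi_profile.mi, dtype=float)
    if mi.size != y.size:
        raise ValueError("MI profile and outcome cover different subject counts")
    train = np.flatnonzero(mi < train_cut)
    test = np.flatnonzero(mi > test_cut)
    if train.size < 4 or test.size < 4:
        raise ValueError(
            f"subgroups too small: {train.size} train (MI<{train_cut}), "
            f"{test.size} test (MI>{test_cut}); need >=4 each"
        )
    model = fit_cpm(X[train], y[train], p_threshold, score_mode, outcome_name)
    pred_direct = predict_cpm(model, X[test])
    r_direct = _pearson(pred_direct, y[test])
    if refit_inverted:
        from .core import summary_score, _fit_linear
        scores_tr = -np.asarray(summary_score(X[train], model.mask, score_mode))
        inv_model = _fit_linear(
            model.mask, scores_tr, y[train], score_mode, X.shape[1], outcome_name
        )
        scores_te = -np.asarray(summary_score(X[test], model.mask, score_mode))
        pred_inv = inv_model.intercept + inv_model.slope * scores_te
    else:
        pred_inv = predict_cpm(model, X[test], invert_scores=True)
    r_inverted = _pearson(pred_inv, y[test])
    logger.info(
        "inverse experiment (%s): n_train=%d n_test=%d r_direct=%.3f r_inverted=%.3f",
        outcome_name or "outcome", train.size, test.size, r_direct, r_inverted,
    )
    return InverseModelResult(
        outcome_name=outcome_name,
        r_direct=float(r_direct),
        r_inverted=float(r_inverted),
        n_train=int(train.size),
        n_test=int(test.size),
        model=model,
    )
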