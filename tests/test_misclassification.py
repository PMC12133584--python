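"""Binary scorer classification, misclassification index, covariate dissection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpmkit import core, misclassification as mc
from cpmkit.synthetic import SyntheticConfig, balanced_atlas, generate


class TestBinarize:
    def test_even_n_median_split(self):
        classes = mc.binarize_outcome(np.array([1.0, 2.0, 3.0, 4.0]))
        assert classes.tolist() == [0, 0, 1, 1]

    def test_odd_n_at_median_goes_low(self):
        classes = mc.binarize_outcome(np.array([10.0, 20.0, 30.0]))
        assert classes.tolist() == [0, 0, 1]

    def test_class_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in (9, 10, 31, 92):
            classes = mc.binarize_outcome(rng.normal(size=n))
            assert abs((classes == 0).sum() - (classes == 1).sum()) <= 1

    def test_constant_outcome_rejected(self):
        with pytest.raises(core.DegenerateDataError):
            mc.binarize_outcome(np.full(10, 3.0))


@pytest.fixture(scope="module")
def separable_dataset():
    """Strong signal, no discordant subjects: classes nearly separable."""
    cfg = SyntheticConfig(
        n_subjects=40, atlas=balanced_atlas(5, ("DMN", "VIS", "SM", "FPN")),
        planted_fraction=0.1, default_pair_negative=("SM", "FPN"),
        effect_beta=3.0, outcome_noise_sd=0.05, seed=3,
    )
    conn, behavior, truth = generate(cfg)
    return conn, behavior.outcome("total"), truth


class TestMisclassificationIndex:
    def test_separable_subjects_have_low_mi(self, separable_dataset):
        conn, y, _ = separable_dataset
        prof = mc.run_misclassification(
            conn, mc.binarize_outcome(y), n_iterations=20, seed=3
        )
        assert np.median(prof.mi) == 0.0
        # the subject furthest from the class boundary is never misclassified
        extreme = int(np.argmax(np.abs(y - np.median(y))))
        assert prof.mi[extreme] == 0.0

    def test_mi_bounds_and_frame(self, separable_dataset):
        conn, y, _ = separable_dataset
        prof = mc.run_misclassification(
            conn, mc.binarize_outcome(y), n_iterations=10, seed=3
        )
        assert ((prof.mi >= 0) & (prof.mi <= 1)).all()
        frame = prof.to_frame()
        assert set(frame.columns) == {"scorer_class", "mi", "n_iterations"}
        assert 0.0 <= prof.fraction_above(0.5) <= 1.0

    def test_mi_invariant_to_subject_order(self, separable_dataset):
        conn, y, _ = separable_dataset
        classes = mc.binarize_outcome(y)
        prof = mc.run_misclassification(conn.edges, classes, n_iterations=8, seed=5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(y))
        ids = [f"S{k:04d}" for k in range(len(y))]
        prof_p = mc.run_misclassification(
            conn.edges[perm], classes[perm], n_iterations=8, seed=5,
            subject_ids=[ids[k] for k in perm],
        )
        back = {sid: m for sid, m in zip(prof_p.subject_ids, prof_p.mi)}
        assert all(back[sid] == m for sid, m in zip(ids, prof.mi))

    def test_single_class_rejected(self, separable_dataset):
        conn, y, _ = separable_dataset
        with pytest.raises(core.DegenerateDataError):
            mc.run_misclassification(conn, np.ones(len(y), dtype=int), n_iterations=5)

    def test_too_small_subsample_rejected(self):
        cfg = SyntheticConfig(
            n_subjects=10, atlas=balanced_atlas(4, ("DMN", "VIS")),
            default_pair_positive=("DMN", "VIS"), default_pair_negative=("VIS", "VIS"),
            seed=0,
        )
        conn, behavior, _ = generate(cfg)
        with pytest.raises(core.DegenerateDataError, match="too small"):
            mc.run_misclassification(
                conn, mc.binarize_outcome(behavior.outcome("total")), n_iterations=5
            )


class TestCovariateDissection:
    def test_covariate_copy_of_mi_correlates_perfectly(self, separable_dataset):
        conn, y, _ = separable_dataset
        rng = np.random.default_rng(9)
        mi = rng.uniform(0, 1, size=len(y))
        prof = mc.MIProfile(
            [f"S{k:04d}" for k in range(len(y))], mc.binarize_outcome(y), mi, 100
        )
        data = pd.DataFrame(
            {"total": y, "cov": mi}, index=pd.Index(prof.subject_ids, name="subject_id")
        )
        out = mc.mi_covariate_dissection(prof, data, "total", ["cov"])
        mi_rows = out[out.analysis == "mi_vs_covariate"]
        assert np.allclose(mi_rows.r.dropna(), 1.0)

    def test_small_stratum_flagged_not_computed(self, separable_dataset):
        conn, y, _ = separable_dataset
        mi = np.zeros(len(y))
        mi[:2] = 0.9  # only two "misclassified" subjects
        prof = mc.MIProfile(
            [f"S{k:04d}" for k in range(len(y))], mc.binarize_outcome(y), mi, 100
        )
        data = pd.DataFrame(
            {"total": y, "cov": np.arange(len(y), dtype=float)},
            index=pd.Index(prof.subject_ids, name="subject_id"),
        )
        out = mc.mi_covariate_dissection(prof, data, "total", ["cov"])
        row = out[(out.analysis == "covariate_vs_outcome") & (out.stratum == "misclassified")]
        assert not row.computed.item()
        assert np.isnan(row.r.item())

    def test_categorical_encoding_is_lexicographic(self):
        col = pd.Series(["M", "F", "F", "M"])
        assert mc.encode_covariate(col).tolist() == [1.0, 0.0, 0.0, 1.0]


class TestCovariedPrediction:
    def test_independent_covariate_preserves_accuracy(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        y = behavior.outcome("total")
        scheme = core.SplitScheme(20, 0.7, 13)
        raw = core.run_cpm(conn, y, scheme)
        rng = np.random.default_rng(13)
        z = rng.normal(size=len(y))
        part = mc.covaried_prediction(conn, y, z, scheme)
        assert part.mean_r == pytest.approx(raw.mean_r, abs=0.1)

    def test_missing_covariate_rejected(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        y = behavior.outcome("total")
        z = np.full(len(y), np.nan)
        with pytest.raises(core.DegenerateDataError, match="missing"):
            mc.covaried_prediction(conn, y, z, core.SplitScheme(5, 0.7, 1))
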