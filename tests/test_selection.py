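import numpy as np
import pytest

from mrrmrr import (
    DataMatrix,
    MeasureSpec,
    MRRMRRSelector,
    SelectionConfig,
    first_variable,
    mrmr_forward,
    relevance_one,
    step_score,
)
from mrrmrr.measures import redundancy_pairwise
from mrrmrr import shrinkage


def naive_greedy(data, config):
    """Independent brute-force reimplementation of the forward search."""
    rel = [
        relevance_one(data.Y, data.X[:, j], config.relevance, seed=config.seed)
        for j in range(data.p)
    ]
    selected = [int(np.argmax(rel))]
    while len(selected) < config.m:
        best_j, best = None, -np.inf
        for j in range(data.p):
            if j in selected:
                continue
            if config.redundancy.name == "reg_multiple":
                T = data.X[:, selected]
                if config.redundancy_mode == "multiple":
                    red = shrinkage.reg_multiple_corr(data.X[:, j], T).value
                else:
                    joint = np.column_stack([T, data.X[:, j]])
                    lam = shrinkage.lambda_star(joint)
                    R = shrinkage.sample_correlation(joint)
                    red = float(np.abs((1 - lam) * R[-1, :-1]).mean())
            else:
                red = float(np.mean([
                    redundancy_pairwise(data.X[:, k], data.X[:, j], config.redundancy)
                    for k in selected
                ]))
            score = rel[j] - config.gamma * red
            if score > best:
                best_j, best = j, score
        selected.append(best_j)
    return selected


class TestFirstVariable:
    def test_planted_copy_of_labels_wins(self, rng):
        Y = np.repeat([1, 2], 10)
        X = rng.normal(size=(20, 5))
        X[:, 2] = Y + 0.01 * rng.normal(size=20)
        m = MeasureSpec("relevance", "pearson_abs")
        assert first_variable(DataMatrix(X=X, Y=Y), m) == 2

    def test_tie_goes_to_smallest_index(self, rng):
        Y = np.repeat([1, 2], 10)
        x = rng.normal(size=20)
        X = np.column_stack([x, x, x])
        m = MeasureSpec("relevance", "pearson_abs")
        assert first_variable(DataMatrix(X=X, Y=Y), m) == 0


class TestStepScore:
    def test_gamma_zero_equals_relevance(self, small_data):
        cfg = SelectionConfig(m=3, gamma=0.0,
                              relevance=MeasureSpec("relevance", "pearson_abs"))
        rel = relevance_one(small_data.Y, small_data.X[:, 5], cfg.relevance, seed=cfg.seed)
        assert step_score(small_data.X[:, 5], [0], small_data, cfg) == pytest.approx(rel)

    def test_redundant_candidate_scores_below_fresh_one(self, rng):
        Y = np.repeat([1, 2], 15)
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        data = DataMatrix(X=X, Y=Y)
        cfg = SelectionConfig(
            m=2, gamma=5.0,
            relevance=MeasureSpec("relevance", "pearson_abs"),
            redundancy=MeasureSpec("redundancy", "pearson_abs"),
        )
        dup = step_score(X[:, 1], [0], data, cfg)
        fresh = step_score(X[:, 2], [0], data, cfg)
        assert dup < fresh

    @pytest.mark.parametrize("mode", ["multiple", "pairwise_mean"])
    def test_engine_matches_reference_path(self, rng, mode):
        from mrrmrr.selection import SelectionEngine

        Y = np.repeat([1, 2], 10)
        X = rng.normal(size=(20, 8))
        data = DataMatrix(X=X, Y=Y)
        cfg = SelectionConfig(
            m=4, gamma=0.7,
            relevance=MeasureSpec("relevance", "pearson_abs"),
            redundancy=MeasureSpec("redundancy", "reg_multiple"),
            redundancy_mode=mode,
        )
        eng = SelectionEngine(X, Y, cfg.relevance, cfg.redundancy, mode, cfg.seed)
        for S in ([2], [2, 5], [0, 3, 6]):
            for j in range(8):
                if j in S:
                    continue
                fast = eng.score(S, j, cfg.gamma)
                slow = step_score(X[:, j], S, data, cfg)
                assert fast == pytest.approx(slow, abs=1e-10)


class TestForwardSearch:
    def test_gamma_zero_selects_top_relevance(self, small_data):
        cfg = SelectionConfig(m=4, gamma=0.0,
                              relevance=MeasureSpec("relevance", "pearson_abs"),
                              redundancy=MeasureSpec("redundancy", "pearson_abs"))
        res = mrmr_forward(small_data, cfg)
        rel = [relevance_one(small_data.Y, small_data.X[:, j], cfg.relevance)
               for j in range(small_data.p)]
        assert res.selected == list(np.argsort(-np.array(rel), kind="stable")[:4])

    def test_duplicate_signal_is_skipped_under_redundancy_penalty(self, rng):
        # columns 0 and 1 are byte-identical signals; 2 is an independent signal
        Y = np.repeat([1, 2], 15)
        signal1 = Y + 0.8 * rng.normal(size=30)
        signal2 = Y + 0.8 * rng.normal(size=30)
        X = np.column_stack([signal1, signal1, signal2] + [rng.normal(size=30) for _ in range(5)])
        data = DataMatrix(X=X, Y=Y)
        res = mrmr_forward(data, SelectionConfig(m=3, gamma=1.0))
        picked = set(res.selected)
        assert 2 in picked
        assert len(picked & {0, 1}) == 1  # both distinct signals, never the duplicate
        assert res.selected[1] != 1 or res.selected[0] != 0

    @pytest.mark.parametrize(
        "relevance,redundancy,mode",
        [
            ("pearson_abs", "pearson_abs", "multiple"),
            ("spearman_abs", "ks_pvalue", "multiple"),
            ("lws_adaptive_abs", "reg_multiple", "multiple"),
            ("lws_linear_abs", "reg_multiple", "pairwise_mean"),
            ("mutual_information", "sign_pvalue", "multiple"),
        ],
    )
    def test_matches_brute_force_oracle(self, small_data, relevance, redundancy, mode):
        cfg = SelectionConfig(
            m=4, gamma=0.6,
            relevance=MeasureSpec("relevance", relevance),
            redundancy=MeasureSpec("redundancy", redundancy),
            redundancy_mode=mode,
        )
        assert mrmr_forward(small_data, cfg).selected == naive_greedy(small_data, cfg)

    def test_column_permutation_equivariance(self, small_data, rng):
        cfg = SelectionConfig(m=3, gamma=0.5,
                              relevance=MeasureSpec("relevance", "pearson_abs"),
                              redundancy=MeasureSpec("redundancy", "pearson_abs"))
        base = mrmr_forward(small_data, cfg).selected
        perm = rng.permutation(small_data.p)
        permuted = DataMatrix(X=small_data.X[:, perm], Y=small_data.Y)
        res = mrmr_forward(permuted, cfg).selected
        assert [perm[j] for j in res] == base

    def test_first_step_independent_of_gamma(self, small_data):
        sel = []
        for g in (0.1, 1.7):
            cfg = SelectionConfig(m=2, gamma=g)
            sel.append(mrmr_forward(small_data, cfg).selected[0])
        assert sel[0] == sel[1]

    def test_reproducible_trace(self, small_data):
        cfg = SelectionConfig(m=4, gamma=0.8)
        a = mrmr_forward(small_data, cfg)
        b = mrmr_forward(small_data, cfg)
        assert a.selected == b.selected
        assert a.steps == b.steps

    def test_m_larger_than_p_rejected(self, small_data):
        with pytest.raises(ValueError):
            mrmr_forward(small_data, SelectionConfig(m=100))


class TestMRRMRRSelectorEstimator:
    def test_sklearn_contract(self, small_data):
        from sklearn.base import clone

        sel = MRRMRRSelector(n_features_to_select=3, gamma=0.5,
                             relevance="pearson_abs", redundancy="pearson_abs")
        cloned = clone(sel)
        cloned.fit(small_data.X, small_data.Y)
        assert cloned.support_.sum() == 3
        Xr = cloned.transform(small_data.X)
        assert Xr.shape == (small_data.n, 3)
        assert sorted(cloned.selected_) == sorted(np.flatnonzero(cloned.support_).tolist())

    def test_accepts_arbitrary_binary_labels(self, small_data):
        sel = MRRMRRSelector(n_features_to_select=2, relevance="pearson_abs",
                             redundancy="pearson_abs")
        y = np.where(small_data.Y == 1, "ctrl", "case")
        sel.fit(small_data.X, y)
        assert len(sel.selected_) == 2

    def test_works_in_a_pipeline(self, small_data):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([
            ("select", MRRMRRSelector(n_features_to_select=2, gamma=0.5,
                                      relevance="pearson_abs", redundancy="pearson_abs")),
            ("lda", LinearDiscriminantAnalysis()),
        ])
        pipe.fit(small_data.X, small_data.Y)
        assert pipe.score(small_data.X, small_data.Y) > 0.8
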