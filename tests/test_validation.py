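"""Expert-agreement layer (confusion, purity, panel selection) and the
phenotype-survey association screen, checked against hand-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endopheno as ep
from endopheno.corpus import Corpus, ParticipantRecord, QuestionSchema
from endopheno.inference import MembershipPosterior
from endopheno.summary import hard_assign
from endopheno.validation import (
    ConfusionMatrix,
    ValidationInputError,
    association_frame,
)


class TestConfusion:
    def test_identical_labelings_are_diagonal(self):
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=[f"p{i}" for i in range(10)])
        m = ep.confusion(labels, labels)
        assert np.all(m.cells == np.diag(np.diag(m.cells)))
        assert ep.purity(m) == 1.0

    def test_swapping_arguments_transposes(self):
        idx = [f"p{i}" for i in range(6)]
        a = pd.Series(["x", "x", "y", "y", "y", "x"], index=idx)
        b = pd.Series(["u", "v", "u", "v", "v", "v"], index=idx)
        np.testing.assert_array_equal(ep.confusion(a, b).cells, ep.confusion(b, a).cells.T)

    def test_id_mismatch_rejected(self):
        a = pd.Series(["x"], index=["p1"])
        b = pd.Series(["x"], index=["p2"])
        with pytest.raises(ValidationInputError):
            ep.confusion(a, b)

    def test_worked_panel_fixture_reproduces_four_way_table(self):
        """A 40-participant labeling generated from the published 4-way cell
        counts cross-tabulates back to exactly those 16 cells."""
        ref = ep.load_expert_confusions()["expert1_4way"]
        model_labels, expert_labels, ids = [], [], []
        i = 0
        for r, rl in enumerate(ref.row_labels):
            for c, cl in enumerate(ref.column_labels):
                for _ in range(int(ref.cells[r, c])):
                    ids.append(f"p{i:02d}")
                    model_labels.append(rl)
                    expert_labels.append(cl)
                    i += 1
        m = ep.confusion(
            pd.Series(model_labels, index=ids), pd.Series(expert_labels, index=ids)
        )
        np.testing.assert_array_equal(m.cells, ref.cells)
        assert m.total == 40


class TestPurity:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("expert1_severe", 0.9),
            ("expert2_severe", 0.8),
            ("expert1_mild", 0.775),
            ("expert2_mild", 0.7),
            ("expert1_4way", 0.6),
            ("expert2_4way", 0.55),
        ],
    )
    def test_published_tables(self, name, expected):
        assert ep.purity(ep.load_expert_confusions()[name]) == pytest.approx(expected)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationInputError):
            ep.purity(ConfusionMatrix(np.zeros((2, 2), int), ["a", "b"], ["x", "y"]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 9), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ).filter(lambda c: sum(map(sum, c)) > 0)
    )
    def test_permutation_invariance_and_majority_bound(self, cells):
        m = ConfusionMatrix(np.array(cells), ["a", "b", "c"], ["x", "y", "z"])
        p = ep.purity(m)
        rng = np.random.default_rng(0)
        rp, cp = rng.permutation(3), rng.permutation(3)
        permuted = ConfusionMatrix(
            m.cells[np.ix_(rp, cp)], ["a", "b", "c"], ["x", "y", "z"]
        )
        assert ep.purity(permuted) == pytest.approx(p)
        # majority-class lower bound
        assert p >= m.cells.sum(axis=0).max() / m.total - 1e-12


class TestBinaryCollapse:
    def test_four_way_tables_collapse_to_published_binary_tables(self):
        """Collapsing each expert's 4-way table on the severe phenotype (A)
        and the mildest phenotype (B) reproduces the printed 2x2 tables."""
        tables = ep.load_expert_confusions()
        for expert in ("expert1", "expert2"):
            four = tables[f"{expert}_4way"]
            severe = ep.collapse_to_binary(four, "model_A", ["expert_A"])
            np.testing.assert_array_equal(severe.cells, tables[f"{expert}_severe"].cells)
            mild = ep.collapse_to_binary(four, "model_B", ["expert_B"])
            np.testing.assert_array_equal(mild.cells, tables[f"{expert}_mild"].cells)
            assert severe.total == four.total == 40

    def test_diagonal_collapses_to_diagonal(self):
        m = ConfusionMatrix(np.diag([3, 4, 5]), ["a", "b", "c"], ["x", "y", "z"])
        out = ep.collapse_to_binary(m, "a", ["x"])
        np.testing.assert_array_equal(out.cells, [[3, 0], [0, 9]])

    def test_unknown_labels_rejected(self):
        m = ConfusionMatrix(np.diag([1, 1]), ["a", "b"], ["x", "y"])
        with pytest.raises(ValidationInputError):
            ep.collapse_to_binary(m, "zz", ["x"])
        with pytest.raises(ValidationInputError):
            ep.collapse_to_binary(m, "a", ["zz"])


class TestReviewPanel:
    def _assignments(self, theta, ids):
        return hard_assign(MembershipPosterior(ids, np.asarray(theta, float)))

    def _corpus(self, ids, days, obs):
        schema = [QuestionSchema("q", "", tuple(f"t{i}" for i in range(200)))]
        participants = [
            ParticipantRecord(pid, {"q": {"t0": o}} if o else {}, days_tracked=d)
            for pid, d, o in zip(ids, days, obs)
        ]
        return Corpus(schema, participants)

    def test_activity_filter_boundaries(self):
        # 29 active days disqualifies regardless of volume; so do exactly 100 obs
        ids = ["a", "b", "c"]
        corpus = self._corpus(ids, [29, 30, 30], [500, 100, 101])
        asg = self._assignments([[0.99, 0.01]] * 3, ids)
        with pytest.raises(ValidationInputError, match="phenotype 1"):
            ep.select_review_panel(asg, corpus, n_per_stratum=2)

    def test_uncertainty_rule(self):
        """theta = (0.5, 0.4, 0.05, 0.05): top-2 mass 0.9 >= 0.8 and max <=
        0.95, so the participant is eligible only for the uncertain stratum."""
        ids = ["u"]
        corpus = self._corpus(ids, [40], [200])
        asg = self._assignments([[0.5, 0.4, 0.05, 0.05]], ids)
        with pytest.raises(ValidationInputError, match="certain stratum"):
            ep.select_review_panel(asg, corpus, n_per_stratum=1)
        # with a certain participant added per phenotype, selection succeeds
        ids = ["u"] + [f"c{k}" for k in range(4)]
        corpus = self._corpus(ids, [40] * 5, [200] * 5)
        theta = [[0.5, 0.4, 0.05, 0.05]] + [
            [0.97 if j == k else 0.01 for j in range(4)] for k in range(4)
        ]
        panel = ep.select_review_panel(self._assignments(theta, ids), corpus, n_per_stratum=1)
        assert panel.uncertain == ["u"]
        assert panel.size == 5

    def test_full_panel_on_synthetic_fit(self):
        cfg = ep.well_separated_config(
            K_true=4, D=350, alpha_true=0.1, seed=21,
            volume_model=ep.VolumeModel(family="poisson", means=13.0),
        )
        corpus, _ = ep.sample_corpus(cfg)
        h = ep.Hyperparameters(4, 0.1, 0.01)
        _, post, _ = ep.fit(corpus, h, n_iter=250, burn_in=120, seed=21, thin=5)
        panel = ep.select_review_panel(hard_assign(post), corpus, seed=21)
        assert panel.size == 40
        assert len(set(panel.participant_ids)) == 40
        # same seed reproduces the same panel
        panel2 = ep.select_review_panel(hard_assign(post), corpus, seed=21)
        assert panel.participant_ids == panel2.participant_ids


class TestChiSquare:
    def test_exact_independence(self):
        r = ep.chi_square_independence(np.array([[10, 10], [10, 10]]))
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.dof == 1

    def test_matches_hand_formula(self):
        table = np.array([[7, 2], [2, 29]], dtype=float)
        expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        r = ep.chi_square_independence(table)
        assert r.statistic == pytest.approx(stat, abs=1e-10)
        assert r.low_expected_count  # expected cell below 5 flagged

    def test_doubling_cells_doubles_statistic(self):
        t = np.array([[12, 5, 9], [3, 14, 7]])
        assert ep.chi_square_independence(2 * t).statistic == pytest.approx(
            2 * ep.chi_square_independence(t).statistic
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationInputError):
            ep.chi_square_independence(np.array([[5, 0], [3, 0]]))


class TestKruskalWallis:
    def test_matches_rank_formula(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        pooled = np.concatenate(groups)
        N = len(pooled)
        ranks = pd.Series(pooled).rank().to_numpy()
        rbar = ranks.mean()
        h = 0.0
        start = 0
        for g in groups:
            r_g = ranks[start:start + len(g)]
            h += len(g) * (r_g.mean() - rbar) ** 2
            start += len(g)
        h *= 12 / (N * (N + 1))
        r = ep.kruskal_wallis(groups)
        assert r.statistic == pytest.approx(h, abs=1e-10)
        assert r.dof == 1

    def test_identical_groups_score_zero(self):
        r = ep.kruskal_wallis([np.array([1.0, 2, 3]), np.array([2.0, 1, 3])])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(ValidationInputError, match="identical"):
            ep.kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0])])

    def test_null_calibration_by_permutation(self):
        """Group labels permuted over one pooled sample: rejection at the
        0.05 level lands in [0.03, 0.07] over 1000 replicates."""
        rng = np.random.default_rng(5)
        pooled = rng.normal(size=40)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            perm = rng.permutation(pooled)
            groups = [perm[:10], perm[10:20], perm[20:]]
            rejections += ep.kruskal_wallis(groups).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestAssociationScreen:
    def _fit_free_assignments(self, truth):
        # use ground-truth memberships directly: screens are posterior-agnostic
        return hard_assign(
            MembershipPosterior(truth.participant_ids, truth.theta_true)
        )

    def test_strong_binary_effect_flagged(self):
        from endopheno.synthetic import strong_binary_covariate

        _, truth = ep.sample_corpus(
            ep.GeneratorConfig(D=400, alpha_true=0.05, seed=2)
        )
        survey = ep.sample_survey(truth, [strong_binary_covariate(truth.K)], seed=3)
        results = ep.association_screen(self._fit_free_assignments(truth), survey)
        flagged = {r.covariate: r.significant for r in results}
        assert flagged["flag"]

    def test_null_covariates_reject_near_nominal_rate(self):
        """Zero-effect covariates across replicated synthetic surveys reject
        at roughly the nominal 5% level."""
        from endopheno.synthetic import null_covariates

        _, truth = ep.sample_corpus(ep.GeneratorConfig(D=300, alpha_true=0.5, seed=4))
        asg = self._fit_free_assignments(truth)
        n_tests = rejections = 0
        for rep in range(40):
            survey = ep.sample_survey(
                truth, null_covariates(truth.K, n_categorical=5, n_continuous=5),
                seed=100 + rep,
            )
            for r in ep.association_screen(asg, survey):
                n_tests += 1
                rejections += r.significant
        assert 0.02 <= rejections / n_tests <= 0.08

    def test_single_level_covariate_skipped(self):
        _, truth = ep.sample_corpus(ep.GeneratorConfig(D=60, alpha_true=0.5, seed=6))
        survey = pd.DataFrame(
            {"participant_id": truth.participant_ids, "const": ["same"] * len(truth.participant_ids)}
        )
        results = ep.association_screen(self._fit_free_assignments(truth), survey)
        assert results == []

    def test_untyped_covariate_rejected(self):
        _, truth = ep.sample_corpus(ep.GeneratorConfig(D=60, alpha_true=0.5, seed=6))
        survey = pd.DataFrame(
            {"participant_id": truth.participant_ids,
             "x": np.arange(len(truth.participant_ids), dtype=float)}
        )
        with pytest.raises(ValidationInputError, match="unknown type"):
            ep.association_screen(
                self._fit_free_assignments(truth), survey,
                covariate_types={"x": "ordinal"},
            )

    def test_association_frame_round_trip(self):
        _, truth = ep.sample_corpus(ep.GeneratorConfig(D=120, alpha_true=0.5, seed=8))
        from endopheno.synthetic import null_covariates

        survey = ep.sample_survey(truth, null_covariates(truth.K), seed=1)
        results = ep.association_screen(self._fit_free_assignments(truth), survey)
        frame = association_frame(results)
        assert set(frame["test"]) <= {"chi_square", "kruskal_wallis"}
        assert frame["p_value"].between(0, 1).all()
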