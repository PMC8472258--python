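import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from karyoevol import (
    ChromModel,
    build_rate_matrix,
    expected_events,
    fit_model,
    likelihood,
    marginal_ancestral_states,
    read_counts,
    read_newick,
    select_model,
)
from karyoevol.chromnum import (
    ChromModelError,
    ChromModelFit,
    EventExpectation,
    Propagator,
    _demi_targets,
)
from karyoevol.experiments import model_selection_experiment
from karyoevol.synthetic import simulate_chrom_counts, simulate_yule_tree

from oracles import enumerate_loglik, enumerate_posteriors, series_expm


def _model(nmax=8, gain=0.0, loss=0.0, dupl=0.0, demi=0.0, **kw):
    return ChromModel("CONST_RATE_DEMI_EST", gain, loss, dupl, demi, nmax=nmax, **kw)


class TestRateMatrix:
    def test_all_rates_zero(self):
        assert np.all(build_rate_matrix(_model()) == 0.0)

    def test_gain_only_with_absorbing_boundary(self):
        Q = build_rate_matrix(_model(nmax=3, gain=1.0))
        assert Q[0, 1] == 1.0 and Q[1, 2] == 1.0
        assert np.all(Q[2] == 0.0)  # state 3 absorbs
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_duplication_cap(self):
        Q = build_rate_matrix(_model(nmax=5, dupl=1.0))
        assert Q[2, 4] == 1.0  # 2*3 = 6 capped to 5

    def test_demi_split_on_odd_states(self):
        Q = build_rate_matrix(_model(nmax=10, demi=1.0))
        assert Q[2, 3] == 0.5 and Q[2, 4] == 0.5  # 3 -> 4.5 splits to 4, 5
        assert Q[3, 5] == 1.0  # 4 -> 6 exactly

    def test_demi_from_state_one_drops_self_target(self):
        assert _demi_targets(1, 10) == [(2, 0.5)]

    @given(
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=3),
    )
    def test_rows_of_q_and_p_sum_correctly(self, g, l, d, m, t):
        Q = build_rate_matrix(_model(nmax=9, gain=g, loss=l, dupl=d, demi=m))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        P = Propagator(Q)(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0.0)


class TestLikelihood:
    def test_single_tip_zero_branch_degenerate_prior(self):
        tree = read_newick("(A:0);")
        counts = read_counts("A\t4")
        prior = np.zeros(8)
        prior[3] = 1.0
        model = _model(nmax=8, gain=0.5, loss=0.5, root_prior=prior)
        assert likelihood(tree, counts, model) == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_brute_force_oracle(self):
        tree = read_newick("(A:1,B:1);")
        counts = read_counts("A\t4\nB\t5")
        model = ChromModel("CONST_RATE_NO_DUPL", gain=0.1, loss=0.1, nmax=10)
        P = series_expm(build_rate_matrix(model), 1.0)
        expected = np.log(sum((1 / 10) * P[r, 3] * P[r, 4] for r in range(10)))
        assert likelihood(tree, counts, model) == pytest.approx(expected, abs=1e-10)

    def test_all_missing_tips_give_logl_zero(self, three_tip_tree):
        counts = read_counts(">A\nx\n>B\nx\n>C\nx\n")
        model = _model(gain=0.3, loss=0.2, dupl=0.1, demi=0.1)
        assert likelihood(three_tip_tree, counts, model) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "newick,counts_text",
        [
            ("((A:1,B:1):0.5,C:1.5);", "A\t4\nB\t5\nC\t6"),
            ("((A:0.3,B:0.6):0.4,(C:0.9,D:0.2):0.7);", "A\t2\nB\t3\nC\t5\nD\t4"),
            ("(A:0.5,B:0.5,C:1.0);", "A\t3\nB\t3\nC\t6"),  # polytomy
        ],
    )
    def test_pruning_matches_enumeration(self, newick, counts_text):
        tree = read_newick(newick)
        counts = read_counts(counts_text)
        model = _model(nmax=8, gain=0.4, loss=0.6, dupl=0.2, demi=0.3)
        assert likelihood(tree, counts, model) == pytest.approx(
            enumerate_loglik(tree, counts, model), abs=1e-10
        )

    def test_invariant_to_child_order(self):
        counts = read_counts("A\t4\nB\t5\nC\t6")
        model = _model(gain=0.3, loss=0.5, demi=0.2)
        a = likelihood(read_newick("((A:1,B:1):0.5,C:1.5);"), counts, model)
        b = likelihood(read_newick("(C:1.5,(B:1,A:1):0.5);"), counts, model)
        assert a == pytest.approx(b, abs=1e-12)

    def test_count_above_nmax_rejected(self, three_tip_tree):
        counts = read_counts("A\t4\nB\t5\nC\t20")
        with pytest.raises(ChromModelError, match="Nmax"):
            likelihood(three_tip_tree, counts, _model(nmax=8, gain=0.1, loss=0.1))


class TestFit:
    def test_no_change_data_drives_rates_to_bound(self, three_tip_tree):
        counts = read_counts("A\t6\nB\t6\nC\t6")
        prior = np.zeros(16)
        prior[5] = 1.0
        fit = fit_model(
            three_tip_tree, counts, "CONST_RATE_NO_DUPL", n_starts=2, seed=1,
            nmax=16, root_prior=prior,
        )
        assert fit.model.gain < 1e-4 and fit.model.loss < 1e-4
        assert fit.logL == pytest.approx(0.0, abs=1e-3)

    def test_needs_two_informative_tips(self, three_tip_tree):
        counts = read_counts(">A\n6\n>B\nx\n>C\nx\n")
        with pytest.raises(ChromModelError, match="non-missing"):
            fit_model(three_tip_tree, counts, "CONST_RATE")

    def test_aic_bookkeeping(self, three_tip_tree, small_counts):
        fit = fit_model(three_tip_tree, small_counts, "CONST_RATE", n_starts=1, seed=0)
        assert fit.k == 3
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.logL)
        assert fit.logL <= 0.0

    def test_nmax_padding_insensitivity(self):
        tree = simulate_yule_tree(30, 5.0, seed=4)
        model = ChromModel("CONST_RATE_NO_DUPL", gain=0.3, loss=0.6, nmax=20)
        counts, _ = simulate_chrom_counts(tree, model, 8, seed=4)
        m10 = ChromModel("CONST_RATE_NO_DUPL", gain=0.3, loss=0.6,
                         nmax=counts.max_count() + 10)
        m30 = ChromModel("CONST_RATE_NO_DUPL", gain=0.3, loss=0.6,
                         nmax=counts.max_count() + 30)
        l10 = likelihood(tree, counts, m10) - np.log(1.0 / m10.nmax)
        l30 = likelihood(tree, counts, m30) - np.log(1.0 / m30.nmax)
        # conditioned on the root state scale (uniform prior shifts by log Nmax)
        assert abs(l10 - l30) < 0.01


class TestSelect:
    @staticmethod
    def _fit(name, aic, key=("d",)):
        model = ChromModel(name, 0.1, 0.1, 0.1 if "DUPL" not in name else 0.0,
                           0.1 if name == "CONST_RATE_DEMI" else
                           (0.1 if name == "CONST_RATE_DEMI_EST" else 0.0),
                           nmax=10)
        return ChromModelFit(model=model, logL=model.k - aic / 2, data_key=key)

    def test_minimum_aic_wins(self):
        best = select_model([
            self._fit("CONST_RATE_NO_DUPL", 100.0),
            self._fit("CONST_RATE", 101.9),
        ])
        assert best.k == 2

    def test_tie_breaks_toward_fewer_parameters(self):
        best = select_model([
            self._fit("CONST_RATE_DEMI_EST", 100.0),
            self._fit("CONST_RATE_NO_DUPL", 100.0),
        ])
        assert best.k == 2

    def test_single_fit_returned(self):
        fit = self._fit("CONST_RATE", 50.0)
        assert select_model([fit]) is fit

    def test_different_data_rejected(self):
        with pytest.raises(ChromModelError, match="different data"):
            select_model([
                self._fit("CONST_RATE", 100.0, key=("a",)),
                self._fit("CONST_RATE", 100.0, key=("b",)),
            ])

    def test_aic_prefers_generating_model_class(self):
        res = model_selection_experiment(n_replicates=10, n_tips=100, seed_base=1,
                                         n_starts=2)
        assert res.success_fraction > 0.5


class TestMarginalASR:
    def test_frozen_chain_concentrates_on_observed_state(self, three_tip_tree):
        counts = read_counts("A\t6\nB\t6\nC\t6")
        fit = ChromModelFit(model=_model(nmax=10), logL=0.0)
        post = marginal_ancestral_states(three_tip_tree, counts, fit)
        state, pp = post.map_state(three_tip_tree.node_id[three_tip_tree.root])
        assert (state, pp) == (6, pytest.approx(1.0))

    def test_matches_enumeration(self, three_tip_tree):
        counts = read_counts("A\t3\nB\t4\nC\t6")
        model = _model(nmax=7, gain=0.5, loss=0.7, dupl=0.2, demi=0.4)
        fit = ChromModelFit(model=model, logL=0.0)
        post = marginal_ancestral_states(three_tip_tree, counts, fit)
        oracle = enumerate_posteriors(three_tip_tree, counts, model)
        for nid, expected in oracle.items():
            assert np.allclose(post.probs[nid], expected, atol=1e-10)

    def test_posteriors_normalized(self, four_tip_tree):
        counts = read_counts("A\t2\nB\t3\nC\t5\nD\t4")
        fit = ChromModelFit(model=_model(gain=0.2, loss=0.9, demi=0.1), logL=0.0)
        post = marginal_ancestral_states(four_tip_tree, counts, fit)
        for p in post.probs.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p >= 0)


class TestExpectedEvents:
    def _fit_on(self, tree, counts, **rates):
        model = _model(nmax=12, **rates)
        return ChromModelFit(model=model, logL=0.0)

    def test_impossible_event_has_zero_expectation(self, three_tip_tree):
        counts = read_counts("A\t4\nB\t5\nC\t4")
        fit = self._fit_on(three_tip_tree, counts, gain=0.4, loss=0.4)
        ev = expected_events(three_tip_tree, counts, fit, nsim=300, seed=1)
        assert ev.total_expected("duplication") == 0.0
        assert ev.total_expected("demiduplication") == 0.0

    def test_threshold_flag_rule(self):
        import pandas as pd

        df = pd.DataFrame(
            {"gain": [0.2], "loss": [0.7], "duplication": [0.0],
             "demiduplication": [0.0]},
            index=pd.Index(["b1"], name="branch"),
        )
        ev = EventExpectation(df, threshold=0.5, nsim=100, seed=0)
        assert ev.flagged() == [("b1", "loss")]

    def test_flag_count_monotone_in_threshold(self, three_tip_tree):
        counts = read_counts("A\t3\nB\t5\nC\t8")
        fit = self._fit_on(three_tip_tree, counts, gain=0.5, loss=0.5, dupl=0.2)
        ev = expected_events(three_tip_tree, counts, fit, nsim=400, seed=2)
        counts_by_threshold = []
        for thr in (0.0, 0.25, 0.5, 1.0):
            ev.threshold = thr
            counts_by_threshold.append(len(ev.flagged()))
        assert counts_by_threshold == sorted(counts_by_threshold, reverse=True)

    def test_same_seed_reproducible(self, three_tip_tree):
        counts = read_counts("A\t4\nB\t5\nC\t6")
        fit = self._fit_on(three_tip_tree, counts, gain=0.3, loss=0.6, demi=0.2)
        a = expected_events(three_tip_tree, counts, fit, nsim=300, seed=9)
        b = expected_events(three_tip_tree, counts, fit, nsim=300, seed=9)
        assert a.expectations.equals(b.expectations)

    def test_different_seeds_agree_within_monte_carlo_error(self, three_tip_tree):
        counts = read_counts("A\t4\nB\t5\nC\t6")
        fit = self._fit_on(three_tip_tree, counts, gain=0.3, loss=0.6)
        nsim = 4000
        a = expected_events(three_tip_tree, counts, fit, nsim=nsim, seed=1)
        b = expected_events(three_tip_tree, counts, fit, nsim=nsim, seed=2)
        for ev_name in ("gain", "loss"):
            diff = (a.expectations[ev_name] - b.expectations[ev_name]).abs()
            # Poisson variance bound on the per-branch Monte-Carlo SE
            se = np.sqrt((a.expectations[ev_name] + 1.0 / nsim) / nsim)
            assert (diff <= 3 * se + 0.02).all()

    def test_expectations_track_true_event_counts(self):
        # event-rich regime (long branches) so the single true realization
        # per branch carries enough signal for a rank correlation
        rhos = []
        for seed in (11, 12, 13):
            tree = simulate_yule_tree(30, 0.5, seed=seed)
            model = ChromModel("CONST_RATE_NO_DUPL", gain=0.3, loss=0.6, nmax=30)
            counts, true_log = simulate_chrom_counts(tree, model, 12, seed=seed)
            fit = ChromModelFit(model=model, logL=0.0)
            ev = expected_events(tree, counts, fit, nsim=1500, seed=seed)
            joined = ev.expectations.join(true_log, rsuffix="_true")
            rhos.append(stats.spearmanr(joined["loss"], joined["loss_true"]).statistic)
        assert np.mean(rhos) > 0.7
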