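"""Ideal posteriors, event extraction, and the logistic belief readout."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy.special import expit

from chemevolve import bayes, tasks
from chemevolve.bayes import (
    BayesTaskModel,
    BeliefModel,
    event_posterior_series,
    extract_events,
    fit_readout,
    posterior,
    posterior_on_grid,
)
from chemevolve.tasks import ChannelBolus, Protocol


def oracle_posterior(seq, p1, p0, prior):
    """Exact-arithmetic Bayes oracle over an explicit event sequence."""
    p1, p0, prior = Fraction(p1), Fraction(p0), Fraction(prior)
    like1, like0 = prior, 1 - prior
    for associated in seq:
        like1 *= p1 if associated else (1 - p1)
        like0 *= p0 if associated else (1 - p0)
    return like1 / (like1 + like0)


class TestPosterior:
    @pytest.mark.parametrize("p1, p0", [(0.75, 0.25), (0.9, 0.1)])
    def test_matches_enumeration_oracle(self, p1, p0):
        """Exact agreement with brute-force Bayes on all event strings of
        length <= 6."""
        model = BayesTaskModel("abba", p1=p1, p0=p0, prior=0.5)
        for length in range(7):
            for seq in itertools.product([True, False], repeat=length):
                n, m = sum(seq), length - sum(seq)
                expected = float(oracle_posterior(seq, p1, p0, 0.5))
                assert posterior(n, m, model) == pytest.approx(expected, abs=1e-12)

    def test_no_evidence_returns_prior(self):
        model = BayesTaskModel("abba", 0.75, 0.25, prior=0.5)
        assert posterior(0, 0, model) == 0.5
        model2 = BayesTaskModel("abba", 0.75, 0.25, prior=0.3)
        assert posterior(0, 0, model2) == pytest.approx(0.3)

    def test_symmetric_model_balanced_counts(self):
        model = BayesTaskModel("abba", 0.75, 0.25, prior=0.5)
        for k in range(5):
            assert posterior(k, k, model) == pytest.approx(0.5)

    def test_direct_single_event_value(self):
        model = BayesTaskModel("abba", 0.75, 0.25, prior=0.5)
        assert posterior(1, 0, model) == pytest.approx(0.75)

    def test_monotonicity(self):
        """Associated events never decrease, unassociated never increase
        the posterior (p1 > p0)."""
        model = BayesTaskModel("noisy_clocked", 0.9, 0.1)
        for n in range(6):
            for m in range(6):
                p = posterior(n, m, model)
                assert posterior(n + 1, m, model) >= p
                assert posterior(n, m + 1, model) <= p

    def test_iterated_update_equals_closed_form(self):
        """Applying Bayes' rule event-by-event (posterior becomes next
        prior) equals the count formula."""
        model = BayesTaskModel("abba", 0.75, 0.25, prior=0.5)
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq = rng.random(8) < 0.6
            running = model.prior
            for associated in seq:
                l1 = model.p1 if associated else 1 - model.p1
                l0 = model.p0 if associated else 1 - model.p0
                running = running * l1 / (running * l1 + (1 - running) * l0)
            n, m = int(seq.sum()), int(len(seq) - seq.sum())
            assert running == pytest.approx(posterior(n, m, model), abs=1e-12)


class TestExtractEvents:
    def test_abba_pair_counting(self):
        model = BayesTaskModel.abba()
        # pairs: A->B, B->A, B->A  => (n, m) = (2, 1)
        boluses = []
        for t0, (first, second) in zip((0.0, 100.0, 200.0),
                                       [("A", "B"), ("B", "A"), ("B", "A")]):
            boluses += [ChannelBolus(t0, first), ChannelBolus(t0 + 20.0, second)]
        p = Protocol(300.0, boluses, [], "S->C")
        events = extract_events(p, model)
        assert [e.associated for e in events] == [False, True, True]
        assert [e.time for e in events] == [20.0, 120.0, 220.0]

    def test_noisy_clocked_unpaired_tick_is_unassociated(self):
        model = BayesTaskModel.noisy_clocked()
        p = Protocol(
            300.0,
            [ChannelBolus(100.0, "B"), ChannelBolus(120.0, "A"),
             ChannelBolus(200.0, "B")],
            [],
            "associated",
        )
        events = extract_events(p, model)
        assert [e.associated for e in events] == [True, False]
        assert [e.time for e in events] == [120.0, 220.0]

    def test_empty_train_has_no_events(self):
        model = BayesTaskModel.noisy_clocked()
        p = Protocol(100.0, [], [], "unassociated")
        assert extract_events(p, model) == []

    def test_unsupported_task_rejected(self):
        with pytest.raises(ValueError):
            BayesTaskModel.for_task("clocked")

    def test_step_function_attachment(self):
        model = BayesTaskModel.abba()
        p = Protocol(
            100.0,
            [ChannelBolus(10.0, "B"), ChannelBolus(30.0, "A")],
            [],
            "S->C",
        )
        times, post = event_posterior_series(p, model)
        grid = np.array([0.0, 29.99, 30.0, 99.0])
        vals = posterior_on_grid(grid, times, post, model.prior)
        assert vals[0] == vals[1] == 0.5  # before the event completes
        assert vals[2] == vals[3] == pytest.approx(0.75)


class TestFitReadout:
    def test_recovers_planted_weights(self, rng):
        """Identifiable synthetic fixture: targets generated by a known
        logistic readout are recovered within 5%."""
        X = rng.normal(size=(4000, 3))
        w_true = np.array([1.0, -2.0, 0.5])
        b_true = 0.3
        y = expit(X @ w_true + b_true)
        model = fit_readout(X, y, ["a", "b", "c"])
        w_hat = np.array([model.weights[k] for k in ("a", "b", "c")])
        assert np.allclose(w_hat, w_true, rtol=0.05)
        assert model.bias == pytest.approx(b_true, rel=0.05)

    def test_constant_half_target_gives_zero_weights(self, rng):
        X = rng.normal(size=(500, 2))
        y = np.full(500, 0.5)
        model = fit_readout(X, y, ["a", "b"])
        assert np.allclose([model.weights["a"], model.weights["b"], model.bias],
                           0.0, atol=1e-6)

    def test_single_species_logodds_fixture(self, rng):
        """A species whose concentration equals the posterior log-odds is
        read out with weight ~1 and bias ~0."""
        z = rng.uniform(-3, 3, size=2000)
        X = z[:, None]
        y = expit(z)
        model = fit_readout(X, y, ["m"])
        assert model.weights["m"] == pytest.approx(1.0, rel=0.02)
        assert model.bias == pytest.approx(0.0, abs=0.02)


class TestBeliefCorrelation:
    def test_constant_readout_scores_zero(self, abba_net, abba_protocols):
        model = BeliefModel(weights={f: 0.0 for f in abba_net.species}, bias=0.0)
        task_model = BayesTaskModel.abba()
        pooled, per_env = bayes.belief_correlation(
            model, abba_net, task_model, test_envs=abba_protocols.protocols,
            record_stride=100,
        )
        assert pooled == 0.0
        assert np.all(per_env == 0.0)

    def test_fixture_separates_from_random_baseline(self, abba_net):
        """The hand-built associative network encodes the posterior far
        better than randomly constituted networks."""
        from chemevolve.chemistry import ChemistryRules

        task_model = BayesTaskModel.abba()
        rng = np.random.default_rng(10)
        train = tasks.gen_environments("abba", 5, rng)
        test = tasks.gen_environments("abba", 8, rng)
        readout = bayes.fit_network_readout(
            abba_net, task_model, rng, train_envs=train
        )
        pooled, _ = bayes.belief_correlation(
            readout, abba_net, task_model, test_envs=test
        )
        baseline = bayes.random_network_baseline(
            task_model,
            ChemistryRules("aggregation", 2, 4),
            np.random.default_rng(11),
            n_networks=6,
            n_train_envs=10,
            n_test_envs=16,
        )
        assert pooled > np.percentile(baseline["correlations"], 95)
        assert pooled > 0.5

    def test_baseline_distribution_size(self):
        from chemevolve.chemistry import ChemistryRules

        task_model = BayesTaskModel.noisy_clocked()
        res = bayes.random_network_baseline(
            task_model,
            ChemistryRules("aggregation", 2, 4),
            np.random.default_rng(0),
            n_networks=1,
            n_train_envs=4,
            n_test_envs=4,
        )
        assert len(res["correlations"]) <= 1
        assert res["n_networks"] + res["n_failed"] >= 1
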