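"""Protocol generators: stated structure, matching constraints, fitness."""

import numpy as np
import pytest

from chemevolve import tasks
from chemevolve.chemistry import ChemistryRules
from chemevolve.network import Network, Reaction, SpeciesSpec
from chemevolve.tasks import (
    Protocol,
    ProtocolSet,
    TargetWindow,
    gen_2bit,
    gen_abba,
    gen_clocked,
    gen_nonclocked,
    gen_noisy_clocked,
)


def pairs_of(pset):
    by_id = {}
    for p in pset.protocols:
        by_id.setdefault(p.pair_id, []).append(p)
    return by_id


class TestClocked:
    def test_structure(self, rng):
        pset = gen_clocked(rng, n_protocols=10)
        for pid, pair in pairs_of(pset).items():
            assoc = next(p for p in pair if p.condition == "associated")
            unassoc = next(p for p in pair if p.condition == "unassociated")
            # identical stimulus boluses across the matched pair
            assert np.array_equal(assoc.channel_times("B"), unassoc.channel_times("B"))
            # control never occurs in the unassociated condition
            assert len(unassoc.channel_times("A")) == 0
            # every stimulus followed by a control 20 units later
            b = assoc.channel_times("B")
            assert np.allclose(assoc.channel_times("A"), b + 20.0)
            # targets: value tracks the condition over (t_B, t_B + 20]
            for p, v in ((assoc, 1.0), (unassoc, 0.0)):
                assert all(w.value == v for w in p.targets)
                assert np.allclose([w.start for w in p.targets], b)
                assert all(w.end - w.start == 20.0 for w in p.targets)

    def test_ticks_on_the_clock_grid(self, rng):
        pset = gen_clocked(rng, n_protocols=20)
        for p in pset.protocols:
            assert np.all(np.mod(p.channel_times("B"), 100.0) == 0)

    def test_bolus_probability_one_half(self):
        rng = np.random.default_rng(0)
        pset = gen_clocked(rng, n_protocols=500)
        counts = [len(p.channel_times("B")) for p in pset.protocols
                  if p.condition == "associated"]
        assert np.mean(counts) == pytest.approx(5.0, abs=0.3)  # 10 ticks x 0.5


class TestNoisyClocked:
    def test_noise_is_matched_and_flips_pairing(self, rng):
        pset = gen_noisy_clocked(rng, n_protocols=50)
        saw_noise_in_unassoc = False
        for pid, pair in pairs_of(pset).items():
            assoc = next(p for p in pair if p.condition == "associated")
            unassoc = next(p for p in pair if p.condition == "unassociated")
            b = assoc.channel_times("B")
            assert np.array_equal(b, unassoc.channel_times("B"))
            a_assoc = set(assoc.channel_times("A"))
            a_unassoc = set(unassoc.channel_times("A"))
            # a tick is paired in exactly one of the two conditions
            for t in b:
                assert ((t + 20.0) in a_assoc) != ((t + 20.0) in a_unassoc)
            saw_noise_in_unassoc |= bool(a_unassoc)
        assert saw_noise_in_unassoc  # flipped ticks carry a pair in unassociated

    def test_flip_rate_one_in_ten(self):
        rng = np.random.default_rng(1)
        pset = gen_noisy_clocked(rng, n_protocols=400)
        flips = 0
        total = 0
        for p in pset.protocols:
            if p.condition != "unassociated":
                continue
            total += len(p.channel_times("B"))
            flips += len(p.channel_times("A"))
        assert flips / total == pytest.approx(0.1, abs=0.02)


class TestNonClocked:
    def test_intervals_and_independence(self, rng):
        pset = gen_nonclocked(rng, n_protocols=30)
        for pid, pair in pairs_of(pset).items():
            assoc = next(p for p in pair if p.condition == "associated")
            unassoc = next(p for p in pair if p.condition == "unassociated")
            b = assoc.channel_times("B")
            assert np.array_equal(b, unassoc.channel_times("B"))
            gaps = np.diff(np.concatenate([[0.0], b]))
            assert np.all((gaps >= 100.0) & (gaps <= 300.0))
            assert np.allclose(assoc.channel_times("A"), b + 20.0)
            # independent control renewal process in the unassociated arm
            a_gaps = np.diff(np.concatenate([[0.0], unassoc.channel_times("A")]))
            assert np.all((a_gaps >= 100.0) & (a_gaps <= 300.0))

    def test_control_rates_match_across_conditions(self):
        rng = np.random.default_rng(2)
        pset = gen_nonclocked(rng, n_protocols=200)
        n_assoc = sum(len(p.channel_times("A")) for p in pset.protocols
                      if p.condition == "associated")
        n_unassoc = sum(len(p.channel_times("A")) for p in pset.protocols
                        if p.condition == "unassociated")
        assert n_unassoc / n_assoc == pytest.approx(1.0, abs=0.1)


class TestAbba:
    def test_event_structure(self, rng):
        pset = gen_abba(rng, n_protocols=20)
        for p in pset.protocols:
            times = sorted(b.time for b in p.boluses)
            starts = times[::2]
            seconds = times[1::2]
            assert np.allclose(np.array(seconds) - np.array(starts), 20.0)
            assert np.all(np.diff(starts) >= 50.0)  # refractory period
            assert p.horizon == 2000.0

    def test_majority_proportions_and_matching(self):
        rng = np.random.default_rng(3)
        pset = gen_abba(rng, n_protocols=150)
        frac = {}
        for cond in ("S->C", "C->S"):
            n_ba = 0
            n = 0
            for p in pset.protocols:
                if p.condition != cond:
                    continue
                bs = sorted(p.boluses, key=lambda b: b.time)
                for first, second in zip(bs[::2], bs[1::2]):
                    n += 1
                    n_ba += first.channel == "B"
            frac[cond] = n_ba / n
        assert frac["S->C"] == pytest.approx(0.75, abs=0.03)
        assert frac["C->S"] == pytest.approx(0.25, abs=0.03)
        # matched pairs share event start times
        for pid, pair in pairs_of(pset).items():
            t0 = sorted(b.time for b in pair[0].boluses)
            t1 = sorted(b.time for b in pair[1].boluses)
            assert t0 == t1

    def test_targets_follow_stimulus_pulses(self, rng):
        pset = gen_abba(rng, n_protocols=5)
        for p in pset.protocols:
            b_times = set(p.channel_times("B"))
            assert {w.start for w in p.targets} == b_times
            v = 1.0 if p.condition == "S->C" else 0.0
            assert all(w.value == v for w in p.targets)


class TestTwoBit:
    def test_sixteen_series(self):
        pset = gen_2bit()
        assert len(pset.protocols) == 16
        conds = {(p.pair_id, p.condition) for p in pset.protocols}
        assert len(conds) == 16

    def test_probe_and_weights(self):
        pset = gen_2bit()
        for p in pset.protocols:
            expected_w = 3.0 if p.condition == "B->A" else 1.0
            assert all(w.weight == expected_w for w in p.targets)
            # probe pairs at the 5th and 7th slots start with a stimulus
            times = {b.time: b.channel for b in p.boluses}
            for t0 in (500.0, 700.0):
                assert times[t0] == "B"
                assert times[t0 + 20.0] == ("A" if p.condition == "B->A" else "B")
            # low-output window precedes each probe
            pre = [w for w in p.targets if w.end in (500.0, 700.0)]
            assert all(w.value == 0.0 and w.end - w.start == 10.0 for w in pre)


class TestFitness:
    @pytest.fixture
    def tracking_net(self):
        """Network whose output is identically zero (no dynamics)."""
        species = [
            SpeciesSpec("0", 1.0, 0.0, 0.0, 0.0),
            SpeciesSpec("1", 1.0, 0.0, 0.0, 0.0),
            SpeciesSpec("01", 1.0, 0.0, 0.0, 0.0),
            SpeciesSpec("11", 1.0, 0.0, 0.0, 0.0),
        ]
        return Network(
            rules=ChemistryRules("polymer", 2, 4),
            species={s.formula: s for s in species},
            reactions=[],
            io_list=["0", "1", "01", "11"],
        )

    def test_perfect_tracking_scores_zero(self, tracking_net):
        protocol = Protocol(
            horizon=10.0,
            boluses=[],
            targets=[TargetWindow(2.0, 4.0, 0.0)],
            condition="unassociated",
        )
        assert tasks.fitness(tracking_net, [protocol]) == 0.0

    def test_constant_half_against_alternating_targets(self, tracking_net):
        # output pinned at 0.5 by initial concentration, no decay
        tracking_net.species["01"].initial_concentration = 0.5
        protocol = Protocol(
            horizon=10.0,
            boluses=[],
            targets=[TargetWindow(1.0, 3.0, 0.0), TargetWindow(5.0, 7.0, 1.0)],
            condition="associated",
        )
        assert tasks.fitness(tracking_net, [protocol]) == pytest.approx(-0.25)

    def test_weights_scale_errors(self, tracking_net):
        tracking_net.species["01"].initial_concentration = 1.0
        base = Protocol(10.0, [], [TargetWindow(1.0, 3.0, 0.0, 1.0),
                                   TargetWindow(5.0, 7.0, 1.0, 1.0)], "x")
        weighted = Protocol(10.0, [], [TargetWindow(1.0, 3.0, 0.0, 3.0),
                                       TargetWindow(5.0, 7.0, 1.0, 1.0)], "x")
        # output is 1 everywhere: errors 1 and 0; tripling the first window's
        # weight moves the weighted mean from 1/2 to 3/4
        assert tasks.fitness(tracking_net, [base]) == pytest.approx(-0.5)
        assert tasks.fitness(tracking_net, [weighted]) == pytest.approx(-0.75)

    def test_fitness_is_reproducible(self, abba_net, abba_protocols):
        f1 = tasks.fitness(abba_net, abba_protocols)
        f2 = tasks.fitness(abba_net, abba_protocols)
        assert f1 == f2 < 0


class TestProtocolIO:
    def test_round_trip(self, tmp_path, rng):
        pset = gen_noisy_clocked(rng, n_protocols=3)
        path = tmp_path / "protocols.json"
        pset.save(path)
        loaded = ProtocolSet.load(path)
        assert loaded.to_dict() == pset.to_dict()
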