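"""BD family/network scores against an independent predictive-chain oracle.

The oracle computes the marginal likelihood of a family the slow way: walk
through the samples one at a time and multiply the Dirichlet-multinomial
posterior-predictive probability of each observation given the counts seen
so far.  By exchangeability this must equal exp(family_log_score) for any
sample order.
"""

import math

import numpy as np
import pandas as pd
import pytest

from pobn import (
    BipartiteNetwork,
    ScoreConfig,
    averaged_score,
    completions_from_states,
    edge_removal_score,
    family_counts,
    family_log_score,
    network_log_score,
)
from pobn.scoring import (
    IMPORTANCE,
    LOG_MEAN_EXP,
    MEAN_OF_LOGS,
    CompletionScoreTable,
    counts_from_arrays,
)

from .conftest import random_discrete


def predictive_chain_log_prob(parent_configs, child_states, alpha=1.0, r=3):
    """Independent oracle: sequential predictive product, in log space."""
    counts = {}
    total = 0.0
    for j, k in zip(parent_configs, child_states):
        row = counts.setdefault(j, [0] * r)
        total += math.log((alpha + row[k]) / (r * alpha + sum(row)))
        row[k] += 1
    return total


def frame(rows: dict) -> pd.DataFrame:
    names = list(rows)
    n = len(rows[names[0]])
    return pd.DataFrame(
        np.array([rows[k] for k in names], dtype=np.int8),
        index=names, columns=[f"s{i}" for i in range(n)],
    )


class TestFamilyCounts:
    def test_no_parent_tally(self):
        data = frame({"g": [0, 0, 1]})
        fc = family_counts("g", (), data)
        assert fc.q == 1 and fc.n.tolist() == [[2, 1, 0]]

    def test_one_parent_tally(self):
        data = frame({"p": [0, 0, 1, 2], "g": [0, 0, 1, 2]})
        fc = family_counts("g", ("p",), data)
        assert fc.n.tolist() == [[2, 0, 0], [0, 1, 0], [0, 0, 1]]

    def test_missing_row_rejected(self):
        with pytest.raises(KeyError):
            family_counts("g", ("p",), frame({"g": [0, 1, 2]}))

    def test_matches_nested_loop_tally(self, rng):
        data = random_discrete(rng, ["p1", "p2", "g"], 200)
        fc = family_counts("g", ("p1", "p2"), data)
        brute = np.zeros((9, 3), dtype=int)
        for s in data.columns:
            j = 3 * data.at["p1", s] + data.at["p2", s]  # first parent most significant
            brute[j, data.at["g", s]] += 1
        assert (fc.n == brute).all()


class TestFamilyLogScore:
    def test_zero_samples_scores_zero(self):
        fc = family_counts("g", ("p",), frame({"g": [], "p": []}))
        assert family_log_score(fc, ScoreConfig()) == 0.0

    def test_closed_form_no_parent(self):
        # sequential predictive chain for states (0,0,1):
        # (1/3) * (2/4) * (1/5) = 1/30
        chain = predictive_chain_log_prob([0, 0, 0], [0, 0, 1])
        assert chain == pytest.approx(math.log(1 / 30), abs=1e-12)
        fc = family_counts("g", (), frame({"g": [0, 0, 1]}))
        assert family_log_score(fc, ScoreConfig()) == pytest.approx(math.log(1 / 30), abs=1e-9)

    def test_closed_form_one_parent(self):
        # pairs (parent, child) = (0,0),(0,0),(1,1),(2,2):
        # (1/3 * 2/4) * (1/3) * (1/3) = 1/54
        chain = predictive_chain_log_prob([0, 0, 1, 2], [0, 0, 1, 2])
        assert chain == pytest.approx(math.log(1 / 54), abs=1e-12)
        data = frame({"p": [0, 0, 1, 2], "g": [0, 0, 1, 2]})
        fc = family_counts("g", ("p",), data)
        assert family_log_score(fc, ScoreConfig()) == pytest.approx(math.log(1 / 54), abs=1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ScoreConfig(alpha=0.0)

    @pytest.mark.parametrize("n_parents", [0, 1, 2, 3])
    def test_matches_predictive_chain_on_random_families(self, rng, n_parents):
        # 50 random families per parent count = 200 total; <= 500 samples
        for _ in range(50):
            n = int(rng.integers(1, 501))
            alpha = float(rng.choice([0.5, 1.0, 2.0]))
            child = rng.integers(0, 3, size=n)
            parents = rng.integers(0, 3, size=(n_parents, n))
            w = 3 ** np.arange(n_parents - 1, -1, -1)
            js = (w @ parents) if n_parents else np.zeros(n, dtype=int)
            expected = predictive_chain_log_prob(js.tolist(), child.tolist(), alpha=alpha)
            from pobn.scoring import family_log_score_from_counts

            got = family_log_score_from_counts(counts_from_arrays(child, parents), alpha)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_exchangeability_any_sample_order(self, rng):
        n = 120
        child = rng.integers(0, 3, size=n)
        parent = rng.integers(0, 3, size=(1, n))
        ref = None
        from pobn.scoring import family_log_score_from_counts

        score = family_log_score_from_counts(counts_from_arrays(child, parent), 1.0)
        for _ in range(5):
            perm = rng.permutation(n)
            chain = predictive_chain_log_prob(parent[0, perm].tolist(), child[perm].tolist())
            assert chain == pytest.approx(score, abs=1e-9)

    def test_noise_parent_does_not_help_on_average(self, rng):
        # Bayesian Occam: attaching an independent uniform parent should not
        # raise the expected family score (n = 2000, 20 replicates)
        from pobn.scoring import family_log_score_from_counts

        deltas = []
        for _ in range(20):
            child = rng.integers(0, 3, size=2000)
            noise = rng.integers(0, 3, size=(1, 2000))
            s0 = family_log_score_from_counts(counts_from_arrays(child, np.empty((0, 2000), dtype=int)), 1.0)
            s1 = family_log_score_from_counts(counts_from_arrays(child, noise), 1.0)
            deltas.append(s1 - s0)
        assert np.mean(deltas) < 0


class TestNetworkLogScore:
    def test_empty_network_empty_data(self):
        assert network_log_score(BipartiteNetwork(), pd.DataFrame(), ScoreConfig()) == 0.0

    def test_decomposes_into_disconnected_families(self, rng):
        data = random_discrete(rng, ["R1", "R2", "G1", "G2"], 50)
        net = BipartiteNetwork({"R1", "R2"}, {"G1", "G2"}, {("R1", "G1"), ("R2", "G2")})
        cfg = ScoreConfig()
        half1 = BipartiteNetwork({"R1"}, {"G1"}, {("R1", "G1")})
        half2 = BipartiteNetwork({"R2"}, {"G2"}, {("R2", "G2")})
        assert network_log_score(net, data, cfg) == pytest.approx(
            network_log_score(half1, data, cfg) + network_log_score(half2, data, cfg), abs=1e-9
        )

    def test_equals_sum_of_family_scores(self, rng, default_model):
        net = default_model.net
        rows = sorted(net.regulators) + sorted(net.targets)
        data = random_discrete(rng, rows, 100)
        cfg = ScoreConfig()
        total = sum(
            family_log_score(family_counts(g, tuple(sorted(net.parents_of(g))), data), cfg)
            for g in sorted(net.targets)
        ) + sum(family_log_score(family_counts(r, (), data), cfg) for r in sorted(net.regulators))
        assert network_log_score(net, data, cfg) == pytest.approx(total, abs=1e-9)

    def test_sample_order_invariance(self, rng, small_net):
        rows = sorted(small_net.regulators) + sorted(small_net.targets)
        data = random_discrete(rng, rows, 80)
        perm = rng.permutation(data.columns)
        cfg = ScoreConfig()
        assert network_log_score(small_net, data, cfg) == pytest.approx(
            network_log_score(small_net, data[perm], cfg), abs=1e-9
        )


class TestAveragedScore:
    @pytest.fixture
    def setup(self, rng, small_net):
        observed = random_discrete(rng, sorted(small_net.targets), 60)
        states = rng.integers(0, 3, size=(5, 2, 60))
        completions = completions_from_states(small_net, observed, states)
        return small_net, observed, completions

    @pytest.mark.parametrize("mode", [MEAN_OF_LOGS, LOG_MEAN_EXP, IMPORTANCE])
    def test_single_completion_equals_network_score(self, setup, mode):
        net, observed, completions = setup
        one = completions_from_states(net, observed, completions.states[:1])
        completed = pd.concat(
            [observed, pd.DataFrame(one.states[0], index=one.regulator_ids, columns=observed.columns)]
        )
        cfg = ScoreConfig(averaging=mode)
        assert averaged_score(net, observed, one, cfg) == pytest.approx(
            network_log_score(net, completed, cfg), abs=1e-9
        )

    @pytest.mark.parametrize("mode", [MEAN_OF_LOGS, LOG_MEAN_EXP, IMPORTANCE])
    def test_identical_completions_collapse(self, setup, mode):
        net, observed, completions = setup
        rep = completions_from_states(net, observed, np.repeat(completions.states[:1], 7, axis=0))
        one = completions_from_states(net, observed, completions.states[:1])
        cfg = ScoreConfig(averaging=mode)
        assert averaged_score(net, observed, rep, cfg) == pytest.approx(
            averaged_score(net, observed, one, cfg), abs=1e-9
        )
        # and edge removals collapse the same way
        edge = sorted(net.edges)[0]
        assert edge_removal_score(net, edge, observed, rep, cfg) == pytest.approx(
            edge_removal_score(net, edge, observed, one, cfg), abs=1e-9
        )

    def test_mean_of_logs_is_arithmetic_mean(self, setup):
        net, observed, completions = setup
        cfg = ScoreConfig(averaging=MEAN_OF_LOGS)
        per = []
        for m in range(completions.m):
            one = completions_from_states(net, observed, completions.states[m : m + 1])
            per.append(averaged_score(net, observed, one, cfg))
        assert averaged_score(net, observed, completions, cfg) == pytest.approx(np.mean(per), abs=1e-9)

    def test_zero_completions_rejected(self, setup):
        net, observed, completions = setup
        empty = completions_from_states(net, observed, completions.states[:0])
        with pytest.raises(ValueError):
            averaged_score(net, observed, empty, ScoreConfig())


class TestEdgeRemoval:
    @pytest.fixture
    def setup(self, rng, default_model):
        net = default_model.net
        observed = random_discrete(rng, sorted(net.targets), 150)
        states = rng.integers(0, 3, size=(8, 4, 150))
        return net, observed, completions_from_states(net, observed, states)

    @pytest.mark.parametrize("mode", [MEAN_OF_LOGS, LOG_MEAN_EXP])
    def test_incremental_equals_full_recompute(self, setup, mode):
        net, observed, completions = setup
        cfg = ScoreConfig(averaging=mode)
        for edge in sorted(net.edges):
            incremental = edge_removal_score(net, edge, observed, completions, cfg)
            full = averaged_score(net.remove_edge(edge), observed, completions, cfg)
            assert incremental == pytest.approx(full, abs=1e-9)

    def test_importance_mode_full_recompute_contract(self, setup):
        # full recomputation of the removal network's per-completion totals,
        # combined by the same ratio rule, must match the incremental path
        net, observed, completions = setup
        cfg = ScoreConfig(averaging=IMPORTANCE)
        from scipy.special import logsumexp

        table = CompletionScoreTable(net, observed, completions, cfg)
        for edge in sorted(net.edges)[:4]:
            sub = CompletionScoreTable(net.remove_edge(edge), observed, completions, cfg)
            delta = sub.totals - table.totals
            full = table.averaged() + float(logsumexp(delta) - np.log(len(delta)))
            assert edge_removal_score(net, edge, observed, completions, cfg) == pytest.approx(full, abs=1e-9)

    def test_only_target_family_changes(self, setup):
        net, observed, completions = setup
        cfg = ScoreConfig()
        table = CompletionScoreTable(net, observed, completions, cfg)
        edge = sorted(net.edges)[0]
        sub = CompletionScoreTable(net.remove_edge(edge), observed, completions, cfg)
        gi = table._gene_idx[edge[1]]
        keep = [i for i in range(len(table.genes)) if i != gi]
        assert np.allclose(table.gene_scores[:, keep], sub.gene_scores[:, keep])
        assert np.allclose(table.root_scores, sub.root_scores)

    def test_absent_edge_rejected(self, setup):
        net, observed, completions = setup
        with pytest.raises(KeyError):
            edge_removal_score(net, ("R1", "nonexistent"), observed, completions, ScoreConfig())
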