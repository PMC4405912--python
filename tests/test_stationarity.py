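import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microtime import (
    OtuTimeSeries,
    OUParams,
    adf_test,
    fitch_parsimony,
    p_test,
    simulate_ou,
    stationary_fraction,
)


def _frac_from_log(logab: np.ndarray) -> np.ndarray:
    ab = 10.0 ** logab
    return ab / ab.sum(axis=1, keepdims=True)


class TestAdfTest:
    def test_ou_series_rejected_as_stationary(self, rng):
        hits = 0
        for _ in range(100):
            s = 10 ** simulate_ou(OUParams(lam=0.5, mu=-3, sigma=0.3), 200, seed=rng)
            hits += adf_test(s).stationary
        assert hits >= 90

    def test_random_walk_size_near_alpha(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            s = 10 ** (-3 + 0.1 * np.cumsum(rng.standard_normal(200)))
            hits += adf_test(s).stationary
        assert 0.02 <= hits / reps <= 0.08

    def test_deterministic_trend_not_rejected(self):
        s = 10 ** (0.01 * np.arange(200) - 4)
        assert not adf_test(s).stationary

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adf_test(np.full(50, 0.5))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            adf_test(np.linspace(0.1, 0.2, 10))

    def test_zeros_floored_at_detection_limit(self):
        s = np.concatenate([np.zeros(10), 10 ** np.random.default_rng(0).uniform(-4, -3, 90)])
        result = adf_test(s, detection_limit=1e-5)
        assert np.isfinite(result.adf_statistic)

    def test_lag_count_bounded(self, rng):
        s = 10 ** simulate_ou(OUParams(lam=0.5, mu=-3, sigma=0.3), 100, seed=rng)
        result = adf_test(s)
        assert 0 <= result.n_lags <= int(12 * (100 / 100) ** 0.25)


class TestStationaryFraction:
    def test_mixed_community_fraction(self, rng):
        """80 mean-reverting + 20 random-walk OTUs: the ADF screen recovers
        a stationary fraction close to the mixture weight."""
        n = 200
        cols = {}
        for k in range(80):
            cols[f"ou{k}"] = simulate_ou(
                OUParams(lam=rng.uniform(0.3, 0.8), mu=rng.uniform(-4, -2), sigma=0.3),
                n,
                seed=rng,
            )
        for k in range(20):
            cols[f"rw{k}"] = -3 + 0.05 * np.cumsum(rng.standard_normal(n))
        logab = pd.DataFrame(cols).to_numpy()
        counts = (1e7 * _frac_from_log(logab)).round().astype(int)
        series = OtuTimeSeries(
            counts=pd.DataFrame(counts, columns=list(cols)), detection_limit=1e-7
        )
        frac, results = stationary_fraction(series, top_n=100)
        assert 0.70 <= frac <= 0.90
        assert len(results) == 100

    def test_fewer_otus_than_top_n_warns_and_uses_all(self, rng):
        logab = np.column_stack(
            [simulate_ou(OUParams(lam=0.5, mu=-2, sigma=0.3), 100, seed=rng) for _ in range(5)]
        )
        counts = (1e6 * _frac_from_log(logab)).round().astype(int)
        series = OtuTimeSeries(counts=pd.DataFrame(counts))
        with pytest.warns(UserWarning, match="using all"):
            frac, results = stationary_fraction(series, top_n=100)
        assert len(results) == 5

    def test_no_correlation_between_outcome_and_abundance(self, rng):
        """With identical dynamics at every abundance level, ADF outcomes do
        not track mean abundance."""
        from scipy.stats import spearmanr

        n = 200
        mus = rng.uniform(-5, -1.5, size=60)
        logab = np.column_stack(
            [simulate_ou(OUParams(lam=0.5, mu=mu, sigma=0.3), n, seed=rng) for mu in mus]
        )
        counts = (1e8 * _frac_from_log(logab)).round().astype(int)
        series = OtuTimeSeries(
            counts=pd.DataFrame(counts, columns=[f"o{k}" for k in range(60)]),
            detection_limit=1e-8,
        )
        frac, results = stationary_fraction(series, top_n=60)
        pvals = np.array([results[f"o{k}"].p_value for k in range(60)])
        rho = spearmanr(mus, pvals).statistic
        assert abs(rho) < 0.35


def _brute_force_parsimony(tree: TreeNode, labels: dict) -> int:
    """Minimum label changes over all internal-state assignments."""
    internals = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    states = sorted(set(labels.values()))
    best = np.inf
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        changes = 0
        for node in tree.traverse(include_self=True):
            if node.parent is None:
                continue
            s = labels[node.name] if node.is_tip() else assign[id(node)]
            sp = assign[id(node.parent)]
            changes += s != sp
        best = min(best, changes)
    return int(best)


class TestFitchParsimony:
    def test_monophyletic_label_costs_one_change(self):
        tree = TreeNode.read(["((a,b),(c,d));"])
        labels = {"a": 1, "b": 1, "c": 0, "d": 0}
        assert fitch_parsimony(tree, labels) == 1

    def test_matches_brute_force_on_random_small_trees(self, rng):
        for rep in range(30):
            n = int(rng.integers(4, 9))
            names = [f"t{k}" for k in range(n)]
            newick = _random_newick(names, rng)
            tree = TreeNode.read([newick])
            labels = {nm: int(rng.integers(0, 2)) for nm in names}
            if len(set(labels.values())) < 2:
                labels[names[0]] = 1 - labels[names[0]]
            assert fitch_parsimony(tree, labels) == _brute_force_parsimony(tree, labels)

    def test_handles_multifurcation(self):
        tree = TreeNode.read(["((a,b,c),(d,e));"])
        labels = {"a": 1, "b": 1, "c": 0, "d": 0, "e": 0}
        assert fitch_parsimony(tree, labels) == _brute_force_parsimony(tree, labels)


def _random_newick(names, rng) -> str:
    nodes = [f"{n}:1" for n in names]
    while len(nodes) > 1:
        k = min(len(nodes), int(rng.integers(2, 4)))
        idx = rng.choice(len(nodes), size=k, replace=False)
        merged = "(" + ",".join(nodes[i] for i in idx) + "):1"
        nodes = [nd for i, nd in enumerate(nodes) if i not in idx] + [merged]
    return nodes[0] + ";"


class TestPTest:
    def test_agrees_with_exhaustive_enumeration(self, rng):
        """Sampled permutation p-value matches the exhaustive permutation
        distribution on a 6-leaf tree (all 6!/(3!3!)-distinct labelings)."""
        tree = TreeNode.read(["(((a,b),c),((d,e),f));"])
        names = list("abcdef")
        labels = {"a": 1, "b": 1, "c": 1, "d": 0, "e": 0, "f": 0}
        observed = fitch_parsimony(tree, labels)
        null = [
            fitch_parsimony(tree, dict(zip(names, perm)))
            for perm in itertools.permutations([1, 1, 1, 0, 0, 0])
        ]
        exact = np.mean([s <= observed for s in null])
        p, score = p_test(tree, labels, n_permutations=4000, seed=0)
        assert score == observed == 1
        assert p == pytest.approx(exact, abs=0.02)

    def test_validity_under_random_labels(self, rng):
        """P(p <= alpha) stays near or below alpha when labels carry no
        phylogenetic signal (permutation p-values are super-uniform)."""
        tree = TreeNode.read([_random_newick([f"t{k}" for k in range(12)], rng)])
        hits = 0
        trials = 100
        for _ in range(trials):
            vals = rng.permutation([1] * 4 + [0] * 8)
            labels = {f"t{k}": int(v) for k, v in enumerate(vals)}
            p, _ = p_test(tree, labels, n_permutations=200, seed=rng)
            hits += p <= 0.05
        assert hits / trials <= 0.10

    def test_single_class_rejected(self):
        tree = TreeNode.read(["((a,b),(c,d));"])
        with pytest.raises(ValueError, match="both classes"):
            p_test(tree, {n: 1 for n in "abcd"})

    def test_clustered_labels_give_small_p(self):
        newick = "(((a,b),(c,d)),((e,f),(g,h)));"
        tree = TreeNode.read([newick])
        labels = {n: int(n in "abcd") for n in "abcdefgh"}
        p, score = p_test(tree, labels, n_permutations=1000, seed=1)
        assert score == 1
        # 2 of the C(8,4)=70 balanced labelings achieve score 1
        assert p < 0.06
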