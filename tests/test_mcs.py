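"""Search-driver tests on enumerable toy spaces and the SMILES space."""

import itertools
import random

import pytest

from mcsmiles.mcs import (
    BestSequence,
    RandomPolicy,
    SearchNode,
    SmilesSpace,
    generate_library,
    nmcs,
    playout,
    sampling,
    uct_search,
    uct_select,
)
from mcsmiles.scoring import MAX_SCORE, score_state


class TreeSpace:
    """A depth-``d`` tree over moves {0, 1}; leaves score via ``payoff``."""

    def __init__(self, depth, payoff):
        self.depth = depth
        self.payoff = payoff  # tuple of bits -> float

    def initial(self):
        return ()

    def legal(self, state):
        return [0, 1]

    def apply(self, state, move):
        return state + (move,)

    def apply_inplace(self, state, move):  # states are immutable tuples
        raise NotImplementedError

    def is_terminal(self, state):
        return len(state) >= self.depth

    def score(self, state):
        return self.payoff[state]


class MutableTreeSpace(TreeSpace):
    """Same tree with list states so the drivers' in-place path works."""

    def initial(self):
        return []

    def apply(self, state, move):
        return state + [move]

    def apply_inplace(self, state, move):
        state.append(move)

    def score(self, state):
        return self.payoff[tuple(state)]


def random_payoff(depth, seed):
    rng = random.Random(seed)
    return {
        bits: rng.random()
        for bits in itertools.product((0, 1), repeat=depth)
    }


class _ListState(list):
    def copy(self):
        return _ListState(self)


def mutable_space(depth, seed):
    payoff = random_payoff(depth, seed)
    space = MutableTreeSpace(depth, payoff)
    base_init = space.initial
    space.initial = lambda: _ListState(base_init())
    return space, payoff


class HiddenPathSpace(MutableTreeSpace):
    """Leaf score = length of the prefix agreeing with a hidden target
    sequence; the structured payoff nested search is designed for."""

    def __init__(self, depth, target):
        self.depth = depth
        self.target = target
        self.evaluations = 0

    def initial(self):
        return _ListState([])

    def score(self, state):
        self.evaluations += 1
        k = 0
        for a, b in zip(state, self.target):
            if a != b:
                break
            k += 1
        return float(k)


class DominanceWins:
    def __init__(self):
        self.nmcs = 0
        self.sampling = 0


def run_dominance_experiment(depth, replicates, level):
    """Paired comparison of NMCS vs independent playouts at the number of
    terminal evaluations the NMCS run actually used."""
    wins = DominanceWins()
    for rep in range(replicates):
        rng = random.Random(1000 + rep)
        target = tuple(rng.randrange(2) for _ in range(depth))
        space = HiddenPathSpace(depth, target)
        seq = nmcs(space, space.initial(), level, RandomPolicy(),
                   random.Random(rep))
        budget = space.evaluations
        if seq.score == depth:
            wins.nmcs += 1
        rng2 = random.Random(rep)
        best_seen = max(
            playout(space, space.initial(), RandomPolicy(), rng2).score
            for _ in range(budget)
        )
        if best_seen == depth:
            wins.sampling += 1
    return wins


class TestPlayout:
    def test_reaches_valid_terminal_state(self):
        space = SmilesSpace()
        rng = random.Random(1)
        from rdkit import Chem
        from mcsmiles.search_model import expand_shortcuts

        seq = playout(space, space.initial(), RandomPolicy(), rng)
        assert seq.state.terminated
        assert Chem.MolFromSmiles(expand_shortcuts(seq.state.smiles)) is not None

    def test_seeded_determinism(self):
        space = SmilesSpace()
        runs = []
        for _ in range(2):
            rng = random.Random(99)
            runs.append(
                [playout(space, space.initial(), RandomPolicy(), rng).state.smiles
                 for _ in range(100)]
            )
        assert runs[0] == runs[1]

    def test_score_matches_replay(self):
        space = SmilesSpace()
        rng = random.Random(3)
        seq = playout(space, space.initial(), RandomPolicy(), rng)
        replayed = space.initial()
        for mv in seq.moves:
            space.apply_inplace(replayed, mv)
        assert score_state(replayed) == pytest.approx(seq.score)


class TestSampling:
    def test_collects_requested_count_of_max_score_molecules(self):
        space = SmilesSpace()
        rng = random.Random(4)
        out = sampling(space, RandomPolicy(), rng, n_collect=20,
                       max_playouts=5000)
        assert len(out) == 20
        assert all(s.score == pytest.approx(MAX_SCORE) for s in out)

    def test_same_seed_same_library(self):
        space = SmilesSpace()
        a = sampling(space, RandomPolicy(), random.Random(5), n_collect=10,
                     max_playouts=5000)
        b = sampling(space, RandomPolicy(), random.Random(5), n_collect=10,
                     max_playouts=5000)
        assert [s.state.smiles for s in a] == [s.state.smiles for s in b]

    def test_budget_exhaustion_raises(self):
        space = SmilesSpace(accept_fn=lambda s: False)
        with pytest.raises(RuntimeError):
            sampling(space, RandomPolicy(), random.Random(6), n_collect=1,
                     max_playouts=5)


class TestNmcs:
    def test_level_zero_is_a_playout(self):
        space, _ = mutable_space(6, 7)
        a = nmcs(space, space.initial(), 0, RandomPolicy(), random.Random(42))
        b = playout(space, space.initial(), RandomPolicy(), random.Random(42))
        assert a.moves == b.moves and a.score == b.score

    @pytest.mark.parametrize("depth,seed", [(2, 0), (3, 1), (4, 2)])
    def test_level_one_finds_the_enumerated_optimum_on_small_trees(
        self, depth, seed
    ):
        """NMCS at a level matching the tree depth explores every branch,
        so it must land on the exhaustive-enumeration optimum."""
        space, payoff = mutable_space(depth, seed)
        best = max(payoff.values())
        seq = nmcs(space, space.initial(), depth, RandomPolicy(),
                   random.Random(seed))
        assert seq.score == pytest.approx(best)

    def test_replay_consistency_on_smiles_space(self):
        space = SmilesSpace()
        seq = nmcs(space, space.initial(), 1, RandomPolicy(), random.Random(8),
                   stop_on_accept=True)
        replayed = space.initial()
        for mv in seq.moves:
            space.apply_inplace(replayed, mv)
        assert score_state(replayed) == pytest.approx(seq.score)

    def test_nmcs_dominates_sampling_at_equal_budget(self):
        """Hidden-path toy: leaf score = length of the prefix matching a
        hidden move sequence.  At an equal number of terminal evaluations,
        level-2 NMCS (which locks in good prefixes) finds the optimum at
        least as often as independent playouts."""
        wins = run_dominance_experiment(depth=10, replicates=30, level=2)
        assert wins.nmcs >= wins.sampling
        assert wins.nmcs >= 20  # nested search reliably solves this toy


class TestUctSelect:
    def test_prefers_less_visited_child_at_equal_mean(self):
        node = SearchNode(visits=3)
        node.children["a"] = SearchNode(visits=1, total_score=0.5)
        node.children["b"] = SearchNode(visits=2, total_score=1.0)
        assert uct_select(node, c=1.0) == "a"

    def test_c_zero_is_pure_exploitation(self):
        node = SearchNode(visits=10)
        node.children["a"] = SearchNode(visits=5, total_score=1.0)   # mean 0.2
        node.children["b"] = SearchNode(visits=5, total_score=4.0)   # mean 0.8
        assert uct_select(node, c=0.0) == "b"

    def test_puct_follows_the_prior_all_else_equal(self):
        node = SearchNode(visits=4)
        node.children["a"] = SearchNode(visits=2, total_score=1.0, prior=0.9)
        node.children["b"] = SearchNode(visits=2, total_score=1.0, prior=0.1)
        assert uct_select(node, c=1.0, puct=True) == "a"

    def test_no_children_raises(self):
        with pytest.raises(ValueError):
            uct_select(SearchNode(), c=1.0)


class TestUctSearch:
    def test_finds_enumerated_optimum_on_toy_tree(self):
        space, payoff = mutable_space(4, 3)
        seq = uct_search(space, RandomPolicy(), random.Random(0),
                         iterations=2000, c=1.0)
        assert seq.score == pytest.approx(max(payoff.values()))

    def test_visit_fraction_concentrates_on_best_arm(self):
        """Two-armed bandit: the empirical visit share of the best arm
        grows toward 1 as iterations accumulate."""
        payoff = {(0,): 0.2, (1,): 0.8}
        space, _ = mutable_space(1, 0)
        space.payoff = payoff

        # run manually to inspect the root statistics
        from mcsmiles.mcs import SearchNode
        root_best = []
        for iters in (50, 2000):
            rng = random.Random(1)
            # reconstruct by running uct_search and counting via closure
            calls = {0: 0, 1: 0}
            orig_score = space.score

            def counting_score(state):
                calls[state[0]] += 1
                return orig_score(state)

            space.score = counting_score
            uct_search(space, RandomPolicy(), rng, iterations=iters, c=1.0)
            space.score = orig_score
            root_best.append(calls[1] / (calls[0] + calls[1]))
        assert root_best[1] > root_best[0]
        assert root_best[1] > 0.9

    def test_single_iteration_is_one_playout(self):
        space, payoff = mutable_space(5, 9)
        seq = uct_search(space, RandomPolicy(), random.Random(2), iterations=1)
        assert len(seq.moves) == 5
        assert seq.score == pytest.approx(payoff[tuple(seq.moves)])

    def test_seeded_reproducibility(self):
        space, _ = mutable_space(6, 11)
        a = uct_search(space, RandomPolicy(), random.Random(7), iterations=200)
        b = uct_search(space, RandomPolicy(), random.Random(7), iterations=200)
        assert a.moves == b.moves and a.score == b.score

    def test_backpropagation_conserves_root_visits(self):
        space, _ = mutable_space(4, 13)
        counted = {"n": 0}
        orig = space.score

        def count(state):
            counted["n"] += 1
            return orig(state)

        space.score = count
        uct_search(space, RandomPolicy(), random.Random(3), iterations=123)
        assert counted["n"] == 123


class TestGenerateLibrary:
    @pytest.mark.parametrize("algo,mode", [
        ("sampling", "random"),
        ("nmcs", "random"),
        ("sampling", "ngram"),
        ("nmcs", "ngram"),
        ("sampling", "enforced"),
        ("uct", "random"),
        ("puct", "ngram"),
    ])
    def test_all_algorithm_playout_combinations(self, algo, mode, corpus):
        from rdkit import Chem

        lib = generate_library(
            10, algorithm=algo, playout_mode=mode, seed=17, corpus=corpus,
            level=2, uct_iterations=500,
        )
        assert len(lib) == 10
        for mol in lib:
            assert Chem.MolFromSmiles(mol.smiles) is not None
            assert mol.score == pytest.approx(MAX_SCORE)

    def test_seeded_reproducibility(self, corpus):
        a = generate_library(15, algorithm="nmcs", playout_mode="random", seed=3)
        b = generate_library(15, algorithm="nmcs", playout_mode="random", seed=3)
        assert [m.smiles for m in a] == [m.smiles for m in b]
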