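"""Monte Carlo search drivers over the legal-move model.

Three search strategies maximize the compliance score over the move
space defined by :mod:`mcsmiles.search_model`:

* **sampling** -- independent playouts from the empty state, stopping a
  playout's run once a molecule reaches the best possible score;
* **NMCS** -- Nested Monte Carlo Search: each level evaluates every legal
  move with a lower-level search (level 0 is a playout), then advances
  along the best route found so far;
* **UCT / PUCT** -- bandit tree search with the classic
  ``X_S + C * sqrt(ln V / V_S)`` selection rule, or the prior-weighted
  ``X_S + C * P_S * sqrt(V) / (1 + V_S)`` rule when a prior is available.

All drivers work on any *search space* object exposing ``initial()``,
``legal(state)``, ``apply(state, move)``, ``apply_inplace(state, move)``,
``is_terminal(state)`` and ``score(state)``, which keeps them testable on
small enumerable toy problems.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from random import Random
from typing import Callable, Iterable

from . import search_model as sm
from .priors import (
    AtomRatioTarget,
    NgramModel,
    cycle_close_decision,
    policy_weights,
    train_ngrams,
)
from .scoring import MAX_SCORE, score_state
from .search_model import RING_CLOSE, GenerationState, SearchConfig

EPS = 1e-9


@dataclass
class BestSequence:
    """A move sequence and the score of the terminal state it reaches."""

    moves: tuple[str, ...]
    score: float
    state: object | None = None  # terminal state, when the space provides one


# ---------------------------------------------------------------------------
# Search space facade
# ---------------------------------------------------------------------------

class SmilesSpace:
    """The SMILES-generation search space.

    ``score_fn`` maps a terminal :class:`GenerationState` to the value the
    search maximizes (the compliance score by default); ``accept_fn``
    decides whether a terminal molecule joins the generated library
    (reaching the maximum compliance score of 5 by default).
    """

    def __init__(
        self,
        config: SearchConfig = sm.DEFAULT_CONFIG,
        matrices: sm.FrequencyMatrices | None = None,
        score_fn: Callable[[GenerationState], float] | None = None,
        accept_fn: Callable[[GenerationState], bool] | None = None,
        convention: str = "atom",
    ):
        self.config = config
        self.matrices = matrices
        self.convention = convention
        self._score = score_fn or (lambda s: score_state(s, convention))
        self.accept = accept_fn or (
            lambda s: score_state(s, convention) >= MAX_SCORE - EPS
        )

    def initial(self) -> GenerationState:
        return sm.init_state(self.config)

    def legal(self, state: GenerationState) -> list[str]:
        return sm.legal_moves(state, self.matrices, self.config)

    def apply(self, state: GenerationState, move: str) -> GenerationState:
        new = state.copy()
        sm.apply_move_inplace(new, move, self.config)
        return new

    def apply_inplace(self, state: GenerationState, move: str) -> None:
        sm.apply_move_inplace(state, move, self.config)

    def is_terminal(self, state: GenerationState) -> bool:
        return state.terminated

    def score(self, state: GenerationState) -> float:
        return self._score(state)


def enforced_score_fn(
    target: AtomRatioTarget, convention: str = "atom"
) -> Callable[[GenerationState], float]:
    """Compliance score minus the heavy-atom-ratio deviation from ``target``.

    Used by the *enforced* playout mode: move selection stays uniform and
    the pull toward FDA-like atom ratios acts through the score."""

    def fn(state: GenerationState) -> float:
        return score_state(state, convention) - target.deviation(state.smiles)

    return fn


# ---------------------------------------------------------------------------
# Playout policies
# ---------------------------------------------------------------------------

class RandomPolicy:
    """Uniform choice among the legal moves (also the *enforced* policy)."""

    def __call__(self, space, state, legal: list[str], rng: Random) -> str:
        return legal[rng.randrange(len(legal))]


class NgramPolicy:
    """N-gram-weighted choice, with the separate ring-closure coin flip."""

    def __init__(self, model: NgramModel):
        self.model = model

    def __call__(self, space, state, legal: list[str], rng: Random) -> str:
        if RING_CLOSE in legal:
            if len(legal) == 1:
                return RING_CLOSE
            cyc, _ = state._innermost_cycle()
            if cyc is not None and cycle_close_decision(self.model, cyc, rng):
                return RING_CLOSE
            legal = [m for m in legal if m != RING_CLOSE]
        weights = policy_weights(self.model, state, legal)
        return _weighted_choice(weights, rng)


def _weighted_choice(weights: dict[str, float], rng: Random) -> str:
    x = rng.random()
    acc = 0.0
    last = None
    for move, p in weights.items():
        acc += p
        last = move
        if x < acc:
            return move
    return last  # guard against floating-point shortfall


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def playout(space, state, policy, rng: Random) -> BestSequence:
    """Complete ``state`` to a terminal state under ``policy``."""
    if space.is_terminal(state):
        raise ValueError("playout from a terminal state")
    current = state.copy()
    moves: list[str] = []
    while not space.is_terminal(current):
        legal = space.legal(current)
        move = policy(space, current, legal, rng)
        space.apply_inplace(current, move)
        moves.append(move)
    return BestSequence(tuple(moves), space.score(current), current)


def sampling(
    space,
    policy,
    rng: Random,
    n_collect: int = 1,
    max_playouts: int | None = None,
    progress: Callable[[int], None] | None = None,
) -> list[BestSequence]:
    """Independent playouts from the start state; a playout run ends once a
    molecule reaches the acceptance criterion (best possible score)."""
    accept_fn = getattr(space, "accept", None)
    collected: list[BestSequence] = []
    attempts = 0
    while len(collected) < n_collect:
        if max_playouts is not None and attempts >= max_playouts:
            if not collected:
                raise RuntimeError(
                    f"sampling exhausted {max_playouts} playouts with no "
                    f"accepted molecule"
                )
            break
        seq = playout(space, space.initial(), policy, rng)
        attempts += 1
        if accept_fn is None or accept_fn(seq.state):
            collected.append(seq)
            if progress is not None:
                progress(len(collected))
    return collected


def nmcs(
    space,
    state,
    level: int,
    policy,
    rng: Random,
    stop_on_accept: bool = False,
) -> BestSequence:
    """Nested Monte Carlo Search of the given level (level 0 is a playout).

    At each step the level runs a level-1 search on every legal move,
    keeps the best sequence seen anywhere in the level (global memory),
    then advances along that sequence's next move.  Moves are explored in
    a seeded random order: every child is still searched, but no branch is
    systematically visited first, which keeps early-stopping generation
    runs from all sharing a lexicographically-first prefix.  With
    ``stop_on_accept`` the search returns as soon as any explored terminal
    state satisfies the space's acceptance criterion, which is how
    generation runs terminate once the score ceiling is reached.
    """
    if level <= 0:
        return playout(space, state, policy, rng)
    current = state.copy()
    played: list[str] = []
    best: BestSequence | None = None
    accept = getattr(space, "accept", None)
    while not space.is_terminal(current):
        children = list(space.legal(current))
        rng.shuffle(children)
        for move in children:
            child = space.apply(current, move)
            if space.is_terminal(child):
                sub = BestSequence((), space.score(child), child)
            elif level == 1:
                sub = playout(space, child, policy, rng)
            else:
                sub = nmcs(space, child, level - 1, policy, rng, stop_on_accept)
            cand = BestSequence(
                tuple(played) + (move,) + sub.moves, sub.score, sub.state
            )
            if best is None or cand.score > best.score:
                best = cand
            if (
                stop_on_accept
                and accept is not None
                and cand.state is not None
                and accept(cand.state)
            ):
                return cand
        nxt = best.moves[len(played)]
        space.apply_inplace(current, nxt)
        played.append(nxt)
    if best is None or space.score(current) >= best.score:
        best = BestSequence(tuple(played), space.score(current), current)
    return best


@dataclass
class SearchNode:
    """UCT/PUCT tree statistics for one state."""

    visits: int = 0
    total_score: float = 0.0
    prior: float = 0.0
    children: dict[str, "SearchNode"] = field(default_factory=dict)
    untried: list[str] | None = None

    @property
    def mean_score(self) -> float:
        return self.total_score / self.visits if self.visits else 0.0


def uct_select(node: SearchNode, c: float, puct: bool = False) -> str:
    """Pick the child move maximizing the UCT (or PUCT) upper bound.

    UCT:  X_S + C * sqrt(ln V / V_S); PUCT: X_S + C * P_S * sqrt(V) / (1 + V_S).
    Ties break toward the earliest-inserted move.
    """
    if not node.children:
        raise ValueError("uct_select on a node with no expanded children")
    best_move, best_val = None, -math.inf
    for move, child in node.children.items():
        if puct:
            val = child.mean_score + c * child.prior * math.sqrt(node.visits) / (
                1 + child.visits
            )
        else:
            if child.visits == 0:
                return move
            val = child.mean_score + c * math.sqrt(
                math.log(node.visits) / child.visits
            )
        if val > best_val:
            best_move, best_val = move, val
    return best_move


def uct_search(
    space,
    policy,
    rng: Random,
    iterations: int = 10_000,
    c: float = 1.0,
    prior_fn: Callable[[object, list[str]], dict[str, float]] | None = None,
    time_limit: float | None = None,
    score_scale: float = 1.0,
    stop_on_accept: bool = False,
) -> BestSequence:
    """Selection / expansion / evaluation / backpropagation loop from the
    initial state; returns the best playout sequence seen.

    ``prior_fn`` switches selection to the PUCT formula with the prior it
    returns; ``score_scale`` maps scores into [0, 1] for the bandit
    statistics (the returned sequence keeps the raw score).
    """
    root = SearchNode()
    best: BestSequence | None = None
    accept = getattr(space, "accept", None) if stop_on_accept else None
    deadline = time.monotonic() + time_limit if time_limit is not None else None
    for _ in range(iterations):
        if deadline is not None and time.monotonic() > deadline:
            break
        node = root
        state = space.initial().copy()
        path_nodes = [root]
        path_moves: list[str] = []
        # selection
        while (
            node.untried is not None
            and not node.untried
            and node.children
            and not space.is_terminal(state)
        ):
            move = uct_select(node, c, puct=prior_fn is not None)
            node = node.children[move]
            space.apply_inplace(state, move)
            path_nodes.append(node)
            path_moves.append(move)
        # expansion
        if not space.is_terminal(state):
            if node.untried is None:
                node.untried = list(space.legal(state))
                if prior_fn is not None:
                    node._priors = prior_fn(state, node.untried)
            if node.untried:
                move = node.untried.pop(0)
                child = SearchNode()
                if prior_fn is not None:
                    child.prior = getattr(node, "_priors", {}).get(move, 0.0)
                node.children[move] = child
                space.apply_inplace(state, move)
                node = child
                path_nodes.append(node)
                path_moves.append(move)
        # evaluation
        if space.is_terminal(state):
            seq = BestSequence(tuple(path_moves), space.score(state), state)
        else:
            tail = playout(space, state, policy, rng)
            seq = BestSequence(
                tuple(path_moves) + tail.moves, tail.score, tail.state
            )
        # backpropagation
        value = seq.score / score_scale
        for n in path_nodes:
            n.visits += 1
            n.total_score += value
        if best is None or seq.score > best.score:
            best = seq
        if accept is not None and seq.state is not None and accept(seq.state):
            break
    if best is None:
        raise RuntimeError("uct_search performed no iterations")
    return best


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratedMolecule:
    smiles: str        # standard SMILES, shortcuts expanded
    score: float       # compliance score
    moves: tuple[str, ...]


def generate_library(
    n: int,
    algorithm: str = "nmcs",
    playout_mode: str = "random",
    seed: int = 0,
    config: SearchConfig = sm.DEFAULT_CONFIG,
    corpus: list[str] | None = None,
    ngram_model: NgramModel | None = None,
    matrices: sm.FrequencyMatrices | None = None,
    ratio_target: AtomRatioTarget | None = None,
    level: int = 3,
    c: float = 1.0,
    uct_iterations: int = 2_000,
    max_playouts_per_molecule: int = 10_000,
    convention: str = "atom",
    progress: Callable[[int], None] | None = None,
) -> list[GeneratedMolecule]:
    """Generate ``n`` molecules that reach the compliance-score ceiling.

    ``algorithm`` is one of ``sampling``, ``nmcs``, ``uct``, ``puct``;
    ``playout_mode`` one of ``random``, ``enforced``, ``ngram``.  A corpus
    (list of SMILES) supplies the n-gram prior, the frequency matrices
    and the enforced atom-ratio target when the corresponding objects are
    not passed explicitly.  Every run is reproducible from ``seed``.
    """
    rng = Random(seed)
    if playout_mode == "ngram" and ngram_model is None:
        if corpus is None:
            raise ValueError("ngram playout needs a corpus or a trained model")
        ngram_model = train_ngrams(corpus)
    if matrices is None and corpus is not None:
        matrices = sm.build_frequency_matrices(corpus)
    if playout_mode == "enforced" and ratio_target is None:
        if corpus is None:
            raise ValueError("enforced playout needs a corpus or a ratio target")
        ratio_target = AtomRatioTarget.from_corpus(corpus)

    score_fn = None
    if playout_mode == "enforced":
        score_fn = enforced_score_fn(ratio_target, convention)
    space = SmilesSpace(config, matrices, score_fn=score_fn, convention=convention)
    policy = (
        NgramPolicy(ngram_model) if playout_mode == "ngram" else RandomPolicy()
    )
    prior_fn = None
    if algorithm == "puct":
        if ngram_model is None:
            raise ValueError("puct needs an n-gram prior")
        prior_fn = lambda state, legal: policy_weights(ngram_model, state, legal)

    out: list[GeneratedMolecule] = []
    attempts = 0
    budget = max_playouts_per_molecule * n
    while len(out) < n:
        if attempts > budget:
            raise RuntimeError(
                f"generation budget exhausted after {attempts} runs "
                f"({len(out)}/{n} molecules)"
            )
        attempts += 1
        if algorithm == "sampling":
            seq = playout(space, space.initial(), policy, rng)
            if not space.accept(seq.state):
                continue
        elif algorithm == "nmcs":
            seq = nmcs(space, space.initial(), level, policy, rng,
                       stop_on_accept=True)
            if not space.accept(seq.state):
                continue
        elif algorithm in ("uct", "puct"):
            seq = uct_search(
                space, policy, rng, iterations=uct_iterations, c=c,
                prior_fn=prior_fn, score_scale=MAX_SCORE, stop_on_accept=True,
            )
            if seq.state is None or not space.accept(seq.state):
                continue  # failed run; restart with fresh tree
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        out.append(
            GeneratedMolecule(
                sm.expand_shortcuts(seq.state.smiles),
                score_state(seq.state, convention),  # compliance, not guide
                seq.moves,
            )
        )
        if progress is not None:
            progress(len(out))
    return out


def write_library(
    path: str,
    molecules: Iterable[GeneratedMolecule],
    header: str | None = None,
) -> None:
    """Write a generated library as a .smi file (``SMILES<TAB>score``)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for mol in molecules:
            fh.write(f"{mol.smiles}\t{mol.score:.4f}\n")


def read_smiles_file(path: str) -> list[str]:
    """Read a .smi file: one SMILES per line, optional name column,
    ``#`` comment lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out
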