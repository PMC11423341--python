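"""Playout policies: uniform random, enforced atom ratios, and n-gram priors.

The n-gram model stores conditional next-token probabilities given the
last ``order`` tokens of the growing SMILES (token level, so ``Cl`` and
the group shortcuts count as one symbol; ring digits are canonicalized to
a generic digit).  Tokens with conditional probability below a pruning
threshold are considered too rare to play.  Ring closures are not drawn
from the n-gram table: a separate per-length closure probability decides
when an open ring terminates, with defaults matching the 5/6/7-ring
proportions of FDA-approved drugs (0.228, 0.751, 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

from .alphabet import tokenize, END, RING_DIGITS
from .search_model import (
    AROM_OPEN,
    RING_CLOSE,
    RING_OPEN,
    GenerationState,
    OpenCycle,
    compress_shortcuts,
)

START = "^"

DEFAULT_CYCLE_CLOSE_PROBS = {5: 0.228, 6: 0.751, 7: 0.02}

# Move -> context-token mapping used both when reading a training corpus
# and when matching a state's recent tokens against the table.
_MOVE_TOKEN = {RING_OPEN: "1", AROM_OPEN: "c", RING_CLOSE: "1"}


@dataclass
class NgramModel:
    """Conditional next-token probabilities of fixed order."""

    order: int = 3
    table: dict[tuple[str, ...], dict[str, float]] = field(default_factory=dict)
    prune_threshold: float = 0.001
    cycle_close_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CYCLE_CLOSE_PROBS)
    )

    def probability(self, context: tuple[str, ...], token: str) -> float:
        return self.table.get(context, {}).get(token, 0.0)

    def to_text(self) -> str:
        lines = [f"#meta order={self.order} prune={self.prune_threshold}"]
        for length, p in sorted(self.cycle_close_probs.items()):
            lines.append(f"@cycle\t{length}\t{p}")
        for ctx in sorted(self.table):
            for tok, p in sorted(self.table[ctx].items()):
                lines.append(f"{' '.join(ctx)}\t{tok}\t{p:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "NgramModel":
        model = cls(table={}, cycle_close_probs={})
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#meta"):
                for part in line[len("#meta"):].split():
                    key, val = part.split("=")
                    if key == "order":
                        model.order = int(val)
                    elif key == "prune":
                        model.prune_threshold = float(val)
                continue
            if line.startswith("@cycle"):
                _, length, p = line.split("\t")
                model.cycle_close_probs[int(length)] = float(p)
                continue
            ctx_s, tok, p = line.split("\t")
            ctx = tuple(ctx_s.split(" "))
            model.table.setdefault(ctx, {})[tok] = float(p)
        return model


def _corpus_tokens(smiles: str) -> list[str]:
    """Tokenize a corpus line for counting: compress shortcuts, canonicalize
    ring digits, and append the termination marker."""
    toks = tokenize(compress_shortcuts(smiles.strip()))
    return [("1" if t in RING_DIGITS else t) for t in toks] + [END]


def train_ngrams(corpus: list[str], order: int = 3) -> NgramModel:
    """Count every length-``order`` context in the corpus into conditional
    next-token probabilities.  Contexts shorter than the order are padded
    with a start sentinel so the first characters are modelled too."""
    if not corpus:
        raise ValueError("empty corpus")
    counts: dict[tuple[str, ...], dict[str, int]] = {}
    pad = (START,) * order
    for line in corpus:
        toks = _corpus_tokens(line)
        seq = pad + tuple(toks)
        for i in range(order, len(seq)):
            ctx = seq[i - order:i]
            nxt = seq[i]
            counts.setdefault(ctx, {}).setdefault(nxt, 0)
            counts[ctx][nxt] += 1
    table = {
        ctx: {tok: c / sum(row.values()) for tok, c in row.items()}
        for ctx, row in counts.items()
    }
    return NgramModel(order=order, table=table)


def state_context(model: NgramModel, state: GenerationState) -> tuple[str, ...]:
    toks = [("1" if t in RING_DIGITS else t) for t in state.tokens[-model.order:]]
    pad = model.order - len(toks)
    return (START,) * pad + tuple(toks)


def policy_weights(
    model: NgramModel, state: GenerationState, legal: list[str]
) -> dict[str, float]:
    """N-gram weights over the legal moves.

    Raw probabilities below the pruning threshold are dropped before the
    restriction to legal moves; the surviving weights are renormalized.
    Unseen contexts (or contexts whose every legal continuation is pruned)
    fall back to the uniform distribution -- the returned map is never
    empty and always sums to one.
    """
    if not legal:
        raise ValueError("no legal moves to weight")
    row = model.table.get(state_context(model, state))
    weights: dict[str, float] = {}
    if row:
        for move in legal:
            p = row.get(_MOVE_TOKEN.get(move, move), 0.0)
            if p >= model.prune_threshold:
                weights[move] = p
    total = sum(weights.values())
    if total <= 0.0:
        u = 1.0 / len(legal)
        return {move: u for move in legal}
    return {move: p / total for move, p in weights.items()}


def cycle_close_decision(
    model: NgramModel, open_cycle: OpenCycle, rng: Random
) -> bool:
    """Decide whether to terminate an open ring at its current length.

    Closure is drawn with the configured per-length probability; at the
    maximum ring length closure is forced since the ring cannot grow."""
    length = open_cycle.length
    if length >= max(model.cycle_close_probs):
        return True
    p = model.cycle_close_probs.get(length, 0.0)
    return rng.random() < p


@dataclass(frozen=True)
class AtomRatioTarget:
    """Target heavy-atom fractions (summing to 1 over C/O/N/F/S/Cl)."""

    ratios: dict[str, float]

    @classmethod
    def from_corpus(cls, corpus: list[str]) -> "AtomRatioTarget":
        from .scoring import heavy_atom_counts

        totals: dict[str, int] = {}
        for line in corpus:
            try:
                for el, k in heavy_atom_counts(line.strip()).items():
                    totals[el] = totals.get(el, 0) + k
            except ValueError:
                continue
        if not totals:
            raise ValueError("no parseable SMILES in corpus")
        n = sum(totals.values())
        return cls(ratios={el: k / n for el, k in sorted(totals.items())})

    def deviation(self, smiles: str) -> float:
        """Sum of absolute differences between a molecule's heavy-atom
        fractions and the target fractions (0 when identical)."""
        from .scoring import heavy_atom_counts

        counts = heavy_atom_counts(smiles)
        n = sum(counts.values())
        elements = set(self.ratios) | set(counts)
        return sum(
            abs(counts.get(el, 0) / n - self.ratios.get(el, 0.0))
            for el in elements
        )

    def to_text(self) -> str:
        return "".join(f"{el}\t{p:.10g}\n" for el, p in sorted(self.ratios.items()))

    @classmethod
    def from_text(cls, text: str) -> "AtomRatioTarget":
        ratios = {}
        for line in text.splitlines():
            if line.strip():
                el, p = line.split("\t")
                ratios[el] = float(p)
        return cls(ratios=ratios)


def enforced_weights(
    target: AtomRatioTarget, state: GenerationState, legal: list[str]
) -> dict[str, float]:
    """Uniform weights over the legal moves.

    The enforced playout selects uniformly exactly like the random one;
    the atom-ratio objective enters through an extra score term (see
    :func:`mcsmiles.mcs.enforced_score_fn`), not through the weights."""
    if not legal:
        raise ValueError("no legal moves to weight")
    u = 1.0 / len(legal)
    return {move: u for move in legal}
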