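"""Legal-move model for character-by-character SMILES construction.

Every move offered by :func:`legal_moves` leaves a state from which at
least one completion into a syntactically and valence-valid SMILES exists,
so any playout policy restricted to these moves produces a parseable
molecule -- the structural validity guarantee at the heart of the package.

The bookkeeping follows four rules:

1. A SMILES may only terminate at the root subtree level (all parentheses
   closed) with no open ring bonds.
2. Each subtree level has an *active atom* (the last one added at that
   level) whose remaining covalent valence is tracked; moves that exceed
   it are illegal.
3. Only the most recently opened ring may be closed.
4. Rings close at 5, 6 or 7 atoms (aromatic rings at 5 or 6), so no
   strained or macrocyclic rings are ever produced.

A ``finish_asap`` flag set after a configurable number of characters
forbids opening new subtrees or rings (finishing already-open ones stays
legal), which keeps playouts and molecules short.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .alphabet import (
    ALIPHATIC_VALENCE,
    AROMATIC_SIGMA,
    ATOM_TOKENS,
    END,
    HETERO2_TOKENS,
    RING_DIGITS,
    tokenize,
)
from ._parse import parse_graph

logger = logging.getLogger(__name__)

# Move vocabulary, beyond the atom tokens themselves:
#   "("  open subtree          ")"  close subtree
#   "="  next bond is double   "#"  next bond is triple
#   RING_OPEN   open an aliphatic ring on the active atom
#   AROM_OPEN   start an aromatic ring: appends "c" plus a ring digit
#   RING_CLOSE  close the most recent ring at the active atom
#   END         terminate the SMILES
RING_OPEN = "ring"
AROM_OPEN = "aring"
RING_CLOSE = "close"

ALIPHATIC_ATOMS = ("C", "N", "O", "F", "S", "Cl", "W", "M", "U")
AROMATIC_CONT = ("c", "n", "o", "s", "[nH]")

# Atoms that may follow an explicit double / triple bond symbol.
DOUBLE_TARGETS = ("C", "N", "O", "S")
TRIPLE_TARGETS = ("C", "N")

MAX_AROMATIC_N = 3  # cap on pyridine-type nitrogens per aromatic ring


@dataclass(frozen=True)
class SearchConfig:
    """Tunable limits of the search model (all lengths in characters)."""

    min_cycle: int = 5
    max_cycle: int = 7
    rare_bond_threshold: float = 1.0 / 10_000
    finish_asap_after: int = 25
    max_chars: int = 60
    min_chars: int = 10
    allowed_atoms: frozenset[str] = frozenset(ALIPHATIC_ATOMS)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_cycle > self.max_cycle:
            raise ValueError("min_cycle must not exceed max_cycle")
        if self.finish_asap_after >= self.max_chars:
            raise ValueError("finish_asap_after must be below max_chars")


DEFAULT_CONFIG = SearchConfig()


@dataclass
class OpenCycle:
    """One ring currently under construction."""

    digit: str
    length: int           # ring atoms placed so far, opening atom included
    depth: int            # subtree depth the ring lives at
    aromatic: bool
    hetero2: bool = False  # has the two-pi-electron member (o/s/[nH]) been placed
    n_count: int = 0
    outer_snapshot: int = -1  # outer ring's length when this fused ring opened


@dataclass
class FrequencyMatrices:
    """Atom and bond counts scanned from a training corpus.

    Bonds are keyed by ``(token_a, token_b, order)`` with the token pair
    sorted; aromatic ring bonds use order ``0``.  ``bond_totals`` counts,
    for each token, every bond it participates in, which is the denominator
    of the rare-bond rule: a bond seen in less than ``rare_bond_threshold``
    of either partner's bonds is an illegal move.
    """

    bond_counts: dict[tuple[str, str, int], int] = field(default_factory=dict)
    atom_counts: dict[str, int] = field(default_factory=dict)
    bond_totals: dict[str, int] = field(default_factory=dict)

    def is_rare(self, a: str, b: str, order: int, threshold: float) -> bool:
        key = (min(a, b), max(a, b), order)
        count = self.bond_counts.get(key, 0)
        for tok in (a, b):
            total = self.bond_totals.get(tok)
            if total and count < threshold * total:
                return True
        return False

    def to_text(self) -> str:
        lines = ["# token_a\ttoken_b\torder\tcount"]
        for (a, b, order), count in sorted(self.bond_counts.items()):
            lines.append(f"{a}\t{b}\t{order}\t{count}")
        lines.append("# atom\tcount")
        for tok, count in sorted(self.atom_counts.items()):
            lines.append(f"{tok}\t{count}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FrequencyMatrices":
        m = cls()
        section = 0
        for line in text.splitlines():
            if line.startswith("#"):
                section += 1
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if section <= 1:
                a, b, order, count = parts
                key = (a, b, int(order))
                m.bond_counts[key] = int(count)
                for tok in (a, b):
                    m.bond_totals[tok] = m.bond_totals.get(tok, 0) + int(count)
            else:
                m.atom_counts[parts[0]] = int(parts[1])
        return m


@dataclass
class GenerationState:
    """An in-progress SMILES with its valence and ring bookkeeping.

    ``stack`` holds the active atom index of every open subtree level
    (``-1`` is the pre-first-atom sentinel); ``atom_rem[i]`` is atom *i*'s
    remaining valence, which at a terminal state equals its implicit
    hydrogen count.
    """

    tokens: list[str] = field(default_factory=list)
    atom_tok: list[str] = field(default_factory=list)
    atom_rem: list[int] = field(default_factory=list)
    stack: list[int] = field(default_factory=lambda: [-1])
    open_cycles: list[OpenCycle] = field(default_factory=list)
    pending_order: int = 1
    finish_asap: bool = False
    terminated: bool = False
    char_count: int = 0

    @property
    def smiles(self) -> str:
        """The internal-alphabet SMILES built so far."""
        return "".join(self.tokens)

    @property
    def depth(self) -> int:
        return len(self.stack)

    def copy(self) -> "GenerationState":
        return GenerationState(
            tokens=self.tokens.copy(),
            atom_tok=self.atom_tok.copy(),
            atom_rem=self.atom_rem.copy(),
            stack=self.stack.copy(),
            open_cycles=[replace(c) for c in self.open_cycles],
            pending_order=self.pending_order,
            finish_asap=self.finish_asap,
            terminated=self.terminated,
            char_count=self.char_count,
        )

    # -- helpers -----------------------------------------------------------
    def _innermost_cycle(self) -> tuple[OpenCycle | None, int]:
        """The most recent open ring at the current depth, and how many
        open rings live at that depth (1 normal, 2 when building a fused
        bicyclic)."""
        if not self.open_cycles:
            return None, 0
        cyc = self.open_cycles[-1]
        if cyc.depth != self.depth:
            return None, 0
        n_same = 1
        if len(self.open_cycles) > 1 and self.open_cycles[-2].depth == self.depth:
            n_same = 2
        return cyc, n_same

    def _head(self) -> tuple[int, str | None, int, bool]:
        idx = self.stack[-1]
        if idx < 0:
            return idx, None, 0, False
        tok = self.atom_tok[idx]
        return idx, tok, self.atom_rem[idx], tok in AROMATIC_SIGMA


def init_state(config: SearchConfig = DEFAULT_CONFIG) -> GenerationState:
    """An empty SMILES: only atom additions are legal from here."""
    return GenerationState()


def is_terminal(state: GenerationState) -> bool:
    return state.terminated


def _forced_close(cyc: OpenCycle, config: SearchConfig) -> bool:
    if cyc.aromatic:
        return cyc.length == 6 or (cyc.length == 5 and cyc.hetero2)
    return cyc.length >= config.max_cycle


def _bond_ok(
    matrices: FrequencyMatrices | None,
    prev: str | None,
    new: str,
    order: int,
    config: SearchConfig,
) -> bool:
    if matrices is None or prev is None:
        return True
    return not matrices.is_rare(prev, new, order, config.rare_bond_threshold)


def _forced_finish(state: GenerationState, config: SearchConfig) -> list[str]:
    """Shortest-path finishing moves once the character budget is exhausted."""
    cyc, _ = state._innermost_cycle()
    last = state.tokens[-1] if state.tokens else None
    if state.pending_order > 1:
        return ["C"]
    if cyc is not None:
        if cyc.aromatic:
            if cyc.length == 6 or (cyc.length == 5 and cyc.hetero2):
                return [RING_CLOSE]
            return ["c"]
        if cyc.length >= config.min_cycle:
            return [RING_CLOSE]
        return ["C"]
    if last == "(":
        return ["C"]
    if state.depth > 1:
        return [")"]
    return [END]


def legal_moves(
    state: GenerationState,
    matrices: FrequencyMatrices | None = None,
    config: SearchConfig = DEFAULT_CONFIG,
) -> list[str]:
    """All moves playable from ``state``; never empty for a non-terminal state."""
    if state.terminated:
        raise ValueError("legal_moves called on a terminal state")
    if state.char_count >= config.max_chars:
        return _forced_finish(state, config)

    moves = _candidate_moves(state, matrices, config)
    if not moves and matrices is not None:
        # The rare-bond filter must never corner the search; retry without it.
        moves = _candidate_moves(state, None, config)
    if not moves:
        # Saturated active atom early in the string: finish structurally.
        moves = _forced_finish(state, config)
    return moves


def _candidate_moves(
    state: GenerationState,
    matrices: FrequencyMatrices | None,
    config: SearchConfig,
) -> list[str]:
    head_idx, head_tok, head_rem, head_aro = state._head()
    cyc, n_same = state._innermost_cycle()
    last = state.tokens[-1] if state.tokens else None
    depth = state.depth
    pending = state.pending_order

    # After "=" or "#" the only legal continuation is a compatible atom.
    if pending > 1:
        targets = DOUBLE_TARGETS if pending == 2 else TRIPLE_TARGETS
        min_left = 0
        if cyc is not None:
            min_left = 2 if n_same >= 2 else 1
        out = []
        for a in targets:
            if a not in config.allowed_atoms:
                continue
            if ALIPHATIC_VALENCE[a] - pending < min_left:
                continue
            if _bond_ok(matrices, head_tok, a, pending, config):
                out.append(a)
        return out

    if cyc is not None and _forced_close(cyc, config):
        return [RING_CLOSE]

    moves: list[str] = []

    if cyc is not None and cyc.aromatic:
        # Inside an aromatic ring: continue with aromatic atoms, branch off
        # a carbon, or close (closure only ever happens as a forced move).
        max_len = 5 if cyc.hetero2 else 6
        nxt = cyc.length + 1
        if nxt <= max_len and _bond_ok(matrices, head_tok, "c", 0, config):
            moves.append("c")
        if nxt <= max_len and cyc.n_count < MAX_AROMATIC_N and _bond_ok(
            matrices, head_tok, "n", 0, config
        ):
            moves.append("n")
        if not cyc.hetero2 and nxt <= 5:
            for a in ("o", "s", "[nH]"):
                if _bond_ok(matrices, head_tok, a, 0, config):
                    moves.append(a)
        if head_rem >= 2 and last != "(" and not state.finish_asap:
            moves.append("(")
        return moves

    # ---- aliphatic context ----
    if head_idx < 0:
        # Empty SMILES: one atom only, nothing else.
        return [a for a in ALIPHATIC_ATOMS if a in config.allowed_atoms]

    min_left = 0
    if cyc is not None:
        min_left = 2 if n_same >= 2 else 1
    if head_rem >= 1:
        for a in ALIPHATIC_ATOMS:
            if a not in config.allowed_atoms:
                continue
            if ALIPHATIC_VALENCE[a] - 1 < min_left:
                continue
            if _bond_ok(matrices, head_tok, a, 1, config):
                moves.append(a)

    # "(" -- one valence for the branch, one kept to continue afterwards.
    if (
        head_rem >= 2
        and last != "("
        and not state.finish_asap
        and not (cyc is not None and n_same >= 2)
    ):
        moves.append("(")

    # "=" / "#".  When the active atom is also the chain head of a ring one
    # level down (we are right after "(" on a ring atom), one extra valence
    # must stay reserved so the ring can still be continued.
    reserve = 0
    if last == "(" and len(state.stack) >= 2 and state.stack[-2] == head_idx:
        below = [c for c in state.open_cycles if c.depth == depth - 1]
        if below:
            reserve = 1
    if not head_aro and head_rem >= 2 + reserve:
        targets = [
            a for a in DOUBLE_TARGETS
            if a in config.allowed_atoms
            and ALIPHATIC_VALENCE[a] - 2 >= min_left
            and _bond_ok(matrices, head_tok, a, 2, config)
        ]
        if targets and not (cyc is not None and cyc.aromatic):
            moves.append("=")
    if not head_aro and cyc is None and head_rem >= 3 + reserve:
        targets = [
            a for a in TRIPLE_TARGETS
            if a in config.allowed_atoms
            and _bond_ok(matrices, head_tok, a, 3, config)
        ]
        if targets:
            moves.append("#")

    # Ring openings.
    can_open_digit = len(state.open_cycles) < 8 and not state.finish_asap
    if (
        can_open_digit
        and head_rem >= 2
        and not head_aro
        and last in ALIPHATIC_ATOMS
        and (cyc is None or (not cyc.aromatic and n_same == 1))
    ):
        moves.append(RING_OPEN)
    if (
        can_open_digit
        and head_rem >= 1
        and cyc is None
        and _bond_ok(matrices, head_tok, "c", 0 if head_aro else 1, config)
    ):
        moves.append(AROM_OPEN)

    # Ring closure (aliphatic; aromatic closures are forced above).
    if (
        cyc is not None
        and not cyc.aromatic
        and config.min_cycle <= cyc.length <= config.max_cycle
        and last not in ("(", ")")
        and head_rem >= (2 if n_same >= 2 else 1)
    ):
        moves.append(RING_CLOSE)

    if depth > 1 and last != "(" and cyc is None:
        moves.append(")")

    if (
        depth == 1
        and not state.open_cycles
        and state.tokens
        and state.char_count >= config.min_chars
    ):
        moves.append(END)

    return moves


def apply_move_inplace(
    state: GenerationState, move: str, config: SearchConfig = DEFAULT_CONFIG
) -> None:
    """Mutating fast path of :func:`apply_move` (no legality re-check)."""
    if move == END:
        state.terminated = True
        return
    if move == "(":
        state.stack.append(state.stack[-1])
        state.tokens.append("(")
        state.char_count += 1
    elif move == ")":
        state.stack.pop()
        state.tokens.append(")")
        state.char_count += 1
    elif move in ("=", "#"):
        state.pending_order = 2 if move == "=" else 3
        state.tokens.append(move)
        state.char_count += 1
    elif move == RING_OPEN:
        digit = _free_digit(state)
        cyc, n_same = state._innermost_cycle()
        new = OpenCycle(digit, 1, state.depth, aromatic=False)
        if cyc is not None:
            new.outer_snapshot = cyc.length
        state.open_cycles.append(new)
        state.atom_rem[state.stack[-1]] -= 1  # reserve the closure bond
        state.tokens.append(digit)
        state.char_count += 1
    elif move == AROM_OPEN:
        digit = _free_digit(state)
        head = state.stack[-1]
        idx = len(state.atom_tok)
        rem = AROMATIC_SIGMA["c"] - 1  # one sigma reserved for the closure
        if head >= 0:
            state.atom_rem[head] -= 1
            rem -= 1
        state.atom_tok.append("c")
        state.atom_rem.append(rem)
        state.stack[-1] = idx
        state.open_cycles.append(OpenCycle(digit, 1, state.depth, aromatic=True))
        state.tokens.append("c")
        state.tokens.append(digit)
        state.char_count += 2
    elif move == RING_CLOSE:
        cyc = state.open_cycles.pop()
        state.atom_rem[state.stack[-1]] -= 1
        state.tokens.append(cyc.digit)
        state.char_count += 1
        if (
            cyc.outer_snapshot >= 0
            and state.open_cycles
            and state.open_cycles[-1].depth == cyc.depth
        ):
            # Fused bicyclic: the closing bond re-enters the outer ring.
            state.open_cycles[-1].length = cyc.outer_snapshot + 1
    elif move in AROMATIC_SIGMA:
        # aromatic ring continuation (aromatic atoms are only ever playable
        # inside an open aromatic ring; openings use AROM_OPEN)
        cyc = state.open_cycles[-1]
        head = state.stack[-1]
        state.atom_rem[head] -= 1
        idx = len(state.atom_tok)
        state.atom_tok.append(move)
        state.atom_rem.append(AROMATIC_SIGMA[move] - 1)
        state.stack[-1] = idx
        cyc.length += 1
        if move == "n":
            cyc.n_count += 1
        if move in HETERO2_TOKENS:
            cyc.hetero2 = True
        state.tokens.append(move)
        state.char_count += len(move)
    else:
        # aliphatic atom addition
        order = state.pending_order
        head = state.stack[-1]
        if head >= 0:
            state.atom_rem[head] -= order
        idx = len(state.atom_tok)
        state.atom_tok.append(move)
        state.atom_rem.append(ALIPHATIC_VALENCE[move] - (order if head >= 0 else 0))
        state.stack[-1] = idx
        cyc, _ = state._innermost_cycle()
        if cyc is not None:
            cyc.length += 1
        state.pending_order = 1
        state.tokens.append(move)
        state.char_count += len(move)
    if state.char_count >= config.finish_asap_after:
        state.finish_asap = True


def apply_move(
    state: GenerationState, move: str, config: SearchConfig = DEFAULT_CONFIG,
    matrices: FrequencyMatrices | None = None, check: bool = False,
) -> GenerationState:
    """Return the successor state after playing ``move`` (the input is untouched)."""
    if check and move not in legal_moves(state, matrices, config):
        raise ValueError(f"illegal move {move!r} from {state.smiles!r}")
    new = state.copy()
    apply_move_inplace(new, move, config)
    return new


def _free_digit(state: GenerationState) -> str:
    used = {c.digit for c in state.open_cycles}
    for d in "123456789":
        if d not in used:
            return d
    raise RuntimeError("ring digit space exhausted")


# ---------------------------------------------------------------------------
# Shortcut handling and corpus scanning
# ---------------------------------------------------------------------------

def expand_shortcuts(smiles: str) -> str:
    """Rewrite the internal W/M/U tokens into standard SMILES.

    Placement is token-aware so the expansion stays syntactically valid:
    a leading trifluoromethyl is spelled fluorine-first (``FC(F)(F)...``)
    so the rest of the string attaches to the carbon, and ring digits that
    follow a sulfinyl/sulfonyl atom are moved onto the sulfur, before the
    ``(=O)`` branches.
    """
    toks = tokenize(smiles)
    out: list[str] = []
    seen_atom = False
    i = 0
    while i < len(toks):
        t = toks[i]
        if t == "W":
            out.append("C(F)(F)F" if seen_atom else "FC(F)(F)")
            seen_atom = True
        elif t in ("M", "U"):
            digits = []
            j = i + 1
            while j < len(toks) and toks[j] in RING_DIGITS:
                digits.append(toks[j])
                j += 1
            tail = "(=O)" if t == "M" else "(=O)(=O)"
            out.append("S" + "".join(digits) + tail)
            i = j - 1
            seen_atom = True
        else:
            if t in ATOM_TOKENS:
                seen_atom = True
            out.append(t)
        i += 1
    return "".join(out)


def compress_shortcuts(smiles: str) -> str:
    """Replace trifluoromethyl / sulfinyl / sulfonyl spellings with W/M/U.

    Operates textually on the common linear spellings (``C(F)(F)F``,
    ``S(=O)(=O)``, ``S(=O)``); the inverse of :func:`expand_shortcuts` on
    its image.
    """
    s = smiles.replace("S(=O)(=O)", "U").replace("S(=O)", "M")
    s = s.replace("C(F)(F)F", "W").replace("FC(F)(F)", "WX")
    # "FC(F)(F)X" spells the group fluorine-first at a string start; the
    # marker keeps the attachment point on the right side of the token.
    if "WX" in s:
        s = s.replace("WX", "W")
    return s


def build_frequency_matrices(corpus: list[str]) -> FrequencyMatrices:
    """Scan a corpus of SMILES into atom and bond frequency matrices.

    Each line is shortcut-compressed first so the counts condition on the
    same tokens the generator plays.  Unreadable lines are skipped with a
    log message; an entirely unreadable corpus is an error.
    """
    m = FrequencyMatrices()
    parsed = 0
    for line in corpus:
        try:
            g = parse_graph(compress_shortcuts(line.strip()))
        except ValueError as exc:
            logger.warning("skipping corpus line %r: %s", line, exc)
            continue
        parsed += 1
        for atom in g.atoms:
            m.atom_counts[atom.token] = m.atom_counts.get(atom.token, 0) + 1
        for bond in g.bonds:
            a, b = g.atoms[bond.a].token, g.atoms[bond.b].token
            order = 0 if bond.aromatic else bond.order
            key = (min(a, b), max(a, b), order)
            m.bond_counts[key] = m.bond_counts.get(key, 0) + 1
            for tok in (a, b):
                m.bond_totals[tok] = m.bond_totals.get(tok, 0) + 1
    if parsed == 0:
        raise ValueError("no parseable SMILES in corpus")
    return m
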