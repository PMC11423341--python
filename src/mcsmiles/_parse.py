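"""Single-pass reader for the organic-subset SMILES this package emits.

This is *not* a general SMILES parser (RDKit is used wherever full
chemistry perception is needed); it is the cheap one-pass scan that the
descriptor computation and the bond frequency matrices are built on.  It
understands the internal group shortcuts (W/M/U) as well as their expanded
standard forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import (
    ALIPHATIC_VALENCE,
    AROMATIC_SIGMA,
    ATOM_TOKENS,
    RING_DIGITS,
    tokenize,
)


@dataclass
class ParsedAtom:
    token: str
    aromatic: bool
    used: int = 0          # sum of external bond orders (aromatic ring bonds count 1)


@dataclass
class ParsedBond:
    a: int
    b: int
    order: int
    aromatic: bool


@dataclass
class ParsedGraph:
    atoms: list[ParsedAtom] = field(default_factory=list)
    bonds: list[ParsedBond] = field(default_factory=list)


def parse_graph(smiles: str) -> ParsedGraph:
    """Scan a SMILES string into atoms and bonds.

    Raises ``ValueError`` on syntax the subset does not cover (unclosed
    rings or parentheses, dangling bond symbols, unknown tokens).
    """
    g = ParsedGraph()
    tokens = tokenize(smiles)
    prev: int | None = None
    stack: list[int | None] = []
    ring_open: dict[str, tuple[int, int]] = {}
    pending = 1
    for tok in tokens:
        if tok == "(":
            stack.append(prev)
        elif tok == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' in {smiles!r}")
            prev = stack.pop()
        elif tok == "=":
            pending = 2
        elif tok == "#":
            pending = 3
        elif tok in RING_DIGITS:
            if prev is None:
                raise ValueError(f"ring digit before any atom in {smiles!r}")
            if tok in ring_open:
                j, order = ring_open.pop(tok)
                aro = g.atoms[prev].aromatic and g.atoms[j].aromatic
                order = max(order, pending)
                g.bonds.append(ParsedBond(prev, j, order, aro))
                g.atoms[prev].used += order
                g.atoms[j].used += order
            else:
                ring_open[tok] = (prev, pending)
            pending = 1
        elif tok in ATOM_TOKENS:
            idx = len(g.atoms)
            g.atoms.append(ParsedAtom(tok, tok in AROMATIC_SIGMA))
            if prev is not None:
                aro = g.atoms[prev].aromatic and g.atoms[idx].aromatic
                g.bonds.append(ParsedBond(prev, idx, pending, aro))
                g.atoms[prev].used += pending
                g.atoms[idx].used += pending
            pending = 1
            prev = idx
        else:  # pragma: no cover - tokenize already rejects these
            raise ValueError(f"unexpected token {tok!r}")
    if stack:
        raise ValueError(f"unclosed parenthesis in {smiles!r}")
    if ring_open:
        raise ValueError(f"unclosed ring bond in {smiles!r}")
    if not g.atoms:
        raise ValueError("empty SMILES")
    return g


def implicit_hydrogens(atom: ParsedAtom) -> int:
    """Implicit hydrogen count of a parsed atom under this subset's rules."""
    tok = atom.token
    if tok == "W":
        return 0
    if tok == "[nH]":
        return 1
    if atom.aromatic:
        cap = 3 if tok == "c" else 2
        return max(0, cap - atom.used)
    if tok in ("M", "U"):
        return max(0, 2 - atom.used)
    return max(0, ALIPHATIC_VALENCE[tok] - atom.used)
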