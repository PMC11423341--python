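"""Move alphabet: atom tokens, valences, masses and the shortcut table.

The generator works over an internal alphabet in which three common
functional groups are single tokens -- ``W`` (trifluoromethyl), ``M``
(sulfinyl) and ``U`` (sulfonyl) -- so that the character-level prior does
not have to learn their internal syntax.  Bromine, phosphorus and all
inorganic atoms are deliberately absent: the generator targets the common
organic subset found in approved small-molecule drugs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable


@dataclass(frozen=True)
class AtomSpec:
    """One registered atom (or group) token.

    ``valence`` is the number of external bonds the token can form; for the
    group shortcuts this is what remains after the group-internal bonds.
    ``implicit_h`` maps the number of consumed external bonds to the implicit
    hydrogen count of the finished token.
    """

    symbol: str
    valence: int
    aromatic_capable: bool
    implicit_h: Callable[[int], int]


def _h_rule(valence: int) -> Callable[[int], int]:
    return lambda used: max(0, valence - used)


# Aliphatic atoms.  Sulfur appears three times: plain thioether S plus the
# sulfinyl (M) and sulfonyl (U) bonding modes as their own tokens.
ALIPHATIC_VALENCE: dict[str, int] = {
    "C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1,
    "W": 1,   # -CF3, terminal
    "M": 2,   # -S(=O)-
    "U": 2,   # -S(=O)(=O)-
}

# sigma-bond capacity of aromatic tokens (ring bonds count 1 each).
AROMATIC_SIGMA: dict[str, int] = {
    "c": 3,      # 2 ring bonds + 1 substituent/H
    "n": 2,      # pyridine-type, ring bonds only
    "o": 2,
    "s": 2,
    "[nH]": 2,   # pyrrole-type, ring bonds only, one explicit H
}

ATOM_TOKENS = frozenset(ALIPHATIC_VALENCE) | frozenset(AROMATIC_SIGMA)

# Pyrrole-type contributors of two pi electrons; an aromatic five-ring
# needs exactly one of these, a six-ring none.
HETERO2_TOKENS = frozenset({"o", "s", "[nH]"})

REGISTRY: dict[str, AtomSpec] = {}
for _t, _v in ALIPHATIC_VALENCE.items():
    REGISTRY[_t] = AtomSpec(_t, _v, False, _h_rule(0 if _t == "W" else _v))
for _t, _v in AROMATIC_SIGMA.items():
    REGISTRY[_t] = AtomSpec(
        _t, _v, True,
        (lambda used: 1) if _t == "[nH]"
        else (_h_rule(3) if _t == "c" else _h_rule(0)),
    )

# Standard average atomic weights to three decimals.
ELEMENT_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "S": 32.067, "Cl": 35.453, "H": 1.008,
}

# Heavy-atom composition of every token, used for mass, atom counts and
# heavy-atom ratio bookkeeping.
COMPOSITION: dict[str, dict[str, int]] = {
    "C": {"C": 1}, "N": {"N": 1}, "O": {"O": 1}, "F": {"F": 1},
    "S": {"S": 1}, "Cl": {"Cl": 1},
    "W": {"C": 1, "F": 3}, "M": {"S": 1, "O": 1}, "U": {"S": 1, "O": 2},
    "c": {"C": 1}, "n": {"N": 1}, "o": {"O": 1}, "s": {"S": 1},
    "[nH]": {"N": 1},
}

SHORTCUT_EXPANSION = {"W": "C(F)(F)F", "M": "S(=O)", "U": "S(=O)(=O)"}

STRUCTURAL_TOKENS = frozenset("()=#123456789$")

RING_DIGITS = "123456789"

# Termination move marker; never written into the output SMILES.
END = "$"


def token_mass(token: str) -> float:
    """Mass of a token's heavy atoms (no hydrogens)."""
    return sum(ELEMENT_MASS[el] * k for el, k in COMPOSITION[token].items())


def token_heavy_atoms(token: str) -> int:
    return sum(COMPOSITION[token].values())


def token_no_count(token: str) -> int:
    """Number of N plus O atoms contributed by the token."""
    comp = COMPOSITION[token]
    return comp.get("N", 0) + comp.get("O", 0)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string (internal or standard organic subset) into tokens.

    Raises ``ValueError`` on characters outside the supported alphabet
    (brackets other than ``[nH]``, charges, stereo marks, Br/P/I...).
    """
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "C" and i + 1 < n and smiles[i + 1] == "l":
            tokens.append("Cl")
            i += 2
        elif ch == "[":
            if smiles[i:i + 4] == "[nH]":
                tokens.append("[nH]")
                i += 4
            else:
                raise ValueError(f"unsupported bracket atom at {i}: {smiles!r}")
        elif ch in ALIPHATIC_VALENCE or ch in "cnos":
            tokens.append(ch)
            i += 1
        elif ch in "()=#" or ch in RING_DIGITS:
            tokens.append(ch)
            i += 1
        elif ch == "-":
            # explicit single bond: redundant in this subset
            i += 1
        else:
            raise ValueError(f"unsupported character {ch!r} in {smiles!r}")
    return tokens
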