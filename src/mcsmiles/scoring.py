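"""Molecular descriptors and the five-term Lipinski compliance score.

The score rewards molecules that satisfy the Rule-of-5-style constraints

* molecular weight <= 500 Da,
* 20 <= total atom count (hydrogens included) <= 70,
* at most 5 hydrogen-bond donors,
* at most 10 hydrogen-bond acceptors,

through five terms ``alpha_i = 1 - penalty_i``, each penalty a linear
ramp clamped at zero, so the total is at most 5 and equals 5 exactly on
the feasible region.  clogP is deliberately not part of the score.

Descriptors come from a single pass over the SMILES string (no chemistry
toolkit involved); hydrogen-bond acceptors are counted as all N and O
atoms, donors as N/O atoms bearing at least one hydrogen (the Lipinski
conventions).  Donor counting is switchable to per-hydrogen counting
(``convention="h_count"``), under which water has 2 donors instead of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import (
    COMPOSITION,
    ELEMENT_MASS,
    token_heavy_atoms,
    token_mass,
    token_no_count,
)
from ._parse import implicit_hydrogens, parse_graph
from .search_model import GenerationState, compress_shortcuts

H_MASS = ELEMENT_MASS["H"]


@dataclass(frozen=True)
class DescriptorSet:
    """The four descriptors the compliance score is built on."""

    mass: float   # Daltons, implicit hydrogens included
    natoms: int   # atom count including hydrogens
    nhbd: int     # hydrogen-bond donors
    nhba: int     # hydrogen-bond acceptors (N + O count)


@dataclass(frozen=True)
class ScoreBreakdown:
    alpha1: float  # molecular weight <= 500
    alpha2: float  # at most 70 atoms
    alpha3: float  # at least 20 atoms
    alpha4: float  # at most 5 H-bond donors
    alpha5: float  # at most 10 H-bond acceptors

    @property
    def total(self) -> float:
        return self.alpha1 + self.alpha2 + self.alpha3 + self.alpha4 + self.alpha5


MAX_SCORE = 5.0


def _donor_token(token: str) -> bool:
    comp = COMPOSITION[token]
    return token != "W" and ("N" in comp or "O" in comp) and token not in ("M", "U")


def compute_descriptors(smiles: str, convention: str = "atom") -> DescriptorSet:
    """Descriptors from one pass over an (internal or standard) SMILES string.

    ``convention`` selects how donors are counted: ``"atom"`` counts N/O
    atoms carrying at least one H, ``"h_count"`` sums those hydrogens.

    Shortcut groups are recognized in either spelling: the string is
    compressed first so a sulfinyl/sulfonyl sulfur keeps its bonding mode
    (and hence its implicit-hydrogen rule) wherever it sits in the string.
    """
    g = parse_graph(compress_shortcuts(smiles))
    mass = 0.0
    heavy = 0
    hydrogens = 0
    nhba = 0
    nhbd = 0
    for atom in g.atoms:
        h = implicit_hydrogens(atom)
        mass += token_mass(atom.token) + H_MASS * h
        heavy += token_heavy_atoms(atom.token)
        hydrogens += h
        nhba += token_no_count(atom.token)
        if h > 0 and _donor_token(atom.token):
            nhbd += h if convention == "h_count" else 1
    return DescriptorSet(mass=mass, natoms=heavy + hydrogens, nhbd=nhbd, nhba=nhba)


def descriptors_from_state(
    state: GenerationState, convention: str = "atom"
) -> DescriptorSet:
    """Fast descriptor path for terminal search states.

    At a terminal state each atom's remaining valence *is* its implicit
    hydrogen count, so no string re-parse is needed.  Agrees exactly with
    :func:`compute_descriptors` on the state's SMILES.
    """
    mass = 0.0
    heavy = 0
    hydrogens = 0
    nhba = 0
    nhbd = 0
    for tok, rem in zip(state.atom_tok, state.atom_rem):
        if tok == "W":
            h = 0
        elif tok == "[nH]":
            h = 1
        else:
            h = rem
        mass += token_mass(tok) + H_MASS * h
        heavy += token_heavy_atoms(tok)
        hydrogens += h
        nhba += token_no_count(tok)
        if h > 0 and _donor_token(tok):
            nhbd += h if convention == "h_count" else 1
    return DescriptorSet(mass=mass, natoms=heavy + hydrogens, nhbd=nhbd, nhba=nhba)


def compliance_score(d: DescriptorSet) -> ScoreBreakdown:
    """The five-term drug-likeness score; total <= 5, with equality exactly
    when all four descriptor constraints are met."""
    return ScoreBreakdown(
        alpha1=1.0 - max(d.mass - 500.0, 0.0) / 500.0,
        alpha2=1.0 - max(d.natoms - 70, 0) / 70.0,
        alpha3=1.0 + min(d.natoms - 20, 0) / 20.0,
        alpha4=1.0 - max(d.nhbd - 5, 0) / 5.0,
        alpha5=1.0 - max(d.nhba - 10, 0) / 10.0,
    )


def score_smiles(smiles: str, convention: str = "atom") -> float:
    """Total compliance score of a SMILES string."""
    return compliance_score(compute_descriptors(smiles, convention)).total


def score_state(state: GenerationState, convention: str = "atom") -> float:
    return compliance_score(descriptors_from_state(state, convention)).total


def heavy_atom_counts(smiles: str) -> dict[str, int]:
    """Heavy atoms by element, group shortcuts expanded."""
    g = parse_graph(smiles)
    counts: dict[str, int] = {}
    for atom in g.atoms:
        for el, k in COMPOSITION[atom.token].items():
            counts[el] = counts.get(el, 0) + k
    return counts
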