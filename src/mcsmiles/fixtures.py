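"""Packaged and generated corpora so every component runs with no download.

``load_curated`` returns a small hand-assembled set of well-known approved
drugs (aspirin, ibuprofen, celecoxib, ...) restricted to the C/O/N/F/S/Cl
organic subset this package generates.  It plays the statistical role of a
large drug database -- atom and bond frequencies, ring sizes, CF3 /
sulfinyl / sulfonyl groups -- at toy scale.

``synthetic_corpus`` produces SMILES by running the search model itself
under an n-gram policy, so the output is valid by construction and
retraining n-grams on it recovers the driving conditionals within
sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from random import Random

from .mcs import NgramPolicy, SmilesSpace, playout
from .priors import NgramModel
from .search_model import DEFAULT_CONFIG, SearchConfig, expand_shortcuts


@dataclass(frozen=True)
class FixtureCorpus:
    smiles: tuple[str, ...]
    provenance: str  # "curated" | "synthetic"
    generator_params: dict | None = None

    def __iter__(self):
        return iter(self.smiles)

    def __len__(self) -> int:
        return len(self.smiles)


def load_curated() -> FixtureCorpus:
    """The packaged curated drug corpus (one canonical SMILES per line)."""
    text = (
        resources.files("mcsmiles").joinpath("data/curated_drugs.smi")
        .read_text()
    )
    smiles = tuple(
        line.split()[0]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    if not smiles:
        raise FileNotFoundError("curated corpus resource is empty")
    return FixtureCorpus(smiles=smiles, provenance="curated")


def synthetic_corpus(
    model: NgramModel,
    n: int,
    seed: int = 0,
    config: SearchConfig = DEFAULT_CONFIG,
    expanded: bool = True,
) -> FixtureCorpus:
    """``n`` SMILES sampled from the search model under ``model``'s policy.

    Valid by construction; with ``expanded=False`` the internal shortcut
    alphabet is kept, which is the representation n-gram training uses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = Random(seed)
    space = SmilesSpace(config)
    policy = NgramPolicy(model)
    out = []
    for _ in range(n):
        seq = playout(space, space.initial(), policy, rng)
        smi = seq.state.smiles
        out.append(expand_shortcuts(smi) if expanded else smi)
    return FixtureCorpus(
        smiles=tuple(out),
        provenance="synthetic",
        generator_params={"n": n, "seed": seed, "order": model.order},
    )
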