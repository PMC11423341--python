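"""Library metrics: validity, uniqueness, novelty, average edit distance.

Validity is the fraction of SMILES an independent chemistry toolkit
(RDKit) can parse and sanitize.  Uniqueness and novelty compare canonical
forms, so rewritings of the same molecule count as duplicates.  The
average edit distance is the mean Levenshtein distance over all unordered
pairs among the first 1,000 library entries (the conventional sample size
for this metric), computed with edlib.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import edlib
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

EDIT_SAMPLE = 1000


@dataclass(frozen=True)
class MetricsReport:
    n: int
    validity: float                # percent
    uniqueness: float              # percent
    novelty: float | None          # percent; None without a reference set
    avg_edit_distance: float | None  # characters; None for libraries of < 2

    def to_tsv(self) -> str:
        rows = [
            ("n", str(self.n)),
            ("validity_pct", f"{self.validity:.2f}"),
            ("uniqueness_pct", f"{self.uniqueness:.2f}"),
            ("novelty_pct",
             "NA" if self.novelty is None else f"{self.novelty:.2f}"),
            ("avg_edit_distance",
             "NA" if self.avg_edit_distance is None
             else f"{self.avg_edit_distance:.3f}"),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in rows)


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def validity(library: list[str]) -> float:
    """Percentage of entries the toolkit parses and sanitizes."""
    if not library:
        raise ValueError("empty library")
    ok = sum(1 for s in library if Chem.MolFromSmiles(s) is not None)
    return 100.0 * ok / len(library)


def uniqueness(library: list[str]) -> float:
    """Percentage of distinct molecules (canonical-form comparison)."""
    if not library:
        raise ValueError("empty library")
    canon = []
    for s in library:
        c = _canonical(s)
        if c is None:
            raise ValueError(f"unparseable SMILES in library: {s!r}")
        canon.append(c)
    return 100.0 * len(set(canon)) / len(canon)


def novelty(library: list[str], reference: list[str]) -> float:
    """Percentage of library molecules absent from the reference set."""
    if not library or not reference:
        raise ValueError("library and reference must be non-empty")
    ref = set()
    for s in reference:
        c = _canonical(s)
        if c is None:
            raise ValueError(f"unparseable SMILES in reference: {s!r}")
        ref.add(c)
    absent = 0
    for s in library:
        c = _canonical(s)
        if c is None:
            raise ValueError(f"unparseable SMILES in library: {s!r}")
        if c not in ref:
            absent += 1
    return 100.0 * absent / len(library)


def avg_edit_distance(library: list[str], m: int = EDIT_SAMPLE) -> float:
    """Mean Levenshtein distance over all unordered pairs of the first
    ``m`` entries, as raw character strings."""
    if m < 2:
        raise ValueError("need at least 2 strings")
    sample = library[:m]
    if len(sample) < 2:
        raise ValueError("library too small for pairwise distances")
    total = 0
    pairs = 0
    for a, b in combinations(sample, 2):
        total += edlib.align(a, b, task="distance")["editDistance"]
        pairs += 1
    return total / pairs


def evaluate_library(
    library: list[str],
    reference: list[str] | None = None,
    edit_sample: int = EDIT_SAMPLE,
) -> MetricsReport:
    """All four metrics for a generated library.

    Uniqueness is computed on the parseable subset (so a partially invalid
    external library still gets a report); novelty needs ``reference``.
    """
    if not library:
        raise ValueError("empty library")
    val = validity(library)
    parseable = [s for s in library if Chem.MolFromSmiles(s) is not None]
    uniq = uniqueness(parseable) if parseable else 0.0
    nov = novelty(parseable, reference) if reference and parseable else None
    aed = (
        avg_edit_distance(library, edit_sample)
        if len(library) >= 2 and edit_sample >= 2
        else None
    )
    return MetricsReport(
        n=len(library), validity=val, uniqueness=uniq,
        novelty=nov, avg_edit_distance=aed,
    )
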