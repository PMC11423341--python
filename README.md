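# mcsmiles

De novo generation of drug-like small molecules by Monte Carlo search
over a validity-guaranteeing SMILES grammar.

Most neural molecule generators emit some fraction of unparseable or
valence-broken SMILES and need a big training corpus before they produce
anything sensible.  `mcsmiles` takes the opposite route: a *legal-move
model* builds SMILES character by character and only ever offers moves
that can still be completed into a syntactically and valence-valid
molecule, so **100% of generated SMILES are valid by construction** —
with or without training data.  On top of that move space, Monte Carlo
search algorithms (independent sampling, Nested Monte Carlo Search,
UCT/PUCT) maximize a five-term drug-likeness score, and optional
statistical priors (character n-grams, corpus atom ratios, bond
frequency filters) steer playouts toward drug-like chemistry.

The score is a Rule-of-5-style compliance function of four cheaply
computed descriptors (one pass over the string, no toolkit needed):

    alpha1 = 1 - max(mass - 500, 0)/500      # MW <= 500 Da
    alpha2 = 1 - max(natoms - 70, 0)/70      # at most 70 atoms (H included)
    alpha3 = 1 + min(natoms - 20, 0)/20      # at least 20 atoms
    alpha4 = 1 - max(nhbd - 5, 0)/5          # <= 5 H-bond donors
    alpha5 = 1 - max(nhba - 10, 0)/10        # <= 10 H-bond acceptors
    score  = alpha1 + alpha2 + alpha3 + alpha4 + alpha5   # max 5

Generation collects molecules that reach the ceiling of 5.  Generated
libraries are assessed with the standard metrics — validity, uniqueness,
novelty and average pairwise edit distance — using RDKit as the
independent oracle.

The package ships a curated corpus of 267 approved-drug SMILES so every
feature (n-gram priors, frequency matrices, enforced atom ratios,
novelty references) works offline.

## Worked example

```python
from mcsmiles import generate_library, evaluate_library
from mcsmiles.fixtures import load_curated

corpus = list(load_curated())
lib = generate_library(1000, algorithm="nmcs", playout_mode="ngram",
                       seed=7, corpus=corpus)
print(lib[0].smiles, lib[0].score)

report = evaluate_library([m.smiles for m in lib], reference=corpus)
print(report.to_tsv())
```

prints

```
NS(=O)(=O)c1sccc1c1cccc(S(=O)(=O)Nc2ccccc2C(F)(F)F)n1 5.0
n	1000
validity_pct	100.00
uniqueness_pct	99.70
novelty_pct	100.00
avg_edit_distance	26.107
```

Every molecule parses in RDKit (validity 100%), 99.7% are distinct after
canonicalization, none of them is one of the corpus drugs (novelty 100%
against that reference), and two generated strings differ by ~26 edit
operations on average — a spread-out library.  The first molecule scores
a full 5.0: its weight (463.5 Da), atom count (41), donors (2) and
acceptors (7) all sit inside the drug-likeness box.

The same runs from the shell:

```bash
mcsmiles generate --algo nmcs --playout ngram --n 1000 --seed 7 --out lib.smi
mcsmiles evaluate --library lib.smi --reference ref.smi
```

(`--algo sampling|nmcs|uct|puct`, `--playout random|enforced|ngram`;
`mcsmiles train-ngrams`, `freq-matrices` and `make-fixtures` expose the
priors and the synthetic-corpus generator.)

## Layout

| module | contents |
|---|---|
| `mcsmiles.search_model` | legal-move model, state bookkeeping, shortcut expansion, frequency matrices |
| `mcsmiles.scoring` | single-pass descriptors and the compliance score |
| `mcsmiles.priors` | n-gram model, cycle-closure policy, atom-ratio targets |
| `mcsmiles.mcs` | sampling, NMCS, UCT/PUCT, library generation |
| `mcsmiles.evaluation` | validity / uniqueness / novelty / edit distance |
| `mcsmiles.fixtures` | packaged drug corpus and synthetic-corpus generator |
| `mcsmiles.cli` | the `mcsmiles` command |

See `docs/methods.md` for the model's assumptions, parameter defaults
and known limitations.
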