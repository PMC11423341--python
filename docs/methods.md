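# Methods

## The generation model

`mcsmiles` builds molecules as SMILES strings one token at a time.  The
central object is a *legal-move model*: from any partial string it
enumerates exactly the tokens that can be appended such that the string
can still be completed into a syntactically and valence-valid SMILES.
Because every playout policy is restricted to these moves, **every**
completed molecule parses and sanitizes in RDKit — validity is a
structural property of the move model, not a statistical outcome, and it
holds with or without training data.

The bookkeeping the model maintains:

* **Subtree depth.** One stack frame per open parenthesis; the string may
  only terminate at the root level, and `)` is illegal at the root.
* **Remaining valence of the active atom.** Each frame tracks the last
  atom added at that level; appending an atom consumes the pending bond
  order (1 by default, 2/3 after `=`/`#`) from both partners.  At a
  terminal state an atom's remaining valence *is* its implicit hydrogen
  count, which is what makes single-pass descriptor evaluation exact.
* **Open rings.** A ring-opening digit reserves one valence on the
  opening atom; only the most recently opened ring may close, and only at
  5, 6 or 7 atoms.  Smaller rings are strained, larger ones rare in
  drugs.  A second ring may open while an aliphatic ring is still open at
  the same depth, producing fused bicyclics that share exactly one bond;
  while two rings are open every in-ring atom must keep two spare
  valences so the double closure can never dead-end.
* **Aromatic mode.** An aromatic ring opens as `c` + digit and must be
  completed before anything else happens at that depth.  Six-membered
  aromatic rings contain only `c`/`n` (at most 3 `n`); five-membered
  rings contain exactly one two-pi-electron contributor from
  {`o`, `s`, `[nH]`} and close at 5.  These composition rules guarantee a
  kekulizable ring in every case, so aromaticity never breaks the
  validity guarantee.  Fused aromatics and N-substituted pyrrole-type
  nitrogens are not generated — a deliberate trade of some chemical
  diversity for a provable guarantee.
* **finish-ASAP.** Once the string reaches `finish_asap_after`
  characters, expansion moves (new branches, new rings) become illegal
  while completion moves stay legal, keeping molecules and playouts
  short.  At `max_chars` the model switches to pure forced-completion
  moves, so playout length is strictly bounded.

The atom alphabet is C, O, N, F, S, Cl plus three group tokens: `W`
(trifluoromethyl), `M` (sulfinyl `S(=O)`), `U` (sulfonyl `S(=O)(=O)`),
which keep sulfur's higher bonding modes and the CF3 group out of the
prior's learning problem.  Br and P are excluded as rare in approved
drugs.  Expansion back to standard SMILES is token-aware: a leading CF3
is written fluorine-first and ring digits attach to the sulfur before its
`(=O)` branches, so the expanded text is always parseable.

When a training corpus is supplied, its atom/bond **frequency matrices**
additionally prune bonds seen in less than 1/10,000 of either partner
atom's bonds; if pruning would leave no move, the filter is dropped for
that step so the search can never corner itself.

## The compliance score

For a molecule with molecular weight `mass` (Da), total atom count
`natoms` (hydrogens included), `nhbd` hydrogen-bond donors and `nhba`
acceptors:

    alpha1 = 1 - max(mass - 500, 0)/500
    alpha2 = 1 - max(natoms - 70, 0)/70
    alpha3 = 1 + min(natoms - 20, 0)/20
    alpha4 = 1 - max(nhbd - 5, 0)/5
    alpha5 = 1 - max(nhba - 10, 0)/10
    score  = alpha1 + ... + alpha5        (maximum 5)

Each term is a linear penalty clamped at zero, so over-satisfying a
constraint earns no bonus and the score is 5 exactly on the feasible
region (mass ≤ 500, 20 ≤ natoms ≤ 70, nhbd ≤ 5, nhba ≤ 10).  Acceptors
are counted as all N and O atoms, donors as N/O atoms bearing at least
one hydrogen (per-hydrogen counting is available via
`convention="h_count"`, under which water has 2 donors rather than 1).
Atomic masses are standard average weights to three decimals, matching
RDKit's periodic table so the oracle-agreement tests are exact.  RDKit's
`NumHDonors` additionally counts S–H groups; our Lipinski-style N/O
convention does not, and the tests bound that delta by the number of S–H
atoms.  clogP is deliberately not part of the score.

## Search algorithms

All drivers operate on an abstract search-space interface (initial state,
legal moves, apply, terminal test, score), so they are tested on small
enumerable toy problems as well as on the SMILES space.

* **Sampling** — independent playouts from the empty state; a generation
  run ends when a molecule reaches the score ceiling of 5.
* **NMCS** (default level 3) — at each step, a level-(n−1) search
  evaluates every legal move, the best sequence seen anywhere in the
  level is remembered, and the search advances along its next move.
  Children are explored in a seeded random order: every child is still
  searched, but no branch is systematically first, which matters in
  generation mode where runs stop at the first score-5 molecule — with a
  fixed order all runs would share a lexicographically-first prefix and
  short molecules would collide.
* **UCT / PUCT** — the four-phase selection/expansion/evaluation/
  backpropagation loop.  Selection maximizes `X_S + C·sqrt(ln V / V_S)`
  (UCT; unvisited children first) or `X_S + C·P_S·sqrt(V)/(1 + V_S)`
  (PUCT, with the n-gram prior supplying `P_S`), with `C = 1` and scores
  normalized to [0, 1] (score/5) inside the tree so the constant is
  meaningful.  Ties break toward the earliest-inserted move.  Generation
  wraps the search in a restart loop with an iteration/time budget.

In generation mode each algorithm emits molecules that reach score 5;
NMCS/sampling effectively perform one independent run per molecule,
continuing a single seeded random stream for reproducibility.

## Playout policies

* **random** — uniform over legal moves.
* **enforced** — uniform over legal moves, with an auxiliary score term
  `−Σ |observed − target|` over heavy-atom fractions (C/O/N/F/S/Cl)
  pulling the *search* toward corpus-like atom ratios; the library
  acceptance criterion stays the plain compliance score.
* **ngram** — conditional next-token probabilities of order 3 (token
  level: `Cl`, `[nH]` and the group shortcuts are single symbols, ring
  digits are canonicalized to a generic digit, string starts are padded
  with a sentinel, and an end-of-string token is appended so termination
  is weighted too).  Probabilities below 0.001 are pruned as too rare,
  the rest renormalized over the legal moves; unseen contexts fall back
  to uniform.  Ring closure is not drawn from the table: an open ring
  closes with probability 0.228 at length 5, 0.751 at length 6 and is
  forced at 7 — the 5:6:7 ring-size proportions of FDA-approved drugs.

Because the grammar discards illegal continuations and renormalizes,
training n-grams on the generator's own output recovers the driving
conditionals exactly only away from structural tokens; the test suite
checks exact recovery on a chain-only model (where the grammar never
intervenes) and relative atom-ratio recovery elsewhere.

## Library metrics

Validity = % of SMILES RDKit parses and sanitizes.  Uniqueness = % of
distinct canonical forms (so rewritings of one molecule count as
duplicates).  Novelty = % of canonical forms absent from a user-supplied
reference set.  Average edit distance = mean Levenshtein distance over
all unordered pairs of the first 1,000 entries (edlib-backed, verified
against a dynamic-programming oracle and metric axioms in tests).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `min_cycle` / `max_cycle` | 5 / 7 | allowed ring sizes |
| `rare_bond_threshold` | 1/10 000 | corpus-frequency bond filter |
| `finish_asap_after` | 25 chars | start refusing expansion moves |
| `max_chars` | 60 chars | forced completion beyond this length |
| `min_chars` | 10 chars | earliest voluntary termination |
| n-gram `order` | 3 | context length in tokens |
| `prune_threshold` | 0.001 | minimum conditional probability |
| cycle closure | 0.228 / 0.751 / 0.02 | P(close) at ring length 5/6/7 |
| NMCS `level` | 3 | nesting depth |
| UCT `C` | 1.0 | exploration constant |

`finish_asap_after` and `max_chars` are chosen so that typical molecules
land inside the 20–70-atom window of the score; both are configurable.

## The packaged corpus and what it does (and does not) show

The curated corpus is 267 well-known approved-drug SMILES typed into the
repository (canonicalized, stereochemistry removed, restricted to the
neutral C/O/N/F/S/Cl subset).  It emulates the statistical role of a
large drug database — atom and bond frequencies, ring-size proportions,
CF3/sulfinyl/sulfonyl occurrences — at toy scale.  Priors trained on it
are far sparser than ones trained on hundreds of thousands of compounds:
generated libraries are therefore more diverse and less drug-looking
than corpus-scale runs would give, and corpus-dependent numbers (novelty
against a fixed external collection, absolute edit-distance values)
shift with the corpus.  The structural claims — 100% validity, ring-size
law, score ceiling, closure statistics — do not depend on the corpus at
all.

## Numerical choices and degenerate inputs

Scores are exact floating sums of five clamped terms; the ceiling test
uses equality, not a tolerance, because every term is exactly 1.0 on the
feasible region.  Seeded `random.Random` streams drive all stochastic
components; every public entry point takes a seed and identical seeds
reproduce identical libraries bit-for-bit.  Empty corpora, empty
libraries, unparseable reference entries and terminal-state move queries
raise `ValueError`; unreadable corpus lines are skipped with a log
message.  Metric sample sizes: problem sizes in the test suite are
chosen to exercise claims at full scale where the claim is exact
(10,000-molecule libraries for validity/uniqueness) and at reduced scale
for statistical recovery properties (2,000–3,000-line corpora), with
binomial 3-sigma tolerances.

## Known limitations

* No stereochemistry, charges, isotopes, Br, P or inorganic atoms.
* No fused aromatic systems or N-substituted azoles; aromatic diversity
  is therefore lower than in real drug space.
* The enforced mode's ratio term matches per-molecule atom fractions,
  not library-level fractions.
* The neural playout policy some generators use is out of scope; the
  policy interface (`policy(space, state, legal, rng) -> move`) is the
  plug-in point if one is added.
* Synthesizability, ADMET and docking are external analyses and not
  computed here.
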