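# Methods

This note documents the models, conventions and design choices behind
`lirscan`, and what its synthetic-data tests do and do not establish.

## Motif model

A candidate LIR is located by its 4-residue core: an aromatic residue
(W/F/Y) with an aliphatic residue (I/L/V) exactly three positions
downstream. The reported unit is the 6-residue *window* — two residues of
upstream context plus the core — with the aromatic at window position 3.
This convention follows the published single-motif spans for the HIV-1 Nef
(11-EGWQTI-16) and HSV-1 ICP34.5 (64-RQWLHV-69) candidates, both 6-mers
with the aromatic third.

Two consensus definitions are applied to each window:

* **xLIR** (strict): every position must fall in its allowed set,
  `[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]`.
* **WxxL** (relaxed): only window positions 3 and 6 are constrained
  (to W/F/Y and I/L/V); positions 4–5 are free.

Classification is exclusive with xLIR precedence; since the xLIR sets at
positions 3 and 6 are subsets of the core sets, every xLIR window is also a
core match, and every detected window is at least WxxL. The *subtype*
(W-, F-, Y-type) is the window position-3 residue.

The allowed-residue sets are data, not code: plain-text files with one
line per position, so relaxed or alternative consensi can be swapped in via
`ConsensusPattern.from_files`. The bundled defaults are the exact pair
above.

Decisions taken where the convention was genuinely open:

* **Left-edge cores.** A core starting at sequence position 1 or 2 has a
  truncated (4- or 5-residue) window. These are reported and flagged
  `truncated`, classified WxxL (the full 6-position consensus is undefined
  for them), with PSSM score NaN (a 6-position matrix has no score for a
  shorter window). Dropping them silently would hide real cores.
* **Non-standard residues** (X, B, Z, U, O, J). The strict membership
  functions raise a typed error naming the character; the proteome scanner
  instead skips the affected window with a logged warning, because aborting
  a whole-proteome scan on one ambiguity code is unacceptable. Lowercase
  input is uppercased first.
* **Overlapping cores** are all reported; deduplication is left to the
  consumer.
* **Coordinates** are 1-based inclusive end-to-end, matching how motif
  spans are printed in the autophagy literature.

## PSSM

The scoring matrix is a 6×20 natural-log odds table:

    score[p][r] = ln( (count(p,r) + α·bg[r]) / (n + α) / bg[r] )

where `count(p,r)` is the number of training windows with residue `r` at
position `p`, `n` the number of training windows, `bg` the background
frequencies, and `α` a Laplace-style pseudocount. Defaults: α = 1, uniform
background (1/20). Both are plain function arguments; the matrix round-trips
through a TSV export. Properties that follow from the formula and are
enforced by tests: per-position smoothed frequencies renormalise to 1;
uniform counts give all-zero scores; raising a count never lowers its cell;
the argmax-per-position consensus maximises the window score.

With α = 0 an unseen residue has log-odds −∞; such cells are stored as the
finite sentinel −99 so that window sums stay well defined. A window score
is the **sum of cells, then rounded** (half away from zero) for display —
not a sum of rounded cells.

The bundled training set (`data/lir_training_set.tsv`) contains nine
6-residue windows around experimentally characterised canonical LIR motifs
(p62/SQSTM1, NBR1, OPTN, FUNDC1, NIX, ATG13, ULK1, yeast Atg19, influenza
M2). It is a replaceable curated default: no numerical claim in the tests
or the acceptance script depends on its exact composition, and users with a
larger verified-LIR collection should retrain from their own TSV. NDP52 is
deliberately absent: its LIR is the non-canonical CLIR without an aromatic
anchor, which the 6-position model cannot represent.

## Disorder annotation

Disorder intervals (e.g. from ANCHOR) are consumed as a 1-based inclusive
TSV, never computed internally. A hit is `in_disorder = True` only when its
whole window is contained in a single interval — a strict, reproducible
reading of "motif in a disordered region"; partial overlap is `False`, and
the flag is `"unknown"` when no intervals are supplied. Unsorted or
overlapping intervals are rejected.

## Enrichment statistics

A protein is a LIRCP when it has ≥ 1 hit of the relevant category
("all" = any motif; "xlir" = at least one xLIR). For a subset of size `n`
with `k` LIRCPs inside a universe of size `N` with `K` LIRCPs:

* fold = `(k/n) / (K/N)` — the subset's LIRCP rate relative to the whole
  universe (subset included);
* p-value = exact upper-tail hypergeometric `P(X ≥ k)`, computed with
  integer binomials and one rational division. Exactness is cheap at the
  problem sizes involved and removes any tail-summation stability concern;
  tests cross-check against `scipy.stats.hypergeom.sf` and against direct
  draw enumeration.

The test is one-tailed (enrichment); no correction is applied by default
because folds, not families of p-values, are the primary readout — a
Benjamini–Hochberg `q_value` column is available via `fdr=True`
(delegated to statsmodels). Subtype distributions report W/F/Y proportions
per pattern class, summing to 1 within each row.

## Taxonomy reconciliation

Species names are normalised (case-fold, collapse whitespace, strip
parenthesised strain qualifiers — UniProt organism fields often append
strain suffixes absent from ICTV lists) and compared by Levenshtein edit
distance, implemented as the standard two-row O(m·n) dynamic programme.
Matching prefers an exact normalised match; otherwise the minimal-distance
candidate within `max_distance` (default 2 — tolerant of typographic
variants while avoiding genus-level collisions, and configurable), ties
broken lexicographically for determinism; otherwise unmatched. Baltimore
groups are assigned by keyword from lineage strings, with the
retro/reverse-transcribing token checked before the single-strand tokens so
it can never be shadowed; unknown lineages are `unclassified`, never an
error.

## Synthetic fixtures

The generators define the conditions under which the package is verified:

* **Proteomes.** Uniform lengths (default 80–200 aa), background residues
  drawn i.i.d. From the *inert* alphabet — the 17 standard residues minus
  W, F, Y — no core can arise outside a planted window, so planted-truth
  tests demand exact precision and recall 1.0. A planted window whose own
  stray aromatic would create a second core is rejected at generation time
  rather than silently under-reporting truth. *Full*-background fixtures
  instead derive their truth table from an exhaustive window oracle.
* **Enrichment cohorts.** Bernoulli LIRCP labels; the subset rate is solved
  from the target measured fold `s = f·b·(N−n)/(N − f·n)` so that the
  expected `(k/n)/(K/N)` equals the requested fold (requesting the fold as
  a subset-vs-rest ratio would bias the measured value low, since the
  subset is part of the universe). Infeasible folds raise.
* **Taxa.** Species names built from random syllables, kept pairwise more
  than `2·max_typo_distance` edits apart so a typo's source remains the
  unique nearest neighbour; typos are substitution edits verified to sit at
  exactly the requested distance.

All randomness flows through `numpy.random.default_rng` (PCG64), so equal
spec + seed gives byte-identical FASTA/TSV output across platforms.

What the fixtures do **not** emulate: real amino-acid composition biases,
polyprotein architecture, homology between sequences, or the noise of real
disorder predictions. Passing the planted-recovery tests therefore shows
the scanner's coordinate bookkeeping and pattern logic are exact; it says
nothing about the biological precision of the consensus patterns on real
proteomes, where most WxxL matches are expected to be spurious.

## Verification sizes and numerical checks

The shipped test and acceptance runs use problem sizes chosen to exercise
each property convincingly while staying quick: 1,000 random sequences
(≤ 200 aa) for scanner-vs-oracle equality; 500 planted motifs for exact
recovery; every urn with N ≤ 12 plus thousands of sampled urns to N = 60
for hypergeometric exactness (relative agreement 1e−12); a 3,000-protein
cohort with a 500-protein subset for fold recovery (±0.5). Edit-distance
agreement with the definitional recursive oracle is exhaustive for all
string pairs up to length 3 over a 3-letter alphabet and densely sampled up
to length 7 (the full cross-product at length 7 is ~10⁷ pairs, which adds
no coverage a dense sample does not); metric axioms are checked on 10,000
random triples, and `edlib` provides an additional independent oracle.

## Known limitations

* The bundled PSSM is trained on nine windows; its absolute scores are not
  calibrated (no E-values) and are not comparable with scores from other
  LIR servers trained on different collections.
* Only the two canonical patterns ship; non-canonical LIRs (CLIR/UIM-like,
  non-aromatic) are out of scope.
* Disorder must be precomputed externally; the package only intersects
  intervals.
* Species matching is per-name; it does not attempt genus/family-level
  constraint propagation when several ICTV species tie beyond the distance
  threshold.
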