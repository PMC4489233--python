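# Methods

## Consensus model

`topoconsensus` treats consensus topology prediction as constrained
decoding.  For a protein of length *L* and *N* input methods, the topology
profile is the *L*×4 matrix of voting fractions
*p<sub>c</sub>(x) = (# methods with label x at residue c)/N* over the
labels S (signal peptide), M (membrane helix), i (inside), o (outside).
Methods are equally weighted; if a method failed for a protein it is
simply omitted and the fractions renormalize over the methods present.

The consensus is the grammar-valid label string maximizing the geometric
mean of its per-residue support, computed in log space:

    score(y) = (1/L) · Σ_c log p̃_c(y_c),
    p̃_c(x)  = (p_c(x) + ε) / (1 + 4ε)

Because the maximizing string has fixed length *L*, maximizing the
geometric mean and maximizing the summed log score coincide.  The decoder
is a Viterbi-style dynamic program over an explicit state machine in which
each state emits exactly one label (emission 1 for its own label, 0
otherwise) and transitions are unweighted — the grammar, not learned
probabilities, carries all structural information, and no training is
involved.

**Pseudocount ε (default 10⁻⁶).**  With mutually inconsistent unanimous
columns (e.g. all methods say `i` at *c* and all say `o` at *c*+1, which no
grammar-valid path can follow), every valid path would otherwise contain a
log 0 term.  Adding ε to each fraction and renormalizing over the 4 labels
keeps all paths finite while perturbing informative columns negligibly;
any ε well below 1/(2N) leaves the ranking of label choices within a
column unchanged.  For profiles with no zero entries, decoding with ε=10⁻⁶
and ε=0 agrees (tested).

**State machine.**  States are: the two loop states (i, o), two helix
chains of `min_helix_len` sub-states (one per crossing direction, i→o and
o→i; the last sub-state self-loops when no maximum is set, or the chain
extends to `max_helix_len` with exits allowed past the minimum), and an SP
chain of `max_sp_len` sub-states enterable only at residue 1 and exiting
into the post-SP loop after `min_sp_len`.  Helix chains may start a path
(a leading helix with only a C-terminal flank) and may end one past their
minimum; the validator applies the side-alternation rule only where both
flanks exist, so validator and decoder accept exactly the same language.
When globular paths are disallowed, each loop state splits into a
pre-structure and post-structure copy so every accepted path crosses an M
or S state.

**Tie-breaking.**  On equal scores the predecessor with the lowest index
in the fixed state order (inside loop < outside loop < helix chains < SP
chain) wins, both per column and at the final column.  This makes output
byte-reproducible and implicitly prefers fewer membrane segments: on a
fully uninformative (uniform) profile the decoder returns all-`i`.

**Complexity.**  With the default grammar the machine has ~100 states and
≤3 predecessors per state, so decoding is O(L) with small constants; a
700-residue protein decodes in milliseconds.

## Topology grammar

Defaults: at most one S run, starting at residue 1, length within
[5, 70], followed by `o` (the biology of cleaved signal peptides:
translocated N-terminus); `i` and `o` runs never adjacent; sides alternate
across each helix; minimum helix length 15 (a typical minimal
membrane-spanning helix), no maximum.  All of these are configurable
(`GrammarConfig`) because the underlying HMM conventions differ between
published predictors; whether the post-SP side should be forced to `o` or
left open is genuinely undecided in the field, so it is a parameter with
`o` as default.  Re-entrant/membrane-dipping regions are not representable
in the 4-letter alphabet; reference annotations containing them must be
collapsed by the caller before evaluation.

Raw per-method inputs are deliberately *not* required to be grammar-valid
(real predictors may emit anything); validity is enforced on consensus
output only, and asserted there.

## Insertion free-energy track

ΔG(c) = Σ<sub>j=0..W−1</sub> w<sub>j</sub> · g(seq[c−⌊W/2⌋+j]) for every
center with a full window; W = 21 by default, w ≡ 1.  The packaged scale
holds the position-independent per-residue contributions (kcal/mol) of the
biological, translocon-derived hydrophobicity scale; the full
position-dependent treatment is representable only through the optional
`positional_weights`.  Incomplete windows at the termini are not computed
rather than padded, so a track has max(0, L−W+1) values.  Ambiguity codes
(X/B/Z) contribute the mean of the 20 standard values with a logged
warning by default, or raise under the strict policy.  The packaged values
are data, not code constants, and any user scale in the same format can be
substituted; exact server ΔG reproduction is out of scope since scale
provenance is external.

## Benchmark criteria

A prediction is **correct** when (a) signal-peptide presence matches,
(b) the number of M segments matches, (c) each predicted helix overlaps
its in-order counterpart by ≥ `min_overlap` residues (default 5), and
(d) for membrane-containing references, the first and last membrane-side
labels (read past any SP and any helix) match — inverted topologies fail
here.  With equal helix counts, in-order one-to-one pairing is the natural
reading of "approximately correct locations" and is what is implemented.
For references without helices the orientation of a single soluble domain
is not meaningful and (d) is skipped, which reduces the criterion to the
standard proteome-scanning rules: globular proteins must receive neither
helices nor SP; secreted proteins exactly an SP.

Incorrect predictions fall into a taxonomy, evaluated in order: TM↔SP
cross-prediction when exactly one of reference/prediction has an S run and
the other has a helix starting within the N-terminal `sp_territory`
(default 70 residues, the maximum admitted SP length — the taxonomy needs
a positional rule to separate cross-prediction from generic helix-presence
errors, and SP territory is the principled cutoff); otherwise TM↔non-TM
when helix presence disagrees; otherwise SP↔non-TM when SP presence
disagrees; otherwise wrong topology (classes agree, topology does not).
The kinds are mutually exclusive and exhaustive by construction.
Aggregation reports per-class correct fractions, a 4×4 reference×predicted
class confusion matrix (row-normalized percentages, raw counts kept), and
error-kind counts per reference class.

## Synthetic data generator

The generator emulates the situation the consensus method is designed for:
a proteome-like mixture of protein classes (defaults TM 5%, SP+TM 11%,
SP-only 32%, globular 52%), grammar-valid truth topologies (1–7 helices of
15–30 residues, loops 5–60, SPs 10–40, globular chains 50–300), and five
noisy "methods" per protein.  Per-method noise applies, in fixed order:
SP↔N-terminal-helix swap (p=0.05), SP deletion (0.03) / spurious SP
(0.02), helix deletion (0.05 per helix), spurious helix insertion (0.02
per eligible loop), boundary jitter (±3 residues), and global i/o
inversion (0.02; skipped for SP-bearing proteins, whose post-SP side is
pinned by the grammar).  Every operation repairs side alternation and
restores grammar length minima afterwards, so predictions remain
grammar-valid and length-preserving; infeasible jitters fall back to the
original boundaries.  Membrane-helix (and SP) residues are drawn from a
hydrophobic-weighted composition and loops uniformly, so ΔG tracks dip
inside true helices and the track is statistically checkable.

What the ensemble does **not** emulate: the correlated, sequence-driven
biases of real predictors (errors here are independent across methods
given the truth), cleavage-site chemistry, re-entrant helices, and real
benchmark-set composition.  Consequently, passing the ensemble-recovery
test shows that grammar-constrained profile decoding corrects independent
method errors; it does not certify accuracy numbers on real proteomes,
which require the real external predictors and curated reference sets.

## Determinism and problem sizes

All randomness flows through explicit integer seeds
(`numpy.random.default_rng` seeded per protein and per method), so every
dataset, decode and report is bit-reproducible.  The shipped test suite
and acceptance script use: exhaustive decoder verification on 200 random
profiles up to length 10 under a reduced grammar (minimum helix 3, SP
2–6 — with the default minima no helix fits in an enumerable length, so
the reduced grammar is what actually exercises the helix states against
brute force); 100 proteins for unanimous-input recovery; 500 proteins ×
5 methods for the ensemble study; 100 random 60-mers for window-sum
verification.  These sizes make every claim checkable in seconds while
keeping the multinomial sampling error on ensemble rates at the
percent level.

## Known limitations

* The per-residue agreement track is a convenience reliability readout
  (fraction of methods matching the consensus label); it is not a
  calibrated posterior.
* Equal method weighting is the only supported scheme; confidence-weighted
  profiles would require per-method reliabilities the input format does
  not carry.
* The evaluation pairs helices strictly in order after requiring equal
  counts; it does not attempt optimal bipartite matching for unequal
  counts, because such predictions are already incorrect under the
  criterion.
* The ΔG module scores windows independently; it does not optimize helix
  placement or length against the track.
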