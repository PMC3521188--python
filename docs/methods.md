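# Methods

## Model

A base-specific cleavage experiment is idealised at the compomer level.  A
digest of sequence `s` at cut base `x` produces the maximal `x`-free
substrings of `s` ("cleavage fragments"); the measurement of one digest is
the *set* of fragment base compositions (compomers).  Peak intensities,
multiplicities, mass accuracy, adducts and the peak→composition decoding
step are all outside the model: a spectrum is a mathematical set of
compomers, so a composition occurring in several fragments appears once.

Fragment conventions, fixed once and used everywhere:

* An empty fragment arises only *between two adjacent* occurrences of the
  cut base.  A leading or trailing cut base contributes no empty fragment.
  (This convention is forced by the worked spectra: a sequence that begins
  and ends with A has no all-zero compomer in its A spectrum.)
* Empty fragments are always classified internal.  A fragment is
  *left-ended* if it touches position 1, *right-ended* if it touches the
  last position, *internal* otherwise.  A fragment spanning the whole host
  (cut base absent) is simultaneously left- and right-ended; the
  three-way classification is not exhaustive there, so the package exposes
  boolean end flags and a fourth `whole` class label.
* The empty sequence digests to an empty fragment list.
* Coordinates are 0-based half-open internally, 1-based inclusive in all
  user-facing reports.

Two reconstruction objectives are supported, both minimising Hamming
distance to the reference over same-length candidates (substitutions only):
containment of the candidate's spectra in the measurement (MSP) or coverage
of the measurement by the candidate's spectra (MSQ).

## The MSP dynamic program

For each cut base `x` and measured compomer `c ∈ C_x`, the candidate set
`I_x(c)` holds the arrangements of `c` that exclude `x`, contain every
other alphabet base, and whose internal fragments (for all cut bases) have
measured compomers.  `L_x`/`R_x` additionally require measured left-/right-
ended fragments.  Enumeration is by recursive multiset permutation with
incremental pruning: a prefix dies as soon as a completed internal fragment
leaves the measurement.  `|I_x(c)|` is bounded by the multinomial
coefficient of `c` (asserted), and the whole index is factorial in fragment
size in the worst case, so construction aborts with a diagnostic beyond a
configurable cap (default 10^6 strings).  Over a two-letter alphabet the
index is linear in `|s|` and the solver runs in polynomial time.

A feasible candidate containing every alphabet base must begin with a
fragment in some `L_x`, end with one in some `R_x`, and be I-compatible
throughout.  The DP value `H(i, t)` is the minimum distance between the
length-`i` reference prefix and such a string ending in fragment `t`.
Transitions split `x·t = p·q` at the *pivot* — the rightmost position
holding a first occurrence — so the predecessor fragment lies in `I_x′`
(`x′` the pivot base), carries `p` as a suffix, and the transition pays the
mismatch cost of `q` only; overlapping fragments are never double-counted.
Initial states are `H(|t|, t)` for `t ∈ L_x`.  The optimum is the best
`H(|s|, t)` over right-end-compatible `t`; the table stores, per state, the
cost together with the lexicographically smallest optimal prefix, which
doubles as backtracking state and makes tie-breaking deterministic
(smallest reconstruction, stable across runs).

**Candidates omitting a base.**  The recurrence only reaches strings
containing every alphabet base.  For each proper sub-alphabet the same DP
is re-run with candidates drawn from the active bases only; compatibility
is checked for active cut bases (an absent base induces no internal
fragments), and for every excluded base the whole candidate is its single
fragment, so its full composition must occur in that base's spectrum.
Because that constraint couples the global composition, the sub-alphabet
DP carries the prefix composition through its states (pruned against the
admissible target compositions, of which there are at most a handful) and
accepts only exact matches at the end.  Single-base candidates are checked
directly.  The global optimum is the best across all runs.  Exactness of
the combined search is validated against exhaustive enumeration on 200+
seeded random instances in the acceptance suite.

## MSQ: ball search and NP-hardness machinery

MSQ is NP-hard even over `{G, T}`, so the exact solver is a Hamming-ball
search: radii are scanned outward from the reference and all candidates at
a radius are tested for coverage feasibility, returning the smallest
feasible radius and its lexicographically smallest witness.  Two
composition bounds prune the scan: distinct compomers in `C_x` must be
realised by distinct disjoint fragments, so any feasible sequence carries
at least the summed non-cut counts of `C_x` for every other base and at
least `|C_x| − 1` copies of `x`; the substitutions needed to reach those
counts lower-bound the starting radius.  `max_radius` defaults to 4
(realistic assays expect very few SNPs per amplicon) and is overridable;
exhaustion is reported as a status, not an error.

The reduction from restricted 3-partition (distinct integers, each
strictly between `B/4` and `B/2`, summing to `mB`) is constructive in both
directions: the instance `s·T = (G^(B+2) T)^m`, `C_G = {G0T0, G0T1}`,
`C_T = {G^(a_i) T0}` has optimum exactly `2m` iff a valid partition
exists; `partition_to_solution` emits the optimal sequence for a partition
and `solution_to_partition` recovers a partition from any optimum by the
linear run-length scan, validating the triples against the source instance
rather than trusting loop bookkeeping.  A normalisation helper rescales
general distinct-integer instances into the size window (add `B` to every
element, multiply `B` by 4).  Integers are stored natively; the
unary-encoding argument behind *strong* NP-completeness is a property of
the reduction's size analysis, not of the code.

## Oracles

Brute-force reference solvers (full enumeration over all `|Σ|^|s|` strings,
and a ball-restricted variant) establish ground truth on small instances.
They share no code with the solvers — fragments are recomputed by an
independent character scan and feasibility comes straight from the
definitions — so a solver bug cannot agree with its own oracle.  Full
enumeration is capped at `4^9` candidates by default.

## Simulator

The generator emulates the assay at the compomer level only: a uniform
random reference, exactly `k` substitutions at uniformly chosen positions
(the regime the method targets is a handful of SNPs per amplicon; tests
use `k ≤ 2`), and the sample's in-silico spectra as the measurement.
Spurious peaks are modelled as uniformly sampled *realisable* compositions
(no cut base, weight bounded by the largest observed weight plus two,
widened only if that space is saturated); missing peaks as uniform
deletions.  Defaults of 0–2 added/dropped compomers per spectrum are
arbitrary, as no quantitative noise rates are established for the assay.
What passing tests show is therefore combinatorial correctness under an
idealised measurement — not robustness to mass-domain effects (calibration
error, adducts, intensity-dependent dropout), which the model does not
represent.

With unperturbed spectra the sample itself is feasible for both
objectives, so the solved distance never exceeds the injected count (the
*witness guarantee*, asserted in tests).  The solved distance can
genuinely undershoot it: short references underdetermine the sample, and a
feasible sequence closer to the reference often exists.  The recovery
report consequently distinguishes `frac_distance_bounded` (witness bound
holds; 1.0 without perturbation) from `frac_distance_recovered` (exact
equality) and `frac_calls_recovered` (exact call set).  Perturbations are
monotone, not neutral: added peaks can only keep or *lower* the MSP
optimum, dropped peaks can only keep or lower the MSQ optimum; both are
asserted as inequalities.

## Problem sizes and numerical choices

Randomised validation uses instances the exhaustive oracle can certify:
lengths 3–9 over two-letter alphabets and 3–7 over the four-letter
alphabet, 200+ instances in the acceptance suite, with and without
perturbation.  The polynomial two-letter claim is smoke-tested at length
60.  The NP-hardness no-instance `A = {12, 13, 14, 15, 16, 22}`, `m = 2`,
`B = 46` (no triple sums to 46) is the smallest found satisfying the strict
size window; its radius-`2m` ball (~3.5M candidates over a length-97
reference) is searched exhaustively to confirm infeasibility.  All
randomness flows through explicit integer seeds below 2^31; identical
seeds reproduce identical instances, reports and reconstructions.

## Known limitations

* No edit-distance variant: insertions/deletions are out of scope.
* No mass-domain modelling (see Simulator above); converting raw spectra
  to compomers is the instrument pipeline's job.
* MSP solving inherits the factorial worst case of the candidate index;
  the cap turns pathological inputs into diagnostics rather than results.
* MSQ solving is exponential in the search radius by nature of the
  problem; the solver is exact but intended for small radii or small
  instances.
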