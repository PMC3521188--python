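# cleavesnp

Exact combinatorial solvers for SNP discovery from **base-specific cleavage
and mass spectrometry**.

In this assay a target amplicon is transcribed in vitro and digested to
completion in four separate reactions, each cutting at every occurrence of
one base (e.g. RNase A cleavage of modified transcripts).  MALDI-TOF mass
spectrometry of each digest yields peaks that decode to *compomers* — the
base composition `AiCjGkTl` of each cut-base-free fragment.  The four
*compomer spectra* `C_Σ = {C_A, C_C, C_G, C_T}` jointly constrain the sample
sequence, and single-nucleotide differences from a known reference show up
as unanticipated compositions.  `cleavesnp` turns those constraints into
exact sequence reconstruction.

## The two reconstruction problems

Given a reference `s` and measured spectra `C_Σ`, find a same-length
sequence `s′` minimising the Hamming distance `d_H(s, s′)` subject to:

* **SNP-MSP** — `C_x(s′) ⊆ C_x` for every cut base `x`: every in-silico
  peak of the reconstruction must be measured.  Robust to spurious peaks,
  vulnerable to missing ones.  Solved **exactly by dynamic programming**
  over cleavage fragments: states are `(prefix length i, candidate fragment
  t)` with

  `H(i, t) = min over t′ ∈ I_x′ with suffix p of { H(i − |q|, t′) + d_H(s[i−|q|+1, i], q) }`

  where `x·t = p·q` is split at the rightmost first-occurrence position
  (the *pivot*), and `I_x` / `L_x` / `R_x` are the internal / left-end /
  right-end compatible arrangements of the measured compomers.  The optimum
  is `min H(|s|, t)` over `t ∈ R_x`.  Polynomial over two-letter alphabets;
  factorial in fragment size in the worst case (guarded by an index cap).

* **SNP-MSQ** — `C_x ⊆ C_x(s′)` for every `x`: every measured peak must be
  explained.  Robust to missing peaks, vulnerable to spurious ones — and
  **NP-hard even over a two-letter alphabet**, by reduction from restricted
  3-partition.  Solved exactly at small scale by Hamming-ball search with
  composition pruning; the full reduction machinery (instance construction,
  partition ↔ optimal-solution conversion at distance `2m`) is included.

The SNP calls are the mismatches between `s` and the reconstruction,
reported 1-based as TSV or minimal VCF 4.2.

Every solver is validated against brute-force oracles (independent code
paths) on hundreds of seeded random instances, and a compomer-level
simulator generates test instances with controllable SNP counts, spurious
peaks and peak dropout.

## Worked example

The two-letter instance `s = ATAAT` with measured spectra
`C_A = {A0T1, A0T2}`, `C_T = {A0T0, A1T0}`:

```sh
$ cat instance.json
{
  "alphabet": "AT",
  "reference": "ATAAT",
  "spectra": {"A": ["A0T1", "A0T2"], "T": ["A0T0", "A1T0"]}
}
$ cleavesnp solve-msp --instance instance.json --out snps.tsv --emit-sequence
distance	1
sequence	ATATT
$ cat snps.tsv
POS	REF	ALT
4	A	T
```

The reference itself is infeasible (its digest at A contains the empty
fragment `A0T0`, which was not measured), and one substitution suffices:
`ATATT` — position 4, `A→T` (`ATTAT` is co-optimal; ties break to the
lexicographically smallest sequence).  The coverage-style formulation
agrees here:

```sh
$ cleavesnp solve-msq --instance instance.json --emit-sequence
distance	1
sequence	ATATT
```

Digesting a sequence directly:

```sh
$ cleavesnp spectra --seq ACATGCTACATTA --cut A
A0C0G0T2
A0C1G0T0
A0C1G1T2
```

Simulating an instance and encoding a 3-partition instance:

```sh
$ cleavesnp --seed 7 simulate --length 12 --snps 2 --out sim.json --truth truth.tsv
wrote instance with 2 injected SNPs to sim.json
$ cleavesnp reduce-3part --set 4,5,6 --m 1 --b 15 --out reduced.json
wrote reduced instance (|s| = 17, optimum 2m = 2 iff partition exists) to reduced.json
```

Exit codes: 0 solved, 1 infeasible instance, 2 usage/validation error.

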