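"""Synthetic-instance generation at the compomer level.

The wet-lab pipeline -- PCR with T7-promoter-tagged primers, in-vitro
transcription, four complete RNase A base-specific digests, MALDI-TOF of
each digest, and decoding of peaks to base compositions -- is emulated here
as a single idealisation: the measured spectra of a sample sequence are its
in-silico compomer spectra.  On top of that, two perturbation regimes model
the two real failure modes that motivate the MSP/MSQ split:

* *spurious compomers* (noise peaks): extra plausible compositions are added
  to a spectrum.  MSP (containment in the measurement) is immune; MSQ may
  become infeasible.
* *dropped compomers* (missing peaks): true compositions are removed.  MSQ
  is immune while a feasible witness survives; MSP may lose the true
  solution.

Mass-domain effects (m/z error, adducts, intensities) are out of scope.
All randomness flows through explicit integer seeds, so every run is
replayable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    Alphabet,
    Compomer,
    DNA,
    ProblemInstance,
    SpectraCollection,
    ValidationError,
    spectra_of,
)
from .msp import SnpCall, call_snps, dp_solve
from .msq import solve_msq

_SEED_SPACE = 2**31


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic instance.

    ``snps`` reference/sample substitutions are injected; ``add_noise`` and
    ``drop`` spurious/removed compomers are applied per spectrum.  The seed
    is mandatory: identical configs reproduce identical instances.
    """

    length: int
    snps: int
    seed: int
    add_noise: int = 0
    drop: int = 0
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValidationError("length must be non-negative")
        if not 0 <= self.snps <= self.length:
            raise ValidationError(f"snps must be between 0 and the length ({self.length})")
        if self.add_noise < 0 or self.drop < 0:
            raise ValidationError("noise counts must be non-negative")


def random_sequence(n: int, alphabet: Alphabet = DNA, seed: int = 0) -> str:
    """Uniform i.i.d. sequence of length *n*; deterministic in *seed*."""
    if n < 0:
        raise ValidationError("length must be non-negative")
    rng = random.Random(seed)
    return "".join(rng.choice(alphabet.bases) for _ in range(n))


def inject_snps(
    s: str, k: int, seed: int = 0, alphabet: Alphabet = DNA
) -> tuple[str, list[SnpCall]]:
    """Substitute exactly *k* positions, each to a uniformly chosen other base.

    Returns the mutated sequence and the ground-truth call list (1-based).
    """
    if k > len(s):
        raise ValidationError(f"cannot inject {k} substitutions into a length-{len(s)} sequence")
    rng = random.Random(seed)
    positions = sorted(rng.sample(range(len(s)), k))
    chars = list(s)
    truth = []
    for p in positions:
        alt = rng.choice([b for b in alphabet.bases if b != s[p]])
        chars[p] = alt
        truth.append(SnpCall(p + 1, s[p], alt))
    return "".join(chars), truth


def make_instance(s_ref: str, s_sample: str, alphabet: Alphabet = DNA) -> ProblemInstance:
    """Idealised measurement: the instance pairing *s_ref* with the sample's spectra.

    By construction the sample is feasible for both problem variants, so the
    optimum of either is at most the injected substitution count.
    """
    if len(s_ref) != len(s_sample):
        raise ValidationError("reference and sample must have equal length")
    return ProblemInstance(alphabet, s_ref, spectra_of(s_sample, alphabet))


def _random_compomer(
    rng: random.Random, x: str, alphabet: Alphabet, max_weight: int
) -> Compomer:
    """A random realisable composition for cut base *x*: no cut base, bounded weight."""
    others = [b for b in alphabet.bases if b != x]
    w = rng.randint(0, max_weight)
    counts = [0] * len(alphabet)
    for _ in range(w):
        counts[alphabet.index(rng.choice(others))] += 1
    return Compomer(alphabet, tuple(counts))


def perturb_spectra(
    C: SpectraCollection, add_n: int, drop_n: int, seed: int = 0
) -> SpectraCollection:
    """Add spurious and remove true compomers, per spectrum.

    Added compomers are plausible decodes: they exclude the cut base and
    their weight is bounded by the largest observed weight plus two.  Drops
    are sampled uniformly from the existing compomers; *drop_n* may not
    exceed any spectrum's size.
    """
    rng = random.Random(seed)
    alphabet = C.alphabet
    out = C
    for x in alphabet.bases:
        comps = set(C[x])
        if drop_n > len(comps):
            raise ValidationError(
                f"cannot drop {drop_n} compomers from the {x} spectrum of size {len(comps)}"
            )
        max_w = max((c.weight for c in comps), default=2) + 2
        for victim in rng.sample(sorted(comps, key=str), drop_n):
            comps.remove(victim)
        added = 0
        misses = 0
        while added < add_n:
            cand = _random_compomer(rng, x, alphabet, max_w)
            if cand in comps:
                # Small alphabets have few realisable compositions per
                # weight; widen the bound once the space looks saturated.
                misses += 1
                if misses >= 50:
                    max_w += 1
                    misses = 0
                continue
            comps.add(cand)
            added += 1
        out = out.replace(x, comps)
    return out


def simulate_instance(config: SimulationConfig) -> tuple[ProblemInstance, list[SnpCall]]:
    """Generate one reference/sample instance per the config; returns truth calls."""
    rng = random.Random(config.seed)
    s_ref = random_sequence(config.length, config.alphabet, rng.randrange(_SEED_SPACE))
    s_sample, truth = inject_snps(s_ref, config.snps, rng.randrange(_SEED_SPACE), config.alphabet)
    instance = make_instance(s_ref, s_sample, config.alphabet)
    if config.add_noise or config.drop:
        spectra = perturb_spectra(
            instance.spectra, config.add_noise, config.drop, rng.randrange(_SEED_SPACE)
        )
        instance = ProblemInstance(config.alphabet, s_ref, spectra)
    return instance, truth


def recovery_experiment(
    lengths: Sequence[int],
    snp_counts: Sequence[int],
    add_noise: Sequence[int] = (0,),
    drop: Sequence[int] = (0,),
    problems: Iterable[str] = ("msp", "msq"),
    trials: int = 20,
    seed: int = 0,
    alphabet: Alphabet = DNA,
) -> pd.DataFrame:
    """Recovery rates of the solvers over a perturbation grid.

    For every grid cell, *trials* seeded instances are generated and solved.
    The report records three fractions: trials whose solved distance stays
    within the injected substitution count (the witness guarantee -- with
    unperturbed spectra the sample itself is feasible, so the optimum can
    never exceed it), trials whose solved distance equals the injected count
    exactly, and trials whose call set matches the ground truth exactly.
    Exact recovery can fail even without perturbation: short references
    underdetermine the sample and a feasible sequence closer to the
    reference may exist.  Cell seeds are embedded in the table for replay.
    """
    rng = random.Random(seed)
    rows = []
    for problem in problems:
        for n in lengths:
            for k in snp_counts:
                for a in add_noise:
                    for d in drop:
                        cell_seed = rng.randrange(_SEED_SPACE)
                        cell_rng = random.Random(cell_seed)
                        dist_bounded = dist_ok = calls_ok = 0
                        for _ in range(trials):
                            cfg = SimulationConfig(
                                length=n,
                                snps=k,
                                seed=cell_rng.randrange(_SEED_SPACE),
                                add_noise=a,
                                drop=d,
                                alphabet=alphabet,
                            )
                            instance, truth = simulate_instance(cfg)
                            if problem == "msp":
                                sol = dp_solve(instance.reference, instance.spectra)
                            else:
                                sol = solve_msq(
                                    instance.reference, instance.spectra, max_radius=k + a + 1
                                )
                            if sol.feasible and sol.distance <= k:
                                dist_bounded += 1
                            if sol.feasible and sol.distance == k:
                                dist_ok += 1
                                if sol.snps == truth:
                                    calls_ok += 1
                        rows.append(
                            {
                                "problem": problem,
                                "length": n,
                                "snps": k,
                                "add_noise": a,
                                "drop": d,
                                "trials": trials,
                                "seed": cell_seed,
                                "frac_distance_bounded": dist_bounded / trials,
                                "frac_distance_recovered": dist_ok / trials,
                                "frac_calls_recovered": calls_ok / trials,
                            }
                        )
    return pd.DataFrame(rows)
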