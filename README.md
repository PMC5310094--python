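# spacedseeds

Model-free selection and parameter-free sensitivity calculation of spaced
seeds for DNA sequence comparison.

## The problem

Seed-and-extend alignment tools (BLAST-like search, read mapping,
alignment-free classifiers) anchor comparisons on short patterns.  A *spaced
seed* π is a binary pattern such as `1101` in which `1` marks a position that
must match and `0` a position that may mismatch; it *hits* a gapless
alignment — encoded as a match/mismatch string x over {1, 0} — at position i
when every must-match position faces a `1`.  Which seed of a given weight w
(number of `1`s, the selectivity) is best depends on how alignments are
modelled, and every classical criterion fixes a nuisance parameter first:
the Bernoulli match probability p, an identity interval [p_a, p_b], a match
count m, or a mismatch budget k.

This package implements a two-stage, parameter-free alternative.  The
central object is the **coefficient vector**

    c(π, m) = #{ x ∈ {0,1}^ℓ : |x|₁ = m and π hits x },   m = 0 … ℓ,

computed exactly by a counting-semiring dynamic program over the
*at-least-one-hit* DFA of the seed set (lazily intersected with the linear
match-counting automaton).  Every common sensitivity measure is a positively
weighted functional of c(π, ·):

* **Bernoulli** — Pr_π(p, ℓ) = Σ_m c(π,m) p^m (1−p)^(ℓ−m);
* **Hit Integration** — (∫_{p_a}^{p_b} Pr_π(p, ℓ) dp) / (p_b − p_a), with a
  seed-independent closed form for each monomial integral;
* **Dirac** — c(π,m) / C(ℓ,m);
* **Heaviside** — the mean of Dirac over a match-count window [m_a, m_b];

so if c(π_a, m) ≥ c(π_b, m) for all m (with one strict inequality), π_a
**dominates** π_b and π_b is never optimal under any of the four models.
Stage 1 filters a candidate class down to its dominant antichain without
touching any parameter.  Stage 2 extracts, per model, the Pareto-optimal
seeds *as a function of the free parameter*: sign analysis of exact rational
difference polynomials (Sturm-based root isolation) for the continuous
models, exact rational argmax for the discrete ones, with the lossless
border — the smallest m with c(π, m′) = C(ℓ, m′) for all m′ ≥ m — annotated.
Losslessness is also decided independently by a tropical (min, +) DP which
returns an undetected witness alignment on failure.  For the asymptotic
regime the package computes λ (Perron eigenvalue of the hit DFA's
sub-stochastic matrix after final-state removal) and the prefactor β with
no-hit(ℓ) ≈ β λ^ℓ.

## Worked example

```python
>>> from fractions import Fraction
>>> import spacedseeds as sp
>>> sp.hit_positions(sp.Seed("1101"), "111010101111")
{9, 2}
>>> vec = sp.count_coefficients("1101", 4)
>>> vec.coefficients
(0, 0, 0, 1, 1)
>>> sp.bernoulli_sensitivity(vec, Fraction(7, 10))
Fraction(343, 1000)
>>> sp.lossless_tropical("1101", 5, 1)
(False, '10111')
>>> sp.lossless_tropical("1101", 6, 1)
(True, None)
```

The seed `1101` hits the example alignment twice (positions 2 and 9).  At
ℓ = 4 only the two alignments `1101` and `1111` are detected, giving the
exact hit probability 343/1000 = 0.343 at p = 0.7.  The seed misses the
single-mismatch alignment `10111` at ℓ = 5 but detects every alignment with
at most one mismatch from ℓ = 6 on, i.e. it is (6, 1)-lossless.

The same computations are available from the shell:

```sh
spacedseeds sensitivity --seed 1101 --length 4 --model bernoulli --p 7/10
spacedseeds lossless --seed 1101 --length 5 --k 1
spacedseeds design --weight 3 --max-span 6 --lengths 10:10 --models bernoulli,dirac
spacedseeds asym --seed 111010010100110111 --p 0.7
```

All JSON output serializes exact values as `"numerator/denominator"`
strings; floats appear only in explicitly float-valued fields.

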