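"""Candidate generation and the end-to-end two-stage selection pipeline.

Small classes (single seeds of moderate weight) are enumerated exhaustively;
large weights or multiple co-designed seeds use a seeded hill climb whose
local optima are *locally dominant* — not dominated by any single-edit
neighbour.  The final selection never depends on the search pivot: the
dominant filter and the Pareto extraction stay parameter-free.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass
from fractions import Fraction
from typing import Sequence

from .counting import CoefficientVector, count_coefficients
from .dominance import DominantClass, DominanceVerdict, compare, dominant_filter
from .models import bernoulli_sensitivity
from .pareto import (
    CONTINUOUS_MODELS,
    DISCRETE_MODELS,
    ContinuousParetoResult,
    DiscreteParetoResult,
    pareto_continuous,
    pareto_discrete,
)
from .seedcore import Seed, SeedSet

__all__ = ["SearchSpec", "enumerate_seeds", "hill_climb", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class SearchSpec:
    """What to search: n seeds per set, weight, span cap, lengths, and mode."""

    n: int = 1
    weight: int = 3
    max_span: int | None = None           # default 2 * weight
    lengths: tuple[int, ...] = ()         # default (2 * weight .. 64)
    mode: str = "exhaustive"              # or "hillclimb"
    rng_seed: int = 0
    restarts: int = 32
    max_steps: int = 1000

    def __post_init__(self) -> None:
        if self.weight < 1 or self.n < 1:
            raise ValueError("need weight >= 1 and n >= 1")
        if self.mode not in ("exhaustive", "hillclimb"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_span is not None and self.max_span < self.weight:
            raise ValueError("max_span must be >= weight")

    @property
    def span_cap(self) -> int:
        return self.max_span if self.max_span is not None else 2 * self.weight

    @property
    def length_range(self) -> tuple[int, ...]:
        return self.lengths or tuple(range(2 * self.weight, 65))


def enumerate_seeds(weight: int, max_span: int) -> list[Seed]:
    """All canonical seeds of the given weight and span in [weight..max_span].

    Canonical seeds start and end with '1', so for w >= 2 the count is
    sum over s of C(s-2, w-2); generated in (span, lexicographic) order.
    """
    if weight < 1:
        raise ValueError("weight must be >= 1")
    if max_span < weight:
        raise ValueError("max_span must be >= weight")
    out: list[Seed] = []
    if weight == 1:
        return [Seed("1")]
    from itertools import combinations

    for span in range(weight, max_span + 1):
        # choose positions of the w-2 interior must-match symbols
        patterns = []
        for interior in combinations(range(1, span - 1), weight - 2):
            pat = ["0"] * span
            pat[0] = pat[-1] = "1"
            for i in interior:
                pat[i] = "1"
            patterns.append("".join(pat))
        out.extend(Seed(p) for p in sorted(patterns))
    return out


def _neighbours(seedset: SeedSet, weight: int, max_span: int) -> list[SeedSet]:
    """Single-edit moves: swap one '1' with one '0' inside one member seed,
    or grow/shrink that seed's span within bounds (weight preserved)."""
    out = []
    seeds = list(seedset.seeds)
    for idx, seed in enumerate(seeds):
        pat = seed.pattern
        ones = [i for i, c in enumerate(pat) if c == "1"]
        zeros = [i for i, c in enumerate(pat) if c == "0"]
        variants: set[str] = set()
        for i in ones:
            for j in zeros:
                q = list(pat)
                q[i], q[j] = "0", "1"
                cand = "".join(q).strip("0")
                if cand and cand.count("1") == weight:
                    variants.add(cand)
        # grow: insert a don't-care between two symbols
        if len(pat) < max_span:
            for j in range(1, len(pat)):
                variants.add(pat[:j] + "0" + pat[j:])
        # shrink: delete one don't-care
        for j in zeros:
            variants.add(pat[:j] + pat[j + 1 :])
        for cand in variants:
            if not cand or cand[0] != "1" or cand[-1] != "1":
                continue
            if not (weight <= len(cand) <= max_span):
                continue
            try:
                new_seed = Seed(cand)
            except ValueError:
                continue
            if new_seed.weight != weight:
                continue
            new_seeds = seeds[:idx] + [new_seed] + seeds[idx + 1 :]
            if len({s.pattern for s in new_seeds}) != len(new_seeds):
                continue
            out.append(SeedSet(tuple(new_seeds)).canonical())
    # de-duplicate, preserve deterministic order
    seen: set[str] = set()
    uniq = []
    for ss in out:
        key = str(ss)
        if key not in seen:
            seen.add(key)
            uniq.append(ss)
    return uniq


def _random_seed(rng: random.Random, weight: int, max_span: int) -> Seed:
    span = rng.randint(weight, max_span)
    if weight == 1:
        return Seed("1")
    interior = rng.sample(range(1, span - 1), weight - 2) if weight > 2 else []
    pat = ["0"] * span
    pat[0] = pat[-1] = "1"
    for i in interior:
        pat[i] = "1"
    return Seed("".join(pat))


def hill_climb(
    spec: SearchSpec, length: int, pivot_p: Fraction = Fraction(1, 2)
) -> list[tuple[SeedSet, CoefficientVector]]:
    """Randomized local search for locally dominant seed sets.

    A move is accepted iff the new coefficient vector dominates the current
    one, or is incomparable with a strictly larger Bernoulli value at the
    pivot probability (search guidance only — the pivot never enters the
    final, parameter-free selection).  Returned local optima are not
    dominated by any single-edit neighbour.  Fully reproducible per rng_seed.
    """
    rng = random.Random(spec.rng_seed)
    w, cap = spec.weight, spec.span_cap
    found: dict[str, tuple[SeedSet, CoefficientVector]] = {}
    for _ in range(spec.restarts):
        while True:
            seeds = [_random_seed(rng, w, cap) for _ in range(spec.n)]
            if len({s.pattern for s in seeds}) == spec.n:
                break
        current = SeedSet(tuple(seeds)).canonical()
        cur_vec = count_coefficients(current, length)
        cur_val = bernoulli_sensitivity(cur_vec, pivot_p)
        for _ in range(spec.max_steps):
            improved = False
            for cand in _neighbours(current, w, cap):
                vec = count_coefficients(cand, length)
                verdict = compare(vec, cur_vec)
                if verdict is DominanceVerdict.A_DOMINATES_B:
                    accept = True
                elif verdict is DominanceVerdict.INCOMPARABLE:
                    accept = bernoulli_sensitivity(vec, pivot_p) > cur_val
                else:
                    accept = False
                if accept:
                    current, cur_vec = cand, vec
                    cur_val = bernoulli_sensitivity(vec, pivot_p)
                    improved = True
                    break
            if not improved:
                break
        found.setdefault(str(current), (current, cur_vec))
    return [found[k] for k in sorted(found)]


@dataclass(frozen=True)
class PipelineResult:
    """Dominant classes and Pareto envelopes, per alignment length."""

    spec: SearchSpec
    dominant: dict[int, list[DominantClass]]
    pareto: dict[int, dict[str, ContinuousParetoResult | DiscreteParetoResult]]

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "lengths": sorted(self.dominant),
            "models": sorted({m for per_l in self.pareto.values() for m in per_l}),
            "dominant_sizes": {
                l: {
                    "classes": len(cls),
                    "seeds": sum(len(c.members) for c in cls),
                }
                for l, cls in self.dominant.items()
            },
        }


def run_pipeline(
    spec: SearchSpec, models: Sequence[str] = (), lengths: Sequence[int] | None = None
) -> PipelineResult:
    """Stage 1 (candidates -> coefficient vectors -> dominant filter) then
    stage 2 (parameter-free Pareto extraction per requested model)."""
    lens = tuple(lengths) if lengths is not None else spec.length_range
    for m in models:
        if m not in CONTINUOUS_MODELS + DISCRETE_MODELS:
            raise ValueError(f"unknown model {m!r}")
    dominant: dict[int, list[DominantClass]] = {}
    pareto: dict[int, dict] = {}
    for l in lens:
        if spec.mode == "exhaustive":
            if spec.n != 1:
                raise ValueError("exhaustive mode supports single seeds only")
            cands = [
                (SeedSet((s,)), count_coefficients(s, l))
                for s in enumerate_seeds(spec.weight, spec.span_cap)
                if s.span <= l
            ]
        else:
            cands = hill_climb(spec, l)
        classes = dominant_filter(cands)
        dominant[l] = classes
        reps = [(c.representative, c.vector) for c in classes]
        per_model: dict[str, ContinuousParetoResult | DiscreteParetoResult] = {}
        for m in models:
            if m in CONTINUOUS_MODELS:
                per_model[m] = pareto_continuous(reps, m)
            else:
                per_model[m] = pareto_discrete(reps, m)
        pareto[l] = per_model
    return PipelineResult(spec, dominant, pareto)
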