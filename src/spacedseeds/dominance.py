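"""Dominance partial order between seeds and the dominant-set filter.

Seed A *dominates* seed B (at fixed alignment length l) when
c_A[m] >= c_B[m] for every match count m, with at least one strict
inequality.  Because every sensitivity model here is a positively weighted
combination of the c[m], a dominated seed can never be optimal under any of
them — so filtering to the dominant antichain is a model-free first stage
that shrinks the candidate set before any parameter is chosen.

Seeds with *identical* vectors are strictly equivalent under all four models;
they are kept together as an equivalence class, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .counting import CoefficientVector
from .seedcore import SeedSet

__all__ = ["DominanceVerdict", "compare", "compare_joint", "dominant_filter", "DominantClass"]


class DominanceVerdict(Enum):
    A_DOMINATES_B = "a_dominates_b"
    B_DOMINATES_A = "b_dominates_a"
    EQUIVALENT = "equivalent"
    INCOMPARABLE = "incomparable"


def compare(vec_a: CoefficientVector, vec_b: CoefficientVector) -> DominanceVerdict:
    """Componentwise comparison of two coefficient vectors at the same length."""
    if vec_a.length != vec_b.length:
        raise ValueError(f"length mismatch: {vec_a.length} vs {vec_b.length}")
    a_ge = True
    b_ge = True
    for ca, cb in zip(vec_a.coefficients, vec_b.coefficients):
        if ca < cb:
            a_ge = False
        elif ca > cb:
            b_ge = False
        if not a_ge and not b_ge:
            return DominanceVerdict.INCOMPARABLE
    if a_ge and b_ge:
        return DominanceVerdict.EQUIVALENT
    return DominanceVerdict.A_DOMINATES_B if a_ge else DominanceVerdict.B_DOMINATES_A


def compare_joint(
    vecs_a: Sequence[CoefficientVector], vecs_b: Sequence[CoefficientVector]
) -> DominanceVerdict:
    """Dominance required simultaneously over a range of alignment lengths.

    A dominates B jointly when A's vector dominates-or-equals B's at every
    length, with strict dominance at at least one.
    """
    if len(vecs_a) != len(vecs_b):
        raise ValueError("need the same lengths on both sides")
    a_ge = b_ge = True
    for va, vb in zip(vecs_a, vecs_b):
        v = compare(va, vb)
        if v is DominanceVerdict.A_DOMINATES_B:
            b_ge = False
        elif v is DominanceVerdict.B_DOMINATES_A:
            a_ge = False
        elif v is DominanceVerdict.INCOMPARABLE:
            a_ge = b_ge = False
        if not a_ge and not b_ge:
            return DominanceVerdict.INCOMPARABLE
    if a_ge and b_ge:
        return DominanceVerdict.EQUIVALENT
    return DominanceVerdict.A_DOMINATES_B if a_ge else DominanceVerdict.B_DOMINATES_A


@dataclass(frozen=True)
class DominantClass:
    """One equivalence class of the dominant set: all members share a vector."""

    members: tuple[SeedSet, ...]
    vector: CoefficientVector

    @property
    def representative(self) -> SeedSet:
        return self.members[0]


def dominant_filter(
    candidates: Sequence[tuple[SeedSet, CoefficientVector]],
) -> list[DominantClass]:
    """Keep every candidate not dominated by any other (the dominant antichain).

    Candidates with identical vectors are grouped into one class with every
    member retained.  Pairwise O(n^2 * l) with early exit; candidate sets in
    practice stay in the low thousands.
    """
    if not candidates:
        return []
    lengths = {vec.length for _, vec in candidates}
    if len(lengths) != 1:
        raise ValueError(f"mixed alignment lengths in candidate list: {sorted(lengths)}")
    # group strict equivalents first (identical vectors), then compare classes
    groups: dict[tuple[int, ...], list[SeedSet]] = {}
    vecs: dict[tuple[int, ...], CoefficientVector] = {}
    for ss, vec in candidates:
        key = vec.coefficients
        groups.setdefault(key, []).append(ss)
        vecs.setdefault(key, vec)
    keys = list(groups)
    dominated = [False] * len(keys)
    for i in range(len(keys)):
        if dominated[i]:
            continue
        for j in range(len(keys)):
            if i == j:
                continue
            v = compare(vecs[keys[j]], vecs[keys[i]])
            if v is DominanceVerdict.A_DOMINATES_B:
                dominated[i] = True
                break
    return [
        DominantClass(tuple(groups[keys[i]]), vecs[keys[i]])
        for i in range(len(keys))
        if not dominated[i]
    ]
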