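"""Spaced seeds, binary alignments and hit semantics.

A spaced seed is a pattern over ``{1, 0}`` where ``1`` marks a *must-match*
position and ``0`` a *don't-care* position.  A gapless alignment is encoded as
a binary string with ``1`` for a match and ``0`` for a mismatch.  The seed
*hits* the alignment at (1-based) position ``i`` when every must-match symbol
of the seed faces a ``1`` in the alignment window starting at ``i``.

Seeds are kept in canonical form: the pattern must begin and end with ``1``,
since shifted variants have identical hit sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SeedError",
    "EmptySeedError",
    "InvalidSymbolError",
    "NonCanonicalSeedError",
    "Seed",
    "SeedSet",
    "Alignment",
    "parse_seed",
    "parse_seed_set",
    "hit_positions",
    "hits",
    "read_seed_file",
    "write_seed_file",
]


class SeedError(ValueError):
    """Base class for seed parsing/validation errors."""


class EmptySeedError(SeedError):
    """Raised for an empty seed pattern."""


class InvalidSymbolError(SeedError):
    """Raised when a pattern contains symbols other than '0'/'1'."""


class NonCanonicalSeedError(SeedError):
    """Raised when a pattern has a leading or trailing don't-care symbol."""


@dataclass(frozen=True, order=True)
class Seed:
    """A spaced seed in canonical form (starts and ends with '1')."""

    pattern: str

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise EmptySeedError("seed pattern is empty")
        if set(p) - {"0", "1"}:
            raise InvalidSymbolError(f"seed pattern {p!r} contains symbols outside {{0,1}}")
        if p[0] != "1" or p[-1] != "1":
            raise NonCanonicalSeedError(
                f"seed pattern {p!r} is non-canonical (must start and end with '1')"
            )

    @property
    def weight(self) -> int:
        """Number of must-match symbols (selectivity)."""
        return self.pattern.count("1")

    @property
    def span(self) -> int:
        """Total pattern length, don't-cares included."""
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern


@dataclass(frozen=True)
class SeedSet:
    """An ordered set of distinct spaced seeds, used jointly (any-seed hit)."""

    seeds: tuple[Seed, ...]

    def __post_init__(self) -> None:
        if not self.seeds:
            raise SeedError("a seed set needs at least one seed")
        patterns = [s.pattern for s in self.seeds]
        if len(set(patterns)) != len(patterns):
            raise SeedError(f"duplicate seed pattern in set: {patterns}")

    @classmethod
    def of(cls, *patterns: str | Seed) -> "SeedSet":
        return cls(tuple(p if isinstance(p, Seed) else Seed(p) for p in patterns))

    @property
    def n(self) -> int:
        return len(self.seeds)

    @property
    def max_span(self) -> int:
        return max(s.span for s in self.seeds)

    @property
    def min_weight(self) -> int:
        return min(s.weight for s in self.seeds)

    def canonical(self) -> "SeedSet":
        """Member order normalized (sorted patterns); used to de-duplicate sets."""
        return SeedSet(tuple(sorted(self.seeds, key=lambda s: (s.span, s.pattern))))

    def __iter__(self) -> Iterator[Seed]:
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    def __str__(self) -> str:
        return ",".join(s.pattern for s in self.seeds)


@dataclass(frozen=True)
class Alignment:
    """A gapless alignment as a match (1) / mismatch (0) string."""

    symbols: str

    def __post_init__(self) -> None:
        if set(self.symbols) - {"0", "1"}:
            raise ValueError(f"alignment {self.symbols!r} contains symbols outside {{0,1}}")

    @property
    def length(self) -> int:
        return len(self.symbols)

    @property
    def matches(self) -> int:
        """Number of match symbols m = |x|_1."""
        return self.symbols.count("1")

    def __str__(self) -> str:
        return self.symbols


def parse_seed(text: str) -> Seed:
    """Parse one canonical seed pattern; raises a typed :class:`SeedError`."""
    return Seed(text.strip())


def parse_seed_set(text: str) -> SeedSet:
    """Parse a comma-separated seed set, e.g. ``"1101,111"``."""
    parts = [t for t in (s.strip() for s in text.split(",")) if t]
    if not parts:
        raise SeedError(f"no seed patterns in {text!r}")
    return SeedSet.of(*parts)


def hit_positions(seed: Seed, alignment: Alignment | str) -> set[int]:
    """1-based positions where the seed hits the alignment.

    Position ``i`` is a hit iff every must-match symbol of the seed faces a
    '1' in ``alignment[i .. i+span-1]``.  Empty when span exceeds the length.
    """
    x = alignment.symbols if isinstance(alignment, Alignment) else alignment
    s, pat = seed.span, seed.pattern
    must = [j for j in range(s) if pat[j] == "1"]
    return {
        i + 1
        for i in range(len(x) - s + 1)
        if all(x[i + j] == "1" for j in must)
    }


def hits(seedset: SeedSet | Seed, alignment: Alignment | str) -> bool:
    """True iff at least one seed of the set hits the alignment at least once."""
    if isinstance(seedset, Seed):
        seedset = SeedSet((seedset,))
    return any(hit_positions(seed, alignment) for seed in seedset)


def read_seed_file(path: str | Path) -> list[SeedSet]:
    """Read a plain-text seed file: one seed set per line, comma-separated
    patterns, ``#`` starts a comment, blank lines ignored."""
    sets: list[SeedSet] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sets.append(parse_seed_set(line))
    return sets


def write_seed_file(path: str | Path, seedsets: Iterable[SeedSet], header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(str(ss) for ss in seedsets)
    Path(path).write_text("\n".join(lines) + "\n")
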