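"""Deterministic automata for the at-least-one-hit language of a seed set.

The hit DFA is built by a subset construction over *compatible seed-prefix
lengths*: a state records, for every seed of the set, which prefix lengths of
that seed are compatible with the suffix of the input read so far (a prefix of
length ``l`` is compatible when each of its must-match symbols faced a '1').
Completing any seed's full span leads to a single absorbing final state —
once hit, always hit.  For a single seed of weight ``w`` and span ``s`` the
reachable state count is O(w * 2**(s-w)).

The intersection product with the linear match-counting automaton (states
0..l matches) is built lazily, breadth-first, so that only pairs reachable
within ``l`` input symbols are ever materialized.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

from .seedcore import SeedSet, Seed

__all__ = ["HitAutomaton", "ProductAutomaton", "build_hit_dfa", "minimize", "build_product"]


@dataclass(frozen=True)
class HitAutomaton:
    """Complete DFA over {0,1}; states are 0..n-1, state 0 is initial.

    ``delta[q]`` is the pair ``(next on '0', next on '1')``; ``finals`` is the
    set of accepting states (absorbing, by construction).
    """

    delta: tuple[tuple[int, int], ...]
    finals: frozenset[int]
    initial: int = 0

    @property
    def n_states(self) -> int:
        return len(self.delta)

    def step(self, state: int, symbol: str) -> int:
        return self.delta[state][1 if symbol == "1" else 0]

    def accepts(self, word: str) -> bool:
        q = self.initial
        for b in word:
            q = self.delta[q][1 if b == "1" else 0]
        return q in self.finals

    def to_tsv(self) -> str:
        """Dump transitions as TSV (state, symbol, next_state, is_final, is_initial)."""
        rows = ["state\tsymbol\tnext_state\tis_final\tis_initial"]
        for q, (n0, n1) in enumerate(self.delta):
            for sym, nxt in (("0", n0), ("1", n1)):
                rows.append(
                    f"{q}\t{sym}\t{nxt}\t{int(q in self.finals)}\t{int(q == self.initial)}"
                )
        return "\n".join(rows) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph hit_dfa {", "  rankdir=LR;"]
        for q in range(self.n_states):
            shape = "doublecircle" if q in self.finals else "circle"
            lines.append(f'  {q} [shape={shape}];')
        for q, (n0, n1) in enumerate(self.delta):
            lines.append(f'  {q} -> {n0} [label="0"];')
            lines.append(f'  {q} -> {n1} [label="1"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_hit_dfa(seedset: SeedSet | Seed | str) -> HitAutomaton:
    """DFA accepting exactly the binary strings hit by at least one seed."""
    if isinstance(seedset, str):
        seedset = SeedSet.of(seedset)
    elif isinstance(seedset, Seed):
        seedset = SeedSet((seedset,))

    patterns = [s.pattern for s in seedset]
    spans = [len(p) for p in patterns]

    # State = frozenset of (seed index, active prefix length), 1 <= len < span.
    # Prefix length 0 is implicitly always active (a hit can start anywhere).
    start: frozenset[tuple[int, int]] = frozenset()
    FINAL = "FINAL"

    ids: dict[object, int] = {start: 0}
    order: list[object] = [start]
    delta: list[list[int]] = []
    queue = deque([start])
    final_id: int | None = None

    def successor(state: frozenset, bit: str):
        new: set[tuple[int, int]] = set()
        for i, pat in enumerate(patterns):
            active = [pl for (j, pl) in state if j == i]
            active.append(0)
            for pl in active:
                if pat[pl] == "0" or bit == "1":
                    if pl + 1 == spans[i]:
                        return FINAL
                    new.add((i, pl + 1))
        return frozenset(new)

    rows: dict[int, list[int]] = {}
    while queue:
        state = queue.popleft()
        row = []
        for bit in "01":
            nxt = successor(state, bit)
            if nxt is FINAL:
                if final_id is None:
                    final_id = len(order)
                    ids[FINAL] = final_id
                    order.append(FINAL)
                row.append(final_id)
            else:
                if nxt not in ids:
                    ids[nxt] = len(order)
                    order.append(nxt)
                    queue.append(nxt)
                row.append(ids[nxt])
        rows[ids[state]] = row

    if final_id is None:          # unreachable in practice (weight >= 1)
        final_id = len(order)
        order.append(FINAL)
    rows[final_id] = [final_id, final_id]   # absorbing

    delta = [rows[i] for i in range(len(order))]
    return HitAutomaton(tuple((r[0], r[1]) for r in delta), frozenset({final_id}))


def minimize(dfa: HitAutomaton) -> HitAutomaton:
    """Language-equivalent minimal DFA via Moore partition refinement.

    Unreachable states are trimmed first; the result keeps state 0 initial and
    renumbers classes in breadth-first discovery order for reproducibility.
    """
    # trim unreachable
    reach = [dfa.initial]
    seen = {dfa.initial}
    for q in reach:
        for nxt in dfa.delta[q]:
            if nxt not in seen:
                seen.add(nxt)
                reach.append(nxt)
    remap = {q: i for i, q in enumerate(reach)}
    delta = [(remap[dfa.delta[q][0]], remap[dfa.delta[q][1]]) for q in reach]
    finals = {remap[q] for q in dfa.finals if q in remap}
    n = len(delta)

    # Moore refinement: split classes by (class, class-of-0-succ, class-of-1-succ)
    cls = [1 if q in finals else 0 for q in range(n)]
    while True:
        sig = {}
        new_cls = [0] * n
        for q in range(n):
            key = (cls[q], cls[delta[q][0]], cls[delta[q][1]])
            if key not in sig:
                sig[key] = len(sig)
            new_cls[q] = sig[key]
        if new_cls == cls:
            break
        cls = new_cls

    # renumber classes in BFS order from the initial state's class
    bfs_order: list[int] = []
    cmap: dict[int, int] = {}

    def cid(c: int) -> int:
        if c not in cmap:
            cmap[c] = len(cmap)
            bfs_order.append(c)
        return cmap[c]

    rep: dict[int, int] = {}
    for q in range(n):
        rep.setdefault(cls[q], q)
    cid(cls[0])
    out_delta: list[tuple[int, int]] = []
    i = 0
    while i < len(bfs_order):
        c = bfs_order[i]
        q = rep[c]
        out_delta.append((cid(cls[delta[q][0]]), cid(cls[delta[q][1]])))
        i += 1
    out_finals = frozenset(cmap[cls[q]] for q in finals)
    return HitAutomaton(tuple(out_delta), out_finals)


@dataclass(frozen=True)
class ProductAutomaton:
    """Lazy breadth-first product of a hit DFA with the 1-counting automaton.

    States are pairs ``(match_count, hit_state)`` reachable within ``depth``
    input symbols; ids are assigned in breadth-first discovery order.
    ``delta[i]`` maps to successor ids, or -1 when the successor lies beyond
    the depth cap.
    """

    depth: int
    states: tuple[tuple[int, int], ...]
    delta: tuple[tuple[int, int], ...]
    final_ids: frozenset[int]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_id(self, match_count: int, hit_state: int) -> int | None:
        try:
            return self.states.index((match_count, hit_state))
        except ValueError:
            return None


def build_product(dfa: HitAutomaton, length: int) -> ProductAutomaton:
    """Materialize only the product states reachable in <= ``length`` steps."""
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    # BFS by depth; a state first reached at depth d can still move while d < length
    start = (0, dfa.initial)
    ids = {start: 0}
    states = [start]
    depth_of = [0]
    delta: dict[int, list[int]] = {}
    frontier = [start]
    for d in range(length):
        nxt_frontier = []
        for st in frontier:
            m, q = st
            sid = ids[st]
            row = delta.setdefault(sid, [-1, -1])
            for bit in (0, 1):
                t = (m + bit, dfa.delta[q][bit])
                if t not in ids:
                    ids[t] = len(states)
                    states.append(t)
                    depth_of.append(d + 1)
                    nxt_frontier.append(t)
                row[bit] = ids[t]
        frontier = nxt_frontier
    full_delta = tuple(tuple(delta.get(i, [-1, -1])) for i in range(len(states)))
    finals = frozenset(i for i, (m, q) in enumerate(states) if q in dfa.finals)
    return ProductAutomaton(length, tuple(states), full_delta, finals)
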