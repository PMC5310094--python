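"""Asymptotic no-hit decay: the Perron eigenvalue of the sub-stochastic matrix.

For a fixed match probability p, the probability that a seed set never hits
an alignment of length l decays geometrically:

    no-hit(l) ~ beta * lambda**l    (l -> infinity)

where lambda is the largest (positive) eigenvalue of the hit DFA's
transition matrix restricted to non-final states — each '1'-transition
weighted p, each '0'-transition weighted 1-p — and beta the associated
prefactor.  lambda is computed as the spectral radius of that sparse matrix;
beta by the convergent ratio no-hit(l) / lambda**l, iterated until stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .automata import build_hit_dfa, minimize
from .seedcore import Seed, SeedSet

__all__ = ["SubstochasticSystem", "build_substochastic", "no_hit_probability", "lambda_beta"]


@dataclass(frozen=True)
class SubstochasticSystem:
    """Non-final-state transition matrix of a hit DFA at match probability p.

    Row sums are <= 1; the missing mass is what leaks into the absorbing
    final states.  ``initial`` indexes the DFA start state (always retained:
    final states are absorbing, so every non-final state stays reachable).
    """

    matrix: sp.csr_matrix
    initial: int
    p: float
    n_states: int

    def __post_init__(self) -> None:
        rs = np.asarray(self.matrix.sum(axis=1)).ravel()
        if rs.size and rs.max() > 1 + 1e-12:
            raise ValueError("matrix is not sub-stochastic (row sum > 1)")
        if rs.size and np.all(rs > 1 - 1e-12):
            raise ValueError("no row leaks mass to the final states; not sub-stochastic")


def build_substochastic(seedset: SeedSet | Seed | str, p: float) -> SubstochasticSystem:
    """Minimized hit DFA, final states removed, transitions weighted (1-p, p)."""
    if not 0 < p < 1:
        raise ValueError("need 0 < p < 1 (boundary values are degenerate)")
    dfa = minimize(build_hit_dfa(seedset))
    nonfinal = [q for q in range(dfa.n_states) if q not in dfa.finals]
    index = {q: i for i, q in enumerate(nonfinal)}
    rows, cols, data = [], [], []
    for q in nonfinal:
        n0, n1 = dfa.delta[q]
        for nxt, w in ((n0, 1.0 - p), (n1, p)):
            if nxt in index:
                rows.append(index[q])
                cols.append(index[nxt])
                data.append(w)
    n = len(nonfinal)
    mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return SubstochasticSystem(mat, index[dfa.initial], p, n)


def no_hit_probability(system: SubstochasticSystem, length: int) -> float:
    """1 - hit probability at the given alignment length, via matrix powering."""
    v = np.zeros(system.n_states)
    v[system.initial] = 1.0
    for _ in range(length):
        v = v @ system.matrix
    return float(v.sum())


def lambda_beta(
    system: SubstochasticSystem,
    ratio_tol: float = 1e-10,
    max_steps: int = 200_000,
) -> tuple[float, float]:
    """Perron root lambda and prefactor beta of the no-hit decay.

    lambda is the spectral radius of the (trimmed, reachable) sub-stochastic
    matrix; beta is obtained by iterating v <- v (M / lambda) from the
    initial distribution until the total mass stabilizes (successive-ratio
    stability below ``ratio_tol`` — the convergence certificate).  Flags
    non-convergence instead of returning a stale value.
    """
    n = system.n_states
    if n == 1:
        lam = float(system.matrix[0, 0])
        return lam, 1.0
    if n <= 300:
        eigvals = np.linalg.eigvals(system.matrix.toarray())
        lam = float(np.max(np.abs(eigvals)))  # Perron root = spectral radius
    else:
        vals = spla.eigs(system.matrix.astype(float), k=1, which="LM",
                         return_eigenvectors=False, maxiter=5000, tol=0)
        lam = float(np.abs(vals[0]))
    if not 0 < lam < 1:
        raise ValueError(f"spectral radius {lam} outside (0, 1); degenerate system")

    scaled = system.matrix / lam
    v = np.zeros(n)
    v[system.initial] = 1.0
    prev = v.sum()
    stable = 0
    for _ in range(max_steps):
        v = v @ scaled
        cur = float(v.sum())
        if prev > 0 and abs(cur - prev) <= ratio_tol * max(prev, 1e-300):
            stable += 1
            if stable >= 5:
                return lam, cur
        else:
            stable = 0
        prev = cur
    raise RuntimeError(
        f"beta ratio did not converge within {max_steps} steps "
        f"(last ratio {prev}); reducible or ill-conditioned system"
    )
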