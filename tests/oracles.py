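"""Independent oracles used by the test suite.

The LP oracle enumerates candidate vertices of the flux polytope
{S·v = 0, lb ≤ v ≤ ub} exhaustively: every vertex has at least
n − rank(S) coordinates pinned at a bound, so enumerating all such
pinned subsets and solving the remaining square system visits every
vertex.  It is only usable for tiny networks (n ≤ ~8) and shares no code
with the solver under test.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def vertex_enumeration_max(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray, tol: float = 1e-8
) -> float | None:
    """Maximum of c·v over the flux polytope, or None if infeasible."""
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best: float | None = None
    for pinned_tuple in combinations(range(n), k):
        pinned = list(pinned_tuple)
        free = [j for j in range(n) if j not in pinned]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue
        for choice in product((0, 1), repeat=k):
            v = np.empty(n)
            for idx, j in enumerate(pinned):
                v[j] = lb[j] if choice[idx] == 0 else ub[j]
            rhs = -S[:, pinned] @ v[pinned] if k else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol * max(1.0, np.abs(v).max()):
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def random_network(seed: int, max_reactions: int = 8):
    """A small random stoichiometric network with finite box bounds.

    Returns (S, lb, ub, c) with c selecting one reaction to maximize.
    Bounds always admit v = 0, so the problem is feasible and bounded.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(1, max(2, n - 1)))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    # sparsify so networks are not fully coupled
    mask = rng.random((m, n)) < 0.35
    S[mask] = 0.0
    lb = np.where(rng.random(n) < 0.5, -10.0, 0.0)
    ub = np.where(rng.random(n) < 0.2, 0.0, 10.0)
    ub = np.maximum(ub, lb)
    c = np.zeros(n)
    c[int(rng.integers(n))] = 1.0
    return S, lb, ub, c


def textbook_pearson(x, y) -> float:
    """Plain product-moment formula, independent of numpy.corrcoef."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    return num / den


def half_normal_truncation_cutoff_z() -> float:
    """Asymptotic cutoff, in z-units of the bulk normal, produced by the
    truncate-at-mean-then-moment-fit procedure applied to a pure normal:
    retained values follow the lower half-normal with mean −φ(0)/Φ(0)·σ and
    sd σ·sqrt(1 − (φ(0)/Φ(0))²); the cutoff is their sum."""
    lam = np.sqrt(2.0 / np.pi)  # φ(0)/Φ(0)
    return float(-lam + np.sqrt(1.0 - lam**2))
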