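"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: NNLS by exhaustive
support enumeration over unconstrained least squares, and one-to-one dot
matching by exhaustive assignment enumeration.
"""

from itertools import combinations, permutations

import numpy as np


def nnls_by_enumeration(r: np.ndarray, b: np.ndarray, tol: float = 1e-10):
    """Global NNLS optimum by enumerating all 2^C supports.

    For each support, solve unconstrained least squares on those columns;
    keep solutions that are feasible (non-negative on the support) and return
    the one with the smallest residual.  Exact for small C because the global
    NNLS optimum restricted to its own support is the unconstrained LS
    solution there, hence appears in the enumeration.
    """
    m, c = r.shape
    best_x = np.zeros(c)
    best_res = float(np.linalg.norm(b))
    for k in range(1, c + 1):
        for support in combinations(range(c), k):
            sub = r[:, support]
            coef, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if np.any(coef < -tol):
                continue
            x = np.zeros(c)
            x[list(support)] = np.clip(coef, 0.0, None)
            res = float(np.linalg.norm(r @ x - b))
            if res < best_res - 1e-15:
                best_x, best_res = x, res
    return best_x, best_res


def best_assignment(pos_a: np.ndarray, pos_b: np.ndarray, radius: float):
    """Minimum-total-distance one-to-one matching by brute-force enumeration.

    Enumerates all injective assignments of the smaller list into the larger
    (feasible only within ``radius``) and returns the assignment with the
    most pairs, ties broken by total distance.  Exponential; small inputs
    only.
    """
    na, nb = len(pos_a), len(pos_b)
    swap = na > nb
    if swap:
        pos_a, pos_b = pos_b, pos_a
        na, nb = nb, na
    dist = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    best = (0, 0.0, [])
    for targets in permutations(range(nb), na):
        pairs = [
            (i, j) for i, j in zip(range(na), targets) if dist[i, j] <= radius
        ]
        total = sum(dist[i, j] for i, j in pairs)
        key = (len(pairs), -total)
        if key > (best[0], -best[1]):
            best = (len(pairs), total, pairs)
    n_pairs, total, pairs = best
    if swap:
        pairs = [(j, i) for i, j in pairs]
    return n_pairs, total, pairs
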