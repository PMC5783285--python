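"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately takes a different algorithmic route from the
implementation it checks: dense quadratic programming for the ranking-SVM
objective, breadth-first search for single-linkage components, exhaustive
simple-path enumeration for widest paths, and direct per-pair arithmetic for
RMSD matrices and preference counts.
"""

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def qp_reference_objective(diffs: np.ndarray, c: float) -> float:
    """Solve min 1/2||w||^2 + c*sum(xi) s.t. w.x_p >= 1 - xi_p directly.

    Dense primal quadratic program over (w, xi) via SLSQP; suitable for tiny
    instances (<= ~20 pairs).
    """
    X = np.asarray(diffs, dtype=float)
    m, d = X.shape

    def objective(z):
        w, xi = z[:d], z[d:]
        return 0.5 * w @ w + c * xi.sum()

    def grad(z):
        w, xi = z[:d], z[d:]
        return np.concatenate([w, np.full(m, c)])

    def hess(z):
        H = np.zeros((d + m, d + m))
        H[:d, :d] = np.eye(d)
        return H

    A = np.hstack([X, np.eye(m)])  # w.x_p + xi_p >= 1
    constraint = LinearConstraint(A, lb=np.ones(m), ub=np.inf)
    bounds = [(None, None)] * d + [(0, None)] * m
    res = minimize(
        objective,
        np.ones(d + m),
        jac=grad,
        hess=hess,
        method="trust-constr",
        bounds=bounds,
        constraints=[constraint],
        options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
    )
    assert res.status in (1, 2), res.message
    return float(res.fun)


def bfs_single_linkage(matrix: np.ndarray, cutoff: float) -> list[set]:
    """Connected components of the <=cutoff graph by breadth-first search."""
    m = np.asarray(matrix)
    n = m.shape[0]
    unseen = set(range(n))
    components = []
    while unseen:
        start = min(unseen)
        queue = [start]
        comp = {start}
        unseen.remove(start)
        while queue:
            i = queue.pop()
            for j in list(unseen):
                if m[i, j] <= cutoff:
                    unseen.remove(j)
                    comp.add(j)
                    queue.append(j)
        components.append(comp)
    return components


def enumerate_strongest_paths(W: np.ndarray) -> np.ndarray:
    """Widest-path strengths by exhaustive simple-path enumeration."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    P = np.zeros((n, n))

    def dfs(node, target, visited, strength):
        best = -np.inf
        for nxt in range(n):
            if nxt in visited:
                continue
            s = min(strength, W[node, nxt])
            if nxt == target:
                best = max(best, s)
            else:
                best = max(best, dfs(nxt, target, visited | {nxt}, s))
        return best

    for a in range(n):
        for b in range(n):
            if a != b:
                P[a, b] = dfs(a, b, {a}, np.inf)
    return P


def pairwise_rmsd(ligands: np.ndarray) -> np.ndarray:
    """Per-pair RMSD by direct double loop."""
    n = ligands.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((ligands[i] - ligands[j]) ** 2).sum(axis=1).mean())
    return out


def count_preferences(rankings, n: int) -> np.ndarray:
    """weight(a, b) = number of rankings placing a above b, by direct count."""
    W = np.zeros((n, n), dtype=int)
    for ranking in rankings:
        pos = {int(d): p for p, d in enumerate(ranking)}
        for a in range(n):
            for b in range(n):
                if a != b and pos[a] < pos[b]:
                    W[a, b] += 1
    return W
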