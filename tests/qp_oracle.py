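"""Independent brute-force SVM oracle for cross-checking the classifier.

Solves the soft-margin SVM dual directly with SLSQP:

    max_a  sum a_i - 1/2 sum_ij a_i a_j y_i y_j <x_i, x_j>
    s.t.   0 <= a_i <= C,  sum a_i y_i = 0

and recovers w = sum a_i y_i x_i and the bias from free support vectors.
Deliberately shares no code with the package's SVM path.
"""

import numpy as np
from scipy.optimize import minimize


def solve_svm_dual(X, y, C=1.0):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    best = None
    for start in (np.zeros(n), np.full(n, min(C, 1.0) / 2)):
        res = minimize(neg_dual, start, jac=grad, bounds=[(0, C)] * n,
                       constraints=[cons], method="SLSQP",
                       options={"maxiter": 2000, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    a = np.clip(best.x, 0, C)
    # KKT polish: fix near-bound multipliers at their bounds and solve the
    # remaining equality-constrained QP exactly for the free set
    for _ in range(3):
        tol = 1e-5 * max(C, 1.0)
        free = (a > tol) & (a < C - tol)
        if not free.any():
            break
        at_C = a >= C - tol
        F = np.where(free)[0]
        nf = len(F)
        A = np.zeros((nf + 1, nf + 1))
        A[:nf, :nf] = Q[np.ix_(F, F)]
        A[:nf, nf] = y[F]
        A[nf, :nf] = y[F]
        rhs = np.zeros(nf + 1)
        rhs[:nf] = 1.0 - Q[np.ix_(F, np.where(at_C)[0])] @ (
            np.full(int(at_C.sum()), C))
        rhs[nf] = -C * y[at_C].sum()
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        a_new = np.where(at_C, C, 0.0)
        a_new[F] = sol[:nf]
        if np.all(a_new >= -tol) and np.all(a_new <= C + tol):
            a = np.clip(a_new, 0, C)
        break
    w = (a * y) @ X
    # bias from free SVs (0 < a < C): y_i (w.x_i + b) = 1
    tol = 1e-6 * max(C, 1.0)
    free = (a > tol) & (a < C - tol)
    if free.any():
        b = float(np.mean(y[free] - X[free] @ w))
    else:
        # fall back: midpoint of the margin constraints
        sv = a > tol
        b = float(np.mean(y[sv] - X[sv] @ w)) if sv.any() else 0.0
    return a, w, b


def decision_values(X_test, w, b):
    return np.asarray(X_test, dtype=float) @ w + b
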