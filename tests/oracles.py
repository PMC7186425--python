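"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's sparse code paths: dense tabular
recursion for A, explicit block construction for H, and a dense normal-
equation solve for the bivariate animal model.
"""

import numpy as np


def dense_a(sire, dam):
    """Tabular-recursion numerator relationship matrix."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def random_pedigree(rng, n_founders=10, n_per_gen=15, n_gens=4):
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    prev = list(range(n_founders))
    for _ in range(n_gens):
        cur = []
        for _ in range(n_per_gen):
            s, d = rng.choice(prev, 2, replace=False)
            cur.append(len(sire))
            sire.append(int(s))
            dam.append(int(d))
        prev = cur
    return np.array(sire), np.array(dam)


def dense_h(A, g, idx, omega=0.95, rescale=True):
    """Explicit dense single-step H from its textbook block form."""
    n = A.shape[0]
    a22 = A[np.ix_(idx, idx)]
    g_adj = np.asarray(g, dtype=float)
    if rescale:
        denom = np.mean(np.diag(g_adj)) - np.mean(g_adj)
        a = (np.mean(np.diag(a22)) - np.mean(a22)) / denom
        b = np.mean(a22) - a * np.mean(g_adj)
        g_adj = a * g_adj + b
    gw = omega * g_adj + (1 - omega) * a22
    rest = np.setdiff1d(np.arange(n), idx)
    a22i = np.linalg.inv(a22)
    A12 = A[np.ix_(rest, idx)]
    H = np.zeros((n, n))
    H[np.ix_(rest, rest)] = (A[np.ix_(rest, rest)]
                             + A12 @ a22i @ (gw - a22) @ a22i @ A12.T)
    H[np.ix_(rest, idx)] = A12 @ a22i @ gw
    H[np.ix_(idx, rest)] = H[np.ix_(rest, idx)].T
    H[np.ix_(idx, idx)] = gw
    return H


def dense_mme_ebv(records, h_inv_dense, g0, sigma2_e):
    """Dense bivariate animal-model solve; returns (n, 2) EBVs.

    ``records``: DataFrame with animal / trait / generation / phenotype.
    ``g0``: 2x2 genetic covariance; ``sigma2_e``: per-trait residual
    variances (length 2).
    """
    n = h_inv_dense.shape[0]
    X, Z, y, r = [], [], [], []
    for t in (1, 2):
        sub = records[records["trait"] == t]
        gens = np.sort(sub["generation"].unique())
        Xt = np.zeros((len(sub), len(gens)))
        for k, g in enumerate(gens):
            Xt[(sub["generation"] == g).to_numpy(), k] = 1.0
        Zt = np.zeros((len(sub), n))
        Zt[np.arange(len(sub)), sub["animal"].to_numpy()] = 1.0
        X.append(Xt)
        Z.append(Zt)
        y.append(sub["phenotype"].to_numpy(dtype=float))
        r.append(1.0 / sigma2_e[t - 1])
    K = np.linalg.inv(g0)
    b1, b2 = X[0].shape[1], X[1].shape[1]
    N = b1 + b2 + 2 * n
    lhs = np.zeros((N, N))
    rhs = np.zeros(N)
    ob = [0, b1]
    oa = [b1 + b2, b1 + b2 + n]
    for t in range(2):
        lhs[ob[t]:ob[t] + X[t].shape[1], ob[t]:ob[t] + X[t].shape[1]] = \
            X[t].T @ X[t] * r[t]
        lhs[ob[t]:ob[t] + X[t].shape[1], oa[t]:oa[t] + n] = \
            X[t].T @ Z[t] * r[t]
        lhs[oa[t]:oa[t] + n, ob[t]:ob[t] + X[t].shape[1]] = \
            Z[t].T @ X[t] * r[t]
        lhs[oa[t]:oa[t] + n, oa[t]:oa[t] + n] = Z[t].T @ Z[t] * r[t]
        rhs[ob[t]:ob[t] + X[t].shape[1]] = X[t].T @ y[t] * r[t]
        rhs[oa[t]:oa[t] + n] = Z[t].T @ y[t] * r[t]
    for i in range(2):
        for j in range(2):
            lhs[oa[i]:oa[i] + n, oa[j]:oa[j] + n] += K[i, j] * h_inv_dense
    sol = np.linalg.solve(lhs, rhs)
    return np.column_stack([sol[oa[0]:oa[0] + n], sol[oa[1]:oa[1] + n]])
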