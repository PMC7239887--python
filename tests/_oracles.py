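"""Independent reference implementations used only to cross-check the package.

These deliberately share no code with gmvnet's solvers: the elastic net is
solved by accelerated proximal gradient (FISTA) on the same objective, OLS
by explicit normal equations.
"""

import numpy as np


def prox_grad_elastic_net(X, y, alpha, lam, n_iter=200_000, tol=1e-13):
    """FISTA on (1/(2n))||y - b0 - Xb||^2 + lam(alpha|b|_1 + (1-alpha)/2 |b|_2^2).

    X must be standardized (so the intercept is mean(y)).  Returns the
    coefficient vector.
    """
    n, p = X.shape
    b0 = y.mean()
    G = X.T @ X / n
    c = X.T @ (y - b0) / n
    L = float(np.linalg.eigvalsh(G).max()) + lam * (1 - alpha)
    if L <= 0:
        return np.zeros(p)
    thr = lam * alpha / L
    beta = np.zeros(p)
    z = beta.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = G @ z - c + lam * (1 - alpha) * z
        w = z - grad / L
        beta_new = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        z = beta_new + (t - 1) / t_new * (beta_new - beta)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta, t = beta_new, t_new
    return beta


def ridge_closed_form(X, y, lam):
    """(X'X/n + lam I)^-1 X'(y - mean(y))/n for standardized X."""
    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ (y - y.mean()) / n
    return np.linalg.solve(G + lam * np.eye(p), c)


def ols_normal_equations(X, y):
    """[intercept, slopes] via explicit normal equations."""
    D = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(D.T @ D, D.T @ y)
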