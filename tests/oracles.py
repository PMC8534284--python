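"""Independent brute-force oracles used by the test-suite and acceptance
checks. These deliberately avoid the code paths they verify."""

from __future__ import annotations

import numpy as np


def glasso_bruteforce(S: np.ndarray, lam: float, tol: float = 1e-12, max_iter: int = 200000) -> np.ndarray:
    """Proximal-gradient (ISTA with backtracking) solver for the graphical
    lasso objective

        min_Theta  -logdet(Theta) + tr(S Theta) + lam * sum_{i != j} |Theta_ij|

    over positive-definite matrices. Slow but simple; intended for tiny
    problems (p <= ~6) as an independent check of faster solvers.
    """
    p = S.shape[0]
    theta = np.linalg.inv(S + lam * np.eye(p))
    theta = (theta + theta.T) / 2.0
    off_mask = ~np.eye(p, dtype=bool)

    def smooth(t: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(t)
        if sign <= 0:
            return np.inf
        return float(np.trace(S @ t) - logdet)

    step = 1.0
    f_cur = smooth(theta)
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        while True:
            cand = theta - step * grad
            # soft-threshold the off-diagonal entries
            cand[off_mask] = np.sign(cand[off_mask]) * np.maximum(
                np.abs(cand[off_mask]) - step * lam, 0.0
            )
            cand = (cand + cand.T) / 2.0
            f_new = smooth(cand)
            diff = cand - theta
            quad = f_cur + float(np.sum(grad * diff)) + float(np.sum(diff**2)) / (2 * step)
            if np.isfinite(f_new) and f_new <= quad + 1e-15:
                break
            step *= 0.5
            if step < 1e-14:
                return theta
        if np.max(np.abs(cand - theta)) < tol:
            theta = cand
            break
        theta, f_cur = cand, f_new
        step *= 1.05
    return theta


def stepup_adjust(p_values: np.ndarray, by: bool) -> np.ndarray:
    """Textbook step-up FDR adjustment (cumulative minimum form).

    adjusted_(i) = min_{j >= i} min(1, c * m * p_(j) / j), with c = 1 for
    the Benjamini-Hochberg procedure and c = sum_{k=1..m} 1/k for
    Benjamini-Yekutieli.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    c = np.sum(1.0 / np.arange(1, m + 1)) if by else 1.0
    scaled = np.minimum(c * m * ranked / np.arange(1, m + 1), 1.0)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = adjusted
    return out


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normal-equations solve, written out explicitly."""
    return np.linalg.inv(X.T @ X) @ X.T @ y
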