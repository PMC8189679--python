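"""Reference solver for the full constrained bilinear objective.

Minimizes ``||E - b 1' - CS . TFA||^2`` over all parameters at once by
multi-start projected gradient descent with backtracking line search,
instead of alternating exact block solves.  It shares no code with the
alternating-least-squares path, so it serves as an independent
cross-check of the fitted objective value on small instances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constraints import ActivityBounds
from .containers import (
    ControlStrengthMatrix,
    ExpressionMatrix,
    SignConstraintMatrix,
)

__all__ = ["projected_gradient_fit"]


def _project_cs(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    out = np.where(S > 0, np.maximum(C, 0.0), np.where(S < 0, np.minimum(C, 0.0), 0.0))
    return out


def _project_tfa(
    A: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    deferred: list[tuple[int, int, int]],
    floor: float,
) -> np.ndarray:
    A = np.clip(A, lower, upper)
    # overexpression entries must exceed the (already projected) reference
    for j, k, kref in deferred:
        A[j, k] = max(A[j, k], A[j, kref] + floor)
    return A


def projected_gradient_fit(
    expr: ExpressionMatrix,
    signs: SignConstraintMatrix,
    bounds: ActivityBounds,
    n_restarts: int = 20,
    n_steps: int = 3000,
    seed: int = 0,
    tol: float = 1e-12,
) -> tuple[float, ControlStrengthMatrix, np.ndarray]:
    """Best SSE over restarts, with the corresponding parameters.

    Returns (sse, control strengths with baselines, activity array).
    """
    genes = expr.gene_ids
    tfs = bounds.tf_ids
    samples = expr.sample_ids
    E = expr.values
    S = signs.signs.reindex(index=genes, columns=tfs, fill_value=0).to_numpy().astype(float)
    lower = bounds.lower.loc[tfs, samples].to_numpy().astype(float)
    upper = bounds.upper.loc[tfs, samples].to_numpy().astype(float)
    tf_idx = {tf: j for j, tf in enumerate(tfs)}
    s_idx = {s: k for k, s in enumerate(samples)}
    deferred = [
        (tf_idx[tf], s_idx[s], s_idx[ref])
        for (tf, s), ref in bounds.deferred.items()
        if tf in tf_idx and s in s_idx and ref in s_idx
    ]
    rng = np.random.default_rng(seed)
    G, T, K = len(genes), len(tfs), len(samples)

    best_sse = np.inf
    best_params = None
    for _ in range(n_restarts):
        C = _project_cs(S * rng.uniform(0.2, 2.0, size=(G, T)), S)
        b = E.mean(axis=1) + rng.normal(0, 0.1, size=G)
        A = _project_tfa(
            rng.lognormal(0.0, 0.5, size=(T, K)), lower, upper, deferred, bounds.floor
        )
        step = 1.0 / max(1.0, np.linalg.norm(A) * np.linalg.norm(C) + G)
        R = C @ A + b[:, None] - E
        f = float(np.sum(R * R))
        for _ in range(n_steps):
            gC = 2.0 * R @ A.T
            gb = 2.0 * R.sum(axis=1)
            gA = 2.0 * C.T @ R
            improved = False
            for _ in range(30):
                C2 = _project_cs(C - step * gC, S)
                b2 = b - step * gb
                A2 = _project_tfa(A - step * gA, lower, upper, deferred, bounds.floor)
                R2 = C2 @ A2 + b2[:, None] - E
                f2 = float(np.sum(R2 * R2))
                if f2 <= f:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            rel = (f - f2) / max(f, 1e-300)
            C, b, A, R, f = C2, b2, A2, R2, f2
            step *= 1.3
            if rel < tol:
                break
        if f < best_sse:
            best_sse = f
            best_params = (C.copy(), b.copy(), A.copy())

    assert best_params is not None
    C, b, A = best_params
    cs = ControlStrengthMatrix(
        pd.DataFrame(C, index=genes, columns=tfs), pd.Series(b, index=genes)
    )
    return best_sse, cs, A
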