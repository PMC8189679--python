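"""Sign-constrained bilinear factorization of expression matrices.

The model is ``E = CS . TFA`` with per-gene baselines: the log2 expression
of gene *i* in sample *k* is

    e_ik = b_i + sum_j cs_ij * a_jk

with ``cs_ij`` zero off the network, sign-constrained on edges, and
``a_jk >= 0`` with perturbation bounds (a deleted TF's activity is held at
zero, an overexpressed TF's must exceed its unperturbed-reference
activity).  The fit alternates two exact constrained least-squares blocks:
a per-gene control-strength step and a per-sample activity step.  Each
block reduces to non-negative least squares after flipping columns by
their constrained sign and concentrating out the unconstrained baseline,
so every step is an exact minimizer and training error is monotone
non-increasing.

The public surface is the scikit-learn style :class:`BilinearTFA`
estimator; :func:`fit_model` and :func:`refit_activities` are thin
functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .constraints import DEFAULT_FLOOR, ActivityBounds
from .containers import (
    ActivityMatrix,
    ControlStrengthMatrix,
    ExpressionMatrix,
    NetworkMap,
    PerturbationKey,
    SignConstraintMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "BilinearTFA",
    "cs_step",
    "tfa_step",
    "normalize_mean_activity",
    "fit_model",
    "refit_activities",
    "signed_binary_cs",
    "variance_explained",
]


# ---------------------------------------------------------------------------
# constrained least-squares primitives

def _nnls_signed_with_intercept(
    A: np.ndarray, y: np.ndarray, signs: np.ndarray
) -> tuple[np.ndarray, float]:
    """min ||b + A x - y||^2 s.t. x_j * signs_j >= 0, b free.

    Columns are flipped by their sign so the constraint becomes x >= 0,
    and the free intercept is concentrated out by centering (for fixed x
    the optimal b is the mean residual), leaving a plain NNLS problem.
    """
    if A.shape[1] == 0:
        return np.zeros(0), float(np.mean(y))
    Af = A * signs[np.newaxis, :]
    Ac = Af - Af.mean(axis=0)
    yc = y - y.mean()
    z, _ = nnls(Ac, yc)
    x = z * signs
    b = float(np.mean(y - A @ x))
    return x, b


def _nnls_lower_bounded(
    A: np.ndarray, y: np.ndarray, lb: np.ndarray
) -> np.ndarray:
    """min ||A x - y||^2 s.t. x >= lb elementwise (shift to NNLS)."""
    if A.shape[1] == 0:
        return np.zeros(0)
    shift = A @ lb
    z, _ = nnls(A, y - shift)
    return lb + z


# ---------------------------------------------------------------------------
# alternating steps (functional surface)

def cs_step(
    expr: ExpressionMatrix,
    tfa: ActivityMatrix,
    signs: SignConstraintMatrix,
) -> ControlStrengthMatrix:
    """Exact per-gene constrained regression of CS and baselines, TFA fixed."""
    samples = expr.sample_ids
    A_full = tfa.activities.loc[:, samples].to_numpy()  # T x S
    tf_index = {tf: j for j, tf in enumerate(tfa.tf_ids)}
    S = signs.signs.reindex(index=expr.gene_ids, columns=tfa.tf_ids, fill_value=0)
    Sv = S.to_numpy()
    E = expr.values
    G, T = len(expr.gene_ids), len(tfa.tf_ids)
    CS = np.zeros((G, T))
    b = np.zeros(G)
    for i in range(G):
        idx = np.nonzero(Sv[i])[0]
        x, b[i] = _nnls_signed_with_intercept(
            A_full[idx].T, E[i], Sv[i, idx].astype(float)
        )
        CS[i, idx] = x
    return ControlStrengthMatrix(
        pd.DataFrame(CS, index=expr.gene_ids, columns=tfa.tf_ids),
        pd.Series(b, index=expr.gene_ids),
    )


def _bounds_arrays(
    bounds: ActivityBounds, tfs: list[str], samples: list[str]
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Lower bounds, fixed-zero mask and deferred (tf, sample, ref) index
    triples in array form."""
    lower = bounds.lower.loc[tfs, samples].to_numpy(dtype=float).copy()
    upper = bounds.upper.loc[tfs, samples].to_numpy(dtype=float)
    fixed_zero = (lower == 0.0) & (upper == 0.0)
    tf_idx = {tf: j for j, tf in enumerate(tfs)}
    s_idx = {s: k for k, s in enumerate(samples)}
    deferred = []
    for (tf, s), ref in bounds.deferred.items():
        if tf not in tf_idx or s not in s_idx:
            continue
        if ref not in s_idx:
            raise ValidationError(
                f"deferred reference sample {ref!r} not among samples"
            )
        deferred.append((tf_idx[tf], s_idx[s], s_idx[ref]))
    return lower, fixed_zero, deferred


def _tfa_solve(
    C: np.ndarray,
    resid: np.ndarray,
    lower: np.ndarray,
    fixed_zero: np.ndarray,
    deferred: list[tuple[int, int, int]],
    floor: float,
) -> np.ndarray:
    """Per-sample bounded least squares for activities; samples with
    deferred (overexpression) bounds are solved after their references."""
    T, K = lower.shape
    A = np.zeros((T, K))
    deferred_cols = {k for (_, k, _) in deferred}
    order = [k for k in range(K) if k not in deferred_cols] + sorted(deferred_cols)
    lb = lower.copy()
    for k in order:
        for j, kk, kref in deferred:
            if kk == k:
                lb[j, k] = A[j, kref] + floor
        free = ~fixed_zero[:, k]
        a = np.zeros(T)
        a[free] = _nnls_lower_bounded(C[:, free], resid[:, k], lb[free, k])
        A[:, k] = a
    return A


def tfa_step(
    expr: ExpressionMatrix,
    cs: ControlStrengthMatrix,
    bounds: ActivityBounds,
) -> ActivityMatrix:
    """Exact per-sample bounded regression of activities, CS fixed.

    Samples without deferred (overexpression) bounds are solved first so
    the deferred lower bounds can resolve against freshly fitted
    reference activities.
    """
    genes = [g for g in cs.gene_ids if g in set(expr.gene_ids)]
    if not genes:
        raise ValidationError("no shared genes between expression and CS")
    tfs = cs.tf_ids
    samples = expr.sample_ids
    C = cs.cs.loc[genes].to_numpy()  # G x T
    resid = expr.data.loc[genes].to_numpy() - cs.baselines.loc[genes].to_numpy()[:, None]
    lower, fixed_zero, deferred = _bounds_arrays(bounds, tfs, samples)
    A = _tfa_solve(C, resid, lower, fixed_zero, deferred, bounds.floor)
    return ActivityMatrix(pd.DataFrame(A, index=tfs, columns=samples))


def normalize_mean_activity(
    cs: ControlStrengthMatrix,
    tfa: ActivityMatrix,
    key: PerturbationKey | None = None,
    include_deleted: bool = True,
) -> tuple[ControlStrengthMatrix, ActivityMatrix]:
    """Rescale so each TF's mean activity across samples is one.

    Scaling a TF's activities and control strengths by inverse factors
    leaves CS.TFA unchanged, so the mean-one convention pins the shared
    scale.  Deletion samples (activity exactly zero) are included in the
    mean by default; pass ``include_deleted=False`` with a key to exclude
    them.
    """
    A = tfa.activities.copy()
    C = cs.cs.copy()
    for tf in tfa.tf_ids:
        row = A.loc[tf]
        if include_deleted or key is None:
            m = float(row.mean())
        else:
            deleted = {
                s
                for s, (t, d) in key.records.items()
                if t == tf and d == "deletion"
            }
            keep = [s for s in A.columns if s not in deleted]
            m = float(row.loc[keep].mean())
        if m == 0.0:
            raise ValidationError(f"TF {tf!r} has zero mean activity")
        A.loc[tf] = row / m
        if tf in C.columns:
            C[tf] = C[tf] * m
    return ControlStrengthMatrix(C, cs.baselines), ActivityMatrix(A)


def signed_binary_cs(signs: SignConstraintMatrix) -> ControlStrengthMatrix:
    """Control strengths fixed at +1/-1 from the sign constraints, with
    zero baselines (baselines are refit downstream)."""
    cs = signs.signs.astype(float)
    return ControlStrengthMatrix(cs, pd.Series(0.0, index=cs.index))


def variance_explained(
    expr: ExpressionMatrix,
    cs: ControlStrengthMatrix,
    tfa: ActivityMatrix,
    baselines: pd.Series | None = None,
) -> float:
    """R^2 of the reconstruction, with total variance taken around each
    gene's mean across samples."""
    genes = [g for g in cs.gene_ids if g in set(expr.gene_ids)]
    b = (baselines if baselines is not None else cs.baselines).loc[genes]
    E = expr.data.loc[genes, :]
    pred = (
        cs.cs.loc[genes, tfa.tf_ids] @ tfa.activities.loc[:, E.columns]
    ).add(b, axis=0)
    resid = E.to_numpy() - pred.to_numpy()
    sse = float(np.sum(resid**2))
    centered = E.to_numpy() - E.to_numpy().mean(axis=1, keepdims=True)
    sst = float(np.sum(centered**2))
    if sst == 0.0:
        raise ValidationError("zero total variance; R^2 undefined")
    return 1.0 - sse / sst


def _sse(expr: ExpressionMatrix, cs: ControlStrengthMatrix, tfa: ActivityMatrix) -> float:
    pred = (cs.cs @ tfa.activities.loc[:, expr.sample_ids]).add(cs.baselines, axis=0)
    return float(np.sum((expr.data.loc[cs.gene_ids].to_numpy() - pred.to_numpy()) ** 2))


# ---------------------------------------------------------------------------
# configuration and results

Stopping = Literal["holdout_peak", "train_converge"]


@dataclass(frozen=True)
class FitConfig:
    n_inits: int = 20
    max_iter: int = 100
    floor: float = DEFAULT_FLOOR
    seed: int = 0
    stopping: Stopping = "holdout_peak"
    train_tol: float = 1e-6
    holdout_refit_iters: int = 20
    patience: int = 3

    def __post_init__(self) -> None:
        if self.n_inits < 1 or self.max_iter < 1:
            raise ValueError("n_inits and max_iter must be >= 1")


@dataclass
class FitResult:
    cs: ControlStrengthMatrix
    tfa: ActivityMatrix
    r2_train: list[float]
    r2_holdout: list[float] | None
    chosen_init: int
    iterations_run: int


# ---------------------------------------------------------------------------
# estimator

class BilinearTFA(BaseEstimator):
    """Sign-constrained bilinear decomposition ``E = CS . TFA``.

    Parameters
    ----------
    n_inits : int, default 20
        Number of random sign-respecting initializations of the CS matrix;
        the best run (by the stopping-criterion R^2) is kept.
    max_iter : int, default 100
        Maximum alternating iterations per initialization.
    floor : float, default 1e-4
        Minimum activity for non-deleted entries.
    seed : int, default 0
        Seeds initialization; identical seed gives identical results.
    stopping : {"holdout_peak", "train_converge"}
        ``holdout_peak`` refits activities on a held-out expression matrix
        after each iteration and stops when its R^2 stops improving;
        ``train_converge`` stops on a small relative change in training
        error.
    train_tol : float, default 1e-6
        Relative SSE change threshold for ``train_converge``.
    holdout_refit_iters : int, default 20
        Alternations of the holdout activity/baseline refit per iteration.
    patience : int, default 3
        Iterations without holdout improvement before stopping.

    Attributes (after ``fit``)
    --------------------------
    cs_ : ControlStrengthMatrix
    tfa_ : ActivityMatrix
    baselines_ : pandas.Series
    r2_train_, r2_holdout_, chosen_init_, n_iter_
    """

    def __init__(
        self,
        n_inits: int = 20,
        max_iter: int = 100,
        floor: float = DEFAULT_FLOOR,
        seed: int = 0,
        stopping: Stopping = "holdout_peak",
        train_tol: float = 1e-6,
        holdout_refit_iters: int = 20,
        patience: int = 3,
    ):
        self.n_inits = n_inits
        self.max_iter = max_iter
        self.floor = floor
        self.seed = seed
        self.stopping = stopping
        self.train_tol = train_tol
        self.holdout_refit_iters = holdout_refit_iters
        self.patience = patience

    # -- helpers ----------------------------------------------------------

    def _init_cs(
        self,
        rng: np.random.Generator,
        genes: list[str],
        signs: SignConstraintMatrix,
        tfs: list[str],
        gene_means: pd.Series,
    ) -> ControlStrengthMatrix:
        S = signs.signs.reindex(index=genes, columns=tfs, fill_value=0).to_numpy()
        mag = rng.uniform(0.2, 2.0, size=S.shape)
        return ControlStrengthMatrix(
            pd.DataFrame(S * mag, index=genes, columns=tfs),
            gene_means.loc[genes].copy(),
        )

    def _prepare(
        self,
        expr: ExpressionMatrix,
        network: NetworkMap,
        key: PerturbationKey,
    ) -> tuple[ExpressionMatrix, PerturbationKey]:
        """Restrict to network target genes and to samples in which a
        network TF was perturbed, plus unperturbed samples."""
        net_tfs = set(network.tfs)
        keep_samples = [
            s
            for s in expr.sample_ids
            if s in key.unperturbed_samples
            or key.records.get(s, (None, None))[0] in net_tfs
        ]
        targets = [g for g in expr.gene_ids if g in set(network.targets)]
        missing = set(network.targets) - set(targets)
        if missing:
            logger.warning(
                "%d network targets absent from expression matrix", len(missing)
            )
        sub = expr.data.loc[targets, keep_samples]
        keep_genes = sub.std(axis=1) > 0
        if not keep_genes.all():
            logger.warning(
                "dropping %d zero-variance genes", int((~keep_genes).sum())
            )
            sub = sub.loc[keep_genes]
        key_sub = PerturbationKey(
            {s: r for s, r in key.records.items() if s in set(keep_samples)},
            tuple(s for s in key.unperturbed_samples if s in set(keep_samples)),
        )
        return ExpressionMatrix(sub), key_sub

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        expr: ExpressionMatrix,
        y=None,
        *,
        network: NetworkMap,
        signs: SignConstraintMatrix,
        key: PerturbationKey,
        holdout_expr: ExpressionMatrix | None = None,
    ) -> "BilinearTFA":
        from .constraints import activity_bounds  # local to avoid cycle at import

        expr_f, key_f = self._prepare(expr, network, key)
        tfs = network.tfs
        bounds = activity_bounds(
            key_f, tfs, expr_f.sample_ids, floor=self.floor
        )
        gene_means = expr_f.data.mean(axis=1)
        rng = np.random.default_rng(self.seed)
        use_holdout = (
            holdout_expr is not None and self.stopping == "holdout_peak"
        )

        best_score = -np.inf
        best: tuple | None = None
        for init in range(self.n_inits):
            cs = self._init_cs(rng, expr_f.gene_ids, signs, tfs, gene_means)
            r2_train: list[float] = []
            r2_hold: list[float] = []
            peak = (-np.inf, None, None, 0)  # (score, cs, tfa, iter)
            stall = 0
            prev_sse = np.inf
            tfa = None
            for it in range(self.max_iter):
                tfa = tfa_step(expr_f, cs, bounds)
                cs = cs_step(expr_f, tfa, signs)
                cs, tfa = normalize_mean_activity(cs, tfa)
                sse = _sse(expr_f, cs, tfa)
                r2_train.append(variance_explained(expr_f, cs, tfa))
                if use_holdout:
                    _, _, r2h = refit_activities(
                        holdout_expr,
                        cs,
                        max_alternations=self.holdout_refit_iters,
                        floor=self.floor,
                    )
                    r2_hold.append(r2h)
                    if r2h > peak[0]:
                        peak = (r2h, cs, tfa, it + 1)
                        stall = 0
                    else:
                        stall += 1
                        if stall >= self.patience:
                            break
                else:
                    if (
                        prev_sse < np.inf
                        and abs(prev_sse - sse) <= self.train_tol * max(prev_sse, 1e-300)
                    ):
                        break
                prev_sse = sse
            if use_holdout and peak[1] is not None:
                score, cs_best, tfa_best, iters = peak
            else:
                score = r2_train[-1]
                cs_best, tfa_best, iters = cs, tfa, len(r2_train)
            if score > best_score:
                best_score = score
                best = (cs_best, tfa_best, r2_train, r2_hold or None, init, iters)

        assert best is not None
        cs_best, tfa_best, r2_train, r2_hold, chosen, iters = best
        # the mean-one rescaling can push floor-level activities slightly
        # below the floor; one exact activity solve against the final CS
        # restores every bound without changing the reconstruction
        tfa_best = tfa_step(expr_f, cs_best, bounds)
        self.cs_, self.tfa_, self.r2_train_, self.r2_holdout_, self.chosen_init_, self.n_iter_ = (
            cs_best, tfa_best, r2_train, r2_hold, chosen, iters
        )
        self.baselines_ = self.cs_.baselines
        self.network_ = network
        return self

    def transform(
        self, expr2: ExpressionMatrix, bounds: ActivityBounds | None = None
    ) -> ActivityMatrix:
        """Refit activities (and per-dataset baselines) to a new dataset
        with the learned control strengths held fixed."""
        tfa, _, _ = refit_activities(
            expr2, self.cs_, bounds=bounds, floor=self.floor
        )
        return tfa

    def fit_transform(self, expr, y=None, **kw):  # pragma: no cover - sugar
        return self.fit(expr, **kw).tfa_


def refit_activities(
    expr2: ExpressionMatrix,
    cs: ControlStrengthMatrix,
    bounds: ActivityBounds | None = None,
    floor: float = DEFAULT_FLOOR,
    max_alternations: int = 100,
    tol: float = 1e-8,
) -> tuple[ActivityMatrix, pd.Series, float]:
    """Fit activities and baselines to a second dataset, CS fixed.

    Alternates the bounded activity step with the closed-form baseline
    step (per-gene mean residual) until the error stabilizes; the TF mean
    is not re-normalized, so activities are on the scale fixed by the CS
    matrix.  By default only the generic positivity floor applies — in the
    train/test protocol the second dataset's perturbation key is reserved
    for evaluation.

    Returns (activities, baselines, R^2 on the shared genes).
    """
    shared = [g for g in cs.gene_ids if g in set(expr2.gene_ids)]
    if not shared:
        raise ValidationError("no shared genes between expression and CS")
    tfs = cs.tf_ids
    samples = expr2.sample_ids
    if bounds is None:
        bounds = ActivityBounds.floor_only(tfs, samples, floor)
    C = cs.cs.loc[shared].to_numpy()
    E = expr2.data.loc[shared, :].to_numpy()
    lower, fixed_zero, deferred = _bounds_arrays(bounds, tfs, samples)
    b = E.mean(axis=1)
    prev = np.inf
    A = np.zeros((len(tfs), len(samples)))
    for _ in range(max_alternations):
        A = _tfa_solve(C, E - b[:, None], lower, fixed_zero, deferred, bounds.floor)
        pred = C @ A
        b = (E - pred).mean(axis=1)
        sse = float(np.sum((E - pred - b[:, None]) ** 2))
        if prev < np.inf and abs(prev - sse) <= tol * max(prev, 1e-300):
            break
        prev = sse
    tfa = ActivityMatrix(pd.DataFrame(A, index=tfs, columns=samples))
    baselines = pd.Series(b, index=shared)
    sst = float(np.sum((E - E.mean(axis=1, keepdims=True)) ** 2))
    if sst == 0.0:
        raise ValidationError("zero total variance; R^2 undefined")
    r2 = 1.0 - sse / sst
    return tfa, baselines, r2


def fit_model(
    expr: ExpressionMatrix,
    net: NetworkMap,
    signs: SignConstraintMatrix,
    key: PerturbationKey,
    config: FitConfig | None = None,
    holdout: ExpressionMatrix | None = None,
) -> FitResult:
    """Functional wrapper over :class:`BilinearTFA`."""
    config = config or FitConfig()
    est = BilinearTFA(
        n_inits=config.n_inits,
        max_iter=config.max_iter,
        floor=config.floor,
        seed=config.seed,
        stopping=config.stopping,
        train_tol=config.train_tol,
        holdout_refit_iters=config.holdout_refit_iters,
        patience=config.patience,
    )
    est.fit(expr, network=net, signs=signs, key=key, holdout_expr=holdout)
    return FitResult(
        cs=est.cs_,
        tfa=est.tfa_,
        r2_train=est.r2_train_,
        r2_holdout=est.r2_holdout_,
        chosen_init=est.chosen_init_,
        iterations_run=est.n_iter_,
    )
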