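"""Synthetic perturbation benchmarks with known ground truth.

Emulates the structure of single-TF perturbation compendia: one
unperturbed wild-type sample plus one sample per TF deletion and/or
overexpression, with the TF-encoding genes' mRNA kept in a separate
matrix (they are never target rows of the fitted expression matrix).
Expression follows the bilinear model exactly —
``E = baselines + CS . TFA`` — plus homoscedastic Gaussian noise in log2
space, so recovery tests are interpretable against the least-squares
objective.

Defaults describe the benchmark conditions used throughout the test
suite: 20 TFs regulating 300 genes, every TF both deleted and
overexpressed once, overexpression driving activity to 4x its wild-type
level, and TF mRNA coupled to activity with correlation 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constraints import DEFAULT_FLOOR
from .containers import (
    ActivityMatrix,
    ControlStrengthMatrix,
    ExpressionMatrix,
    NetworkMap,
    PerturbationKey,
    SignConstraintMatrix,
    ValidationError,
)
from .timecourse import Family, TimeSeries, impulse6, sigmoid4

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_ground_truth",
    "generate_expression",
    "generate_dataset",
    "corrupt_signs",
    "generate_timecourse",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_tfs: int = 20
    n_genes: int = 300
    targets_per_tf: tuple[int, int] = (5, 15)
    frac_activating: float = 0.7
    cs_magnitude: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.25
    ko_fraction: float = 1.0
    oe_fraction: float = 1.0
    oe_multiplier: float = 4.0
    mrna_coupling: float = 0.9
    sign_conflict_fraction: float = 0.0
    baseline_range: tuple[float, float] = (4.0, 10.0)
    wt_sdlog: float = 0.5
    n_unperturbed: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.targets_per_tf
        if lo < 2 or hi < lo:
            raise ValidationError("targets_per_tf lower bound must be >= 2")
        for name in ("frac_activating", "ko_fraction", "oe_fraction", "mrna_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_genes < hi:
            raise ValidationError("n_genes must be at least max targets_per_tf")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    net: NetworkMap
    signs: SignConstraintMatrix
    cs: ControlStrengthMatrix
    tfa: ActivityMatrix
    key: PerturbationKey
    tf_mrna: ExpressionMatrix
    config: GeneratorConfig


def _tf_ids(n: int) -> list[str]:
    return [f"TF{j + 1:03d}" for j in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Sample a network, signed control strengths, an activity design and
    coupled TF mRNA, all consistent with each other."""
    rng = np.random.default_rng(config.seed)
    tfs = _tf_ids(config.n_tfs)
    genes = _gene_ids(config.n_genes)

    # network: distinct multi-target TFs (resample on the rare collision)
    lo, hi = config.targets_per_tf
    targets_by_tf: dict[str, frozenset[str]] = {}
    seen: set[frozenset[str]] = set()
    for tf in tfs:
        for _ in range(100):
            k = int(rng.integers(lo, hi + 1))
            tgts = frozenset(rng.choice(genes, size=k, replace=False))
            if tgts not in seen:
                break
        else:  # pragma: no cover - would need a tiny gene pool
            raise ValidationError("could not sample distinct target sets")
        seen.add(tgts)
        targets_by_tf[tf] = tgts
    net = NetworkMap(targets_by_tf)

    # edge signs and control strengths
    edge_signs: dict[tuple[str, str], int] = {}
    cs = pd.DataFrame(0.0, index=genes, columns=tfs)
    for tf in tfs:
        for g in sorted(net.targets_of(tf)):
            s = 1 if rng.random() < config.frac_activating else -1
            edge_signs[(tf, g)] = s
            cs.loc[g, tf] = s * rng.uniform(*config.cs_magnitude)
    signs = SignConstraintMatrix.from_edge_signs(edge_signs, net)
    # the sign matrix only spans network targets; align CS rows to all genes
    baselines = pd.Series(
        rng.uniform(*config.baseline_range, size=len(genes)), index=genes
    )

    # perturbation design: WT plus one sample per designated KO / OE
    n_ko = int(round(config.ko_fraction * config.n_tfs))
    n_oe = int(round(config.oe_fraction * config.n_tfs))
    ko_tfs = list(rng.choice(tfs, size=n_ko, replace=False)) if n_ko else []
    oe_tfs = list(rng.choice(tfs, size=n_oe, replace=False)) if n_oe else []
    if config.n_unperturbed < 1:
        raise ValidationError("need at least one unperturbed sample")
    wt_samples = (
        ["WT"]
        if config.n_unperturbed == 1
        else [f"WT{i + 1}" for i in range(config.n_unperturbed)]
    )
    samples = wt_samples + [f"KO_{tf}" for tf in ko_tfs] + [f"OE_{tf}" for tf in oe_tfs]
    records: dict[str, tuple[str, str]] = {}
    for tf in ko_tfs:
        records[f"KO_{tf}"] = (tf, "deletion")
    for tf in oe_tfs:
        records[f"OE_{tf}"] = (tf, "overexpression")
    key = PerturbationKey(records, tuple(wt_samples))

    # activities: lognormal variation, perturbations imposed, rows scaled
    # to mean one (the fitting convention), which keeps OE at a fixed
    # multiple of the WT level
    A = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=config.wt_sdlog, size=(len(tfs), len(samples))),
        index=tfs,
        columns=samples,
    )
    for tf in ko_tfs:
        A.loc[tf, f"KO_{tf}"] = 0.0
    for tf in oe_tfs:
        A.loc[tf, f"OE_{tf}"] = config.oe_multiplier * A.loc[tf, wt_samples[0]]
    A = A.div(A.mean(axis=1), axis=0)
    tfa = ActivityMatrix(A)

    # TF mRNA: coupled to (standardized) activity with the configured
    # correlation, then mapped back to log2 expression units
    Av = A.to_numpy()
    mean = Av.mean(axis=1, keepdims=True)
    sd = Av.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (Av - mean) / np.maximum(sd, 1e-12), 0.0)
    c = config.mrna_coupling
    noise = rng.standard_normal(z.shape)
    mrna = c * z + np.sqrt(max(0.0, 1.0 - c * c)) * noise
    tf_mrna = ExpressionMatrix(
        pd.DataFrame(7.0 + mrna, index=tfs, columns=samples)
    )

    cs_matrix = ControlStrengthMatrix(cs, baselines)
    return GroundTruth(net, signs, cs_matrix, tfa, key, tf_mrna, config)


def generate_expression(
    gt: GroundTruth, noise_sd: float, seed: int
) -> ExpressionMatrix:
    """E = baselines + CS . TFA plus N(0, noise_sd^2) in log2 units.

    TF-encoding genes are not target rows; their mRNA lives in
    ``gt.tf_mrna``.
    """
    rng = np.random.default_rng(seed)
    pred = gt.cs.cs.to_numpy() @ gt.tfa.values + gt.cs.baselines.to_numpy()[:, None]
    if noise_sd > 0:
        pred = pred + rng.normal(0.0, noise_sd, size=pred.shape)
    return ExpressionMatrix(
        pd.DataFrame(pred, index=gt.cs.gene_ids, columns=gt.tfa.sample_ids)
    )


def generate_dataset(
    gt: GroundTruth, noise_sd: float, seed: int
) -> tuple[ExpressionMatrix, PerturbationKey, ExpressionMatrix]:
    """A (expression, key, tf_mrna) triple for the benchmark protocol."""
    return generate_expression(gt, noise_sd, seed), gt.key, gt.tf_mrna


def corrupt_signs(
    signs: SignConstraintMatrix,
    per_tf_conflict: Mapping[str, float],
    seed: int,
) -> SignConstraintMatrix:
    """Flip the stated fraction of each TF's edge signs, chosen at random.

    Models sign conflict between perturbation datasets: an edge whose
    constraint disagrees with the true direction of regulation.
    """
    rng = np.random.default_rng(seed)
    edge_signs: dict[tuple[str, str], int] = {}
    net = signs.network
    for tf in net.tfs:
        targets = sorted(net.targets_of(tf))
        frac = per_tf_conflict.get(tf, 0.0)
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"conflict fraction for {tf!r} outside [0, 1]")
        n_flip = int(round(frac * len(targets)))
        flip = set(rng.choice(targets, size=n_flip, replace=False)) if n_flip else set()
        for g in targets:
            s = signs.sign_of(tf, g)
            edge_signs[(tf, g)] = -s if g in flip else s
    return SignConstraintMatrix.from_edge_signs(edge_signs, net)


def generate_timecourse(
    family: Family,
    params,
    times,
    noise_sd: float,
    seed: int,
) -> TimeSeries:
    """Evaluate a sigmoid or impulse at the given times, add Gaussian
    noise, and anchor the series at (0, 0) as a log2 fold change."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    if family == "sigmoid4":
        v = sigmoid4(t, *params)
    elif family == "impulse6":
        v = impulse6(t, *params)
    else:
        raise ValidationError(f"unknown curve family {family!r}")
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    else:
        v = v.copy()
        v[0] = 0.0
    return TimeSeries(t, v)
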