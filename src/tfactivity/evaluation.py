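"""Accuracy metrics for inferred TF activities.

Three core metrics, each judged against a held-out perturbation key:

* direction of perturbation — did the perturbed TF's inferred activity
  move the right way (down for deletion, up for overexpression) relative
  to the unperturbed reference sample;
* median rank percentile — when TFs are ordered by standardized log2
  activity in the expected direction, where does the perturbed TF rank;
* positive TFA–mRNA correlation — the fraction of TFs whose raw inferred
  activities correlate positively with their own mRNA levels, median over
  bootstrap resamples of the samples.

Plus cross-network activity averaging, regulator-recovery curves and
bootstrap correlations of control strengths against a covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    DELETION,
    ActivityMatrix,
    ControlStrengthMatrix,
    ExpressionMatrix,
    NetworkMap,
    PerturbationKey,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "StandardizedActivityMatrix",
    "standardize_activities",
    "direction_metric",
    "rank_percentile_metric",
    "positive_correlation_metric",
    "regulator_recovery_curve",
    "fisher_combine",
    "average_standardized_tfas",
    "bootstrap_cs_correlation",
]


@dataclass
class MetricsReport:
    direction_fraction: float
    direction_p: float
    median_rank_percentile: float
    rank_p: float
    positive_corr_fraction: float
    corr_p: float
    per_tf_detail: pd.DataFrame  # columns: tf, direction_correct, rank_percentile, corr


@dataclass(frozen=True)
class StandardizedActivityMatrix:
    """Per-TF z-scores of log2 activities across samples; constant rows
    are all zero."""

    z: pd.DataFrame  # tfs x samples

    @property
    def tf_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def standardize_activities(
    tfa: ActivityMatrix, floor: float = 1e-4
) -> StandardizedActivityMatrix:
    """z-score of log2(max(activity, floor)) per TF row.

    The floor keeps exact-zero deletion activities finite on the log
    scale.  Standardization makes activity levels comparable between TFs.
    """
    logged = np.log2(np.maximum(tfa.values, floor))
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (logged - mean) / sd, 0.0)
    return StandardizedActivityMatrix(
        pd.DataFrame(z, index=tfa.tf_ids, columns=tfa.sample_ids)
    )


def direction_metric(
    tfa: ActivityMatrix,
    key: PerturbationKey,
    reference: str | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Fraction of perturbation samples whose direction is inferred
    correctly, with a two-sided binomial p-value against chance (0.5).

    A deletion is correct when the TF's activity in the perturbation
    sample is below its activity in the unperturbed reference; an
    overexpression when it is above.  Equal values count as incorrect.
    """
    ref = reference if reference is not None else key.reference_sample
    A = tfa.activities
    rows = []
    for s, (tf, d) in key.records.items():
        if tf not in A.index or s not in A.columns:
            logger.warning("perturbed TF %r absent from activities; skipping %r", tf, s)
            continue
        a, a_ref = A.loc[tf, s], A.loc[tf, ref]
        correct = (a < a_ref) if d == DELETION else (a > a_ref)
        rows.append({"sample": s, "tf": tf, "direction": d, "correct": bool(correct)})
    detail = pd.DataFrame(rows, columns=["sample", "tf", "direction", "correct"])
    if detail.empty:
        raise ValidationError("no evaluable perturbation samples")
    k = int(detail["correct"].sum())
    n = len(detail)
    p = stats.binomtest(k, n, 0.5).pvalue
    return k / n, float(p), detail


def rank_percentile_metric(
    z: StandardizedActivityMatrix,
    key: PerturbationKey,
) -> tuple[float, float, pd.DataFrame]:
    """Median rank percentile of the perturbed TF across samples.

    In deletion samples TFs are sorted ascending by standardized log2
    activity (most negative first); in overexpression samples descending.
    Rank r of numTFs maps to the percentile 100*(1 - (r-1)/numTFs), so
    the top rank scores 100.  Ties share the mean rank.  Significance is
    a sign test: samples above the chance percentile of 50 versus below.
    """
    Z = z.z
    n_tfs = len(Z.index)
    rows = []
    for s, (tf, d) in key.records.items():
        if tf not in Z.index or s not in Z.columns:
            continue
        col = Z[s]
        ranks = stats.rankdata(col.to_numpy() if d == DELETION else -col.to_numpy())
        r = float(ranks[Z.index.get_loc(tf)])
        pct = 100.0 * (1.0 - (r - 1.0) / n_tfs)
        rows.append({"sample": s, "tf": tf, "direction": d, "rank_percentile": pct})
    detail = pd.DataFrame(rows, columns=["sample", "tf", "direction", "rank_percentile"])
    if detail.empty:
        raise ValidationError("no evaluable perturbation samples")
    med = float(detail["rank_percentile"].median())
    above = int((detail["rank_percentile"] > 50).sum())
    below = int((detail["rank_percentile"] < 50).sum())
    p = 1.0 if above + below == 0 else float(
        stats.binomtest(above, above + below, 0.5).pvalue
    )
    return med, p, detail


def positive_correlation_metric(
    tfa: ActivityMatrix,
    tf_mrna: ExpressionMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Median (over bootstrap resamples of samples) fraction of TFs whose
    raw activities correlate positively with their mRNA levels.

    Activities are neither logged nor standardized before correlating.
    The p-value is a two-sided binomial test on the non-resampled count
    of positively correlated TFs against chance (0.5).
    """
    tfs = [t for t in tfa.tf_ids if t in set(tf_mrna.gene_ids)]
    samples = [s for s in tfa.sample_ids if s in set(tf_mrna.sample_ids)]
    if not tfs or len(samples) < 3:
        raise ValidationError("insufficient shared TFs/samples for correlation metric")
    A = tfa.activities.loc[tfs, samples].to_numpy()
    M = tf_mrna.data.loc[tfs, samples].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(samples)

    def _fractions(idx: np.ndarray) -> float:
        a, m = A[:, idx], M[:, idx]
        sa = a.std(axis=1)
        sm = m.std(axis=1)
        ok = (sa > 0) & (sm > 0)
        if not ok.any():
            return np.nan
        ac = a[ok] - a[ok].mean(axis=1, keepdims=True)
        mc = m[ok] - m[ok].mean(axis=1, keepdims=True)
        r = (ac * mc).sum(axis=1) / (
            np.sqrt((ac**2).sum(axis=1)) * np.sqrt((mc**2).sum(axis=1))
        )
        return float(np.mean(r > 0))

    fracs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        f = _fractions(idx)
        if not np.isnan(f):
            fracs.append(f)
    median_fraction = float(np.median(fracs))

    full_idx = np.arange(n)
    corr_per_tf = []
    for j, tf in enumerate(tfs):
        a, m = A[j], M[j]
        if a.std() == 0 or m.std() == 0:
            corr_per_tf.append(np.nan)
        else:
            corr_per_tf.append(float(np.corrcoef(a, m)[0, 1]))
    detail = pd.DataFrame({"tf": tfs, "corr": corr_per_tf})
    valid = detail["corr"].dropna()
    k = int((valid > 0).sum())
    p = float(stats.binomtest(k, len(valid), 0.5).pvalue) if len(valid) else 1.0
    return median_fraction, p, detail


def regulator_recovery_curve(
    z: StandardizedActivityMatrix,
    reference_sample: str,
    gold: Mapping[str, set[str]],
    sample_regulators: Mapping[str, str],
    thresholds: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Recovery of known regulator->TF edges from activity changes.

    In each sample where a regulator was perturbed, TFs are ranked by the
    absolute difference between their standardized log activity and its
    value in the unperturbed reference (largest change first).  The curve
    reports, for each percentile threshold, the fraction of gold edges
    whose target TF ranks at or above that percentile in its regulator's
    sample.  Gold targets absent from the activity matrix are excluded
    and counted in the coverage report.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 100.0, 101)
    Z = z.z
    n_tfs = len(Z.index)
    ref = Z[reference_sample]
    percentiles: list[float] = []
    missing: list[tuple[str, str]] = []
    for s, regulator in sample_regulators.items():
        targets = gold.get(regulator, set())
        if not targets:
            continue
        delta = (Z[s] - ref).abs()
        ranks = stats.rankdata(-delta.to_numpy())
        for t in targets:
            if t not in Z.index:
                missing.append((regulator, t))
                continue
            r = float(ranks[Z.index.get_loc(t)])
            percentiles.append(100.0 * (1.0 - (r - 1.0) / n_tfs))
    pct = np.asarray(percentiles)
    curve = pd.DataFrame(
        {
            "percentile_threshold": list(thresholds),
            "fraction_recovered": [
                float(np.mean(pct >= t)) if len(pct) else np.nan for t in thresholds
            ],
        }
    )
    coverage = {
        "n_edges_evaluated": len(pct),
        "n_edges_missing": len(missing),
        "missing": missing,
    }
    return curve, coverage


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability test: chi2 = -2 sum(ln p), df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValidationError("fisher_combine needs at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must be in (0, 1]")
    chi2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(chi2, df=2 * len(p)))


def _restandardize(df: pd.DataFrame) -> pd.DataFrame:
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    out = df.sub(mean, axis=0)
    nz = sd > 0
    out.loc[nz] = out.loc[nz].div(sd[nz], axis=0)
    out.loc[~nz] = 0.0
    return out


def average_standardized_tfas(
    z_list: Sequence[StandardizedActivityMatrix],
) -> StandardizedActivityMatrix:
    """Average standardized activities across networks.

    TFs present in several matrices get the elementwise mean of their z
    rows; TFs present in one pass through.  Rows are re-standardized so
    the output is again a z-score matrix.
    """
    if not z_list:
        raise ValidationError("no matrices to average")
    shared = set(z_list[0].sample_ids)
    for z in z_list[1:]:
        shared &= set(z.sample_ids)
    if not shared:
        raise ValidationError("disjoint sample sets; nothing to average")
    samples = [s for s in z_list[0].sample_ids if s in shared]
    all_tfs: list[str] = []
    for z in z_list:
        for tf in z.tf_ids:
            if tf not in all_tfs:
                all_tfs.append(tf)
    rows = {}
    for tf in all_tfs:
        stack = [z.z.loc[tf, samples] for z in z_list if tf in z.z.index]
        rows[tf] = pd.concat(stack, axis=1).mean(axis=1)
    out = pd.DataFrame(rows).T.loc[all_tfs, samples]
    return StandardizedActivityMatrix(_restandardize(out))


def bootstrap_cs_correlation(
    cs_a: ControlStrengthMatrix,
    covariate,
    net: NetworkMap,
    min_targets: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, dict]:
    """Per-TF bootstrap correlation of control strengths with a covariate.

    ``covariate`` is either a second :class:`ControlStrengthMatrix`
    (condition-independence check between two fits) or a per-target
    mapping/Series of real values (e.g. promoter binding-event counts).
    For each TF with at least ``min_targets`` targets, its target set is
    resampled with replacement ``n_boot`` times; the TF's score is the
    median Pearson correlation across resamples.  Returns the per-TF
    scores and a summary with the median score and the fraction of TFs
    scoring positive.
    """
    rng = np.random.default_rng(seed)

    def cov_value(tf: str, g: str) -> float | None:
        if isinstance(covariate, ControlStrengthMatrix):
            if g in covariate.cs.index and tf in covariate.cs.columns:
                return float(covariate.cs.loc[g, tf])
            return None
        v = covariate.get(g) if hasattr(covariate, "get") else None
        return None if v is None else float(v)

    scores = {}
    for tf in net.tfs:
        if tf not in cs_a.cs.columns:
            continue
        pairs = [
            (float(cs_a.cs.loc[g, tf]), cov_value(tf, g))
            for g in sorted(net.targets_of(tf))
            if g in cs_a.cs.index
        ]
        pairs = [(a, c) for a, c in pairs if c is not None]
        if len(pairs) < min_targets:
            continue
        a = np.array([p[0] for p in pairs])
        c = np.array([p[1] for p in pairs])
        n = len(a)
        rs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if a[idx].std() == 0 or c[idx].std() == 0:
                continue
            rs.append(float(np.corrcoef(a[idx], c[idx])[0, 1]))
        if rs:
            scores[tf] = float(np.median(rs))
    per_tf = pd.Series(scores, name="median_corr", dtype=float)
    summary = {
        "n_tfs": len(per_tf),
        "median_of_medians": float(per_tf.median()) if len(per_tf) else np.nan,
        "fraction_positive": float((per_tf > 0).mean()) if len(per_tf) else np.nan,
    }
    return per_tf, summary
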