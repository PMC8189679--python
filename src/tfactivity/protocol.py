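"""Three-stage train/refit/evaluate benchmark protocol.

Stage 1 builds a network and sign constraints from dataset 1 and fits the
bilinear model to its expression (using only samples in which a network
TF was perturbed, plus unperturbed samples).  Stage 2 holds the learned
control strengths fixed and refits activities and baselines to dataset
2's expression — all of its samples, but never its perturbation key, so
stage 3 can use that key as independent evaluation data.  The roles of
the two datasets are then swapped and the two directions' metrics are
combined: fractions and percentiles by arithmetic mean, p-values by
Fisher's combined probability test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Union

import pandas as pd

from .constraints import correlation_signs, perturbation_signs
from .containers import (
    ExpressionMatrix,
    NetworkMap,
    PerturbationKey,
    RankedEdgeList,
    SignConstraintMatrix,
)
from .evaluation import (
    MetricsReport,
    direction_metric,
    fisher_combine,
    positive_correlation_metric,
    rank_percentile_metric,
    standardize_activities,
)
from .factorization import (
    FitConfig,
    fit_model,
    refit_activities,
    signed_binary_cs,
)
from .network import NetworkBuildConfig, build_network

__all__ = ["Dataset", "ProtocolResult", "run_protocol", "evaluate_activities"]

SignMode = Literal["correlation", "perturbation"]
CSMode = Literal["optimized", "signed_binary"]


class Dataset(NamedTuple):
    expr: ExpressionMatrix
    key: PerturbationKey
    tf_mrna: ExpressionMatrix


@dataclass
class ProtocolResult:
    per_direction: tuple[MetricsReport, MetricsReport]
    combined: MetricsReport


def evaluate_activities(
    tfa,
    key: PerturbationKey,
    tf_mrna: ExpressionMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    floor: float = 1e-4,
) -> MetricsReport:
    """All three core metrics for an activity matrix against a key."""
    key = key.restrict_to_tfs(tfa.tf_ids)
    frac, p_dir, dir_detail = direction_metric(tfa, key)
    z = standardize_activities(tfa, floor)
    med, p_rank, rank_detail = rank_percentile_metric(z, key)
    corr_frac, p_corr, corr_detail = positive_correlation_metric(
        tfa, tf_mrna, n_boot=n_boot, seed=seed
    )
    per_tf = (
        dir_detail.groupby("tf")["correct"]
        .mean()
        .rename("direction_correct")
        .to_frame()
        .join(rank_detail.groupby("tf")["rank_percentile"].mean())
        .join(corr_detail.set_index("tf")["corr"])
        .reset_index()
    )
    return MetricsReport(
        direction_fraction=frac,
        direction_p=p_dir,
        median_rank_percentile=med,
        rank_p=p_rank,
        positive_corr_fraction=corr_frac,
        corr_p=p_corr,
        per_tf_detail=per_tf,
    )


def _one_direction(
    train: Dataset,
    test: Dataset,
    net_source: Union[NetworkMap, RankedEdgeList],
    sign_mode: SignMode,
    cs_mode: CSMode,
    config: FitConfig,
    net_config: NetworkBuildConfig,
    n_boot: int,
    use_holdout: bool,
) -> MetricsReport:
    if isinstance(net_source, RankedEdgeList):
        net = build_network(net_source, net_config)
    else:
        net = net_source
    if sign_mode == "correlation":
        signs: SignConstraintMatrix = correlation_signs(train.expr, train.tf_mrna, net)
    elif sign_mode == "perturbation":
        signs = perturbation_signs(train.expr, train.key, net)
    else:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")

    if cs_mode == "optimized":
        holdout = test.expr if use_holdout else None
        result = fit_model(train.expr, net, signs, train.key, config, holdout=holdout)
        cs = result.cs
    elif cs_mode == "signed_binary":
        cs = signed_binary_cs(signs)
    else:
        raise ValueError(f"unknown cs_mode {cs_mode!r}")

    # stage 2: the test key is deliberately not passed — only the generic
    # activity floor constrains the refit
    tfa, _, _ = refit_activities(test.expr, cs, floor=config.floor)
    return evaluate_activities(
        tfa, test.key, test.tf_mrna, n_boot=n_boot, seed=config.seed, floor=config.floor
    )


def run_protocol(
    ds1: Dataset,
    ds2: Dataset,
    net_source: Union[NetworkMap, RankedEdgeList, tuple],
    sign_mode: SignMode = "perturbation",
    cs_mode: CSMode = "optimized",
    config: FitConfig | None = None,
    net_config: NetworkBuildConfig | None = None,
    n_boot: int = 1000,
    use_holdout: bool = True,
) -> ProtocolResult:
    """Run the full two-direction benchmark and combine the metrics.

    ``net_source`` is a prebuilt :class:`NetworkMap`, a
    :class:`RankedEdgeList` (the network is then built per direction from
    the training data side), or a pair of either (one per direction).
    ``use_holdout=False`` disables holdout-peak early stopping (the
    training-convergence criterion applies instead).
    """
    config = config or FitConfig()
    net_config = net_config or NetworkBuildConfig()
    if isinstance(net_source, tuple) and len(net_source) == 2 and not isinstance(
        net_source, RankedEdgeList
    ):
        sources = net_source
    else:
        sources = (net_source, net_source)
    rep1 = _one_direction(
        ds1, ds2, sources[0], sign_mode, cs_mode, config, net_config, n_boot, use_holdout
    )
    rep2 = _one_direction(
        ds2, ds1, sources[1], sign_mode, cs_mode, config, net_config, n_boot, use_holdout
    )
    combined = MetricsReport(
        direction_fraction=(rep1.direction_fraction + rep2.direction_fraction) / 2,
        direction_p=fisher_combine([rep1.direction_p, rep2.direction_p]),
        median_rank_percentile=(
            rep1.median_rank_percentile + rep2.median_rank_percentile
        )
        / 2,
        rank_p=fisher_combine([rep1.rank_p, rep2.rank_p]),
        positive_corr_fraction=(
            rep1.positive_corr_fraction + rep2.positive_corr_fraction
        )
        / 2,
        corr_p=fisher_combine([rep1.corr_p, rep2.corr_p]),
        per_tf_detail=pd.concat(
            [
                rep1.per_tf_detail.assign(direction_run=1),
                rep2.per_tf_detail.assign(direction_run=2),
            ],
            ignore_index=True,
        ),
    )
    return ProtocolResult(per_direction=(rep1, rep2), combined=combined)
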