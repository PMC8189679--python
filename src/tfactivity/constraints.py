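"""Sign constraints on control strengths and bounds on activities.

Control-strength signs come either from the correlation between a TF's
mRNA and each target's expression (correlation constraints) or from the
direction in which a target moves when the TF is directly perturbed
(perturbation constraints).  Activity bounds encode the perturbation key:
a deleted TF's activity is pinned at zero in that sample, an
overexpressed TF's activity must exceed its activity in the unperturbed
reference sample, and every other activity sits above a small positive
floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DELETION,
    ExpressionMatrix,
    NetworkMap,
    OVEREXPRESSION,
    PerturbationKey,
    SignConstraintMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityBounds",
    "correlation_signs",
    "perturbation_signs",
    "activity_bounds",
    "DEFAULT_FLOOR",
]

DEFAULT_FLOOR = 1e-4


@dataclass(frozen=True)
class ActivityBounds:
    """Box bounds on the TFA matrix, with deferred overexpression floors.

    ``deferred`` maps (tf, sample) to the reference sample whose *fitted*
    activity sets that entry's lower bound at solve time (the bound is
    reference activity + floor, since a strict inequality is not
    expressible in bounded least squares).
    """

    lower: pd.DataFrame  # tfs x samples
    upper: pd.DataFrame
    floor: float = DEFAULT_FLOOR
    deferred: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValidationError("activity floor must be positive")
        if (self.lower.to_numpy() > self.upper.to_numpy()).any():
            raise ValidationError("activity lower bound exceeds upper bound")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.lower.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lower.columns)

    def is_fixed_zero(self, tf: str, sample: str) -> bool:
        return (
            self.lower.loc[tf, sample] == 0.0 and self.upper.loc[tf, sample] == 0.0
        )

    @staticmethod
    def floor_only(
        tfs: list[str], samples: list[str], floor: float = DEFAULT_FLOOR
    ) -> "ActivityBounds":
        lower = pd.DataFrame(floor, index=tfs, columns=samples)
        upper = pd.DataFrame(np.inf, index=tfs, columns=samples)
        return ActivityBounds(lower, upper, floor)


def correlation_signs(
    expr: ExpressionMatrix,
    tf_mrna: ExpressionMatrix,
    net: NetworkMap,
) -> SignConstraintMatrix:
    """Sign each edge by the Pearson correlation between the TF's mRNA and
    the target's expression across all samples, significant or not.

    An exactly zero correlation defaults to +1 (activation is the majority
    class in the networks this models) with a logged warning.
    """
    samples = [s for s in expr.sample_ids if s in set(tf_mrna.sample_ids)]
    if len(samples) < 3:
        raise ValidationError("need >=3 shared samples for correlation signs")
    E = expr.data.loc[:, samples]
    M = tf_mrna.data.loc[:, samples]
    edge_signs: dict[tuple[str, str], int] = {}
    for tf in net.tfs:
        if tf not in M.index:
            raise ValidationError(f"tf_mrna is missing TF row {tf!r}")
        m = M.loc[tf].to_numpy()
        if np.std(m) == 0:
            raise ValidationError(f"zero-variance mRNA row for TF {tf!r}")
        for g in net.targets_of(tf):
            if g not in E.index:
                raise ValidationError(f"expression is missing target row {g!r}")
            e = E.loc[g].to_numpy()
            if np.std(e) == 0:
                raise ValidationError(f"zero-variance expression row for {g!r}")
            r = float(np.corrcoef(m, e)[0, 1])
            if r == 0.0:
                logger.warning(
                    "zero correlation on edge (%s, %s); defaulting to +1", tf, g
                )
                edge_signs[(tf, g)] = 1
            else:
                edge_signs[(tf, g)] = 1 if r > 0 else -1
    return SignConstraintMatrix.from_edge_signs(edge_signs, net)


def perturbation_signs(
    expr: ExpressionMatrix,
    key: PerturbationKey,
    net: NetworkMap,
    reference: str | None = None,
) -> SignConstraintMatrix:
    """Sign each edge by the direction the target moves under perturbation.

    For a deletion sample, a drop in the target (delta < 0) implies
    activation (+1); for overexpression, a rise implies activation.  When
    a TF has several perturbation samples they vote through the mean of
    the direction-oriented deltas.  A zero net delta defaults to +1 with a
    logged warning.
    """
    ref = reference if reference is not None else key.reference_sample
    E = expr.data
    edge_signs: dict[tuple[str, str], int] = {}
    for tf in net.tfs:
        samples = key.samples_perturbing(tf)
        if not samples:
            raise ValidationError(f"TF {tf!r} has no perturbation sample in key")
        for g in net.targets_of(tf):
            if g not in E.index:
                raise ValidationError(f"expression is missing target row {g!r}")
            evidence = []
            for s in samples:
                delta = E.loc[g, s] - E.loc[g, ref]
                _, direction = key.records[s]
                evidence.append(-delta if direction == DELETION else delta)
            net_effect = float(np.mean(evidence))
            if net_effect == 0.0:
                logger.warning(
                    "zero perturbation delta on edge (%s, %s); defaulting to +1",
                    tf,
                    g,
                )
                edge_signs[(tf, g)] = 1
            else:
                edge_signs[(tf, g)] = 1 if net_effect > 0 else -1
    return SignConstraintMatrix.from_edge_signs(edge_signs, net)


def activity_bounds(
    key: PerturbationKey,
    tfs: list[str],
    samples: list[str],
    floor: float = DEFAULT_FLOOR,
    reference: str | None = None,
) -> ActivityBounds:
    """Per-entry activity bounds implied by a perturbation key.

    Deletion entries are pinned at [0, 0]; overexpression entries get a
    deferred lower bound resolved to (fitted reference activity + floor)
    during the activity step; everything else is [floor, +inf).
    """
    lower = pd.DataFrame(floor, index=tfs, columns=samples, dtype=float)
    upper = pd.DataFrame(np.inf, index=tfs, columns=samples)
    deferred: dict[tuple[str, str], str] = {}
    tf_set = set(tfs)
    sample_set = set(samples)
    for s, (tf, direction) in key.records.items():
        if s not in sample_set or tf not in tf_set:
            continue
        if direction == DELETION:
            lower.loc[tf, s] = 0.0
            upper.loc[tf, s] = 0.0
        elif direction == OVEREXPRESSION:
            ref = reference if reference is not None else key.reference_sample
            if ref not in sample_set:
                raise ValidationError(
                    f"overexpression in {s!r} but reference {ref!r} not in samples"
                )
            deferred[(tf, s)] = ref
    return ActivityBounds(lower, upper, floor, deferred)
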