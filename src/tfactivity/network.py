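"""Qualitative TF network construction from globally ranked edge lists.

Edges arrive ranked by evidence strength (e.g. -log10 binding p-value, or
absolute log fold change of the target under TF perturbation).  A network
of ``n_tfs`` TFs is built by walking the ranking: edges are taken in rank
order until ``n_tfs`` distinct TFs are represented, lower-ranked edges of
those TFs are then added down to ``max_rank``, and the result is pruned —
single-target TFs are dropped, and any group of TFs with identical target
sets is dropped together with the shared targets (such TFs are
statistically indistinguishable in the bilinear model).  Pruning can
evict TFs, so the selection returns to the ranked list, admits
previously passed-over edges (evicted TFs stay excluded), and re-prunes
until the TF set is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .containers import NetworkMap, RankedEdgeList, SignConstraintMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkBuildConfig",
    "build_network",
    "prune_network",
    "select_block",
    "merge_networks",
]

_MAX_ROUNDS = 25


@dataclass(frozen=True)
class NetworkBuildConfig:
    n_tfs: int = 50
    max_rank: int = 1250
    block_size: int = 2000

    def __post_init__(self) -> None:
        if self.n_tfs < 2:
            raise ValueError("n_tfs must be >= 2")
        if self.max_rank < self.n_tfs:
            raise ValueError("max_rank must be >= n_tfs")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


def _prune_dict(by_tf: dict[str, set[str]]) -> dict[str, set[str]]:
    """Single-target and identical-target-set removal, to a fixed point."""
    by_tf = {tf: set(t) for tf, t in by_tf.items()}
    changed = True
    while changed:
        changed = False
        # TFs left with fewer than two targets carry no usable signal
        few = [tf for tf, t in by_tf.items() if len(t) < 2]
        for tf in few:
            del by_tf[tf]
            changed = True
        # groups of TFs with identical target sets are unidentifiable;
        # drop them and their shared targets from the whole network
        groups: dict[frozenset[str], list[str]] = {}
        for tf, t in by_tf.items():
            groups.setdefault(frozenset(t), []).append(tf)
        doomed_targets: set[str] = set()
        for tgset, tfs in groups.items():
            if len(tfs) >= 2:
                for tf in tfs:
                    del by_tf[tf]
                doomed_targets |= tgset
                changed = True
        if doomed_targets:
            for t in by_tf.values():
                t -= doomed_targets
    return by_tf


def prune_network(net: NetworkMap) -> NetworkMap:
    """Remove single-target TFs and identical-target-set TF groups (with
    their shared targets), repeating until neither rule fires.  Idempotent;
    may return an empty network."""
    by_tf = {tf: set(t) for tf, t in net.targets_by_tf.items()}
    return NetworkMap({tf: frozenset(t) for tf, t in _prune_dict(by_tf).items()})


def _select_pass(
    ranked: RankedEdgeList, n_tfs: int, max_rank: int, banned: set[str]
) -> dict[str, set[str]]:
    """One selection pass: take edges in rank order until n_tfs distinct
    (non-banned) TFs appear, then keep only those TFs' edges to max_rank."""
    by_tf: dict[str, set[str]] = {}
    rows = ranked.edges.iloc[: min(max_rank, len(ranked.edges))]
    for tf, target in zip(rows["tf"], rows["target"]):
        if tf in banned:
            continue
        if len(by_tf) < n_tfs or tf in by_tf:
            by_tf.setdefault(tf, set()).add(target)
    return by_tf


def build_network(ranked: RankedEdgeList, config: NetworkBuildConfig) -> NetworkMap:
    """Build a pruned ``n_tfs``-TF network from a ranked edge list.

    Raises ``ValueError`` if fewer than ``n_tfs`` distinct TFs occur within
    ``max_rank``.  If pruning prevents the TF set from stabilizing at
    exactly ``n_tfs``, the stable network is returned and the achieved TF
    count is logged.
    """
    first = _select_pass(ranked, config.n_tfs, config.max_rank, set())
    if len(first) < config.n_tfs:
        raise ValueError(
            f"only {len(first)} distinct TFs within rank {config.max_rank}; "
            f"{config.n_tfs} requested"
        )
    banned: set[str] = set()
    by_tf = first
    for _ in range(_MAX_ROUNDS):
        pruned = _prune_dict(by_tf)
        evicted = set(by_tf) - set(pruned)
        if not evicted:
            by_tf = pruned
            break
        banned |= evicted
        by_tf = _select_pass(ranked, config.n_tfs, config.max_rank, banned)
    else:
        logger.warning("network did not stabilize within %d rounds", _MAX_ROUNDS)
        by_tf = _prune_dict(by_tf)
    if len(by_tf) != config.n_tfs:
        logger.warning(
            "network stabilized at %d TFs (requested %d)", len(by_tf), config.n_tfs
        )
    return NetworkMap({tf: frozenset(t) for tf, t in by_tf.items()})


def select_block(
    ranked: RankedEdgeList, block_index: int, config: NetworkBuildConfig
) -> NetworkMap:
    """Build a network from one fixed-rank block of the edge list.

    Block 1 covers ranks 1..block_size, block 4 covers
    3*block_size+1..4*block_size, and so on; the standard build procedure
    then runs within the block.
    """
    if block_index < 1:
        raise ValueError("block_index is 1-based and must be >= 1")
    start = (block_index - 1) * config.block_size
    stop = block_index * config.block_size
    if start >= len(ranked):
        raise ValueError(
            f"block {block_index} is empty: list has {len(ranked)} edges"
        )
    block = ranked.slice_ranks(start, stop)
    cfg = NetworkBuildConfig(
        n_tfs=config.n_tfs, max_rank=len(block), block_size=config.block_size
    )
    return build_network(block, cfg)


def merge_networks(
    nets: list[tuple[NetworkMap, SignConstraintMatrix]],
) -> tuple[NetworkMap, SignConstraintMatrix]:
    """Union signed networks, dropping sign-conflicted edges.

    Edges whose activation/repression sign differs between inputs are
    removed; TFs then left with a single target are removed together with
    that target gene, repeatedly, until stable.
    """
    if len(nets) < 2:
        raise ValueError("merge_networks needs at least two signed networks")
    edge_signs: dict[tuple[str, str], int] = {}
    conflicted: set[tuple[str, str]] = set()
    for net, signs in nets:
        for tf, targets in net.targets_by_tf.items():
            for g in targets:
                s = signs.sign_of(tf, g)
                prev = edge_signs.get((tf, g))
                if prev is not None and prev != s:
                    conflicted.add((tf, g))
                edge_signs.setdefault((tf, g), s)
    for e in conflicted:
        del edge_signs[e]
    by_tf: dict[str, set[str]] = {}
    for tf, g in edge_signs:
        by_tf.setdefault(tf, set()).add(g)
    # single-target removal cascades; the orphaned target gene leaves the
    # network entirely, which can strand further TFs
    changed = True
    while changed:
        changed = False
        doomed_targets: set[str] = set()
        for tf in list(by_tf):
            if len(by_tf[tf]) < 2:
                doomed_targets |= by_tf.pop(tf)
                changed = True
        if doomed_targets:
            for t in by_tf.values():
                t -= doomed_targets
    merged = NetworkMap({tf: frozenset(t) for tf, t in by_tf.items()})
    surviving = {
        (tf, g): edge_signs[(tf, g)]
        for tf, targets in merged.targets_by_tf.items()
        for g in targets
    }
    return merged, SignConstraintMatrix.from_edge_signs(surviving, merged)
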