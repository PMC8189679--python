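"""Tab-separated readers and writers for the on-disk formats.

One dialect everywhere: UTF-8, tab-separated, '.' decimal, header row.
Readers validate against the target container's invariants and raise
:class:`~tfactivity.containers.ValidationError` naming the offending
entity; missing values are rejected (the supported expression matrices
are complete).
"""

from __future__ import annotations

import os
from typing import Union

import pandas as pd

from .containers import (
    ActivityMatrix,
    ControlStrengthMatrix,
    ExpressionMatrix,
    NetworkMap,
    PerturbationKey,
    RankedEdgeList,
    SignConstraintMatrix,
    ValidationError,
)

PathLike = Union[str, os.PathLike]

_DIRECTIONS = {"deletion", "overexpression", "none"}


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV (first column: gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as e:
        raise ValidationError(f"non-numeric expression cell in {path}: {e}") from e
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        gene = df.index[df[col].isna()][0]
        raise ValidationError(
            f"missing expression value at gene {gene!r}, sample {col!r}"
        )
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_ranked_edges(path: PathLike, allow_self_edges: bool = False) -> RankedEdgeList:
    """Read a tf/target/score TSV; output is ranked by descending score
    with file order preserved among ties."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    for col in ("tf", "target", "score"):
        if col not in df.columns:
            raise ValidationError(f"edge list {path} missing column {col!r}")
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return RankedEdgeList(df, allow_self_edges=allow_self_edges)


def write_ranked_edges(ranked: RankedEdgeList, path: PathLike) -> None:
    ranked.edges.to_csv(path, sep="\t", index=False)


def read_perturbation_key(path: PathLike) -> PerturbationKey:
    """Read a sample/tf/direction TSV; direction 'none' marks unperturbed."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample", "tf", "direction"):
        if col not in df.columns:
            raise ValidationError(f"perturbation key {path} missing column {col!r}")
    records: dict[str, tuple[str, str]] = {}
    unperturbed: list[str] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        s, tf, d = row["sample"], row["tf"], row["direction"]
        if s in seen:
            raise ValidationError(f"sample {s!r} listed twice in key")
        seen.add(s)
        if d not in _DIRECTIONS:
            raise ValidationError(f"unknown direction {d!r} for sample {s!r}")
        if d == "none":
            unperturbed.append(s)
        else:
            records[s] = (tf, d)  # type: ignore[assignment]
    return PerturbationKey(records, tuple(unperturbed))


def write_perturbation_key(key: PerturbationKey, path: PathLike) -> None:
    rows = [
        {"sample": s, "tf": tf, "direction": d}
        for s, (tf, d) in key.records.items()
    ]
    rows += [
        {"sample": s, "tf": "", "direction": "none"}
        for s in key.unperturbed_samples
    ]
    pd.DataFrame(rows, columns=["sample", "tf", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path: PathLike) -> NetworkMap:
    """Read a tf/target TSV into a NetworkMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tf", "target"):
        if col not in df.columns:
            raise ValidationError(f"network {path} missing column {col!r}")
    return NetworkMap.from_edges(zip(df["tf"], df["target"]))


def write_network(net: NetworkMap, path: PathLike) -> None:
    rows = [
        {"tf": tf, "target": g}
        for tf in net.tfs
        for g in sorted(net.targets_of(tf))
    ]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_signs(path: PathLike) -> SignConstraintMatrix:
    """Read a tf/target/sign TSV; the companion network is implied by the
    listed edges."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    for col in ("tf", "target", "sign"):
        if col not in df.columns:
            raise ValidationError(f"sign file {path} missing column {col!r}")
    net = NetworkMap.from_edges(zip(df["tf"], df["target"]))
    edge_signs = {
        (row.tf, row.target): int(row.sign) for row in df.itertuples()
    }
    return SignConstraintMatrix.from_edge_signs(edge_signs, net)


def write_signs(signs: SignConstraintMatrix, path: PathLike) -> None:
    rows = [
        {"tf": tf, "target": g, "sign": signs.sign_of(tf, g)}
        for tf in signs.network.tfs
        for g in sorted(signs.network.targets_of(tf))
    ]
    pd.DataFrame(rows, columns=["tf", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_control_strengths(
    cs_path: PathLike, baselines_path: PathLike
) -> ControlStrengthMatrix:
    cs = pd.read_csv(cs_path, sep="\t", index_col=0, float_precision="round_trip")
    cs.index = cs.index.astype(str)
    cs.index.name = None
    b = pd.read_csv(baselines_path, sep="\t", index_col=0, float_precision="round_trip")["baseline"]
    b.index = b.index.astype(str)
    return ControlStrengthMatrix(cs, b.loc[cs.index])


def write_control_strengths(
    cs: ControlStrengthMatrix, cs_path: PathLike, baselines_path: PathLike
) -> None:
    cs.cs.to_csv(cs_path, sep="\t", index_label="gene")
    cs.baselines.rename("baseline").to_csv(
        baselines_path, sep="\t", index_label="gene"
    )


def read_activities(path: PathLike) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ActivityMatrix(df)


def write_activities(tfa: ActivityMatrix, path: PathLike) -> None:
    tfa.activities.to_csv(path, sep="\t", index_label="tf")
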