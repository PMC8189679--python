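"""Core domain containers for TF activity inference.

The model factors a log2 expression matrix ``E`` (genes x samples) as

    E = CS . TFA

where ``CS`` (genes x TFs, augmented with per-gene baselines) holds
condition-independent control strengths whose signs encode activation (+)
or repression (-), and ``TFA`` (TFs x samples) holds non-negative,
condition-dependent TF activity levels.  All containers index by
identifier (gene, TF or sample name), never by position, so positional
misalignment cannot be expressed at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "RankedEdgeList",
    "NetworkMap",
    "SignConstraintMatrix",
    "PerturbationKey",
    "ControlStrengthMatrix",
    "ActivityMatrix",
    "Direction",
    "DELETION",
    "OVEREXPRESSION",
]

Direction = Literal["deletion", "overexpression"]
DELETION: Direction = "deletion"
OVEREXPRESSION: Direction = "overexpression"


class ValidationError(ValueError):
    """An input violated a container invariant; the message names the entity."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values, genes x samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a DataFrame")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            i, k = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.data.index[i]!r}, "
                f"sample {self.data.columns[k]!r}"
            )
        object.__setattr__(self, "data", self.data.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])


@dataclass(frozen=True)
class RankedEdgeList:
    """TF -> target edges with evidence scores, ranked by descending score.

    Ties keep input order (stable).  Self-edges are rejected unless
    ``allow_self_edges`` is set.
    """

    edges: pd.DataFrame  # columns: tf, target, score
    allow_self_edges: bool = False

    def __post_init__(self) -> None:
        df = self.edges
        for col in ("tf", "target", "score"):
            if col not in df.columns:
                raise ValidationError(f"edge list missing column {col!r}")
        df = df.loc[:, ["tf", "target", "score"]].copy()
        if df["score"].isna().any():
            bad = df.index[df["score"].isna()][0]
            raise ValidationError(f"missing score for edge row {bad}")
        dup = df.duplicated(subset=["tf", "target"])
        if dup.any():
            r = df.loc[dup.idxmax()]
            raise ValidationError(f"duplicate edge ({r.tf!r}, {r.target!r})")
        if not self.allow_self_edges:
            selfe = df["tf"] == df["target"]
            if selfe.any():
                raise ValidationError(
                    f"self-edge not allowed: {df.loc[selfe.idxmax(), 'tf']!r}"
                )
        df = df.sort_values("score", ascending=False, kind="stable")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "edges", df)

    def __len__(self) -> int:
        return len(self.edges)

    def head(self, n: int) -> "RankedEdgeList":
        return RankedEdgeList(self.edges.iloc[:n], self.allow_self_edges)

    def slice_ranks(self, start: int, stop: int) -> "RankedEdgeList":
        """Edges with 1-based rank in (start, stop]."""
        return RankedEdgeList(self.edges.iloc[start:stop], self.allow_self_edges)


@dataclass(frozen=True)
class NetworkMap:
    """Qualitative TF network map: the set of potential direct targets per TF.

    Invariant: every TF has at least two targets (a single-target TF carries
    no information that the baseline cannot absorb).
    """

    targets_by_tf: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for tf, tgts in self.targets_by_tf.items():
            tgts = frozenset(tgts)
            if len(tgts) < 2:
                raise ValidationError(f"TF {tf!r} has fewer than 2 targets")
            clean[tf] = tgts
        object.__setattr__(self, "targets_by_tf", clean)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.targets_by_tf)

    @property
    def targets(self) -> list[str]:
        out: set[str] = set()
        for t in self.targets_by_tf.values():
            out |= t
        return sorted(out)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {
            (tf, g) for tf, tgts in self.targets_by_tf.items() for g in tgts
        }

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.targets_by_tf.values())

    def has_edge(self, tf: str, target: str) -> bool:
        return target in self.targets_by_tf.get(tf, frozenset())

    def targets_of(self, tf: str) -> frozenset[str]:
        return self.targets_by_tf[tf]

    def regulators_of(self, gene: str) -> list[str]:
        return [tf for tf, t in self.targets_by_tf.items() if gene in t]

    @staticmethod
    def from_edges(edges: Iterable[tuple[str, str]]) -> "NetworkMap":
        by_tf: dict[str, set[str]] = {}
        for tf, g in edges:
            by_tf.setdefault(tf, set()).add(g)
        return NetworkMap({tf: frozenset(t) for tf, t in by_tf.items()})


@dataclass(frozen=True)
class SignConstraintMatrix:
    """Sign constraints on control strengths: +1 activation, -1 repression.

    Nonzero exactly on the companion network's edges.
    """

    signs: pd.DataFrame  # genes x tfs, values in {-1, 0, +1}
    network: NetworkMap

    def __post_init__(self) -> None:
        df = self.signs.astype(int)
        vals = set(np.unique(df.to_numpy()))
        if not vals <= {-1, 0, 1}:
            raise ValidationError(f"sign values outside {{-1,0,+1}}: {vals}")
        for tf in self.network.tfs:
            if tf not in df.columns:
                raise ValidationError(f"sign matrix missing TF column {tf!r}")
        for tf, tgts in self.network.targets_by_tf.items():
            col = df[tf]
            for g in tgts:
                if g not in df.index:
                    raise ValidationError(f"sign matrix missing gene row {g!r}")
                if col.loc[g] == 0:
                    raise ValidationError(
                        f"zero sign on network edge ({tf!r}, {g!r})"
                    )
            off = col.index.difference(list(tgts))
            nz = col.loc[off] != 0
            if nz.any():
                g = nz.idxmax()
                raise ValidationError(
                    f"nonzero sign off network for ({tf!r}, {g!r})"
                )
        object.__setattr__(self, "signs", df)

    @staticmethod
    def from_edge_signs(
        edge_signs: Mapping[tuple[str, str], int], network: NetworkMap
    ) -> "SignConstraintMatrix":
        genes = network.targets
        tfs = network.tfs
        df = pd.DataFrame(0, index=genes, columns=tfs, dtype=int)
        for (tf, g), s in edge_signs.items():
            df.loc[g, tf] = int(s)
        return SignConstraintMatrix(df, network)

    def sign_of(self, tf: str, target: str) -> int:
        return int(self.signs.loc[target, tf])


@dataclass(frozen=True)
class PerturbationKey:
    """Maps each perturbation sample to its perturbed TF and direction."""

    records: Mapping[str, tuple[str, Direction]]
    unperturbed_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        recs = dict(self.records)
        for s, (tf, d) in recs.items():
            if d not in (DELETION, OVEREXPRESSION):
                raise ValidationError(f"unknown direction {d!r} for sample {s!r}")
            if s in self.unperturbed_samples:
                raise ValidationError(
                    f"sample {s!r} both perturbed and unperturbed"
                )
        _check_unique(self.unperturbed_samples, "unperturbed sample")
        object.__setattr__(self, "records", recs)
        object.__setattr__(
            self, "unperturbed_samples", tuple(self.unperturbed_samples)
        )

    @property
    def samples(self) -> list[str]:
        return list(self.records) + list(self.unperturbed_samples)

    @property
    def reference_sample(self) -> str:
        """Designated unperturbed reference: first by sample order."""
        if not self.unperturbed_samples:
            raise ValidationError("perturbation key has no unperturbed sample")
        return self.unperturbed_samples[0]

    def perturbed_tfs(self) -> set[str]:
        return {tf for tf, _ in self.records.values()}

    def samples_perturbing(self, tf: str) -> list[str]:
        return [s for s, (t, _) in self.records.items() if t == tf]

    def restrict_to_tfs(self, tfs: Iterable[str]) -> "PerturbationKey":
        tfs = set(tfs)
        recs = {s: r for s, r in self.records.items() if r[0] in tfs}
        return PerturbationKey(recs, self.unperturbed_samples)


@dataclass(frozen=True)
class ControlStrengthMatrix:
    """Fitted control strengths (genes x TFs) plus per-gene baselines."""

    cs: pd.DataFrame
    baselines: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.cs.to_numpy(dtype=float))):
            raise ValidationError("non-finite control strength")
        if not np.all(np.isfinite(self.baselines.to_numpy(dtype=float))):
            raise ValidationError("non-finite baseline")
        if list(self.cs.index) != list(self.baselines.index):
            raise ValidationError("cs rows and baselines must share gene ids")
        object.__setattr__(self, "cs", self.cs.astype(float))
        object.__setattr__(self, "baselines", self.baselines.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cs.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.cs.columns)

    def validate_against(
        self, network: NetworkMap, signs: SignConstraintMatrix | None = None
    ) -> None:
        for tf in self.tf_ids:
            tgts = network.targets_by_tf.get(tf, frozenset())
            col = self.cs[tf]
            off = col.index.difference(list(tgts))
            bad = col.loc[off] != 0
            if bad.any():
                raise ValidationError(
                    f"nonzero CS off network: ({tf!r}, {bad.idxmax()!r})"
                )
            if signs is not None:
                for g in tgts:
                    if g in col.index and col.loc[g] * signs.sign_of(tf, g) < 0:
                        raise ValidationError(
                            f"CS sign violates constraint on ({tf!r}, {g!r})"
                        )


@dataclass(frozen=True)
class ActivityMatrix:
    """Non-negative TF activity levels, TFs x samples."""

    activities: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.activities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite activity value")
        if (vals < 0).any():
            j, k = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative activity for TF {self.activities.index[j]!r} "
                f"in sample {self.activities.columns[k]!r}"
            )
        object.__setattr__(self, "activities", self.activities.astype(float))

    @property
    def tf_ids(self) -> list[str]:
        return list(self.activities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activities.columns)

    @property
    def values(self) -> np.ndarray:
        return self.activities.to_numpy()

    def validate_against(
        self,
        key: PerturbationKey,
        floor: float = 1e-4,
        atol: float = 1e-9,
    ) -> None:
        """Check perturbation-derived bounds: deletions exactly 0, other
        entries at or above the floor, overexpression above the reference."""
        ref = key.reference_sample
        A = self.activities
        for s, (tf, d) in key.records.items():
            if tf not in A.index or s not in A.columns:
                continue
            a = A.loc[tf, s]
            if d == DELETION:
                if a != 0.0:
                    raise ValidationError(
                        f"deleted TF {tf!r} has nonzero activity in {s!r}"
                    )
            else:
                if a + atol < A.loc[tf, ref] + floor:
                    raise ValidationError(
                        f"overexpressed TF {tf!r} activity below reference in {s!r}"
                    )
        for tf in A.index:
            for s in A.columns:
                if key.records.get(s, (None, None))[0] == tf and key.records[s][1] == DELETION:
                    continue
                if A.loc[tf, s] + atol < floor:
                    raise ValidationError(
                        f"activity of {tf!r} in {s!r} below floor {floor}"
                    )
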