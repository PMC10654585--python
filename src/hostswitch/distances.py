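"""Kimura two-parameter distances, gene-flow calls, and OTU delimitation.

The K2P distance separates transition (P) and transversion (Q)
proportions observed between two aligned sequences:

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Sites where either sequence has a gap or N are excluded pairwise
(standard for barcoding distances). Distances are proportions
internally; rendering to percentages happens only at display.

Delimitation is a barcode-gap threshold sweep: single-linkage clustering
at each candidate radius, keeping the partition that maximises the gap
between the largest within-cluster and smallest between-cluster
distance. It deliberately does not reproduce probability-scored
partition ranking.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AlignmentError, NoOverlapError, SaturationError, ValidationError
from .sequences import Alignment

__all__ = [
    "PairwiseDivergence",
    "DistanceMatrix",
    "DelimitationPartition",
    "GeneFlowCall",
    "k2p_distance",
    "k2p_matrix",
    "gene_flow_call",
    "delimit_otus",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_partition",
]

_PURINES = frozenset(b"AG")
_PYRIMIDINES = frozenset(b"CT")


@dataclass(frozen=True)
class PairwiseDivergence:
    """Transition/transversion tallies and the K2P distance for one pair."""

    P: float
    Q: float
    n_sites: int
    n_transitions: int
    n_transversions: int
    d: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1:
            raise ValidationError(f"invalid proportions P={self.P}, Q={self.Q}")

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


def k2p_distance(seq_a: str, seq_b: str) -> PairwiseDivergence:
    """K2P divergence between two aligned sequences (pairwise deletion).

    Raises :class:`SaturationError` when the observed proportions leave
    the domain of the logarithms (1 - 2P - Q <= 0 or 1 - 2Q <= 0) and
    :class:`NoOverlapError` when no comparable site remains.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    purines = np.frombuffer(b"AG", dtype="S1")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid = np.isin(a, acgt) & np.isin(b, acgt)
    n_sites = int(valid.sum())
    if n_sites == 0:
        raise NoOverlapError("no comparable (non-gap, non-N) sites")
    a, b = a[valid], b[valid]
    diff = a != b
    a_pur = np.isin(a, purines)
    b_pur = np.isin(b, purines)
    transitions = int((diff & (a_pur == b_pur)).sum())
    transversions = int((diff & (a_pur != b_pur)).sum())
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"distance undefined at P={P:.4f}, Q={Q:.4f} (saturated divergence)"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDivergence(
        P=P, Q=Q, n_sites=n_sites,
        n_transitions=transitions, n_transversions=transversions, d=d,
    )


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValidationError("negative distances")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("non-zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def permuted(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in order]
        return DistanceMatrix(tuple(order), self.values[np.ix_(idx, idx)])


def k2p_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs K2P distance matrix over an alignment."""
    labels = tuple(alignment.ids)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(alignment[labels[i]], alignment[labels[j]]).d
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


class GeneFlowCall(enum.Enum):
    ONGOING_GENE_FLOW = "ongoing_gene_flow"
    ISOLATED = "isolated"


def gene_flow_call(d: float, threshold: float = 0.05) -> GeneFlowCall:
    """Mechanical gene-flow call: ongoing iff d <= threshold (inclusive)."""
    if d < 0:
        raise ValidationError(f"negative distance {d}")
    return GeneFlowCall.ONGOING_GENE_FLOW if d <= threshold else GeneFlowCall.ISOLATED


@dataclass(frozen=True)
class DelimitationPartition:
    """OTU partition chosen by the barcode-gap sweep.

    ``gap_width`` is min between-cluster minus max within-cluster
    distance; it is None when either term does not exist (single
    cluster, or all clusters singletons).
    """

    clusters: tuple[tuple[str, ...], ...]
    threshold_used: float
    gap_width: float | None


def _single_linkage(matrix: DistanceMatrix, threshold: float) -> list[list[int]]:
    v = matrix.values
    adj = csr_matrix(v <= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(labels):
        groups.setdefault(int(c), []).append(i)
    return list(groups.values())


def _gap_width(matrix: DistanceMatrix, clusters: list[list[int]]) -> float | None:
    v = matrix.values
    n = v.shape[0]
    member = np.empty(n, dtype=int)
    for ci, idxs in enumerate(clusters):
        member[idxs] = ci
    iu, ju = np.triu_indices(n, k=1)
    same = member[iu] == member[ju]
    within = v[iu, ju][same]
    between = v[iu, ju][~same]
    if within.size == 0 or between.size == 0:
        return None
    return float(between.min() - within.max())


def delimit_otus(
    matrix: DistanceMatrix, threshold_grid: Sequence[float]
) -> DelimitationPartition:
    """Gap-maximising single-linkage partition over a threshold grid.

    Ties (equal gap) break to the smallest threshold; if no threshold
    yields a defined gap, the smallest threshold's partition is
    returned with ``gap_width=None``. A 1x1 matrix is a single cluster.
    """
    if not threshold_grid:
        raise ValidationError("threshold grid must be non-empty")
    best: tuple[float, float, list[list[int]]] | None = None  # (gap, thr, clusters)
    fallback: tuple[float, list[list[int]]] | None = None
    for thr in sorted(threshold_grid):
        clusters = _single_linkage(matrix, thr)
        gap = _gap_width(matrix, clusters)
        if fallback is None:
            fallback = (thr, clusters)
        if gap is not None and (best is None or gap > best[0]):
            best = (gap, thr, clusters)
    if best is not None:
        gap, thr, clusters = best
    else:
        thr, clusters = fallback  # type: ignore[misc]
        gap = None
    named = tuple(
        tuple(sorted(matrix.labels[i] for i in idxs)) for idxs in clusters
    )
    return DelimitationPartition(
        clusters=tuple(sorted(named)), threshold_used=thr, gap_width=gap
    )


# -- I/O -------------------------------------------------------------------

def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(Path(path), sep="\t", index_label="label")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise ValidationError(f"{path}: row and column labels disagree")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def write_partition(partition: DelimitationPartition, path: str | Path) -> None:
    rows = [
        {"label": label, "cluster": ci}
        for ci, cluster in enumerate(partition.clusters)
        for label in cluster
    ]
    pd.DataFrame(rows, columns=["label", "cluster"]).to_csv(
        Path(path), sep="\t", index=False
    )
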