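"""Distance-threshold species delimitation (mOTU clustering).

Barcodes are grouped into molecular operational taxonomic units by
single-linkage threshold clustering: two sequences belong to the same
cluster whenever they are connected by a chain of pairwise uncorrected
p-distances at or below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DataError, InsufficientOverlapError

__all__ = [
    "DistanceMatrix",
    "MOTUPartition",
    "p_distance",
    "distance_matrix",
    "objective_cluster",
    "cluster_sequences",
    "count_motus",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_MIN_OVERLAP = 100


def _encode(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences as int8 codes plus a validity mask.

    Positions holding a gap, N or any non-ACGT symbol are masked out and
    take no part in distance computation (pairwise deletion).
    """
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise DataError(f"aligned sequences must share one length, got {sorted(lengths)}")
    n, length = len(seqs), lengths.pop() if lengths else 0
    codes = np.zeros((n, length), dtype=np.int8)
    valid = np.zeros((n, length), dtype=bool)
    for i, seq in enumerate(seqs):
        for j, base in enumerate(seq.upper()):
            code = _CODE.get(base)
            if code is not None:
                codes[i, j] = code
                valid[i, j] = True
    return codes, valid


def p_distance(a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Positions with a gap or ambiguous base in either sequence are excluded
    (pairwise deletion). Raises :class:`InsufficientOverlapError` when fewer
    than ``min_overlap`` positions remain comparable.
    """
    if len(a) != len(b):
        raise DataError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    codes, valid = _encode([a, b])
    both = valid[0] & valid[1]
    compared = int(both.sum())
    if compared < min_overlap:
        raise InsufficientOverlapError(
            f"only {compared} comparable positions (< {min_overlap})"
        )
    mismatches = int((codes[0, both] != codes[1, both]).sum())
    return mismatches / compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances.

    Entries are fractions in [0, 1]; NaN marks pairs with insufficient
    overlap, which are treated as unclusterable together (no edge).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataError("matrix shape does not match label count")
        if v.size:
            if not np.allclose(np.diagonal(v), 0.0):
                raise DataError("distance matrix diagonal must be zero")
            finite = np.isfinite(v)
            if not np.array_equal(finite, finite.T) or not np.allclose(
                v[finite & finite.T], v.T[finite & finite.T]
            ):
                raise DataError("distance matrix must be symmetric")
            if np.any(v[finite] < 0) or np.any(v[finite] > 1):
                raise DataError("distances must lie in [0, 1]")


def distance_matrix(
    labels: Sequence[str],
    seqs: Sequence[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    block: int = 256,
) -> DistanceMatrix:
    """All-vs-all p-distance matrix with pairwise deletion.

    Computed in row blocks so memory stays bounded for thousands of
    sequences.
    """
    if len(labels) != len(seqs):
        raise DataError("labels and sequences differ in length")
    n = len(seqs)
    if n == 0:
        return DistanceMatrix(labels=(), values=np.zeros((0, 0)))
    codes, valid = _encode(seqs)
    out = np.zeros((n, n), dtype=float)
    for start in range(0, n, block):
        stop = min(start + block, n)
        c = codes[start:stop, None, :]  # (b, 1, L)
        v = valid[start:stop, None, :]
        both = v & valid[None, :, :]  # (b, n, L)
        compared = both.sum(axis=2)
        mism = ((c != codes[None, :, :]) & both).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(compared >= min_overlap, mism / compared, np.nan)
        out[start:stop] = d
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(labels=tuple(labels), values=out)


@dataclass(frozen=True)
class MOTUPartition:
    """Assignment of barcode labels to clusters at one distance threshold."""

    threshold: float
    assignment: dict[str, int] = field(compare=False)
    n_clusters: int = 0

    @classmethod
    def from_labels(cls, threshold: float, labels: Sequence[str], comp: Sequence[int]) -> "MOTUPartition":
        # renumber components contiguously in order of first appearance
        remap: dict[int, int] = {}
        assignment: dict[str, int] = {}
        for label, c in zip(labels, comp):
            if c not in remap:
                remap[c] = len(remap)
            assignment[label] = remap[c]
        return cls(threshold=threshold, assignment=assignment, n_clusters=len(remap))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.assignment), "cluster": list(self.assignment.values())}
        )


def objective_cluster(d: DistanceMatrix, threshold: float) -> MOTUPartition:
    """Cluster at a distance threshold (single linkage).

    Clusters are the connected components of the graph joining every pair
    with distance <= threshold. Deterministic; cluster ids are contiguous
    from 0 in order of first appearance.
    """
    if not 0 < threshold < 1:
        raise DataError(f"threshold must be in (0, 1), got {threshold}")
    n = len(d.labels)
    if n == 0:
        return MOTUPartition(threshold=threshold, assignment={}, n_clusters=0)
    with np.errstate(invalid="ignore"):
        adj = np.nan_to_num(d.values, nan=np.inf) <= threshold
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    return MOTUPartition.from_labels(threshold, d.labels, comp)


def cluster_sequences(
    labels: Sequence[str],
    seqs: Sequence[str],
    threshold: float = 0.03,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MOTUPartition:
    """Convenience wrapper: deduplicate, build the matrix, cluster, map back.

    Identical sequences are collapsed before the quadratic distance pass,
    which matters when abundant species contribute many identical barcodes.
    """
    if len(labels) != len(seqs):
        raise DataError("labels and sequences differ in length")
    uniq: dict[str, int] = {}
    rep_labels: list[str] = []
    member_of: list[int] = []
    for label, seq in zip(labels, seqs):
        idx = uniq.get(seq)
        if idx is None:
            idx = len(rep_labels)
            uniq[seq] = idx
            rep_labels.append(label)
        member_of.append(idx)
    dm = distance_matrix(rep_labels, list(uniq), min_overlap=min_overlap)
    rep_part = objective_cluster(dm, threshold)
    rep_cluster = [rep_part.assignment[lab] for lab in rep_labels]
    comp = [rep_cluster[idx] for idx in member_of]
    return MOTUPartition.from_labels(threshold, list(labels), comp)


def count_motus(
    partition: MOTUPartition,
    groups: Mapping[str, str] | pd.Series,
) -> pd.Series:
    """Number of distinct clusters represented in each group.

    ``groups`` maps each partition label to a grouping key (trap id, family
    name, or a single global key). A cluster counts once per group in which
    it has at least one member.
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    missing = [lab for lab in partition.assignment if lab not in groups]
    if missing:
        raise DataError(f"labels without metadata: {missing[:10]}"
                        + ("..." if len(missing) > 10 else ""))
    pairs = {(groups[lab], cl) for lab, cl in partition.assignment.items()}
    counts: dict[str, int] = {}
    for group, _ in pairs:
        counts[group] = counts.get(group, 0) + 1
    return pd.Series(counts, dtype=int).sort_index().rename("n_motus")
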