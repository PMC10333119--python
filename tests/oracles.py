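"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: transitive closure by
repeated boolean matrix products, demultiplexing by scanning every
(specimen, orientation) pair, least squares by normal equations, and PCA by
a dense covariance eigendecomposition.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_p_distance(a: str, b: str) -> float | None:
    """Hand-rolled pairwise-deletion p-distance; None if nothing comparable."""
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            if x != y:
                mismatches += 1
    return mismatches / compared if compared else None


def transitive_closure_clusters(dist: np.ndarray, threshold: float) -> list[frozenset[int]]:
    """O(n^3) single-linkage components via boolean closure."""
    n = dist.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            d = dist[i, j]
            adj[i, j] = i == j or (np.isfinite(d) and d <= threshold)
    closure = adj.copy()
    while True:
        nxt = closure | (closure @ closure)
        if np.array_equal(nxt, closure):
            break
        closure = nxt
    seen: set[int] = set()
    clusters = []
    for i in range(n):
        if i not in seen:
            members = frozenset(np.flatnonzero(closure[i]).tolist())
            clusters.append(members)
            seen |= members
    return clusters


def partition_as_sets(assignment: dict[str, int], labels: list[str]) -> set[frozenset[int]]:
    by_cluster: dict[int, set[int]] = {}
    for idx, label in enumerate(labels):
        by_cluster.setdefault(assignment[label], set()).add(idx)
    return {frozenset(v) for v in by_cluster.values()}


def _mismatch(observed: str, pattern: str) -> int:
    n = 0
    for o, p in zip(observed, pattern):
        allowed = IUPAC[p]
        if p == "N":
            allowed = "ACGTN"
        if o not in allowed.replace("N", "") and not (o == "N" and p == "N"):
            n += 1
    return n


def brute_force_demux(
    read: str,
    entries: dict[str, tuple[str, str]],
    primer_fwd: str,
    primer_rev: str,
    max_primer_mm: int = 2,
) -> tuple[str, str] | None:
    """Scan every (specimen, orientation); assign iff exactly one orientation
    matches (ambiguous dual-orientation reads stay unassigned)."""
    read = read.upper()
    hits = []
    for orient_seq in (read, revcomp(read)):
        for specimen, (ft, rt) in entries.items():
            tl = len(ft)
            if len(orient_seq) <= 2 * tl + len(primer_fwd) + len(primer_rev):
                continue
            if orient_seq[:tl] != ft:
                continue
            if revcomp(orient_seq[-tl:]) != rt:
                continue
            if _mismatch(orient_seq[tl : tl + len(primer_fwd)], primer_fwd) > max_primer_mm:
                continue
            rev_region = revcomp(orient_seq[-(tl + len(primer_rev)) : -tl])
            if _mismatch(rev_region, primer_rev) > max_primer_mm:
                continue
            template = orient_seq[tl + len(primer_fwd) : len(orient_seq) - tl - len(primer_rev)]
            hits.append((specimen, template))
    if len(hits) == 1:
        return hits[0]
    return None


def normal_equations_adjusted_r2(proportions: np.ndarray, families: list[str], offset: float = 0.01) -> float:
    """One-factor OLS adjusted R^2 via normal equations on dummy codes."""
    y = np.log(np.asarray(proportions, dtype=float) + offset)
    levels = sorted(set(families))
    x = np.ones((len(y), len(levels)))
    for j, level in enumerate(levels[1:], start=1):
        x[:, j] = [1.0 if f == level else 0.0 for f in families]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    n, p = len(y), len(levels) - 1
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def covariance_eig_relative(matrix: np.ndarray) -> np.ndarray:
    """Relative eigenvalues of the column covariance, descending."""
    cov = np.cov(matrix, rowvar=False)
    cov = np.atleast_2d(cov)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    return eig / eig.sum()


def textbook_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
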