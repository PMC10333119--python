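"""Family-level community-composition statistics.

Works on a community matrix whose rows are traps/samples, whose columns are
family names, and whose cells are the proportion of mOTUs (or specimens)
per family within the trap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "build_matrix",
    "apply_exclusions",
    "rank_top_families",
    "variance_explained_by_taxon",
    "pca_relative_eigenvalues",
    "PCAResult",
    "turnover_single_site",
    "clade_age_correlation",
    "merge_and_rerank",
]

LOG_OFFSET = 0.01
UNIDENTIFIED = "unassigned"


def build_matrix(
    counts: pd.DataFrame,
    unidentified: str = UNIDENTIFIED,
) -> pd.DataFrame:
    """Row-normalised proportions from a trap x family count table.

    mOTUs that could not be identified to family (column name equal to
    ``unidentified``) are excluded before normalisation. Traps with no
    identified mOTUs are dropped with a warning.
    """
    if (counts.values < 0).any():
        raise DataError("counts must be non-negative")
    mat = counts.drop(columns=[unidentified], errors="ignore").astype(float)
    totals = mat.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"dropping empty traps: {empty}", stacklevel=2)
        mat = mat.drop(index=empty)
        totals = totals.drop(index=empty)
    return mat.div(totals, axis=0)


def apply_exclusions(
    matrix: pd.DataFrame,
    specimen_totals: Mapping[str, int] | pd.Series,
    samples_present: Mapping[str, int] | pd.Series,
    min_specimens: int = 11,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Drop families with too few specimens overall or present in one sample.

    Families with <= 10 specimens across all samples (i.e. fewer than
    ``min_specimens``) or present in fewer than ``min_samples`` samples are
    removed. Rows are NOT re-normalised: proportions keep their original
    denominator.
    """
    specimen_totals = pd.Series(specimen_totals)
    samples_present = pd.Series(samples_present)
    missing = [f for f in matrix.columns if f not in specimen_totals.index or f not in samples_present.index]
    if missing:
        raise DataError(f"metadata missing for families: {missing}")
    keep = [
        f
        for f in matrix.columns
        if specimen_totals[f] >= min_specimens and samples_present[f] >= min_samples
    ]
    return matrix[keep]


def rank_top_families(
    matrix: pd.DataFrame,
    n: int = 20,
    totals: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Rank families by unweighted mean per-trap proportion, descending.

    Ties are broken by total mOTU count (when supplied) and then by name.
    Requesting more families than exist returns all of them with a warning.
    """
    if matrix.empty:
        raise DataError("community matrix is empty")
    if n < 0:
        raise ConfigError("n must be >= 0")
    means = matrix.mean(axis=0)
    totals = pd.Series(totals) if totals is not None else pd.Series(0, index=means.index)
    order = pd.DataFrame(
        {
            "family": means.index,
            "mean_proportion": means.values,
            "total": [totals.get(f, 0) for f in means.index],
        }
    ).sort_values(
        by=["mean_proportion", "total", "family"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    if n > len(order):
        warnings.warn(
            f"requested top {n} but only {len(order)} families present", stacklevel=2
        )
        n = len(order)
    out = order.head(n).drop(columns="total").reset_index(drop=True)
    out.index += 1
    return out


def _to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    long = matrix.stack().rename("proportion").reset_index()
    long.columns = ["trap", "family", "proportion"]
    return long


def variance_explained_by_taxon(
    matrix: pd.DataFrame, offset: float = LOG_OFFSET
) -> float:
    """Adjusted R-squared of log(proportion + offset) ~ family identity.

    The offset is added to every proportion (not only zeros) before the
    natural log, matching the model formula
    ``lm(log(Proportion + 0.01) ~ Taxon)``.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DataError("need >= 2 traps and >= 2 families")
    long = _to_long(matrix)
    long["y"] = np.log(long["proportion"] + offset)
    fit = smf.ols("y ~ C(family)", data=long).fit()
    if fit.df_resid <= 0:
        raise DataError("singular fit: one observation per family level")
    return float(fit.rsquared_adj)


@dataclass(frozen=True)
class PCAResult:
    relative_eigenvalues: np.ndarray  # descending, sums to 1 (or all-zero)
    scores: np.ndarray  # rows x components
    degenerate: bool = False  # constant input matrix


def pca_relative_eigenvalues(matrix: pd.DataFrame) -> PCAResult:
    """PCA of the community matrix: centred, NOT scaled.

    Eigen-decomposes the covariance of the rows and returns eigenvalue
    proportions in descending order plus the row scores.
    """
    if matrix.shape[0] < 2:
        raise DataError("PCA needs >= 2 rows")
    x = matrix.to_numpy(dtype=float)
    centred = x - x.mean(axis=0, keepdims=True)
    # SVD route: eigenvalues of cov = s^2 / (n - 1)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    eig = s**2 / (x.shape[0] - 1)
    total = eig.sum()
    if total <= 0:
        return PCAResult(
            relative_eigenvalues=np.zeros_like(eig),
            scores=np.zeros_like(centred),
            degenerate=True,
        )
    return PCAResult(relative_eigenvalues=eig / total, scores=u * s)


def turnover_single_site(
    incidence: pd.DataFrame,
    families: Sequence[str] | None = None,
    family_of: Mapping[str, str] | pd.Series | None = None,
) -> float:
    """Fraction of species found at exactly one site.

    ``incidence`` is a site x species presence table (bool/0-1). When a
    family subset is given, ``family_of`` must map species to families and
    only species of those families are considered.
    """
    presence = incidence.astype(bool)
    species = list(presence.columns)
    if families is not None:
        if family_of is None:
            raise ConfigError("family subset requires a species -> family mapping")
        family_of = pd.Series(family_of)
        wanted = set(families)
        species = [s for s in species if family_of.get(s) in wanted]
        if not species:
            raise DataError("no species in the requested family subset")
    if not species:
        raise DataError("no species in incidence table")
    n_sites = presence[species].sum(axis=0)
    if (n_sites == 0).any():
        raise DataError("species present at zero sites in incidence table")
    return float((n_sites == 1).mean())


def clade_age_correlation(
    ages: Sequence[float], proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson correlation of clade age vs proportion: (r, n, p)."""
    ages = np.asarray(ages, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if ages.shape != props.shape or ages.size < 3:
        raise DataError("need >= 3 paired observations")
    if (ages <= 0).any():
        raise DataError("clade ages must be positive")
    if np.ptp(ages) == 0 or np.ptp(props) == 0:
        raise DataError("zero variance in ages or proportions")
    r, p = stats.pearsonr(ages, props)
    return float(r), int(ages.size), float(p)


def merge_and_rerank(
    matrix: pd.DataFrame,
    merge_map: Mapping[str, str],
    n: int = 20,
    totals: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Sum merged column groups and recompute the top-n ranking.

    ``merge_map`` sends a family to its merged clade name; unmapped
    families keep their own name. A merge that collides with an existing
    unmerged column is rejected.
    """
    unknown = [f for f in merge_map if f not in matrix.columns]
    if unknown:
        raise DataError(f"merge map keys not in matrix: {unknown}")
    target = {f: merge_map.get(f, f) for f in matrix.columns}
    for f, merged in merge_map.items():
        if merged in matrix.columns and target[merged] == merged and merged != f:
            raise DataError(f"merge target {merged!r} collides with existing family")
    merged_matrix = matrix.T.groupby(matrix.columns.map(target)).sum().T
    merged_totals = None
    if totals is not None:
        totals = pd.Series(totals)
        merged_totals = totals.groupby(totals.index.map(lambda f: target.get(f, f))).sum()
    return rank_top_families(merged_matrix, n=n, totals=merged_totals)
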