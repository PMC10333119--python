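"""Taxonomic-neglect metrics.

Covers the neglect index (NI = detected mOTUs / described species), its
drivers (diversity and body size), per-decade description activity, the
decade-interaction ANCOVA, fractional author-credit scores with the
highly-dedicated-author count, and the corrected global species-richness
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .errors import ConfigError, DataError

__all__ = [
    "FamilyDossier",
    "RichnessEstimate",
    "neglect_index",
    "fit_neglect_drivers",
    "DriverFit",
    "descriptions_per_decade",
    "neglect_activity_correlation",
    "decade_interaction_test",
    "author_scores",
    "count_dedicated_authors",
    "rescale_global_richness",
    "DEFAULT_DECADES",
    "S_THRESHOLD",
]

S_THRESHOLD = 50.0
DEFAULT_DECADES = ((1980, 1989), (1990, 1999), (2000, 2009), (2010, 2019))


@dataclass(frozen=True)
class FamilyDossier:
    """Per-family inputs to the neglect analyses."""

    family: str
    n_motu: int
    n_sp: int
    body_min_mm: float | None = None
    body_max_mm: float | None = None
    clade_age_my: float | None = None

    def __post_init__(self) -> None:
        if self.n_motu < 0 or self.n_sp < 0:
            raise DataError(f"{self.family}: counts must be non-negative")
        if self.body_min_mm is not None and self.body_max_mm is not None:
            if self.body_min_mm <= 0 or self.body_min_mm > self.body_max_mm:
                raise DataError(f"{self.family}: invalid body-size range")

    @property
    def ni(self) -> float:
        return neglect_index(self.n_motu, self.n_sp)

    @property
    def mean_log_body(self) -> float:
        """Mean of the natural logs of the body-size range limits."""
        if self.body_min_mm is None or self.body_max_mm is None:
            raise DataError(f"{self.family}: body-size range unavailable")
        return (np.log(self.body_min_mm) + np.log(self.body_max_mm)) / 2.0


def neglect_index(n_motu: int, n_sp: int) -> float:
    """NI = detected mOTUs / described species; 1 means parity."""
    if n_sp <= 0:
        raise DataError("NI undefined for zero described species")
    if n_motu < 0:
        raise DataError("n_motu must be non-negative")
    return n_motu / n_sp


@dataclass(frozen=True)
class DriverFit:
    """Interaction screen plus the reported neglect-driver model."""

    interaction_pvalue: float
    interaction_removed: bool
    full: object  # statsmodels results, ln(NI) ~ ln(N_mOTU) * body
    final: object  # the model whose coefficients are reported
    coefficients: pd.DataFrame  # term, estimate, se, t, p

    @property
    def formula(self) -> str:
        return (
            "ln_ni ~ ln_nmotu + mean_log_body"
            if self.interaction_removed
            else "ln_ni ~ ln_nmotu * mean_log_body"
        )


def fit_neglect_drivers(
    dossiers: Sequence[FamilyDossier], alpha: float = 0.05
) -> DriverFit:
    """Model ln(NI) on log diversity and body size, screening the interaction.

    The full interaction model is fitted first; when the interaction term's
    p-value is >= ``alpha`` the additive model is refitted and reported.
    """
    rows = [
        {
            "family": d.family,
            "ln_ni": np.log(d.ni),
            "ln_nmotu": np.log(d.n_motu),
            "mean_log_body": d.mean_log_body,
        }
        for d in dossiers
    ]
    if len(rows) < 4:
        raise DataError("need >= 4 dossiers with positive NI")
    data = pd.DataFrame(rows)
    for col in ("ln_nmotu", "mean_log_body"):
        if np.ptp(data[col]) == 0:
            raise DataError(f"predictor {col} is constant (collinear fit)")
    if np.isclose(
        abs(np.corrcoef(data["ln_nmotu"], data["mean_log_body"])[0, 1]), 1.0
    ):
        raise DataError("predictors are perfectly collinear")
    full = smf.ols("ln_ni ~ ln_nmotu * mean_log_body", data=data).fit()
    p_int = float(full.pvalues["ln_nmotu:mean_log_body"])
    remove = bool(np.isnan(p_int)) or p_int >= alpha
    final = smf.ols("ln_ni ~ ln_nmotu + mean_log_body", data=data).fit() if remove else full
    coef = pd.DataFrame(
        {
            "term": final.params.index,
            "estimate": final.params.values,
            "se": final.bse.values,
            "t": final.tvalues.values,
            "p": final.pvalues.values,
        }
    )
    return DriverFit(
        interaction_pvalue=p_int,
        interaction_removed=remove,
        full=full,
        final=final,
        coefficients=coef,
    )


def _decade_label(start: int, end: int) -> str:
    return f"{start}-{end}"


def descriptions_per_decade(
    records: pd.DataFrame,
    decades: tuple[tuple[int, int], ...] = DEFAULT_DECADES,
) -> tuple[pd.DataFrame, int]:
    """Family x decade table of described-species counts (N_sp10).

    ``records`` needs columns family and year, one row per described
    species. Returns (table, number of out-of-range records excluded).
    """
    for col in ("family", "year"):
        if col not in records.columns:
            raise DataError(f"records missing column {col!r}")
    labels = [_decade_label(s, e) for s, e in decades]
    bins = pd.IntervalIndex.from_tuples(decades, closed="both")
    assigned = bins.get_indexer(records["year"])
    excluded = int((assigned == -1).sum())
    inside = records[assigned >= 0].copy()
    inside["decade"] = [labels[i] for i in assigned[assigned >= 0]]
    table = (
        inside.groupby(["family", "decade"]).size().unstack(fill_value=0)
    )
    table = table.reindex(columns=labels, fill_value=0)
    table.columns.name = "decade"
    return table, excluded


def _pooled_log_pairs(
    table: pd.DataFrame,
    ni_by_family: Mapping[str, float] | pd.Series,
    zero_offset: float = 1.0,
) -> pd.DataFrame:
    ni = pd.Series(ni_by_family, dtype=float)
    missing = [f for f in table.index if f not in ni.index]
    if missing:
        raise DataError(f"NI missing for families: {missing}")
    long = table.stack().rename("n_sp10").reset_index()
    long.columns = ["family", "decade", "n_sp10"]
    counts = long["n_sp10"].astype(float).to_numpy()
    long["log_nsp10"] = np.log(np.where(counts > 0, counts, zero_offset))
    long["log_ni"] = np.log(long["family"].map(ni).astype(float))
    return long


def neglect_activity_correlation(
    table: pd.DataFrame,
    ni_by_family: Mapping[str, float] | pd.Series,
    zero_offset: float = 1.0,
) -> tuple[float, int, float]:
    """Pearson r of (log NI, log N_sp10) pooled across decades: (r, n, p).

    Zero description counts receive ``zero_offset`` before the log.
    """
    long = _pooled_log_pairs(table, ni_by_family, zero_offset)
    if len(long) < 3:
        raise DataError("need >= 3 pooled pairs")
    if np.ptp(long["log_ni"]) == 0 or np.ptp(long["log_nsp10"]) == 0:
        raise DataError("zero variance in log NI or log N_sp10")
    r, p = stats.pearsonr(long["log_ni"], long["log_nsp10"])
    return float(r), int(len(long)), float(p)


def decade_interaction_test(
    table: pd.DataFrame,
    ni_by_family: Mapping[str, float] | pd.Series,
    zero_offset: float = 1.0,
) -> tuple[float, tuple[float, float], float]:
    """Nested-model F-test: log(N_sp10) ~ log(NI) vs log(NI) x Decade.

    Returns (F, (df_num, df_den), p). Every decade column must contain at
    least one family; offenders are listed otherwise.
    """
    if table.empty:
        raise DataError("no description counts supplied")
    empty = [c for c in table.columns if table[c].isna().all()]
    if empty:
        raise DataError(f"decades without data: {empty}")
    if len(table.columns) < 2:
        raise DataError(f"need >= 2 decades, got {list(table.columns)}")
    long = _pooled_log_pairs(table, ni_by_family, zero_offset)
    reduced = smf.ols("log_nsp10 ~ log_ni", data=long).fit()
    fullm = smf.ols("log_nsp10 ~ log_ni * C(decade)", data=long).fit()
    comparison = anova_lm(reduced, fullm)
    f_stat = float(comparison.loc[1, "F"])
    df_num = float(comparison.loc[1, "df_diff"])
    df_den = float(fullm.df_resid)
    p_value = float(comparison.loc[1, "Pr(>F)"])
    return f_stat, (df_num, df_den), p_value


def author_scores(
    records: pd.DataFrame,
    decades: tuple[tuple[int, int], ...] = DEFAULT_DECADES,
) -> pd.DataFrame:
    """Fractional author credit per decade: S_i = sum over species of 1/N_auth.

    Each species described in a study with N authors contributes 1/N to
    every author of that study. ``records`` holds one row per described
    species with a semicolon-separated ``authors`` column. Records outside
    the decade windows are ignored; empty author lists are rejected.
    Returns columns author, decade, score.
    """
    labels = [_decade_label(s, e) for s, e in decades]
    bins = pd.IntervalIndex.from_tuples(decades, closed="both")
    credits: dict[tuple[str, str], float] = {}
    for idx, row in records.iterrows():
        authors = [a.strip() for a in str(row["authors"]).split(";") if a.strip()]
        if not authors:
            raise DataError(f"record {idx}: empty author list")
        where = bins.get_indexer([row["year"]])[0]
        if where == -1:
            continue
        decade = labels[where]
        share = 1.0 / len(authors)
        for author in authors:
            key = (author, decade)
            credits[key] = credits.get(key, 0.0) + share
    out = pd.DataFrame(
        [(a, d, s) for (a, d), s in credits.items()],
        columns=["author", "decade", "score"],
    )
    return out.sort_values(["decade", "author"]).reset_index(drop=True)


def count_dedicated_authors(
    scores: pd.DataFrame,
    s_threshold: float = S_THRESHOLD,
    decades: tuple[tuple[int, int], ...] = DEFAULT_DECADES,
) -> pd.Series:
    """Authors with score strictly above the threshold, per decade."""
    labels = [_decade_label(s, e) for s, e in decades]
    if scores.empty:
        return pd.Series(0, index=pd.Index(labels, name="decade"), name="n_dedicated")
    counts = (
        scores[scores["score"] > s_threshold].groupby("decade")["author"].nunique()
    )
    return counts.reindex(labels, fill_value=0).rename("n_dedicated").astype(int)


@dataclass(frozen=True)
class RichnessEstimate:
    """A published richness range plus assumed/observed focal-taxon shares."""

    low: float
    high: float
    p_assumed: float
    p_observed: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_assumed < 1 or not 0 <= self.p_observed < 1:
            raise ConfigError("shares must lie in [0, 1)")
        if self.low > self.high:
            raise ConfigError("low must be <= high")


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP))


def rescale_global_richness(est: RichnessEstimate) -> tuple[float, float]:
    """Correct a richness range for an under-assumed focal-taxon share.

    Each endpoint is divided by 1 - (p_observed - p_assumed) and rounded
    half away from zero to one decimal. When the observed share does not
    exceed the assumed one the estimate is returned unchanged with a
    warning.
    """
    gap = est.p_observed - est.p_assumed
    if gap <= 0:
        import warnings

        warnings.warn("observed share does not exceed assumed share; no correction", stacklevel=2)
        return _round_half_up(est.low), _round_half_up(est.high)
    divisor = 1.0 - gap
    return _round_half_up(est.low / divisor), _round_half_up(est.high / divisor)
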