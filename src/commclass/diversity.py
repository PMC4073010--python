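"""Alpha diversity, habitat typing and demographic associations.

Shannon diversity H' = -sum_i p_i ln p_i is computed on counts rarefied
to a common depth (default 1,000 reads) so read-depth differences do not
bias the comparison.  Habitats split into two types: type I (median H'
below 1.5 and high overall silhouette — one dominant genus, tight
classes) and type II (diverse, diffusely clustered).  Demographic
factors are tested against class membership with Fisher's exact test
(categorical) or one-way ANOVA (continuous), Bonferroni-corrected;
single-taxon differences between two groups use the two-sided
Mann-Whitney-Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import count
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .clustering import CommunityClassSolution, Partition
from .tables import CountTable, ProportionTable, ValidationError, rarefy, to_proportions

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityProfile",
    "HabitatType",
    "AssociationResult",
    "shannon",
    "correlate_silhouette_diversity",
    "classify_habitat_type",
    "fisher_exact_rxc",
    "associate",
    "taxon_vs_group",
    "categorize_bmi",
]


@dataclass
class DiversityProfile:
    """Per-sample Shannon index after rarefaction; 0 <= H' <= ln(S)."""

    sample_ids: list[str]
    shannon_index: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.shannon_index))


@dataclass
class HabitatType:
    habitat: str
    median_shannon: float
    silhouette: float
    habitat_type: str  # "I" or "II"


@dataclass
class AssociationResult:
    factor: str
    test: str
    classes: list
    raw_p: float
    corrected_p: float
    significant: bool
    note: str = ""


def shannon(table: CountTable, depth: int = 1000, seed: int = 0) -> DiversityProfile:
    """Shannon diversity per sample on counts rarefied to ``depth`` reads.

    Samples below the rarefaction depth are dropped (logged by
    ``rarefy``); natural logarithm throughout.
    """
    rare = rarefy(table, depth, seed)
    p = to_proportions(rare).proportions
    h = stats.entropy(p, axis=1)  # -sum p ln p, natural log
    return DiversityProfile(list(rare.sample_ids), h)


def correlate_silhouette_diversity(
    habitats: Sequence[tuple[float, float]]
) -> float:
    """Pearson correlation of (overall silhouette, median Shannon) pairs.

    Reported with the sign as computed; across habitats dominated to
    different degrees it is expected to be strongly negative.
    """
    if len(habitats) < 3:
        raise ValidationError("need at least 3 habitats for a correlation")
    sil = np.array([h[0] for h in habitats], dtype=float)
    div = np.array([h[1] for h in habitats], dtype=float)
    if np.ptp(sil) == 0 or np.ptp(div) == 0:
        raise ValidationError("zero variance in silhouettes or diversities")
    return float(stats.pearsonr(sil, div).statistic)


def classify_habitat_type(
    habitat: str,
    median_shannon: float,
    silhouette: float,
    silhouette_high: float = 0.5,
    shannon_low: float = 1.5,
) -> HabitatType:
    """Type I: median Shannon strictly below 1.5 and silhouette at least
    the high-silhouette cut (default 0.5); everything else is type II."""
    if not -1 <= silhouette <= 1:
        raise ValidationError("silhouette must lie in [-1, 1]")
    is_type_i = median_shannon < shannon_low and silhouette >= silhouette_high
    return HabitatType(
        habitat, median_shannon, silhouette, "I" if is_type_i else "II"
    )


# ---------------------------------------------------------------------------
# exact test on r x c contingency tables


def _table_logprob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i: int, remaining_cols: np.ndarray, acc: list):
        if i == r - 1:
            yield acc + [remaining_cols.copy()]
            return
        def fill(j: int, left: int, row: list):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, row + [v])

        for row in fill(0, int(rows[i]), []):
            row_arr = np.array(row)
            yield from rec(i + 1, remaining_cols - row_arr, acc + [row_arr])

    yield from (np.vstack(t) for t in rec(0, cols.astype(int).copy(), []))


def fisher_exact_rxc(
    table: np.ndarray,
    seed: int = 0,
    mc_draws: int = 100_000,
    enumerate_limit: int = 40,
) -> float:
    """Two-sided exact test of independence on an r x c count table.

    2x2 tables go through the standard exact routine.  Larger tables
    with a small total are enumerated exhaustively (summing the
    probabilities of all tables no more probable than the observed one);
    beyond ``enumerate_limit`` total counts, a seeded Monte-Carlo
    permutation of the conditional distribution is used, with the add-one
    correction so p > 0.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValidationError("contingency table must be 2-D and non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    obs_lp = _table_logprob(table)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if table.sum() <= enumerate_limit:
        p = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _table_logprob(t)
            if lp <= obs_lp + 1e-9:
                p += np.exp(lp)
        return float(min(p, 1.0))
    # Monte-Carlo: permute one margin's labels, conditioning on both margins
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    nr, nc = len(rows), len(cols)
    n = int(table.sum())
    lfact = gammaln(np.arange(n + 2) + 1.0)  # lfact[m] = log(m!)
    margin_lp = lfact[rows].sum() + lfact[cols].sum() - lfact[n]
    exceed = 0
    batch = 5000
    done = 0
    while done < mc_draws:
        b = min(batch, mc_draws - done)
        perms = rng.permuted(np.tile(col_labels, (b, 1)), axis=1)
        flat = row_labels[np.newaxis, :] * nc + perms
        flat += (np.arange(b) * nr * nc)[:, np.newaxis]
        counts = np.bincount(flat.ravel(), minlength=b * nr * nc).reshape(b, -1)
        lp = margin_lp - lfact[counts].sum(axis=1)
        exceed += int((lp <= obs_lp + 1e-9).sum())
        done += b
    return float((1 + exceed) / (1 + mc_draws))


# ---------------------------------------------------------------------------
# demographic associations


def categorize_bmi(values: pd.Series) -> pd.Series:
    """BMI categories: below 25, 25 to under 30, 30 and above."""
    bins = pd.cut(
        pd.to_numeric(values),
        bins=[-np.inf, 25, 30, np.inf],
        right=False,
        labels=["<25", "25-<30", ">=30"],
    )
    return bins.astype(str)


def associate(
    solution: CommunityClassSolution | Partition,
    metadata: pd.DataFrame,
    factors: dict[str, str],
    alpha: float = 0.05,
    seed: int = 0,
    mc_draws: int = 100_000,
) -> list[AssociationResult]:
    """Test demographic factors against community-class membership.

    ``factors`` maps column names of ``metadata`` (indexed by sample id)
    to "categorical" or "continuous".  Categorical factors are tested by
    the exact count-table test across classes, continuous ones by
    one-way ANOVA.  A numeric column named ``bmi`` declared categorical
    is first binned into the standard <25 / 25-<30 / >=30 categories.
    p-values are Bonferroni-corrected within the family of factors
    actually tested; factors with a single observed level are skipped
    and logged.
    """
    part = solution.partition if isinstance(solution, CommunityClassSolution) else solution
    meta = metadata.loc[[s for s in part.sample_ids if s in metadata.index]]
    if len(meta) != len(part.sample_ids):
        raise ValidationError("metadata does not cover all clustered samples")
    meta = metadata.loc[part.sample_ids]
    labels = pd.Series(part.labels, index=part.sample_ids)
    classes = sorted(set(part.labels))
    raw: list[tuple[str, str, float, str]] = []
    seed_stream = count(seed)
    for factor, kind in factors.items():
        if factor not in meta.columns:
            raise ValidationError(f"factor {factor!r} missing from metadata")
        values = meta[factor]
        note = ""
        if kind == "categorical":
            if factor.lower() == "bmi" and pd.api.types.is_numeric_dtype(values):
                values = categorize_bmi(values)
                note = "bmi binned <25 / 25-<30 / >=30"
            if values.nunique() < 2:
                logger.info("factor %r has a single level; skipped", factor)
                continue
            table = pd.crosstab(labels, values).to_numpy()
            p = fisher_exact_rxc(table, seed=next(seed_stream), mc_draws=mc_draws)
            raw.append((factor, "fisher-exact", p, note))
        elif kind == "continuous":
            groups = [
                pd.to_numeric(values[labels == c]).dropna().to_numpy()
                for c in classes
            ]
            groups = [g for g in groups if len(g) > 1]
            if len(groups) < 2:
                logger.info("factor %r: too few groups for ANOVA; skipped", factor)
                continue
            if all(np.ptp(g) == 0 for g in groups):
                raw.append((factor, "anova", 1.0, "constant values"))
                continue
            p = float(stats.f_oneway(*groups).pvalue)
            raw.append((factor, "anova", p, note))
        else:
            raise ValidationError(f"factor kind must be categorical/continuous, got {kind!r}")
    family = len(raw)
    results = []
    for factor, test, p, note in raw:
        corrected = min(1.0, p * family)
        results.append(
            AssociationResult(
                factor, test, classes, p, corrected, corrected < alpha, note
            )
        )
    return results


def taxon_vs_group(
    abund: ProportionTable,
    metadata: pd.DataFrame,
    taxon: str,
    factor: str,
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> AssociationResult:
    """Two-sided rank-sum test of one taxon's abundance between two groups.

    ``n_comparisons`` is the size of the Bonferroni family (e.g. the
    number of taxa screened).  Constant abundances yield p = 1 with a
    warning rather than an error.
    """
    if taxon not in abund.taxon_ids:
        raise ValidationError(f"unknown taxon {taxon!r}")
    meta = metadata.loc[abund.sample_ids]
    levels = sorted(meta[factor].dropna().unique())
    if len(levels) != 2:
        raise ValidationError(
            f"factor {factor!r} must have exactly 2 levels, found {len(levels)}"
        )
    col = abund.proportions[:, abund.taxon_ids.index(taxon)]
    g1 = col[(meta[factor] == levels[0]).to_numpy()]
    g2 = col[(meta[factor] == levels[1]).to_numpy()]
    if len(g1) < 1 or len(g2) < 1:
        raise ValidationError("each factor level needs at least one sample")
    combined = np.concatenate([g1, g2])
    if np.ptp(combined) == 0:
        warnings.warn(f"taxon {taxon!r} has constant abundance; p set to 1")
        p = 1.0
    else:
        # exact null distribution when feasible (small groups, no ties)
        no_ties = len(np.unique(combined)) == len(combined)
        method = "exact" if (no_ties and min(len(g1), len(g2)) <= 25) else "asymptotic"
        p = float(
            stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method).pvalue
        )
    corrected = min(1.0, p * n_comparisons)
    return AssociationResult(
        factor, "mann-whitney", levels, p, corrected, corrected < alpha,
        note=f"taxon={taxon}",
    )
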