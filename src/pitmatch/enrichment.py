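"""Enrichment and group-comparison statistics on junction match labels.

All categorical comparisons use Fisher's exact test; the odds ratio is
the sample (cross-product) OR with a Woolf-type 95% confidence interval
on log2 OR; multiple testing is Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "SlopeTest",
    "fisher_enrichment",
    "repertoire_enrichment",
    "offdiagonal_slope",
    "stage_contingency",
    "donor_level_fractions",
    "vj_usage_enrichment",
    "bh_adjust",
]

_Z95 = 1.959963984540054


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test result.

    ``odds_ratio`` is the sample OR ad/bc; with a zero cell it is the
    Haldane-Anscombe corrected OR (0.5 added to every cell) and
    ``continuity_corrected`` is set.  ``ci_95`` is the Woolf interval
    for log2 OR.  The p-value is always the exact Fisher p on the
    uncorrected table.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log2_odds_ratio: float
    ci_95: tuple[float, float]
    p_value: float
    p_adjusted: float | None = None
    continuity_corrected: bool = False
    sided: str = "two-sided"


def fisher_enrichment(
    table: Sequence[Sequence[int]], sided: str = "two-sided"
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table of nonnegative counts.

    Raises ValueError on a degenerate table (an all-zero row or column:
    the conditional distribution is undefined).
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), (int(table[1][0]), int(table[1][1]))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(f"degenerate 2x2 table {table!r}: a whole margin is zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=sided)
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    orr = (aa * dd) / (bb * cc)
    log2_or = math.log2(orr)
    se_ln = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    half = _Z95 * se_ln / math.log(2)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=orr,
        log2_odds_ratio=log2_or,
        ci_95=(log2_or - half, log2_or + half),
        p_value=float(p),
        continuity_corrected=corrected,
        sided=sided,
    )


def repertoire_enrichment(
    query_matched: int,
    query_total: int,
    bg_matched: int,
    bg_total: int,
    sided: str = "two-sided",
) -> EnrichmentResult:
    """Matched-fraction enrichment of a query repertoire over a background.

    Builds the 2x2 table (matched / non-matched) x (query / background)
    and delegates to :func:`fisher_enrichment`.
    """
    if query_matched > query_total or bg_matched > bg_total:
        raise ValueError("matched count exceeds total")
    table = [
        [query_matched, query_total - query_matched],
        [bg_matched, bg_total - bg_matched],
    ]
    return fisher_enrichment(table, sided=sided)


@dataclass
class SlopeTest:
    """OLS slope of query counts on background counts, tested against a
    fixed null slope via a nested-model F test (both models keep a free
    intercept)."""

    slope: float
    intercept: float
    ci_95: tuple[float, float]
    p_vs_null: float
    null_slope: float
    n: int


def offdiagonal_slope(
    counts_query: Sequence[float],
    counts_background: Sequence[float],
    null_slope: float = 1.0,
) -> SlopeTest:
    """Test whether per-threshold match counts deviate from equivalence.

    ``counts_query`` (y) and ``counts_background`` (x) are match counts
    at increasing distance thresholds from size-comparable (or
    normalized) repertoires.  Fits y = a + b x by OLS and compares
    against the restricted model with the slope fixed at ``null_slope``
    (intercept still free) by an F test — slope below 1 means the query
    accumulates matches faster than the background on the off-diagonal.
    """
    y = np.asarray(counts_query, dtype=float)
    x = np.asarray(counts_background, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("count vectors must be 1-D and equal length")
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 thresholds")
    if np.allclose(x, x[0]):
        raise ValueError("background counts have zero variance")
    res = stats.linregress(x, y)
    rss_full = float(np.sum((y - res.intercept - res.slope * x) ** 2))
    # restricted: slope fixed, intercept = mean residual
    resid = y - null_slope * x
    rss_restr = float(np.sum((resid - resid.mean()) ** 2))
    df_full = n - 2
    if rss_full <= 0:
        p = 0.0 if rss_restr > 1e-12 else 1.0
    else:
        f = (rss_restr - rss_full) / (rss_full / df_full)
        p = float(stats.f.sf(f, 1, df_full))
    half = _Z95 * res.stderr
    return SlopeTest(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_95=(float(res.slope - half), float(res.slope + half)),
        p_vs_null=p,
        null_slope=null_slope,
        n=n,
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment."""
    if len(pvals) == 0:
        return np.array([])
    return multipletests(pvals, method="fdr_bh")[1]


def stage_contingency(
    labels: pd.DataFrame,
    stratum: str | None = None,
    group_col: str = "group",
    matched_col: str = "pit_matched",
    stratum_col: str = "expanded",
) -> pd.DataFrame:
    """Pairwise Fisher tests of matched fractions across donor groups.

    ``labels`` holds one row per junction with a boolean matched flag,
    a donor-group label, and (optionally) an expansion stratum flag.
    When ``stratum`` is given ('expanded' / 'non-expanded'), rows are
    first restricted to that stratum.  For every group pair a 2x2
    (matched/non x group A/B) Fisher test is run; p-values are BH
    adjusted across the pairs.  Groups with zero junctions in the
    stratum are skipped.
    """
    df = labels
    if stratum is not None:
        want = stratum == "expanded"
        df = df[df[stratum_col] == want]
    groups = sorted(g for g in df[group_col].unique() if (df[group_col] == g).any())
    tallies = {
        g: (
            int(((df[group_col] == g) & df[matched_col]).sum()),
            int(((df[group_col] == g) & ~df[matched_col].astype(bool)).sum()),
        )
        for g in groups
    }
    rows = []
    for ga, gb in combinations(groups, 2):
        (ma, ua), (mb, ub) = tallies[ga], tallies[gb]
        if ma + ua == 0 or mb + ub == 0:
            continue
        try:
            res = fisher_enrichment([[ma, ua], [mb, ub]])
        except ValueError:
            continue
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "matched_a": ma,
                "total_a": ma + ua,
                "fraction_a": ma / (ma + ua),
                "matched_b": mb,
                "total_b": mb + ub,
                "fraction_b": mb / (mb + ub),
                "odds_ratio": res.odds_ratio,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].tolist())
    return out


def donor_level_fractions(
    labels: pd.DataFrame,
    donor_col: str = "donor_id",
    group_col: str = "group",
    matched_col: str = "pit_matched",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor matched fractions with rank-based group comparisons.

    Returns (per-donor table, pairwise Wilcoxon rank-sum table).  The
    per-donor table has donor_id, group, n_junctions, fraction_matched;
    donors with zero junctions are excluded.  Group pairs are compared
    with the two-sided Wilcoxon rank-sum (Mann-Whitney) test and BH
    adjusted.
    """
    per = (
        labels.groupby([donor_col, group_col])[matched_col]
        .agg(n_junctions="size", fraction_matched="mean")
        .reset_index()
        .rename(columns={donor_col: "donor_id", group_col: "group"})
    )
    per = per[per["n_junctions"] > 0]
    rows = []
    for ga, gb in combinations(sorted(per["group"].unique()), 2):
        fa = per.loc[per["group"] == ga, "fraction_matched"].to_numpy()
        fb = per.loc[per["group"] == gb, "fraction_matched"].to_numpy()
        if len(fa) == 0 or len(fb) == 0:
            continue
        if np.array_equal(np.sort(fa), np.sort(fb)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(fa, fb, alternative="two-sided").pvalue)
        rows.append({"group_a": ga, "group_b": gb, "n_a": len(fa), "n_b": len(fb), "p": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adj"] = bh_adjust(tests["p"].tolist())
    return per, tests


def vj_usage_enrichment(
    junction_genes: Mapping[str, Sequence[str]],
    matched: Mapping[str, bool],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene over/under-representation among matched junctions.

    ``junction_genes`` maps junction -> gene names it uses (V or J,
    one locus at a time); ``matched`` maps junction -> matched flag.
    For each gene a 2x2 (uses gene / does not) x (matched /
    non-matched) Fisher test is run and BH adjusted across genes.
    """
    from .io import normalize_gene

    juncs = [j for j in junction_genes if j in matched]
    n_matched = sum(1 for j in juncs if matched[j])
    n_non = len(juncs) - n_matched
    gene_use: dict[str, set[str]] = {}
    for j in juncs:
        for g in junction_genes[j]:
            gene_use.setdefault(normalize_gene(g), set()).add(j)
    rows = []
    for gene in sorted(gene_use):
        users = gene_use[gene]
        a = sum(1 for j in users if matched[j])
        b = n_matched - a
        c = len(users) - a
        d = n_non - c
        try:
            res = fisher_enrichment([[a, b], [c, d]])
        except ValueError:
            continue
        rows.append(
            {
                "gene": gene,
                "matched_with_gene": a,
                "matched_without": b,
                "nonmatched_with_gene": c,
                "nonmatched_without": d,
                "odds_ratio": res.odds_ratio,
                "log2_odds_ratio": res.log2_odds_ratio,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].tolist())
        out["significant"] = out["p_adj"] < alpha
    return out


def enrichment_to_row(name: str, res: EnrichmentResult) -> dict:
    """Flatten an EnrichmentResult for the tidy tests TSV."""
    (a, b), (c, d) = res.table
    return {
        "comparison": name,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "odds_ratio": res.odds_ratio,
        "log2_odds_ratio": res.log2_odds_ratio,
        "ci_low": res.ci_95[0],
        "ci_high": res.ci_95[1],
        "p": res.p_value,
        "p_adj": res.p_adjusted,
        "sided": res.sided,
    }
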