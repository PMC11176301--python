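"""Clonal expansion, publicity, convergence and set-overlap statistics.

Definitions operate on the junction amino-acid sequence:

* expanded  — observed in more than one cell (summed across donors);
* public    — observed in more than one donor;
* private   — expanded but confined to a single donor;
* converged — encoded by more than one distinct nucleotide sequence
  (convergent recombination / post-selection convergence).

Singleton single-donor junctions are neither public nor private.
Generation probabilities (Pgen) are consumed from an externally
produced table (e.g. a recombination-model inference tool); this
package never computes Pgen itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import fisher_enrichment
from .io import Repertoire

__all__ = [
    "ClonalityRow",
    "classify_clonality",
    "convergence_summary",
    "set_overlap_test",
    "load_pgen_table",
    "compare_pgen",
]


@dataclass
class ClonalityRow:
    junction_aa: str
    locus: str
    cell_count: int
    donor_count: int
    expanded: bool
    public: bool
    private: bool
    n_nt_variants: int
    converged: bool
    pgen: float | None = None


def classify_clonality(rep: Repertoire, per_donor_expansion: bool = False) -> list[ClonalityRow]:
    """Flag each unique junction as expanded / public / private / converged.

    With ``per_donor_expansion`` a junction counts as expanded only if
    some single donor contributes >1 cell (otherwise expansion is the
    total cell count across donors, which makes every public junction
    with >=2 cells expanded as well).
    """
    rows = []
    for j in sorted(rep.entries):
        e = rep.entries[j]
        if per_donor_expansion:
            expanded = any(c > 1 for c in e.cells_per_donor.values())
        else:
            expanded = e.cell_count > 1
        public = e.donor_count > 1
        private = expanded and e.donor_count == 1
        rows.append(
            ClonalityRow(
                junction_aa=j,
                locus=rep.locus,
                cell_count=e.cell_count,
                donor_count=e.donor_count,
                expanded=expanded,
                public=public,
                private=private,
                n_nt_variants=len(e.nt_sequences),
                converged=len(e.nt_sequences) > 1,
            )
        )
    return rows


def clonality_to_frame(rows: Sequence[ClonalityRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def convergence_summary(
    rows: Sequence[ClonalityRow],
    strata: Mapping[str, Mapping[str, bool]] | None = None,
) -> pd.DataFrame:
    """Converged counts and fractions by locus (and optional strata).

    Junctions without any nt sequence are excluded from denominators
    (their convergence status is unobservable); the excluded count is
    reported.  When both loci are present the TRA-vs-TRB convergence
    difference is tested by Fisher's exact test and attached as
    ``df.attrs['tra_vs_trb_p']``.  ``strata`` optionally maps a stratum
    name -> {junction_aa: bool} (e.g. PIT-matched or public flags) to
    add per-stratum rows.
    """
    usable = [r for r in rows if r.n_nt_variants > 0]
    if not usable:
        raise ValueError("no junctions with nucleotide data: convergence unobservable")
    excluded = len(rows) - len(usable)

    def tally(rs: Sequence[ClonalityRow], label: str, stratum: str = "all") -> dict:
        conv = sum(1 for r in rs if r.converged)
        return {
            "locus": label,
            "stratum": stratum,
            "n": len(rs),
            "converged": conv,
            "fraction": conv / len(rs) if rs else float("nan"),
        }

    out = [tally(usable, "combined")]
    loci = sorted({r.locus for r in usable})
    for loc in loci:
        out.append(tally([r for r in usable if r.locus == loc], loc))
    if strata:
        for name, flags in strata.items():
            for val in (True, False):
                sub = [r for r in usable if flags.get(r.junction_aa, False) is val]
                if sub:
                    out.append(tally(sub, "combined", f"{name}={val}"))
    df = pd.DataFrame(out)
    df.attrs["excluded_no_nt"] = excluded
    if len(loci) == 2:
        t = {
            loc: (
                sum(1 for r in usable if r.locus == loc and r.converged),
                sum(1 for r in usable if r.locus == loc and not r.converged),
            )
            for loc in loci
        }
        res = fisher_enrichment([list(t[loci[0]]), list(t[loci[1]])])
        df.attrs["tra_vs_trb_p"] = res.p_value
    return df


def set_overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[int, float]:
    """Hypergeometric upper-tail test for the overlap of two sets.

    Under the null, ``set_b`` is a uniform draw of its size from a
    universe of ``universe_size`` items containing ``set_a``; the
    returned p is P(overlap >= observed), exact.
    """
    n_a, n_b = len(set_a), len(set_b)
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("universe smaller than a set")
    k = len(set_a & set_b)
    # sf(k-1) = P(X >= k) for X ~ Hypergeom(M=universe, n=|A|, N=|B|)
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_a, n_b))
    return k, min(p, 1.0)


def load_pgen_table(path: str | Path) -> dict[str, float]:
    """Load an externally computed junction -> Pgen table (TSV).

    Expects columns ``junction_aa`` (or ``junction_nt``) and ``pgen``;
    rows with pgen outside (0, 1] are rejected with a logged warning.
    """
    import logging

    df = pd.read_csv(path, sep="\t", dtype={"pgen": float})
    key = "junction_aa" if "junction_aa" in df.columns else "junction_nt"
    if key not in df.columns or "pgen" not in df.columns:
        raise ValueError(f"{path}: need junction_aa/junction_nt and pgen columns")
    bad = (df["pgen"] <= 0) | df["pgen"].isna() | (df["pgen"] > 1)
    if bad.any():
        logging.getLogger(__name__).warning(
            "%s: dropped %d rows with pgen outside (0, 1]", path, int(bad.sum())
        )
    df = df[~bad]
    return dict(zip(df[key].astype(str), df["pgen"].astype(float)))


def compare_pgen(
    pgen: Mapping[str, float], labels: Mapping[str, bool]
) -> dict[str, float]:
    """Compare -log10(Pgen) between matched and non-matched junctions.

    Returns medians per class and a two-sided Wilcoxon rank-sum p.
    Junctions without a Pgen value are ignored.
    """
    m = [-math.log10(pgen[j]) for j in pgen if labels.get(j) is True]
    u = [-math.log10(pgen[j]) for j in pgen if labels.get(j) is False]
    if not m or not u:
        raise ValueError("need Pgen values in both classes")
    if sorted(m) == sorted(u):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(m, u, alternative="two-sided").pvalue)
    return {
        "median_neglog10_matched": float(np.median(m)),
        "median_neglog10_nonmatched": float(np.median(u)),
        "n_matched": len(m),
        "n_nonmatched": len(u),
        "p": p,
    }
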