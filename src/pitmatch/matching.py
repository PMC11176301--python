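"""Edit-distance matching between TCR junction repertoires.

The central operation compares every unique junction in a *query*
repertoire (blood islet-antigen-reactive CD4+ T cells) against a
*reference* repertoire (pancreas-infiltrating T cells, PIT) by
Levenshtein distance.  A TRA junction within distance 1 of any
reference junction is designated "PIT-matched"; a TRB junction is
PIT-matched if it is paired in a cell with a PIT-matched TRA junction.

Distances are exact unit-cost edit distances (substitution, insertion,
deletion each cost 1), computed with the banded dynamic programming of
``edlib`` and pruned by junction length: two strings whose lengths
differ by more than k cannot be within distance k.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .io import Repertoire, normalize_gene

__all__ = [
    "MatchConfig",
    "MatchResult",
    "levenshtein",
    "bounded_levenshtein",
    "match_repertoires",
    "designate_pit_matched",
    "segment_identity",
    "mismatch_positions",
    "match_count_curve",
    "pooled_reference",
]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two amino-acid strings."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def bounded_levenshtein(a: str, b: str, k: int) -> int | None:
    """Edit distance if it is <= k, else None (early abandon)."""
    if abs(len(a) - len(b)) > k:
        return None
    if a == b:
        return 0
    if not a or not b:
        d = max(len(a), len(b))
        return d if d <= k else None
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    return None if d == -1 else d


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters.

    max_distance: junctions farther than this from every reference
        junction are reported as above-threshold (min_distance None).
    cross_locus: allow query and reference loci to differ (used for the
        pooled-reference mode).
    gene_level: "gene" compares V/J names with the allele suffix
        stripped; "allele" compares full names.
    """

    max_distance: int = 1
    cross_locus: bool = False
    gene_level: str = "gene"

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.gene_level not in ("gene", "allele"):
            raise ValueError("gene_level must be 'gene' or 'allele'")


@dataclass
class MatchResult:
    """Minimum-distance match of one query junction against a reference.

    ``min_distance`` is None when the true minimum exceeds the
    configured threshold.  All reference junctions attaining the
    minimum are kept (ties never broken).  ``mismatch_position`` is the
    1-based residue index of the single substitution and is only set
    for length-preserving distance-1 matches with a unique Hamming
    mismatch against at least one hit.
    """

    query_junction_aa: str
    locus: str
    min_distance: int | None
    hits: tuple[str, ...] = ()
    v_identical: bool | None = None
    j_identical: bool | None = None
    mismatch_position: int | None = None
    mismatch_region: str | None = None

    @property
    def matched(self) -> bool:
        return self.min_distance is not None


def _norm_genes(names: Iterable[str], level: str) -> set[str]:
    if level == "allele":
        return {str(n).strip().upper() for n in names if n}
    return {normalize_gene(n) for n in names if n}


def _substitution_position(a: str, b: str) -> int | None:
    """1-based position of the single differing residue, if the two
    equal-length strings differ at exactly one position."""
    if len(a) != len(b):
        return None
    pos = None
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if pos is not None:
                return None
            pos = i + 1
    return pos


def match_repertoires(
    query: Repertoire,
    reference: Repertoire,
    cfg: MatchConfig = MatchConfig(),
) -> list[MatchResult]:
    """Match every unique query junction against a reference repertoire.

    Returns one :class:`MatchResult` per unique query junction, sorted
    by junction string.  Raises ValueError on an empty reference (no
    minimum is definable) or on a locus mismatch unless
    ``cfg.cross_locus`` is set.
    """
    if len(reference) == 0:
        raise ValueError("reference repertoire is empty: minimum distance undefined")
    if len(query) == 0:
        raise ValueError("query repertoire is empty")
    if query.locus != reference.locus and not cfg.cross_locus:
        raise ValueError(
            f"locus mismatch ({query.locus} vs {reference.locus}); "
            "set cross_locus=True to pool"
        )

    ref_exact = set(reference.entries)
    by_len: dict[int, list[str]] = defaultdict(list)
    for r in reference.entries:
        by_len[len(r)].append(r)

    results: list[MatchResult] = []
    for q in sorted(query.entries):
        min_d: int | None = None
        hits: list[str] = []
        if q in ref_exact:
            min_d, hits = 0, [q]
        else:
            for k in range(1, cfg.max_distance + 1):
                for L in range(len(q) - k, len(q) + k + 1):
                    for r in by_len.get(L, ()):
                        if bounded_levenshtein(q, r, k) == k:
                            hits.append(r)
                if hits:
                    min_d = k
                    break
        res = MatchResult(
            query_junction_aa=q,
            locus=query.locus,
            min_distance=min_d,
            hits=tuple(sorted(hits)),
        )
        if min_d is not None:
            qv = _norm_genes(query.entries[q].v_genes, cfg.gene_level)
            qj = _norm_genes(query.entries[q].j_genes, cfg.gene_level)
            hv: set[str] = set()
            hj: set[str] = set()
            for h in hits:
                hv |= _norm_genes(reference.entries[h].v_genes, cfg.gene_level)
                hj |= _norm_genes(reference.entries[h].j_genes, cfg.gene_level)
            res.v_identical = bool(qv & hv) if qv and hv else None
            res.j_identical = bool(qj & hj) if qj and hj else None
            if min_d == 1:
                for h in res.hits:
                    pos = _substitution_position(q, h)
                    if pos is not None:
                        res.mismatch_position = pos
                        break
        results.append(res)
    return results


def designate_pit_matched(
    cells: pd.DataFrame,
    tra_matches: Sequence[MatchResult],
    threshold: int = 1,
) -> pd.DataFrame:
    """Label unique IAR junctions as PIT-matched.

    ``cells`` is a cell-level table with columns cell_id, locus,
    junction_aa (one row per chain).  A TRA junction is PIT-matched iff
    its minimum distance to the reference is <= threshold; a TRB
    junction is PIT-matched iff at least one cell pairs it with a
    PIT-matched TRA junction.  TRB junctions never paired with any TRA
    are labeled non-matched.

    Returns a per-unique-junction frame (junction_aa, locus,
    pit_matched, via).
    """
    dist = {m.query_junction_aa: m.min_distance for m in tra_matches}
    tra_flag = {
        j: (d is not None and d <= threshold) for j, d in dist.items()
    }

    tra_by_cell: dict[str, set[str]] = defaultdict(set)
    trb_by_cell: dict[str, set[str]] = defaultdict(set)
    for row in cells.itertuples(index=False):
        if row.locus == "TRA":
            tra_by_cell[row.cell_id].add(row.junction_aa)
        elif row.locus == "TRB":
            trb_by_cell[row.cell_id].add(row.junction_aa)

    trb_flag: dict[str, bool] = {}
    trb_paired: dict[str, bool] = {}
    for cell_id, trbs in trb_by_cell.items():
        tras = tra_by_cell.get(cell_id, set())
        cell_matched = any(tra_flag.get(t, False) for t in tras)
        for b in trbs:
            trb_paired[b] = trb_paired.get(b, False) or bool(tras)
            trb_flag[b] = trb_flag.get(b, False) or cell_matched

    rows = []
    for j in sorted(tra_flag):
        rows.append({"junction_aa": j, "locus": "TRA", "pit_matched": tra_flag[j], "via": "distance"})
    for j in sorted(trb_flag):
        via = "paired_tra" if trb_paired.get(j) else "unpaired"
        rows.append({"junction_aa": j, "locus": "TRB", "pit_matched": trb_flag[j], "via": via})
    return pd.DataFrame(rows, columns=["junction_aa", "locus", "pit_matched", "via"])


def segment_identity(
    pairs: Sequence[tuple[Mapping[str, object], Mapping[str, object]]],
    level: str = "gene",
) -> pd.DataFrame:
    """Per-pair V/J name identity for matched query/hit junction pairs.

    Each pair is (query, hit) where both carry 'junction_aa',
    'v_genes', 'j_genes' (iterables of names) and optionally
    'min_distance'.  V and J genes are considered identical if they
    have the same name after normalization at the chosen level
    ("any hit" semantics upstream).  Pairs with an absent gene name get
    None and are excluded from summary denominators.
    """
    rows = []
    for q, h in pairs:
        qv, hv = _norm_genes(q.get("v_genes", ()), level), _norm_genes(h.get("v_genes", ()), level)
        qj, hj = _norm_genes(q.get("j_genes", ()), level), _norm_genes(h.get("j_genes", ()), level)
        rows.append(
            {
                "query_junction_aa": q.get("junction_aa"),
                "hit_junction_aa": h.get("junction_aa"),
                "min_distance": q.get("min_distance"),
                "v_identical": bool(qv & hv) if qv and hv else None,
                "j_identical": bool(qj & hj) if qj and hj else None,
            }
        )
    return pd.DataFrame(rows)


def segment_identity_summary(per_pair: pd.DataFrame) -> pd.DataFrame:
    """Fraction of V- and J-identical pairs, separately for Lv0 and Lv1."""
    out = []
    for d in (0, 1):
        sub = per_pair[per_pair["min_distance"] == d]
        for col in ("v_identical", "j_identical"):
            known = sub[col].dropna() if col in sub else pd.Series(dtype=bool)
            out.append(
                {
                    "min_distance": d,
                    "segment": col.split("_")[0].upper(),
                    "n": len(known),
                    "fraction_identical": float(known.mean()) if len(known) else float("nan"),
                }
            )
    return pd.DataFrame(out)


def mismatch_positions(
    pairs: Sequence[tuple[str, str]],
    boundaries: Mapping[str, tuple[int, int]] | None = None,
    boundary_in_germline: bool = False,
) -> pd.DataFrame:
    """Localize single-substitution mismatches and classify their region.

    ``pairs`` are (query, hit) junction strings of equal length at
    Hamming distance 1; length-changing pairs are excluded (counted in
    the 'excluded' attribute of the returned frame); identical pairs
    raise ValueError.  ``boundaries`` maps query junction -> (v_end,
    j_start), 1-based amino-acid indices of the last V-germline and
    first J-germline residue within the junction.  A position is
    V_germline if it lies before the V 3' boundary, J_germline if after
    the J 5' start, else N_region; with ``boundary_in_germline`` the
    boundary residues themselves count as germline.
    """
    rows = []
    excluded = 0
    for q, h in pairs:
        if q == h:
            raise ValueError(f"identical pair {q!r}: no mismatch to localize")
        pos = _substitution_position(q, h)
        if pos is None:
            excluded += 1
            continue
        region = "unknown"
        if boundaries and q in boundaries:
            v_end, j_start = boundaries[q]
            if boundary_in_germline:
                in_v, in_j = pos <= v_end, pos >= j_start
            else:
                in_v, in_j = pos < v_end, pos > j_start
            region = "V_germline" if in_v else ("J_germline" if in_j else "N_region")
        rows.append({"query_junction_aa": q, "hit_junction_aa": h, "position": pos, "region": region})
    df = pd.DataFrame(rows, columns=["query_junction_aa", "hit_junction_aa", "position", "region"])
    df.attrs["excluded_length_changing"] = excluded
    return df


def match_count_curve(
    query: Repertoire,
    reference: Repertoire,
    max_threshold: int,
    cross_locus: bool = False,
) -> list[int]:
    """Cumulative counts of query junctions with min distance <= t.

    Returns counts for t = 0..max_threshold; nondecreasing in t; the
    count at t=0 equals the exact set-intersection size.
    """
    cfg = MatchConfig(max_distance=max_threshold, cross_locus=cross_locus)
    results = match_repertoires(query, reference, cfg)
    counts = []
    for t in range(max_threshold + 1):
        counts.append(sum(1 for r in results if r.min_distance is not None and r.min_distance <= t))
    return counts


def pooled_reference(*reps: Repertoire, locus_label: str = "pooled") -> Repertoire:
    """Pool repertoires (e.g. TRA + TRB references) into one reference.

    Junction strings shared across input repertoires are merged.  Used
    for the mode where matches are scored against the union of
    reference loci rather than within-locus.
    """
    pooled = Repertoire(locus=locus_label, provenance=tuple(p for r in reps for p in r.provenance))
    for rep in reps:
        for j, e in rep.entries.items():
            tgt = pooled.entries.get(j)
            if tgt is None:
                tgt = pooled.entries[j] = type(e)(j)
            tgt.v_genes |= e.v_genes
            tgt.j_genes |= e.j_genes
            tgt.nt_sequences |= e.nt_sequences
            for d, c in e.cells_per_donor.items():
                tgt.cells_per_donor[d] = tgt.cells_per_donor.get(d, 0) + c
    return pooled


def matches_to_frame(results: Sequence[MatchResult], pit_matched: Mapping[str, bool] | None = None) -> pd.DataFrame:
    """Tidy TSV-ready view of match results."""
    rows = []
    for r in results:
        rows.append(
            {
                "query_junction_aa": r.query_junction_aa,
                "locus": r.locus,
                "min_distance": r.min_distance if r.min_distance is not None else "",
                "n_hits": len(r.hits),
                "hits": ",".join(r.hits),
                "v_identical": r.v_identical,
                "j_identical": r.j_identical,
                "mismatch_position": r.mismatch_position if r.mismatch_position else "",
                "mismatch_region": r.mismatch_region or "",
                "pit_matched": pit_matched.get(r.query_junction_aa) if pit_matched else r.matched,
            }
        )
    return pd.DataFrame(rows)
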